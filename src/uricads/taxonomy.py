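"""Pathology taxonomy for ultrasound renal imaging.

The practical taxonomy distinguishes seven categories: healthy (H), four
local pathology groups — cyst (C), pyramid (PYR), hydronephrosis (HYD) and
others (O) — and two global ones — hyper-echoic cortex (HC) and poor
corticomedullary distinction (PCD).  Category index 0 is always the healthy
category, indices ``[1, L]`` are local and ``[L+1, P]`` are global, with
``P = L + G`` total pathologies.

The raw annotation codes form a finer, clinically motivated taxonomy of
eleven pathologies; scarce ones are grouped for training: simple (SCY) and
complicated (CCY) cysts compose the cyst category, and lithiasis (LIT),
angiomyolipoma (ANG), solid renal mass (SRM), cortex thinning (CT) and
cortex eschar (CE) are grouped into "others".
"""

from __future__ import annotations

from dataclasses import dataclass


class UnknownPathologyCode(ValueError):
    """Raised when a raw pathology code is not part of the taxonomy."""


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered category labels: healthy first, then local, then global."""

    healthy_name: str = "H"
    local_names: tuple[str, ...] = ("C", "PYR", "HYD", "O")
    global_names: tuple[str, ...] = ("HC", "PCD")

    @property
    def L(self) -> int:
        """Number of local categories."""
        return len(self.local_names)

    @property
    def G(self) -> int:
        """Number of global categories."""
        return len(self.global_names)

    @property
    def P(self) -> int:
        """Total number of pathologies (local + global)."""
        return self.L + self.G

    @property
    def names(self) -> tuple[str, ...]:
        return (self.healthy_name,) + self.local_names + self.global_names

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown category name: {name!r}") from None

    def is_local(self, k: int) -> bool:
        return 1 <= k <= self.L

    def is_global(self, k: int) -> bool:
        return self.L + 1 <= k <= self.P

    def local_indices(self) -> range:
        return range(1, self.L + 1)

    def global_indices(self) -> range:
        return range(self.L + 1, self.P + 1)


DEFAULT_SCHEME = CategoryScheme()

#: Raw annotation code -> category name in the practical 7-category scheme.
RAW_TO_CATEGORY: dict[str, str] = {
    "H": "H",
    "SCY": "C",
    "CCY": "C",
    "PYR": "PYR",
    "HYD": "HYD",
    "LIT": "O",
    "ANG": "O",
    "SRM": "O",
    "CT": "O",
    "CE": "O",
    "HC": "HC",
    "PCD": "PCD",
}

RAW_CODES = tuple(RAW_TO_CATEGORY)

#: Raw codes that denote local lesions (annotated with bounding boxes).
LOCAL_RAW_CODES = tuple(
    c for c, name in RAW_TO_CATEGORY.items() if name in DEFAULT_SCHEME.local_names
)


def map_raw_to_category(code: str, scheme: CategoryScheme = DEFAULT_SCHEME) -> int:
    """Map a raw pathology code to its category index in ``[0, P]``.

    Parameters
    ----------
    code:
        One of the twelve raw codes (eleven pathologies plus ``"H"``).
    scheme:
        Category scheme defining the index order.

    Raises
    ------
    UnknownPathologyCode
        If ``code`` is not part of the raw taxonomy.
    """
    try:
        name = RAW_TO_CATEGORY[code]
    except (KeyError, TypeError):
        raise UnknownPathologyCode(f"unknown raw pathology code: {code!r}") from None
    return scheme.index(name)
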