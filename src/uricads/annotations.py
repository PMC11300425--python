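"""Case annotations: data model, JSON I/O and polygon rasterization.

Each clinical case is one B-mode image with a polygonal kidney delineation,
indicators for the global pathologies, and bounding boxes with raw codes for
the local lesions.  Coordinates are 0-based pixel indices; boxes are
half-open ``[x_min, x_max) x [y_min, y_max)`` and stored on disk in the
order ``[x_min, x_max, y_min, y_max]``.

On-disk format (JSON): a top-level list of objects ::

    {"image": "case_0001.png", "size": [H, W], "healthy": false,
     "global": {"HC": false, "PCD": true},
     "kidney_polygon": [[x, y], ...],
     "lesions": [{"box": [xmin, xmax, ymin, ymax], "code": "SCY"}]}
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .taxonomy import CategoryScheme, DEFAULT_SCHEME, map_raw_to_category


class AnnotationError(ValueError):
    """Malformed annotation record; message names the record and field."""


@dataclass
class Lesion:
    """One local lesion: half-open box (x_min, x_max, y_min, y_max) + raw code."""

    box: tuple[float, float, float, float]
    code: str

    @property
    def width(self) -> float:
        return self.box[1] - self.box[0]

    @property
    def height(self) -> float:
        return self.box[3] - self.box[2]

    @property
    def area(self) -> float:
        return self.width * self.height

    def category(self, scheme: CategoryScheme = DEFAULT_SCHEME) -> int:
        return map_raw_to_category(self.code, scheme)


@dataclass
class CaseAnnotation:
    """Ground truth for one clinical case (all three network branches)."""

    image_id: str
    size: tuple[int, int]  # (H, W)
    healthy: bool
    global_flags: dict[str, bool]
    kidney_polygon: np.ndarray  # (V, 2) array of (x, y) vertices
    lesions: list[Lesion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kidney_polygon = np.asarray(self.kidney_polygon, dtype=float)

    def validate(self, scheme: CategoryScheme = DEFAULT_SCHEME) -> None:
        H, W = self.size
        poly = self.kidney_polygon
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise AnnotationError(
                f"{self.image_id}: kidney_polygon must have >= 3 (x, y) vertices"
            )
        if not np.all(np.isfinite(poly)):
            raise AnnotationError(f"{self.image_id}: non-finite polygon vertex")
        for name in scheme.global_names:
            if name not in self.global_flags:
                raise AnnotationError(
                    f"{self.image_id}: missing global flag {name!r}"
                )
        for i, les in enumerate(self.lesions):
            xmin, xmax, ymin, ymax = les.box
            if not (xmin < xmax and ymin < ymax):
                raise AnnotationError(
                    f"{self.image_id}: lesion {i} has an empty box {les.box}"
                )
            if xmin < 0 or ymin < 0 or xmax > W or ymax > H:
                raise AnnotationError(
                    f"{self.image_id}: lesion {i} box {les.box} outside "
                    f"image bounds (H={H}, W={W})"
                )
            map_raw_to_category(les.code, scheme)
        if self.healthy and (any(self.global_flags.values()) or self.lesions):
            raise AnnotationError(
                f"{self.image_id}: healthy case must have no pathologies"
            )

    # -- label vectors -------------------------------------------------------

    def multihot(self, scheme: CategoryScheme = DEFAULT_SCHEME) -> np.ndarray:
        """Multi-hot target vector of length P+1 (healthy, locals, globals)."""
        y = np.zeros(scheme.P + 1)
        if self.healthy:
            y[0] = 1.0
        for les in self.lesions:
            y[les.category(scheme)] = 1.0
        for name, flag in self.global_flags.items():
            if flag:
                y[scheme.index(name)] = 1.0
        return y

    def kidney_mask(self) -> np.ndarray:
        return rasterize_polygon(self.kidney_polygon, *self.size)


# -- JSON I/O ---------------------------------------------------------------


def _ann_to_obj(ann: CaseAnnotation) -> dict:
    return {
        "image": ann.image_id,
        "size": [int(ann.size[0]), int(ann.size[1])],
        "healthy": bool(ann.healthy),
        "global": {k: bool(v) for k, v in ann.global_flags.items()},
        "kidney_polygon": [[float(x), float(y)] for x, y in ann.kidney_polygon],
        "lesions": [
            {"box": [float(v) for v in les.box], "code": les.code}
            for les in ann.lesions
        ],
    }


def _obj_to_ann(obj: dict, index: int) -> CaseAnnotation:
    for key in ("image", "size", "healthy", "global", "kidney_polygon", "lesions"):
        if key not in obj:
            raise AnnotationError(f"record {index}: missing required key {key!r}")
    lesions = []
    for j, lobj in enumerate(obj["lesions"]):
        if "box" not in lobj or "code" not in lobj:
            raise AnnotationError(
                f"record {index}: lesion {j} missing 'box' or 'code'"
            )
        lesions.append(Lesion(box=tuple(float(v) for v in lobj["box"]),
                              code=str(lobj["code"])))
    ann = CaseAnnotation(
        image_id=str(obj["image"]),
        size=(int(obj["size"][0]), int(obj["size"][1])),
        healthy=bool(obj["healthy"]),
        global_flags={k: bool(v) for k, v in obj["global"].items()},
        kidney_polygon=np.asarray(obj["kidney_polygon"], dtype=float),
        lesions=lesions,
    )
    try:
        ann.validate()
    except AnnotationError as err:
        raise AnnotationError(f"record {index}: {err}") from None
    return ann


def write_annotations(annotations: list[CaseAnnotation], path: str | Path) -> None:
    for ann in annotations:
        ann.validate()
    payload = [_ann_to_obj(a) for a in annotations]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path: str | Path) -> list[CaseAnnotation]:
    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, list):
        raise AnnotationError("annotation file must contain a top-level list")
    return [_obj_to_ann(obj, i) for i, obj in enumerate(payload)]


# -- rasterization ----------------------------------------------------------


def rasterize_polygon(polygon: np.ndarray, H: int, W: int) -> np.ndarray:
    """Rasterize an (x, y) polygon to a binary ``H x W`` mask.

    A pixel ``(row r, col c)`` is set iff its center ``(c + 0.5, r + 0.5)``
    lies inside the polygon under the even-odd (crossing-number) rule.
    Deterministic; a zero-area polygon yields an empty mask with a warning.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise AnnotationError("polygon must be an (V>=3, 2) array of (x, y)")
    if not np.all(np.isfinite(poly)):
        raise AnnotationError("polygon vertices must be finite")
    if H < 1 or W < 1:
        raise ValueError("H and W must be >= 1")

    cx = np.arange(W) + 0.5
    cy = np.arange(H) + 0.5
    gx = cx[None, :]  # (1, W)
    gy = cy[:, None]  # (H, 1)
    inside = np.zeros((H, W), dtype=bool)
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue  # horizontal edge never crosses a horizontal ray
        crosses_y = (ey1 > gy) != (ey2 > gy)
        x_at_y = ex1 + (gy - ey1) * (ex2 - ex1) / (ey2 - ey1)
        inside ^= crosses_y & (gx < x_at_y)
    mask = inside.astype(np.uint8)
    if mask.sum() == 0:
        shoelace = 0.5 * abs(np.sum(x1 * y2 - x2 * y1))
        if shoelace == 0.0:
            warnings.warn("degenerate (zero-area) polygon rasterized to empty mask")
    return mask


def polygon_area(polygon: np.ndarray) -> float:
    """Shoelace area of an (x, y) polygon."""
    poly = np.asarray(polygon, dtype=float)
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
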