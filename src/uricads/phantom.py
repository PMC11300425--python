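"""Synthetic B-mode kidney phantoms with exact annotations.

Each phantom is a grayscale image holding one kidney rendered as two
concentric ellipses: a darker outer cortex and a brighter inner sinus, on a
dark background (background < cortex < sinus for a healthy kidney).
Pathologies are painted with the echogenicity cues a sonographer would
look for:

* cyst (C)            — dark (hypo-echoic), uniform, roughly spherical spot
                        inside the kidney;
* pyramid (PYR)       — small hypo-echoic wedge at the cortex/sinus
                        interface;
* hydronephrosis (HYD)— enlarged hypo-echoic core in the renal sinus;
* others (O)          — bright (hyper-echoic) focus; lithiasis-type foci
                        additionally cast a darkened vertical shadow band
                        below them, mimicking an acoustic shadow;
* hyper-echoic cortex (HC)      — global cortex brightening, lowering the
                        cortex/sinus contrast;
* poor corticomedullary
  distinction (PCD)   — cortex and sinus intensities pulled together.

Speckle is modeled as multiplicative Rayleigh noise followed by a light
Gaussian smoothing — the canonical desk-scale approximation of B-mode
speckle.  Annotations are exact by construction: the kidney polygon is the
sampled ellipse boundary, and every planted lesion records its tight
bounding box and a raw pathology code.  The phantoms aim at testability of
the pipeline, not physical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .annotations import CaseAnnotation, Lesion, rasterize_polygon, write_annotations
from .taxonomy import DEFAULT_SCHEME


class LesionPlacementError(RuntimeError):
    """No valid in-kidney placement found within the retry budget."""


@dataclass
class PhantomConfig:
    """Rendering recipe for one phantom (intensities in [0, 1])."""

    height: int = 96
    width: int = 96
    background: float = 0.10
    cortex: float = 0.45
    sinus: float = 0.75
    sinus_scale: float = 0.55      # sinus semi-axes as a fraction of kidney's
    speckle: float = 0.25          # multiplicative noise strength
    smoothing_sigma: float = 0.6
    # kidney geometry; None -> sampled from the seeded rng
    center: tuple[float, float] | None = None
    semi_axes: tuple[float, float] | None = None
    rotation_deg: float | None = None
    # pathology recipe
    hc: bool = False
    hc_factor: float = 1.5         # cortex brightening under HC
    pcd: bool = False
    pcd_factor: float = 0.15       # residual cortex/sinus gap under PCD
    lesions: tuple = ()            # tuples of (type in {C, PYR, HYD, O}, count)
    polygon_vertices: int = 48
    seed: int = 0

    @property
    def healthy(self) -> bool:
        return not (self.hc or self.pcd or self.lesions)


def _ellipse_polygon(center, semi_axes, rotation, n) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    a, b = semi_axes
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = np.cos(rotation), np.sin(rotation)
    return np.stack([center[0] + c * x - s * y, center[1] + s * x + c * y], axis=1)


def _sample_geometry(cfg: PhantomConfig, rng: np.random.Generator):
    H, W = cfg.height, cfg.width
    a = cfg.semi_axes[0] if cfg.semi_axes else rng.uniform(0.28, 0.36) * W
    b = cfg.semi_axes[1] if cfg.semi_axes else rng.uniform(0.20, 0.27) * H
    cx = cfg.center[0] if cfg.center else W / 2 + rng.uniform(-0.05, 0.05) * W
    cy = cfg.center[1] if cfg.center else H / 2 + rng.uniform(-0.05, 0.05) * H
    rot = (np.deg2rad(cfg.rotation_deg) if cfg.rotation_deg is not None
           else rng.uniform(-0.4, 0.4))
    if a >= W / 2 or b >= H / 2:
        raise ValueError("kidney semi-axes must fit inside the image")
    return (cx, cy), (a, b), rot


def _paint_disk(img, cx, cy, r, value):
    H, W = img.shape
    yy, xx = np.mgrid[0:H, 0:W]
    disk = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r * r
    img[disk] = value
    return disk


def _tight_box(mask: np.ndarray) -> tuple[float, float, float, float]:
    ys, xs = np.nonzero(mask)
    return (float(xs.min()), float(xs.max() + 1),
            float(ys.min()), float(ys.max() + 1))


def render_noise_free(cfg: PhantomConfig) -> tuple[np.ndarray, CaseAnnotation]:
    """Deterministic noise-free render with its exact annotation."""
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.height, cfg.width
    center, axes, rot = _sample_geometry(cfg, rng)
    polygon = _ellipse_polygon(center, axes, rot, cfg.polygon_vertices)
    kidney = rasterize_polygon(polygon, H, W).astype(bool)
    sinus_axes = (axes[0] * cfg.sinus_scale, axes[1] * cfg.sinus_scale)
    sinus_poly = _ellipse_polygon(center, sinus_axes, rot, cfg.polygon_vertices)
    sinus = rasterize_polygon(sinus_poly, H, W).astype(bool)

    cortex_val, sinus_val = cfg.cortex, cfg.sinus
    if cfg.hc:
        cortex_val = min(cortex_val * cfg.hc_factor, 1.0)
    if cfg.pcd:
        mid = (cfg.cortex + cfg.sinus) / 2.0
        gap = (cfg.sinus - cfg.cortex) * cfg.pcd_factor
        cortex_val, sinus_val = mid - gap / 2.0, mid + gap / 2.0

    img = np.full((H, W), cfg.background)
    img[kidney] = cortex_val
    img[sinus & kidney] = sinus_val

    lesion_records: list[Lesion] = []
    for ltype, count in cfg.lesions:
        for _ in range(count):
            lesion_records.append(
                _plant_lesion(img, ltype, kidney, sinus, center, axes, rot, rng)
            )

    global_flags = {"HC": bool(cfg.hc), "PCD": bool(cfg.pcd)}
    ann = CaseAnnotation(
        image_id=f"phantom_{cfg.seed:08d}",
        size=(H, W),
        healthy=cfg.healthy,
        global_flags=global_flags,
        kidney_polygon=polygon,
        lesions=lesion_records,
    )
    ann.validate()
    return np.clip(img, 0.0, 1.0), ann


def _plant_lesion(img, ltype, kidney, sinus, center, axes, rot, rng,
                  max_tries: int = 60) -> Lesion:
    H, W = img.shape
    if ltype == "HYD":
        # enlarged hypo-echoic sinus core, centered by construction
        core_axes = (axes[0] * 0.45, axes[1] * 0.45)
        poly = _ellipse_polygon(center, core_axes, rot, 40)
        core = rasterize_polygon(poly, H, W).astype(bool) & kidney
        img[core] = 0.16
        return Lesion(box=_tight_box(core), code="HYD")

    for _ in range(max_tries):
        if ltype == "C":
            r = rng.uniform(4.5, 8.0)
            t = rng.uniform(0, 2 * np.pi)
            u = np.sqrt(rng.uniform(0.0, 0.45))
            cx = center[0] + u * axes[0] * np.cos(t)
            cy = center[1] + u * axes[1] * np.sin(t)
            candidate = _disk_mask(img.shape, cx, cy, r)
            value, code = 0.15, rng.choice(["SCY", "CCY"])
        elif ltype == "PYR":
            # wedge at the cortex/sinus interface
            r = rng.uniform(3.0, 5.0)
            t = rng.uniform(0, 2 * np.pi)
            ex, ey = 0.62 * axes[0] * np.cos(t), 0.62 * axes[1] * np.sin(t)
            cx = center[0] + np.cos(rot) * ex - np.sin(rot) * ey
            cy = center[1] + np.sin(rot) * ex + np.cos(rot) * ey
            candidate = _disk_mask(img.shape, cx, cy, r)
            value, code = 0.20, "PYR"
        elif ltype == "O":
            r = rng.uniform(3.0, 5.0)
            t = rng.uniform(0, 2 * np.pi)
            u = np.sqrt(rng.uniform(0.0, 0.4))
            cx = center[0] + u * axes[0] * np.cos(t)
            cy = center[1] + u * axes[1] * np.sin(t)
            candidate = _disk_mask(img.shape, cx, cy, r)
            value, code = 0.95, rng.choice(["LIT", "ANG"])
        else:
            raise ValueError(f"unknown lesion type: {ltype!r}")
        if candidate.sum() == 0:
            continue
        inside = (candidate & kidney).sum() / candidate.sum()
        if inside >= 0.95:
            img[candidate] = value
            box = _tight_box(candidate)
            if code == "LIT":
                _cast_shadow(img, box)
            return Lesion(box=box, code=code)
    raise LesionPlacementError(f"could not place lesion of type {ltype!r}")


def _disk_mask(shape, cx, cy, r):
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    return (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r * r


def _cast_shadow(img, box, attenuation: float = 0.5):
    """Darkened vertical band below a bright lithiasis focus."""
    xmin, xmax, ymin, ymax = (int(round(v)) for v in box)
    img[ymax:, xmin:xmax] *= attenuation


def apply_speckle(image: np.ndarray, strength: float, sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Rayleigh speckle plus Gaussian smoothing."""
    if strength <= 0:
        return image.copy()
    noise = rng.rayleigh(scale=1.0, size=image.shape) / np.sqrt(np.pi / 2.0)
    speckled = image * (1.0 - strength + strength * noise)
    return np.clip(ndimage.gaussian_filter(speckled, sigma), 0.0, 1.0)


def generate_phantom(cfg: PhantomConfig) -> tuple[np.ndarray, CaseAnnotation]:
    """Render one speckled phantom and its annotation (seed-deterministic)."""
    clean, ann = render_noise_free(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD05E]))
    return apply_speckle(clean, cfg.speckle, cfg.smoothing_sigma, rng), ann


#: Default study mixture over phantom conditions.
DEFAULT_MIXTURE = {
    "healthy": 0.40, "C": 0.15, "PYR": 0.10, "HYD": 0.10,
    "O": 0.10, "HC": 0.075, "PCD": 0.075,
}


def config_for_condition(condition: str, seed: int,
                         base: PhantomConfig | None = None,
                         rng: np.random.Generator | None = None) -> PhantomConfig:
    base = base or PhantomConfig()
    rng = rng or np.random.default_rng(seed)
    if condition == "healthy":
        return replace(base, seed=seed, hc=False, pcd=False, lesions=())
    if condition == "HC":
        return replace(base, seed=seed, hc=True, pcd=False, lesions=())
    if condition == "PCD":
        return replace(base, seed=seed, hc=False, pcd=True, lesions=())
    if condition in ("C", "PYR", "HYD", "O"):
        count = 1 if condition == "HYD" else int(rng.integers(1, 3))
        return replace(base, seed=seed, hc=False, pcd=False,
                       lesions=((condition, count),))
    raise ValueError(f"unknown phantom condition: {condition!r}")


def sample_dataset(
    n: int,
    seed: int = 0,
    mixture: dict[str, float] | None = None,
    base: PhantomConfig | None = None,
) -> tuple[list[np.ndarray], list[CaseAnnotation]]:
    """Draw ``n`` phantoms in memory from a condition mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mixture = dict(mixture or DEFAULT_MIXTURE)
    names = sorted(mixture)
    weights = np.array([mixture[k] for k in names], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    master = np.random.default_rng(seed)
    images, anns = [], []
    for i in range(n):
        condition = names[master.choice(len(names), p=weights)]
        case_seed = int(master.integers(0, 2**31 - 1))
        cfg = config_for_condition(condition, case_seed, base, master)
        img, ann = generate_phantom(cfg)
        ann.image_id = f"phantom_{i:05d}"
        images.append(img)
        anns.append(ann)
    return images, anns


def generate_dataset(
    n: int,
    out_dir: str | Path,
    seed: int = 0,
    mixture: dict[str, float] | None = None,
    base: PhantomConfig | None = None,
) -> Path:
    """Write ``n`` phantom PNGs and an annotation JSON; returns the JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, anns = sample_dataset(n, seed, mixture, base)
    for img, ann in zip(images, anns):
        fname = f"{ann.image_id}.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(out / fname)
        ann.image_id = fname
    ann_path = out / "annotations.json"
    write_annotations(anns, ann_path)
    return ann_path
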