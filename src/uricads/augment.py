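"""Seeded data augmentation applied jointly to image and annotation.

Four operations, each applied with an independent probability: rotation,
gamma adjustment, translation, and zoom.  Geometric operations use one
composed affine map applied identically to the image (bilinear warp), the
kidney polygon, and the lesion boxes (boxes are re-tightened to the
axis-aligned hull of their four transformed corners and clipped to the
frame).  Gamma only rescales intensities.  If a transform pushes the
kidney fully out of frame the pair is returned untouched with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from .annotations import CaseAnnotation, Lesion


@dataclass
class AugmentSpec:
    """Augmentation ranges; every range includes the identity transform."""

    rotation_deg: float = 15.0         # rotation ~ U(-r, r)
    gamma_range: tuple[float, float] = (0.8, 1.25)
    translate_frac: float = 0.10       # shift ~ U(-f, f) * side, per axis
    zoom_range: tuple[float, float] = (0.9, 1.1)
    prob: float = 0.5                  # per-operation application probability


@dataclass
class AugmentResult:
    image: np.ndarray
    annotation: CaseAnnotation
    skipped: bool = False              # kidney left the frame; identity returned


def _compose_affine(H, W, angle_rad, scale, shift) -> AffineTransform:
    cx, cy = W / 2.0, H / 2.0
    to_center = AffineTransform(translation=(-cx, -cy))
    rot_zoom = AffineTransform(rotation=angle_rad, scale=(scale, scale))
    back = AffineTransform(translation=(cx + shift[0], cy + shift[1]))
    return AffineTransform(matrix=back.params @ rot_zoom.params @ to_center.params)


def augment(
    image: np.ndarray,
    annotation: CaseAnnotation,
    spec: AugmentSpec,
    rng: np.random.Generator | int = 0,
) -> AugmentResult:
    """Apply one random draw of the augmentation pipeline to a case."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    H, W = annotation.size

    angle = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg)) \
        if rng.random() < spec.prob else 0.0
    scale = rng.uniform(*spec.zoom_range) if rng.random() < spec.prob else 1.0
    if rng.random() < spec.prob:
        shift = (rng.uniform(-spec.translate_frac, spec.translate_frac) * W,
                 rng.uniform(-spec.translate_frac, spec.translate_frac) * H)
    else:
        shift = (0.0, 0.0)
    gamma = rng.uniform(*spec.gamma_range) if rng.random() < spec.prob else 1.0

    tf = _compose_affine(H, W, angle, scale, shift)
    identity_geometry = angle == 0.0 and scale == 1.0 and shift == (0.0, 0.0)

    if identity_geometry:
        new_image = np.asarray(image, dtype=float).copy()
        new_poly = annotation.kidney_polygon.copy()
        new_lesions = [Lesion(box=l.box, code=l.code) for l in annotation.lesions]
    else:
        new_image = warp(np.asarray(image, dtype=float), tf.inverse, order=1,
                         mode="constant", cval=0.0, preserve_range=True)
        new_poly = tf(annotation.kidney_polygon)
        if not _polygon_touches_frame(new_poly, H, W):
            return AugmentResult(np.asarray(image, dtype=float).copy(),
                                 annotation, skipped=True)
        new_lesions = []
        for les in annotation.lesions:
            xmin, xmax, ymin, ymax = les.box
            corners = np.array([[xmin, ymin], [xmin, ymax],
                                [xmax, ymin], [xmax, ymax]])
            tc = tf(corners)
            box = (max(tc[:, 0].min(), 0.0), min(tc[:, 0].max(), float(W)),
                   max(tc[:, 1].min(), 0.0), min(tc[:, 1].max(), float(H)))
            if box[0] >= box[1] or box[2] >= box[3]:
                continue  # lesion left the frame entirely
            new_lesions.append(Lesion(box=box, code=les.code))

    if gamma != 1.0:
        new_image = np.clip(new_image, 0.0, 1.0) ** gamma

    new_ann = CaseAnnotation(
        image_id=annotation.image_id,
        size=annotation.size,
        healthy=annotation.healthy,
        global_flags=dict(annotation.global_flags),
        kidney_polygon=new_poly,
        lesions=new_lesions,
    )
    return AugmentResult(new_image, new_ann, skipped=False)


def _polygon_touches_frame(poly: np.ndarray, H: int, W: int) -> bool:
    return bool(
        (poly[:, 0].max() > 0) and (poly[:, 0].min() < W)
        and (poly[:, 1].max() > 0) and (poly[:, 1].min() < H)
    )
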