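"""Three-branch segmentation / classification / detection network.

A shared multi-scale backbone computes four feature maps ``T_l`` at strides
2, 4, 8 and 16 with ``C_l = width_base * 2**l`` channels (the default width
base 128 gives the 256/512/1024/2048 schedule of a ResNet-50-style
backbone; the ``tiny`` profile keeps the stride schedule at a fraction of
the width for CPU-scale runs).  Two independent feature pyramids with a
fixed channel count ``C`` transform the backbone maps, one feeding the
kidney segmentation branch and one the local-pathology detection branch.
The image-level classification head reads the top backbone tensor ``T_4``
directly (global average pooling + one linear map + per-category sigmoid),
so it sees the full image context rather than a kidney RoI — surrounding
tissue carries diagnostic contrast cues.

For each case the network emits a triplet:

* ``K`` — binary kidney mask at input resolution (highest-scoring
  candidate kept; a no-detection flag accompanies an empty mask),
* ``p_image`` — length-(P+1) multi-label probability vector,
* ``R`` — an (N, 6) stack of region descriptors
  ``[x_min, x_max, y_min, y_max, id, s]`` for detections whose score
  survives non-maximum suppression and the score threshold.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .nn import Conv2d, Linear, Module, Tensor, upsample2x
from .taxonomy import CategoryScheme, DEFAULT_SCHEME


# -- configuration ----------------------------------------------------------


@dataclass
class ModelConfig:
    """Architecture and inference-time settings."""

    width_base: int = 128          # backbone channels: C_l = width_base * 2**l
    fpn_channels: int = 256        # shared pyramid channel count C
    n_local: int = 4
    n_global: int = 2
    score_threshold: float = 0.5   # region survival threshold on s_n
    nms_iou: float = 0.5
    seg_threshold: float = 0.5     # soft-mask binarization (boundary included)
    anchor_sizes: tuple = (12, 24)
    detect_level: int = 2          # pyramid level feeding the detection head
    seed: int = 0

    @classmethod
    def tiny(cls, seed: int = 0) -> "ModelConfig":
        """Reduced-width profile with the full stride schedule."""
        return cls(width_base=4, fpn_channels=16, seed=seed)

    @property
    def scheme(self) -> CategoryScheme:
        scheme = DEFAULT_SCHEME
        if (scheme.L, scheme.G) != (self.n_local, self.n_global):
            raise ValueError("non-default taxonomies need a custom CategoryScheme")
        return scheme

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["anchor_sizes"] = list(self.anchor_sizes)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["anchor_sizes"] = tuple(d.get("anchor_sizes", (12, 24)))
        return cls(**d)

    def digest(self) -> str:
        d = asdict(self)
        d["anchor_sizes"] = list(self.anchor_sizes)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


# -- triplet ----------------------------------------------------------------


@dataclass
class CaseTriplet:
    """Per-case network output: mask K, image scores p_image, regions R."""

    mask: np.ndarray              # (H, W) uint8
    kidney_found: bool
    p_image: np.ndarray           # (P+1,)
    regions: np.ndarray           # (N, 6)


# -- building blocks --------------------------------------------------------


class _Stage(Module):
    """One backbone stage: strided 3x3 conv + 3x3 conv, both ReLU."""

    def __init__(self, c_in, c_out, rng):
        self.down = Conv2d(c_in, c_out, 3, stride=2, rng=rng)
        self.conv = Conv2d(c_out, c_out, 3, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(self.down(x).relu()).relu()


class Backbone(Module):
    """Four-stage strided backbone: T_l at stride 2**l, C_l = base * 2**l."""

    def __init__(self, width_base: int, rng, in_channels: int = 3):
        chans = [width_base * 2 ** l for l in range(1, 5)]
        self.stages = [
            _Stage(in_channels, chans[0], rng),
            _Stage(chans[0], chans[1], rng),
            _Stage(chans[1], chans[2], rng),
            _Stage(chans[2], chans[3], rng),
        ]
        self.channels = chans

    def __call__(self, x: Tensor) -> dict[int, Tensor]:
        maps = {}
        for l, stage in enumerate(self.stages, start=1):
            x = stage(x)
            maps[l] = x
        return maps


class FPN(Module):
    """Top-down feature pyramid with a fixed channel count across scales."""

    def __init__(self, in_channels: list[int], out_channels: int, rng):
        self.laterals = [Conv2d(c, out_channels, 1, pad=0, rng=rng)
                         for c in in_channels]
        self.smooth = [Conv2d(out_channels, out_channels, 3, rng=rng)
                       for _ in in_channels]

    def __call__(self, T: dict[int, Tensor]) -> dict[int, Tensor]:
        lat = {l: self.laterals[l - 1](T[l]) for l in T}
        top = max(T)
        merged = {top: lat[top]}
        for l in sorted(T)[-2::-1]:
            merged[l] = lat[l] + upsample2x(merged[l + 1])
        return {l: self.smooth[l - 1](merged[l]) for l in T}


# -- box utilities ----------------------------------------------------------


def box_iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of half-open boxes in (x_min, x_max, y_min, y_max) order."""
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    ix = (np.minimum(a[:, None, 1], b[None, :, 1])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0.0)
    iy = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 2], b[None, :, 2])).clip(min=0.0)
    inter = ix * iy
    area_a = (a[:, 1] - a[:, 0]) * (a[:, 3] - a[:, 2])
    area_b = (b[:, 1] - b[:, 0]) * (b[:, 3] - b[:, 2])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices (descending score)."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    boxes = np.asarray(boxes, dtype=float)
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        ious = box_iou_matrix(boxes[i], boxes[rest])[0]
        order = rest[ious <= iou_threshold]
    return np.asarray(keep, dtype=int)


# -- the network ------------------------------------------------------------


class SCDCNN(Module):
    """Shared backbone, two FPNs and the three task branches."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        self.scheme = cfg.scheme
        rng = np.random.default_rng(cfg.seed)
        C = cfg.fpn_channels
        self.backbone = Backbone(cfg.width_base, rng)
        self.fpn_image = FPN(self.backbone.channels, C, rng)
        self.fpn_region = FPN(self.backbone.channels, C, rng)
        # image-level multi-label head on T_4
        self.cls_head = Linear(self.backbone.channels[-1], self.scheme.P + 1,
                               rng=rng)
        # dense segmentation head on the finest image-pyramid level
        self.seg_conv = Conv2d(C, C, 3, rng=rng)
        self.seg_out = Conv2d(C, 1, 1, pad=0, rng=rng)
        # dense anchor head on the detection pyramid level
        A, L = len(cfg.anchor_sizes), self.scheme.L
        self.det_conv = Conv2d(C, C, 3, rng=rng)
        self.det_cls = Conv2d(C, A * L, 1, pad=0, rng=rng)
        self.det_box = Conv2d(C, A * 4, 1, pad=0, rng=rng)
        # bias detection toward background so early training is quiet
        self.det_cls.bias.data[:] = -3.0

    # -- forward pieces ------------------------------------------------------

    @staticmethod
    def _to_tensor(image: np.ndarray) -> Tensor:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 2:
            img = np.repeat(img[None], 3, axis=0)  # replicate grayscale
        if img.shape[-1] % 16 or img.shape[-2] % 16 or min(img.shape[-2:]) < 32:
            raise ValueError("image sides must be >= 32 and divisible by 16")
        return Tensor(img)

    def backbone_forward(self, image: np.ndarray) -> dict[int, Tensor]:
        """Multi-scale representation T_l, l = 1..4."""
        return self.backbone(self._to_tensor(image))

    def fpn_forward(self, T: dict[int, Tensor], role: str) -> dict[int, Tensor]:
        if role == "image":
            return self.fpn_image(T)
        if role == "region":
            return self.fpn_region(T)
        raise ValueError(f"unknown FPN role: {role!r}")

    def classify_logits(self, T4: Tensor) -> Tensor:
        pooled = T4.mean_spatial().reshape(1, -1)
        return self.cls_head(pooled).reshape(-1)

    def classify_image(self, T4: Tensor) -> np.ndarray:
        """Length-(P+1) multi-label probabilities from the top backbone map."""
        return self.classify_logits(T4).sigmoid().data.copy()

    def seg_logits(self, F_image: dict[int, Tensor]) -> Tensor:
        x = self.seg_conv(F_image[1]).relu()
        return upsample2x(self.seg_out(x)).reshape(
            F_image[1].shape[-2] * 2, F_image[1].shape[-1] * 2
        )

    def segment_kidney(self, F_image: dict[int, Tensor]) -> tuple[np.ndarray, bool]:
        """Binary kidney mask at input resolution plus a detection flag.

        The soft mask is binarized at the configured threshold (boundary
        value included); among connected candidate components the one with
        the highest peak probability is kept as the single kidney instance.
        """
        prob = self.seg_logits(F_image).sigmoid().data
        return select_kidney_component(prob, self.config.seg_threshold)

    def det_maps(self, F_region: dict[int, Tensor]) -> tuple[Tensor, Tensor]:
        x = self.det_conv(F_region[self.config.detect_level]).relu()
        return self.det_cls(x), self.det_box(x)

    def anchors(self, h: int, w: int) -> np.ndarray:
        """(A*h*w, 4) anchor boxes on the detection grid, image coordinates."""
        stride = 2 ** self.config.detect_level
        cx = (np.arange(w) + 0.5) * stride
        cy = (np.arange(h) + 0.5) * stride
        boxes = []
        for size in self.config.anchor_sizes:
            gx, gy = np.meshgrid(cx, cy)
            half = size / 2.0
            boxes.append(np.stack(
                [gx - half, gx + half, gy - half, gy + half], axis=-1
            ).reshape(-1, 4))
        return np.concatenate(boxes, axis=0)

    def detect_regions(
        self,
        F_region: dict[int, Tensor],
        threshold: float | None = None,
        image_shape: tuple[int, int] | None = None,
    ) -> np.ndarray:
        """Region descriptors (N, 6) surviving NMS and the score threshold."""
        regions, _ = self.detect_regions_indexed(F_region, threshold, image_shape)
        return regions

    def detect_regions_indexed(self, F_region, threshold=None, image_shape=None):
        cfg = self.config
        threshold = cfg.score_threshold if threshold is None else threshold
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        cls_map, box_map = self.det_maps(F_region)
        A, L = len(cfg.anchor_sizes), self.scheme.L
        h, w = cls_map.shape[-2:]
        probs = _stable_sigmoid(cls_map.data.reshape(A, L, h, w))
        deltas = box_map.data.reshape(A, 4, h, w)
        anchors = self.anchors(h, w)
        if image_shape is None:
            stride = 2 ** cfg.detect_level
            image_shape = (h * stride, w * stride)
        return decode_detections(
            probs, deltas, anchors, image_shape, threshold, cfg.nms_iou
        )

    # -- whole case ----------------------------------------------------------

    def forward_case(self, image: np.ndarray,
                     threshold: float | None = None) -> CaseTriplet:
        """Single shared-backbone pass producing the {K, p_image, R} triplet."""
        img = np.asarray(image, dtype=float)
        T = self.backbone_forward(img)
        F_img = self.fpn_forward(T, "image")
        F_reg = self.fpn_forward(T, "region")
        mask, found = self.segment_kidney(F_img)
        p_image = self.classify_image(T[4])
        regions = self.detect_regions(F_reg, threshold, img.shape[-2:])
        return CaseTriplet(mask=mask, kidney_found=found,
                           p_image=p_image, regions=regions)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        cfg = asdict(self.config)
        cfg["anchor_sizes"] = list(self.config.anchor_sizes)
        np.savez(path, __config__=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SCDCNN":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            cfg["anchor_sizes"] = tuple(cfg["anchor_sizes"])
            model = cls(ModelConfig(**cfg))
            arrays = [data[f"param_{i}"]
                      for i in range(len(model.parameters()))]
        model.load_state_arrays(arrays)
        return model


# -- inference helpers (pure numpy) -----------------------------------------


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def select_kidney_component(prob: np.ndarray,
                            threshold: float = 0.5) -> tuple[np.ndarray, bool]:
    """Binarize a soft kidney map and keep the highest-scoring component."""
    binary = prob >= threshold
    if not binary.any():
        return np.zeros_like(prob, dtype=np.uint8), False
    labels, n = ndimage.label(binary)
    scores = ndimage.maximum(prob, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(scores)) + 1
    return (labels == best).astype(np.uint8), True


def decode_detections(probs, deltas, anchors, image_shape, threshold, nms_iou):
    """Decode anchor maps into surviving region descriptors.

    ``probs``: (A, L, h, w) class probabilities; ``deltas``: (A, 4, h, w)
    box offsets (dx, dy, dw, dh in anchor units); ``anchors``: (A*h*w, 4).
    Candidates carry their argmax class and its probability; per-class NMS
    runs before the score threshold, so raising the threshold can only
    shrink the survivor set.  Returns ``(regions (N, 6), survivors)`` where
    survivors are ``(anchor_axis, class_id, row, col)`` index tuples into
    the class map for gradient routing during training.
    """
    A, L, h, w = probs.shape
    H, W = image_shape
    flat_probs = probs.transpose(0, 2, 3, 1).reshape(-1, L)  # (A*h*w, L)
    flat_deltas = deltas.transpose(0, 2, 3, 1).reshape(-1, 4)
    ids = np.argmax(flat_probs, axis=1)          # 0-based local class
    scores = flat_probs[np.arange(len(ids)), ids]

    acx = (anchors[:, 0] + anchors[:, 1]) / 2.0
    acy = (anchors[:, 2] + anchors[:, 3]) / 2.0
    aw = anchors[:, 1] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 2]
    dx, dy, dw, dh = flat_deltas.T
    cx = acx + dx * aw
    cy = acy + dy * ah
    bw = aw * np.exp(np.clip(dw, -4.0, 4.0))
    bh = ah * np.exp(np.clip(dh, -4.0, 4.0))
    boxes = np.stack([cx - bw / 2, cx + bw / 2, cy - bh / 2, cy + bh / 2], axis=1)
    boxes[:, :2] = boxes[:, :2].clip(0.0, W)
    boxes[:, 2:] = boxes[:, 2:].clip(0.0, H)
    valid = (boxes[:, 1] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 2])

    regions, survivors = [], []
    hw = h * w
    for k in range(L):
        # NMS precedes the score threshold; since a box can only be
        # suppressed by a higher-scored one, dropping sub-threshold boxes
        # first yields the identical survivor set (and is much cheaper).
        sel = np.flatnonzero((ids == k) & valid & (scores > threshold))
        if sel.size == 0:
            continue
        keep = sel[nms(boxes[sel], scores[sel], nms_iou)]
        for idx in keep:
            regions.append([*boxes[idx], k + 1, scores[idx]])
            a, rc = divmod(int(idx), hw)
            survivors.append((a, k + 1, rc // w, rc % w))
    if not regions:
        return np.zeros((0, 6)), []
    order = np.argsort(-np.asarray(regions, dtype=float)[:, 5], kind="stable")
    regions = np.asarray(regions, dtype=float)[order]
    survivors = [survivors[i] for i in order]
    return regions, survivors


# -- prediction export ------------------------------------------------------


def mask_to_rle(mask: np.ndarray) -> dict:
    """Row-major run-length encoding of a binary mask."""
    m = np.asarray(mask).astype(np.uint8).reshape(-1)
    diff = np.flatnonzero(np.diff(np.concatenate([[0], m, [0]])))
    starts, ends = diff[::2], diff[1::2]
    return {"size": list(mask.shape), "starts": starts.tolist(),
            "lengths": (ends - starts).tolist()}


def rle_to_mask(rle: dict) -> np.ndarray:
    H, W = rle["size"]
    m = np.zeros(H * W, dtype=np.uint8)
    for s, l in zip(rle["starts"], rle["lengths"]):
        m[s : s + l] = 1
    return m.reshape(H, W)
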