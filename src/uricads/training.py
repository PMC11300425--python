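"""End-to-end multi-task training: losses, fold orchestration, prediction.

The total objective is the unweighted sum of the four branch losses,
``L = L_seg + L_clas + L_reg + L_dgm``:

* ``L_seg``  — per-pixel binary cross-entropy of the kidney mask logits;
* ``L_clas`` — sum of P+1 binary cross-entropies of the image-level head
  against the multi-hot category target (cases may carry several
  concurrent pathologies);
* ``L_reg``  — detection loss of the anchor head: class binary
  cross-entropy (positives and negatives balanced) plus smooth-L1 box
  regression on positive anchors;
* ``L_dgm``  — sum of P+1 binary cross-entropies of the fused diagnosis
  vector, which trains the fusion weights jointly with the branches.

Training is fully seeded: one master seed fans out to parameter
initialization, fold assignment, shuffling and augmentation streams.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fusion as fusion_mod
from .annotations import CaseAnnotation
from .augment import AugmentSpec, augment
from .metrics import MetricUndefined, dice, roc_auc
from .model import (
    CaseTriplet,
    ModelConfig,
    SCDCNN,
    box_iou_matrix,
    mask_to_rle,
)
from .nn import Adam, SGD, Module, Tensor, bce_prob, bce_with_logits, concat, smooth_l1
from .splits import FoldSplit
from .taxonomy import CategoryScheme, DEFAULT_SCHEME


# -- fusion as trainable modules -------------------------------------------


class CategoryFusion(Module):
    """One learnable alpha vector, logistic-reparameterized."""

    mode = "category"

    def __init__(self, n_categories: int):
        self.theta = Tensor(np.zeros(n_categories), requires_grad=True)

    def alpha(self, p_image: Tensor, p_region: Tensor) -> Tensor:
        return self.theta.sigmoid()

    def alpha_numpy(self, p_image: np.ndarray, p_region: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.theta.data))


class AttentionFusion(Module):
    """Per-case alpha from a linear layer over [p_image; p_region]."""

    mode = "attention"

    def __init__(self, n_categories: int, rng: np.random.Generator | None = None):
        m = n_categories
        self.W = Tensor(np.zeros((2 * m, m)), requires_grad=True)
        self.b = Tensor(np.zeros(m), requires_grad=True)

    def alpha(self, p_image: Tensor, p_region: Tensor) -> Tensor:
        x = concat([p_image, p_region]).reshape(1, -1)
        return (x.matmul(self.W) + self.b).reshape(-1).sigmoid()

    def alpha_numpy(self, p_image: np.ndarray, p_region: np.ndarray) -> np.ndarray:
        x = np.concatenate([p_image, p_region])
        return 1.0 / (1.0 + np.exp(-(x @ self.W.data + self.b.data)))


def make_fusion(mode: str, scheme: CategoryScheme = DEFAULT_SCHEME):
    if mode == "category":
        return CategoryFusion(scheme.P + 1)
    if mode == "attention":
        return AttentionFusion(scheme.P + 1)
    raise ValueError(f"unknown fusion mode: {mode!r}")


# -- loss bundle ------------------------------------------------------------


@dataclass
class LossBundle:
    """Per-branch loss values; total is their unweighted sum."""

    seg: float
    clas: float
    reg: float
    dgm: float

    @property
    def total(self) -> float:
        return self.seg + self.clas + self.reg + self.dgm

    def as_dict(self) -> dict:
        return {"seg": self.seg, "clas": self.clas, "reg": self.reg,
                "dgm": self.dgm, "total": self.total}


def _anchor_targets(anchors: np.ndarray, ann: CaseAnnotation,
                    scheme: CategoryScheme, L: int):
    """Match anchors to ground-truth lesions.

    Positive: IoU >= 0.3 with a lesion, plus the best anchor per lesion.
    Everything else is negative.  Returns (cls_targets (n,L), pos_idx,
    box_targets (n_pos, 4)).
    """
    n = anchors.shape[0]
    cls_t = np.zeros((n, L))
    gt_boxes = np.array([les.box for les in ann.lesions], dtype=float
                        ).reshape(-1, 4)
    if gt_boxes.shape[0] == 0:
        return cls_t, np.zeros(0, dtype=int), np.zeros((0, 4))
    gt_cls = np.array([les.category(scheme) for les in ann.lesions], dtype=int)
    ious = box_iou_matrix(anchors, gt_boxes)          # (n, n_gt)
    best_gt = np.argmax(ious, axis=1)
    best_iou = ious[np.arange(n), best_gt]
    positive = best_iou >= 0.3
    positive[np.argmax(ious, axis=0)] = True          # best anchor per lesion
    pos_idx = np.flatnonzero(positive)
    for i in pos_idx:
        cls_t[i, gt_cls[best_gt[i]] - 1] = 1.0

    a = anchors[pos_idx]
    g = gt_boxes[best_gt[pos_idx]]
    aw, ah = a[:, 1] - a[:, 0], a[:, 3] - a[:, 2]
    acx, acy = (a[:, 0] + a[:, 1]) / 2, (a[:, 2] + a[:, 3]) / 2
    gw, gh = g[:, 1] - g[:, 0], g[:, 3] - g[:, 2]
    gcx, gcy = (g[:, 0] + g[:, 1]) / 2, (g[:, 2] + g[:, 3]) / 2
    box_t = np.stack([(gcx - acx) / aw, (gcy - acy) / ah,
                      np.log(gw / aw), np.log(gh / ah)], axis=1)
    return cls_t, pos_idx, box_t


def compute_losses(
    model: SCDCNN,
    image: np.ndarray,
    ann: CaseAnnotation,
    fusion: CategoryFusion | AttentionFusion,
    aggregation: str = "max",
) -> tuple[Tensor, LossBundle, CaseTriplet | None]:
    """Build the joint loss graph for one case; returns (total, bundle, _)."""
    scheme = model.scheme
    img = np.asarray(image, dtype=float)
    H, W = img.shape[-2:]

    T = model.backbone_forward(img)
    F_img = model.fpn_forward(T, "image")
    F_reg = model.fpn_forward(T, "region")

    # segmentation branch
    seg_logits = model.seg_logits(F_img)
    gt_mask = ann.kidney_mask().astype(float)
    l_seg = bce_with_logits(seg_logits, gt_mask, reduction="mean")

    # image classification branch
    cls_logits = model.classify_logits(T[4])
    y = ann.multihot(scheme)
    l_clas = bce_with_logits(cls_logits, y, reduction="sum")

    # region detection branch
    cls_map, box_map = model.det_maps(F_reg)
    A, L = len(model.config.anchor_sizes), scheme.L
    h, w = cls_map.shape[-2:]
    anchors = model.anchors(h, w)
    cls_t, pos_idx, box_t = _anchor_targets(anchors, ann, scheme, L)
    # cls_map layout (A*L, h, w) -> flat (A*h*w, L) entry index
    flat_logits = cls_map.reshape(A, L, h * w)
    weights = np.full(cls_t.shape, 0.0)
    pos_entries = cls_t > 0.5
    n_pos = int(pos_entries.sum())
    n_neg = cls_t.size - n_pos
    if n_pos:
        weights[pos_entries] = 0.5 / n_pos
        weights[~pos_entries] = 0.5 / n_neg
    else:
        weights[:] = 1.0 / cls_t.size
    # reorder targets/weights to the (A, L, h*w) layout of the logits
    t_maps = cls_t.reshape(A, h * w, L).transpose(0, 2, 1)
    w_maps = weights.reshape(A, h * w, L).transpose(0, 2, 1)
    l_reg = bce_with_logits(flat_logits, t_maps, weights=w_maps, reduction="sum")
    if len(pos_idx):
        hw = h * w
        flat_box_idx = []
        for idx in pos_idx:
            a_i, rc = divmod(int(idx), hw)
            for c in range(4):
                flat_box_idx.append(((a_i * 4 + c) * hw) + rc)
        pred_deltas = box_map.gather(flat_box_idx).reshape(-1, 4)
        l_reg = l_reg + smooth_l1(pred_deltas, box_t)

    # diagnosis generation: fuse image and region scores
    p_image_t = cls_logits.sigmoid()
    _, survivors = model.detect_regions_indexed(F_reg, image_shape=(H, W))
    probs_t = cls_map.sigmoid()  # (A*L, h, w)
    local_terms: list[Tensor] = []
    for k in range(1, L + 1):
        idxs = [((a * L + (k - 1)) * h + i) * w + j
                for (a, kk, i, j) in survivors if kk == k]
        if idxs:
            if aggregation != "max":
                raise NotImplementedError(
                    "joint training supports max-aggregation (the default)"
                )
            local_terms.append(probs_t.gather(idxs).max().reshape(1))
        else:
            local_terms.append(Tensor(np.zeros(1)))
    locals_t = concat(local_terms)
    healthy_t = (1.0 - locals_t.mean()).reshape(1)
    p_region_t = concat([healthy_t, locals_t, Tensor(np.zeros(scheme.G))])
    alpha_t = fusion.alpha(p_image_t, p_region_t)
    fused = alpha_t * p_image_t + (1.0 - alpha_t) * p_region_t
    l_dgm = bce_prob(fused, y, reduction="sum")

    total = l_seg + l_clas + l_reg + l_dgm
    bundle = LossBundle(seg=float(l_seg.data), clas=float(l_clas.data),
                        reg=float(l_reg.data), dgm=float(l_dgm.data))
    return total, bundle, None


# -- prediction -------------------------------------------------------------


def predict_case(model: SCDCNN, fusion, image: np.ndarray,
                 image_id: str, aggregation: str = "max") -> dict:
    """Run the full pipeline on one image; returns the export record."""
    triplet = model.forward_case(image)
    kidney_area = float(triplet.mask.sum())
    p_region = fusion_mod.region_vector(
        triplet.regions, method=aggregation,
        kidney_area=kidney_area if kidney_area > 0 else None,
        scheme=model.scheme,
    )
    alpha = fusion.alpha_numpy(triplet.p_image, p_region)
    p = fusion_mod.fuse(triplet.p_image, p_region, alpha)
    return {
        "image": image_id,
        "mask_rle": mask_to_rle(triplet.mask),
        "kidney_found": bool(triplet.kidney_found),
        "p_image": triplet.p_image.tolist(),
        "regions": triplet.regions.tolist(),
        "p_region": p_region.tolist(),
        "alpha": np.asarray(alpha).tolist(),
        "p": p.tolist(),
    }


def predict(model: SCDCNN, fusion, images, image_ids,
            aggregation: str = "max") -> list[dict]:
    return [predict_case(model, fusion, img, iid, aggregation)
            for img, iid in zip(images, image_ids)]


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(path: str | Path, model: SCDCNN, fusion) -> None:
    arrays = {f"model_{i}": a for i, a in enumerate(model.state_arrays())}
    arrays.update({f"fusion_{i}": a for i, a in enumerate(fusion.state_arrays())})
    import dataclasses

    mc = dataclasses.asdict(model.config)
    mc["anchor_sizes"] = list(model.config.anchor_sizes)
    meta = {"model_config": mc, "fusion_mode": fusion.mode,
            "config_digest": model.config.digest()}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        mc = meta["model_config"]
        mc["anchor_sizes"] = tuple(mc["anchor_sizes"])
        model = SCDCNN(ModelConfig(**mc))
        fusion = make_fusion(meta["fusion_mode"], model.scheme)
        model.load_state_arrays(
            [data[f"model_{i}"] for i in range(len(model.parameters()))]
        )
        fusion.load_state_arrays(
            [data[f"fusion_{i}"] for i in range(len(fusion.parameters()))]
        )
    return model, fusion


# -- training loop ----------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 12
    lr: float = 2e-3
    momentum: float = 0.9
    optimizer: str = "adam"  # "adam" | "sgd" 
    fusion_mode: str = "attention"
    aggregation: str = "max"
    augment_spec: AugmentSpec | None = field(default_factory=AugmentSpec)
    seed: int = 0


@dataclass
class FoldResult:
    fold: int
    checkpoint: Path
    best_epoch: int
    best_val_score: float
    history: list[dict]


@dataclass
class TrainResult:
    folds: list[FoldResult]
    predictions: dict[str, dict]   # merged over test folds, one entry per case
    log_path: Path | None


def _val_score(model, fusion, images, anns, aggregation) -> tuple[float, dict]:
    dices, scores, labels = [], [], []
    for img, ann in zip(images, anns):
        rec = predict_case(model, fusion, img, ann.image_id, aggregation)
        from .model import rle_to_mask

        dices.append(dice(rle_to_mask(rec["mask_rle"]), ann.kidney_mask()))
        scores.append(1.0 - rec["p"][0])
        labels.append(0 if ann.healthy else 1)
    mean_dice = float(np.mean(dices))
    try:
        auc = roc_auc(scores, labels) / 100.0
    except MetricUndefined:
        auc = float("nan")
    score = mean_dice if np.isnan(auc) else 0.5 * (mean_dice + auc)
    return score, {"val_dice": mean_dice, "val_binary_auc": auc}


def train(
    images: list[np.ndarray],
    annotations: list[CaseAnnotation],
    folds: list[FoldSplit],
    model_config: ModelConfig,
    train_config: TrainConfig,
    out_dir: str | Path,
) -> TrainResult:
    """Train one model per fold; keep the best-validation checkpoint each.

    Returns per-fold checkpoints and the merged test-fold predictions (each
    case predicted exactly once, by the model that never saw it).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = {a.image_id: (img, a) for img, a in zip(images, annotations)}
    log_path = out / "train_log.jsonl"
    log_f = log_path.open("w")
    master = np.random.SeedSequence(train_config.seed)
    fold_seeds = master.spawn(len(folds))

    fold_results: list[FoldResult] = []
    merged_predictions: dict[str, dict] = {}
    for f, split in enumerate(folds):
        if not split.train:
            raise ValueError(f"fold {f}: empty training set")
        seeds = fold_seeds[f].generate_state(3)
        cfg = ModelConfig(**{**model_config.__dict__,
                             "seed": int(seeds[0] % (2**31))})
        cfg.anchor_sizes = tuple(model_config.anchor_sizes)
        model = SCDCNN(cfg)
        fusion = make_fusion(train_config.fusion_mode, model.scheme)
        params = model.parameters() + fusion.parameters()
        if train_config.optimizer == "adam":
            opt = Adam(params, lr=train_config.lr)
        else:
            opt = SGD(params, lr=train_config.lr,
                      momentum=train_config.momentum)
        shuffle_rng = np.random.default_rng(int(seeds[1] % (2**31)))
        aug_rng = np.random.default_rng(int(seeds[2] % (2**31)))

        best = (-np.inf, 0, None, None)  # score, epoch, model state, fusion state
        history = []
        for epoch in range(train_config.epochs):
            t0 = time.time()
            order = shuffle_rng.permutation(len(split.train))
            epoch_losses = []
            for idx in order:
                img, ann = by_id[split.train[idx]]
                if train_config.augment_spec is not None:
                    res = augment(img, ann, train_config.augment_spec, aug_rng)
                    img, ann = res.image, res.annotation
                total, bundle, _ = compute_losses(
                    model, img, ann, fusion, train_config.aggregation
                )
                if not np.isfinite(total.data):
                    raise FloatingPointError(
                        f"non-finite loss at fold {f} epoch {epoch}: "
                        f"{bundle.as_dict()}"
                    )
                opt.zero_grad()
                total.backward()
                opt.step()
                epoch_losses.append(bundle.as_dict())
            mean_losses = {k: float(np.mean([e[k] for e in epoch_losses]))
                           for k in epoch_losses[0]}
            val_imgs = [by_id[i][0] for i in split.val]
            val_anns = [by_id[i][1] for i in split.val]
            score, val_metrics = _val_score(
                model, fusion, val_imgs, val_anns, train_config.aggregation
            )
            entry = {"fold": f, "epoch": epoch, "losses": mean_losses,
                     **val_metrics, "val_score": score,
                     "seconds": round(time.time() - t0, 2)}
            history.append(entry)
            log_f.write(json.dumps(entry) + "\n")
            log_f.flush()
            if score > best[0]:
                best = (score, epoch,
                        [a.copy() for a in model.state_arrays()],
                        [a.copy() for a in fusion.state_arrays()])

        model.load_state_arrays(best[2])
        fusion.load_state_arrays(best[3])
        ckpt = out / f"fold{f}_best.npz"
        save_checkpoint(ckpt, model, fusion)
        fold_results.append(FoldResult(fold=f, checkpoint=ckpt,
                                       best_epoch=best[1],
                                       best_val_score=float(best[0]),
                                       history=history))
        for iid in split.test:
            img, _ = by_id[iid]
            merged_predictions[iid] = predict_case(
                model, fusion, img, iid, train_config.aggregation
            )
    log_f.close()
    return TrainResult(folds=fold_results, predictions=merged_predictions,
                       log_path=log_path)
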