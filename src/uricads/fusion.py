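"""Diagnosis Generation Module: region-score aggregation and convex fusion.

The detection branch describes a case by a variable-size stack of region
descriptors ``r_n = [x_min, x_max, y_min, y_max, id_n, s_n]``.  This module
turns that stack into an image-level score vector ``p_region`` and fuses it
with the image-branch vector ``p_image`` by a learnable convex combination

    p = alpha * p_image + (1 - alpha) * p_region,   0 <= alpha <= 1,

with one weight per category.  ``alpha`` is either a single learned vector
(category-level fusion) or predicted per case by a linear attention layer
over the concatenation ``[p_image; p_region]`` followed by a logistic
squash that enforces the [0, 1] constraint.

Aggregation methods (per local category k, over the regions assigned to k):

* ``max``  — maximum region score (the system default).
* ``mean`` — mean region score.
* ``lme``  — log-mean-exp, intermediate between mean and max.
* ``area`` — sum of score x box-area, normalized by the kidney area
  (clamped to [0, 1]).

``mean`` and ``lme`` normalize by the per-category region count so each
entry stays a probability; ``literal=True`` instead divides by the total
region count N across categories (under which ``lme`` of a sparse category
can leave [0, 1]).  The healthy entry is ``p_region[0] = 1 - mean of the L
local entries``, and global entries are zero — the region branch carries no
evidence about global pathologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .taxonomy import CategoryScheme, DEFAULT_SCHEME

AGGREGATION_METHODS = ("max", "mean", "lme", "area")


def _region_array(regions) -> np.ndarray:
    r = np.asarray(regions, dtype=float)
    if r.size == 0:
        return r.reshape(0, 6)
    if r.ndim != 2 or r.shape[1] != 6:
        raise ValueError("regions must be an (N, 6) array of descriptors")
    return r


def aggregate(
    regions,
    method: str = "max",
    kidney_area: float | None = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    literal: bool = False,
) -> np.ndarray:
    """Aggregate region scores into one score per local category (length L).

    ``regions`` is an (N, 6) stack of region descriptors (columns: x_min,
    x_max, y_min, y_max, category id, score).  A category with no assigned
    regions scores 0 under every method.  The ``area`` method requires the
    kidney pixel count ``kidney_area > 0``.
    """
    if method not in AGGREGATION_METHODS:
        raise ValueError(f"unknown aggregation method: {method!r}")
    r = _region_array(regions)
    N = r.shape[0]
    if method == "area":
        if kidney_area is None or kidney_area <= 0:
            raise ValueError("area aggregation requires kidney_area > 0")
    out = np.zeros(scheme.L)
    for k in range(1, scheme.L + 1):
        sel = r[r[:, 4].astype(int) == k]
        if sel.shape[0] == 0:
            continue
        s = sel[:, 5]
        norm = N if literal else sel.shape[0]
        if method == "max":
            out[k - 1] = s.max()
        elif method == "mean":
            out[k - 1] = s.sum() / norm
        elif method == "lme":
            out[k - 1] = np.log(np.exp(s).sum() / norm)
        else:  # area
            h = sel[:, 3] - sel[:, 2]
            w = sel[:, 1] - sel[:, 0]
            out[k - 1] = np.clip((s * h * w).sum() / kidney_area, 0.0, 1.0)
    return out


def healthy_score(local_scores) -> float:
    """Healthy probability from local evidence: ``1 - mean(local scores)``."""
    s = np.asarray(local_scores, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one local category")
    return float(1.0 - s.mean())


def assemble_region_vector(
    local_scores, scheme: CategoryScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """Build the length-(P+1) region-branch vector from L local scores.

    Entry 0 is the healthy score, entries [1, L] the local scores, and the
    trailing G global entries are zero.
    """
    s = np.asarray(local_scores, dtype=float)
    if s.shape != (scheme.L,):
        raise ValueError(f"expected {scheme.L} local scores, got shape {s.shape}")
    out = np.zeros(scheme.P + 1)
    out[0] = healthy_score(s)
    out[1 : scheme.L + 1] = s
    return out


def region_vector(
    regions,
    method: str = "max",
    kidney_area: float | None = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    literal: bool = False,
) -> np.ndarray:
    """Aggregate a region stack straight to the length-(P+1) vector."""
    return assemble_region_vector(
        aggregate(regions, method, kidney_area, scheme, literal), scheme
    )


def fuse(p_image, p_region, alpha) -> np.ndarray:
    """Convex per-category combination ``alpha*p_image + (1-alpha)*p_region``."""
    pi = np.asarray(p_image, dtype=float)
    pr = np.asarray(p_region, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if pi.shape != pr.shape or a.shape[-1] != pi.shape[-1]:
        raise ValueError("p_image, p_region and alpha must share the last axis")
    if np.any(a < 0.0) or np.any(a > 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return a * pi + (1.0 - a) * pr


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class AttentionParams:
    """Linear attention layer predicting per-case fusion weights.

    ``alpha = sigmoid(W_att @ [p_image; p_region] + b_att)`` with ``W_att``
    of shape (P+1, 2(P+1)) and ``b_att`` of shape (P+1,).
    """

    W_att: np.ndarray
    b_att: np.ndarray

    def __post_init__(self) -> None:
        self.W_att = np.asarray(self.W_att, dtype=float)
        self.b_att = np.asarray(self.b_att, dtype=float)
        if not (np.all(np.isfinite(self.W_att)) and np.all(np.isfinite(self.b_att))):
            raise ValueError("attention parameters must be finite")


def attention_alpha(p_image, p_region, params: AttentionParams) -> np.ndarray:
    """Per-case fusion weights from the attention layer (rows = cases)."""
    pi = np.atleast_2d(np.asarray(p_image, dtype=float))
    pr = np.atleast_2d(np.asarray(p_region, dtype=float))
    x = np.concatenate([pi, pr], axis=1)  # (n, 2(P+1))
    a = _sigmoid(x @ params.W_att.T + params.b_att)
    return a[0] if np.asarray(p_image).ndim == 1 else a


# -- fitting ----------------------------------------------------------------

_EPS = 1e-7


def fusion_bce_loss(p, labels) -> float:
    """Sum over categories, mean over cases, of binary cross-entropy."""
    p = np.clip(np.atleast_2d(p), _EPS, 1.0 - _EPS)
    y = np.atleast_2d(labels)
    per_case = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum(axis=1)
    return float(per_case.mean())


def _fused_grad(p, labels):
    """d(loss)/d(p) for fusion_bce_loss, clamped like the forward pass."""
    p = np.clip(np.atleast_2d(p), _EPS, 1.0 - _EPS)
    y = np.atleast_2d(labels)
    return (p - y) / (p * (1.0 - p)) / p.shape[0]


def _category_loss_and_grad(theta, pi, pr, y):
    alpha = _sigmoid(theta)
    p = alpha * pi + (1.0 - alpha) * pr
    loss = fusion_bce_loss(p, y)
    dp = _fused_grad(p, y)
    dalpha = (dp * (pi - pr)).sum(axis=0)
    dtheta = dalpha * alpha * (1.0 - alpha)
    return loss, dtheta


def _attention_loss_and_grad(W, b, pi, pr, y):
    x = np.concatenate([pi, pr], axis=1)  # (n, 2m)
    z = x @ W.T + b
    alpha = _sigmoid(z)
    p = alpha * pi + (1.0 - alpha) * pr
    loss = fusion_bce_loss(p, y)
    dp = _fused_grad(p, y)
    dz = dp * (pi - pr) * alpha * (1.0 - alpha)  # (n, m)
    dW = dz.T @ x
    db = dz.sum(axis=0)
    return loss, dW, db


@dataclass
class FusionFit:
    """Result of fitting the fusion stage."""

    mode: str
    alpha: np.ndarray | None = None
    attention: AttentionParams | None = None
    loss_history: list[float] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]

    def weights_for(self, p_image, p_region) -> np.ndarray:
        if self.mode == "category":
            return self.alpha
        return attention_alpha(p_image, p_region, self.attention)

    def predict(self, p_image, p_region) -> np.ndarray:
        return fuse(p_image, p_region, self.weights_for(p_image, p_region))


def _descend(loss_grad, params, n_iter, lr):
    """Full-batch gradient descent with backtracking: loss never increases."""
    history = [loss_grad(*params)[0]]
    step = lr
    for _ in range(n_iter):
        loss, *grads = loss_grad(*params)
        while True:
            trial = [p - step * g for p, g in zip(params, grads)]
            trial_loss = loss_grad(*trial)[0]
            if trial_loss <= loss or step < 1e-12:
                break
            step *= 0.5
        if trial_loss <= loss:
            params = trial
            history.append(trial_loss)
            step = min(step * 1.3, 100.0)
        else:
            history.append(loss)
            break
    return params, history


def fit_fusion(
    p_image,
    p_region,
    labels,
    mode: str = "category",
    n_iter: int = 300,
    lr: float = 1.0,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> FusionFit:
    """Learn fusion weights by minimizing per-category binary cross-entropy.

    ``p_image``, ``p_region`` and multi-hot ``labels`` are (n, P+1) arrays.
    Category mode learns one alpha vector (through a logistic
    reparameterization, so the [0, 1] constraint always holds); attention
    mode learns the linear layer (W_att, b_att), warm-started from the
    category solution (W_att = 0, b_att = category logits) so its training
    loss can only improve on the category-level fit.
    """
    pi = np.atleast_2d(np.asarray(p_image, dtype=float))
    pr = np.atleast_2d(np.asarray(p_region, dtype=float))
    y = np.atleast_2d(np.asarray(labels, dtype=float))
    if pi.shape != pr.shape or pi.shape != y.shape:
        raise ValueError("p_image, p_region and labels must have equal shapes")
    if pi.shape[0] == 0:
        raise ValueError("empty fitting dataset")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be multi-hot (0/1)")
    m = pi.shape[1]
    if m != scheme.P + 1:
        raise ValueError(f"expected vectors of length {scheme.P + 1}")

    theta0 = np.zeros(m)
    (theta,), cat_history = _descend(
        lambda t: _category_loss_and_grad(t, pi, pr, y), [theta0], n_iter, lr
    )
    if mode == "category":
        return FusionFit(mode="category", alpha=_sigmoid(theta),
                         loss_history=cat_history)
    if mode != "attention":
        raise ValueError(f"unknown fusion mode: {mode!r}")

    W0 = np.zeros((m, 2 * m))
    (W, b), att_history = _descend(
        lambda w, bb: _attention_loss_and_grad(w, bb, pi, pr, y),
        [W0, theta.copy()], n_iter, lr,
    )
    return FusionFit(
        mode="attention",
        attention=AttentionParams(W_att=W, b_att=b),
        loss_history=att_history,
    )
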