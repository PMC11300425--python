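import numpy as np
import pytest

from uricads.fusion import (
    AttentionParams,
    _attention_loss_and_grad,
    aggregate,
    assemble_region_vector,
    attention_alpha,
    fit_fusion,
    fuse,
    fusion_bce_loss,
    healthy_score,
    region_vector,
)
from uricads.taxonomy import DEFAULT_SCHEME


def loop_aggregate_oracle(regions, method, kidney_area=None, L=4, literal=False):
    """Naive per-region loop over the aggregation definitions."""
    out = np.zeros(L)
    N = len(regions)
    for k in range(1, L + 1):
        S = [r for r in regions if int(r[4]) == k]
        if not S:
            continue
        scores = [r[5] for r in S]
        norm = N if literal else len(S)
        if method == "max":
            out[k - 1] = max(scores)
        elif method == "mean":
            out[k - 1] = sum(scores) / norm
        elif method == "lme":
            out[k - 1] = np.log(sum(np.exp(s) for s in scores) / norm)
        elif method == "area":
            total = sum(s * (r[3] - r[2]) * (r[1] - r[0])
                        for r, s in zip(S, scores))
            out[k - 1] = min(max(total / kidney_area, 0.0), 1.0)
    return out


def random_region_set(rng, n_max=20):
    n = int(rng.integers(0, n_max + 1))
    if n == 0:
        return np.zeros((0, 6))
    xmin = rng.uniform(0, 60, n)
    ymin = rng.uniform(0, 60, n)
    w = rng.uniform(2, 20, n)
    h = rng.uniform(2, 20, n)
    ids = rng.integers(1, 5, n).astype(float)
    s = rng.uniform(0, 1, n)
    return np.stack([xmin, xmin + w, ymin, ymin + h, ids, s], axis=1)


class TestAggregate:
    def test_max_of_two(self):
        r = np.array([[0, 10, 0, 10, 1, 0.3], [5, 15, 5, 15, 1, 0.9]])
        assert aggregate(r, "max")[0] == 0.9

    def test_lme_single_region_identity(self):
        r = np.array([[0, 10, 0, 10, 2, 0.37]])
        assert aggregate(r, "lme")[1] == pytest.approx(0.37, abs=1e-14)

    def test_area_forced_arithmetic(self):
        r = np.array([[0, 10, 0, 10, 1, 0.8]])  # 10x10 box, score 0.8
        assert aggregate(r, "area", kidney_area=200)[0] == pytest.approx(0.4)

    def test_empty_category_scores_zero_under_all_methods(self):
        r = np.array([[0, 10, 0, 10, 1, 0.5]])
        for method in ("max", "mean", "lme"):
            assert aggregate(r, method)[1:].sum() == 0.0

    def test_area_requires_positive_kidney_area(self):
        with pytest.raises(ValueError):
            aggregate(np.zeros((0, 6)), "area", kidney_area=0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            aggregate(np.zeros((0, 6)), "softmax")

    @pytest.mark.parametrize("method", ["max", "mean", "lme", "area"])
    @pytest.mark.parametrize("literal", [False, True])
    def test_matches_loop_oracle(self, method, literal):
        rng = np.random.default_rng(17)
        for _ in range(200):
            r = random_region_set(rng)
            got = aggregate(r, method, kidney_area=900.0, literal=literal)
            want = loop_aggregate_oracle(r, method, kidney_area=900.0,
                                         literal=literal)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_mean_lme_max_ordering(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            r = random_region_set(rng)
            lo = aggregate(r, "mean")
            mid = aggregate(r, "lme")
            hi = aggregate(r, "max")
            assert np.all(lo <= mid + 1e-12) and np.all(mid <= hi + 1e-12)

    def test_all_methods_stay_in_unit_interval(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            r = random_region_set(rng)
            for method in ("max", "mean", "lme", "area"):
                v = aggregate(r, method, kidney_area=50.0)
                assert np.all(v >= 0.0) and np.all(v <= 1.0)


class TestRegionVector:
    def test_healthy_score_extremes_and_midpoint(self):
        assert healthy_score([0, 0, 0, 0]) == 1.0
        assert healthy_score([1, 1, 1, 1]) == 0.0
        assert healthy_score([0.2, 0.4, 0.6, 0.8]) == pytest.approx(0.5)

    def test_assemble_no_evidence_vector(self):
        np.testing.assert_array_equal(
            assemble_region_vector(np.zeros(4)), [1, 0, 0, 0, 0, 0, 0])

    def test_globals_zero_and_identity_holds(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            locals_ = rng.uniform(0, 1, 4)
            v = assemble_region_vector(locals_)
            assert v.shape == (7,)
            assert v[5] == 0.0 and v[6] == 0.0
            assert v[0] + locals_.mean() == pytest.approx(1.0, abs=1e-15)

    def test_region_vector_composes(self):
        r = np.array([[0, 10, 0, 10, 1, 0.6]])
        v = region_vector(r, "max")
        assert v[1] == 0.6
        assert v[0] == pytest.approx(1 - 0.6 / 4)


class TestFuse:
    def test_identity_limits_and_midpoint(self):
        pi = np.array([0.8] * 7)
        pr = np.array([0.2] * 7)
        np.testing.assert_array_equal(fuse(pi, pr, np.ones(7)), pi)
        np.testing.assert_array_equal(fuse(pi, pr, np.zeros(7)), pr)
        np.testing.assert_allclose(fuse(pi, pr, np.full(7, 0.5)), 0.5)

    def test_convexity_random_trials(self):
        rng = np.random.default_rng(37)
        for _ in range(200):
            pi = rng.uniform(0, 1, 7)
            pr = rng.uniform(0, 1, 7)
            a = rng.uniform(0, 1, 7)
            p = fuse(pi, pr, a)
            assert np.all(p >= np.minimum(pi, pr) - 1e-15)
            assert np.all(p <= np.maximum(pi, pr) + 1e-15)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros(7), np.zeros(7), np.full(7, 1.2))


class TestAttention:
    def test_zero_parameters_give_half(self):
        params = AttentionParams(np.zeros((7, 14)), np.zeros(7))
        a = attention_alpha(np.zeros(7), np.zeros(7), params)
        np.testing.assert_allclose(a, 0.5)

    def test_alpha_monotone_in_bias(self):
        rng = np.random.default_rng(41)
        pi, pr = rng.uniform(0, 1, 7), rng.uniform(0, 1, 7)
        W = rng.normal(size=(7, 14))
        a_lo = attention_alpha(pi, pr, AttentionParams(W, np.full(7, -1.0)))
        a_hi = attention_alpha(pi, pr, AttentionParams(W, np.full(7, 1.0)))
        assert np.all(a_hi > a_lo)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            AttentionParams(np.full((7, 14), np.nan), np.zeros(7))

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(43)
        n = 40
        pi = rng.uniform(0.05, 0.95, (n, 7))
        pr = rng.uniform(0.05, 0.95, (n, 7))
        y = rng.integers(0, 2, (n, 7)).astype(float)
        W = rng.normal(scale=0.3, size=(7, 14))
        b = rng.normal(scale=0.3, size=7)
        _, dW, db = _attention_loss_and_grad(W, b, pi, pr, y)

        def loss(Wx, bx):
            return _attention_loss_and_grad(Wx, bx, pi, pr, y)[0]

        h = 1e-6
        for idx in [(0, 0), (3, 7), (6, 13)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += h
            Wm[idx] -= h
            num = (loss(Wp, b) - loss(Wm, b)) / (2 * h)
            assert dW[idx] == pytest.approx(num, rel=1e-5)
        for j in (0, 6):
            bp, bm = b.copy(), b.copy()
            bp[j] += h
            bm[j] -= h
            num = (loss(W, bp) - loss(W, bm)) / (2 * h)
            assert db[j] == pytest.approx(num, rel=1e-5)


def simulate_fusion_data(alpha_star, n, seed):
    """Labels drawn Bernoulli at the convex mixture with known alpha*."""
    rng = np.random.default_rng(seed)
    m = len(alpha_star)
    pi = rng.uniform(0, 1, (n, m))
    pr = rng.uniform(0, 1, (n, m))
    p = alpha_star * pi + (1 - alpha_star) * pr
    y = (rng.uniform(0, 1, (n, m)) < p).astype(float)
    return pi, pr, y


class TestFitFusion:
    def test_recovers_generating_alpha(self):
        alpha_star = np.array([0.9, 0.7, 0.5, 0.3, 0.8, 0.6, 0.4])
        pi, pr, y = simulate_fusion_data(alpha_star, n=2000, seed=19)
        fit = fit_fusion(pi, pr, y, mode="category")
        assert np.all(np.abs(fit.alpha - alpha_star) < 0.1)

    def test_pure_noise_region_branch_pushes_alpha_to_one(self):
        rng = np.random.default_rng(53)
        n, m = 1500, 7
        pi = rng.uniform(0, 1, (n, m))
        y = (rng.uniform(0, 1, (n, m)) < pi).astype(float)  # p_image exact
        pr = rng.uniform(0, 1, (n, m))                      # pure noise
        fit = fit_fusion(pi, pr, y, mode="category")
        assert np.all(fit.alpha > 0.85)

    def test_loss_non_increasing(self):
        pi, pr, y = simulate_fusion_data(np.full(7, 0.5), n=200, seed=3)
        for mode in ("category", "attention"):
            hist = fit_fusion(pi, pr, y, mode=mode, n_iter=50).loss_history
            assert all(a >= b - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_attention_never_worse_than_category(self):
        pi, pr, y = simulate_fusion_data(
            np.array([0.9, 0.2, 0.5, 0.7, 0.4, 0.6, 0.8]), n=500, seed=5)
        cat = fit_fusion(pi, pr, y, mode="category")
        att = fit_fusion(pi, pr, y, mode="attention")
        assert att.final_loss <= cat.final_loss + 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_fusion(np.zeros((0, 7)), np.zeros((0, 7)), np.zeros((0, 7)))
        with pytest.raises(ValueError):
            fit_fusion(np.zeros((5, 7)), np.zeros((5, 7)), np.full((5, 7), 0.5))

    def test_predict_uses_fitted_weights(self):
        pi, pr, y = simulate_fusion_data(np.full(7, 0.7), n=300, seed=9)
        fit = fit_fusion(pi, pr, y, mode="attention")
        p = fit.predict(pi, pr)
        assert p.shape == (300, 7)
        assert fusion_bce_loss(p, y) == pytest.approx(fit.final_loss, rel=1e-9)
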