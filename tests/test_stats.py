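"""Two-level t-test, BH FDR, PLSR with permutation null, Tjur's D."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from erk_rescale.errors import ValidationError
from erk_rescale.stats import (
    bh_fdr, hierarchical_ttest, pearson_summary, plsr_fit, plsr_null_bounds,
    tjur_discrimination,
)


class TestHierarchicalTtest:
    def test_identical_groups_t_zero(self):
        rng = np.random.default_rng(0)
        group = [rng.normal(0, 1, 50) for _ in range(4)]
        t, p, df = hierarchical_ttest(group, [g.copy() for g in group])
        assert t == 0.0

    def test_symmetry_up_to_sign(self):
        rng = np.random.default_rng(1)
        a = [rng.normal(0, 1, 30) for _ in range(3)]
        b = [rng.normal(0.5, 1, 30) for _ in range(3)]
        t1, p1, _ = hierarchical_ttest(a, b)
        t2, p2, _ = hierarchical_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_collapses_to_welch_on_experiment_means(self):
        """With zero within-experiment variance the procedure reduces to
        Welch's t-test on the experiment means."""
        rng = np.random.default_rng(2)
        means_a = rng.normal(0, 1, 5)
        means_b = rng.normal(0.8, 2, 6)
        a = [np.full(10, m) for m in means_a]
        b = [np.full(10, m) for m in means_b]
        t, p, df = hierarchical_ttest(a, b)
        ref = sps.ttest_ind(means_a, means_b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 for a two-level normal model
        (5 experiments x 100 cells) stays near nominal."""
        rng = np.random.default_rng(3)
        n_rep, rejections = 800, 0
        for _ in range(n_rep):
            def group():
                return [rng.normal(rng.normal(0, 1), 1, 100) for _ in range(5)]
            _, p, _ = hierarchical_ttest(group(), group())
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_single_experiment_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_ttest([np.ones(5)], [np.zeros(5), np.zeros(5)])


def _brute_force_bh(p, alpha):
    """Literal step-up rule: find the largest k with p_(k) <= k/m * alpha."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k / m * alpha:
            k_star = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_star]] = True
    return flags


class TestBhFdr:
    def test_all_tiny_all_flagged(self):
        flags, adj = bh_fdr([0.001] * 10)
        assert flags.all()

    def test_single_p_reduces_to_raw_threshold(self):
        flags, _ = bh_fdr([0.04], alpha=0.05)
        assert flags[0]
        flags, _ = bh_fdr([0.06], alpha=0.05)
        assert not flags[0]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 9)
            p = rng.random(m)
            flags, _ = bh_fdr(p)
            assert np.array_equal(flags, _brute_force_bh(p, 0.05))

    def test_monotone_in_p(self):
        """Lowering any p-value never unflags another test."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.random(6)
            flags, _ = bh_fdr(p)
            i = rng.integers(6)
            p2 = p.copy()
            p2[i] *= rng.random()
            flags2, _ = bh_fdr(p2)
            # every originally flagged test other than i stays flagged
            mask = flags & (np.arange(6) != i)
            assert flags2[mask].all()

    def test_invalid_values_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])


class TestPlsr:
    def test_perfect_single_factor(self):
        """Y affine in one predictor: that predictor's weight dominates and
        the fit is essentially complete within two components (the first
        component alone leaks slightly into finite-sample-correlated
        noise columns)."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 6))
        y = 2.0 + 3.0 * x[:, 1]
        res = plsr_fit(x, y, max_components=3)
        assert res.variance_explained[0] >= 90.0
        assert res.variance_explained[2] >= 99.9
        assert np.argmax(np.abs(res.weights)) == 1

    def test_variance_explained_nondecreasing(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(30, 6))
            y = x @ rng.normal(size=6) + rng.normal(size=30)
            res = plsr_fit(x, y, max_components=5)
            assert np.all(np.diff(res.variance_explained) >= -1e-9)

    def test_matches_sklearn_plsregression(self):
        """Independent cross-check of the NIPALS fit against sklearn on the
        same standardized data."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        x = rng.normal(size=(25, 5))
        y = x @ rng.normal(size=5) + 0.5 * rng.normal(size=25)
        res = plsr_fit(x, y, max_components=3, n_components_reported=3)
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        ref = PLSRegression(n_components=3, scale=False).fit(xs, ys)
        assert np.allclose(res.weights, ref.coef_.ravel(), atol=1e-8)
        r2 = ref.score(xs, ys)
        assert res.variance_explained[2] == pytest.approx(100 * r2, abs=1e-6)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 4))
        y = x @ np.array([1.0, -0.5, 0.0, 0.2]) + rng.normal(size=30)
        res1 = plsr_fit(x, y)
        x2 = x * np.array([10.0, 0.1, 3.0, 1.0]) + np.array([5, -2, 0, 1])
        res2 = plsr_fit(x2, y)
        assert np.allclose(res1.weights, res2.weights, atol=1e-10)

    def test_constant_column_named(self):
        x = np.ones((10, 2))
        x[:, 0] = np.arange(10)
        with pytest.raises(ValidationError, match="x1"):
            plsr_fit(x, np.arange(10.0))

    def test_permuted_response_below_null_quantile(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 6))
        y = rng.permutation(x[:, 0] + rng.normal(size=40))
        obs = plsr_fit(x, y, max_components=1).variance_explained[0]
        null = []
        for _ in range(200):
            null.append(
                plsr_fit(x, rng.permutation(y), max_components=1).variance_explained[0]
            )
        assert obs < np.percentile(null, 99)


class TestPlsrNullBounds:
    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(32, 6))
        y = rng.normal(size=32)
        r1 = plsr_null_bounds(x, y, n_perm=150, seed=7)
        r2 = plsr_null_bounds(x, y, n_perm=150, seed=7)
        assert np.array_equal(r1.null_bounds, r2.null_bounds)

    def test_planted_predictor_flagged(self):
        rng = np.random.default_rng(5)
        hits, others = 0, 0
        n_rep = 25
        for _ in range(n_rep):
            x = rng.normal(size=(32, 6))
            y = x[:, 0] * 1.0 + rng.normal(size=32)
            res = plsr_null_bounds(x, y, n_perm=200,
                                   seed=int(rng.integers(2**31)))
            hits += bool(res.significant[0])
            others += int(res.significant[1:].sum())
        assert hits / n_rep >= 0.8
        assert others / (5 * n_rep) <= 0.2

    def test_low_n_perm_warns(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning):
            plsr_null_bounds(rng.normal(size=(20, 3)), rng.normal(size=20),
                             n_perm=50, seed=0)


class TestTjur:
    def test_perfect_separation_limit(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        d, info = tjur_discrimination(x, x > 0.5)
        assert d >= 0.99
        assert info["penalized"]

    def test_independent_flags_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        flags = rng.random(1000) < 0.5
        d, _ = tjur_discrimination(x, flags)
        assert abs(d) <= 0.05

    def test_four_point_grid_search_oracle(self):
        """On a tiny dataset the ML logistic fit (hence D) can be found by
        brute-force search over a parameter grid."""
        x = np.array([0.0, 1.0, 2.0, 3.0])
        flags = np.array([False, True, False, True])
        def grid_search(c0, c1, half, n):
            best = (-np.inf, None, 0.0, 0.0)
            for b0 in np.linspace(c0 - half, c0 + half, n):
                for b1 in np.linspace(c1 - half, c1 + half, n):
                    p = 1 / (1 + np.exp(-(b0 + b1 * x)))
                    ll = np.sum(np.log(np.where(flags, p, 1 - p)))
                    if ll > best[0]:
                        best = (ll, p[flags].mean() - p[~flags].mean(), b0, b1)
            return best

        _, best_d, b0, b1 = grid_search(0.0, 0.0, 6.0, 121)
        _, best_d, b0, b1 = grid_search(b0, b1, 0.2, 81)
        _, best_d, _, _ = grid_search(b0, b1, 0.01, 41)
        d, info = tjur_discrimination(x, flags)
        assert not info["penalized"]
        assert d == pytest.approx(best_d, abs=1e-3)

    def test_linear_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        flags = rng.random(200) < 1 / (1 + np.exp(-x))
        d1, _ = tjur_discrimination(x, flags)
        d2, _ = tjur_discrimination(3.0 * x - 7.0, flags)
        assert d2 == pytest.approx(d1, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            tjur_discrimination(np.arange(5.0), np.ones(5, dtype=bool))


class TestPearson:
    @pytest.mark.parametrize(
        "y_fn,expected", [(lambda x: 2 * x, 1.0), (lambda x: -x + 3, -1.0)]
    )
    def test_exact_lines(self, y_fn, expected):
        x = np.arange(10.0)
        r, p = pearson_summary(x, y_fn(x))
        assert r == pytest.approx(expected)

    def test_independent_normals_small_r(self):
        rng = np.random.default_rng(0)
        r, p = pearson_summary(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_summary(np.ones(5), np.arange(5.0))
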