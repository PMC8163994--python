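"""Confound regression, permutation FWE, clusters, effect sizes, correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tractoprofile import group_stats as gs
from tractoprofile.group_stats import (
    StatsConfig,
    cluster_filter,
    cohens_d_from_t,
    cohens_f2,
    correlation_permutation_fwe,
    correlation_pvalue,
    permutation_fwe,
    posthoc_power,
    regress_confounds,
    semipartial_correlation,
    ttest_segments,
)


class TestRegressConfounds:
    def test_orthogonal_noiseless_design_returns_demeaned_plus_mean(self, rng):
        n = 20
        X = rng.standard_normal((n, 3))
        Y = np.broadcast_to(rng.standard_normal(5), (n, 5)).copy()
        out = regress_confounds(Y, X)
        np.testing.assert_allclose(out, Y, atol=1e-10)

    def test_perfect_fit_returns_grand_mean(self, rng):
        hl = rng.uniform(5, 40, 24)
        Y = (2.0 * hl)[:, None] * np.ones((1, 4))
        out = regress_confounds(Y, hl[:, None])
        np.testing.assert_allclose(out, Y.mean(axis=0, keepdims=True) * np.ones_like(Y), atol=1e-9)

    def test_residuals_orthogonal_to_confounds(self, rng):
        """OLS normal equations: residuals dot each confound column < 1e-8."""
        n, s = 38, 50
        X = rng.standard_normal((n, 3))
        Y = rng.standard_normal((n, s)) + X @ rng.standard_normal((3, s))
        out = regress_confounds(Y, X)
        resid = out - out.mean(axis=0, keepdims=True)
        Xc = X - X.mean(axis=0, keepdims=True)
        assert np.abs(Xc.T @ resid).max() < 1e-8

    def test_rank_deficient_design_names_columns(self, rng):
        X = rng.standard_normal((10, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            regress_confounds(rng.standard_normal((10, 3)), X, ("a", "b", "a_doubled"))

    def test_within_group_centering_preserves_group_contrast(self, rng):
        """Zero-filled one-group covariates must not absorb the group effect."""
        n = 38
        groups = np.array(["t"] * 19 + ["c"] * 19)
        thi = np.where(groups == "t", rng.normal(16, 10, n), 0.0)
        dur = np.where(groups == "t", rng.normal(11, 7, n), 0.0)
        X = np.column_stack([thi, dur])
        Y = np.where(groups == "t", 1.0, 0.0)[:, None] + rng.normal(0, 0.1, (n, 10))
        pooled = regress_confounds(Y, X)
        centered = regress_confounds(Y, X, center_within=groups)
        gap = lambda M: M[:19].mean() - M[19:].mean()
        assert abs(gap(pooled)) < 0.6  # proxy regression eats the difference
        assert gap(centered) == pytest.approx(1.0, abs=0.1)


class TestTTest:
    def test_hand_computed_pooled_t(self):
        t, p = ttest_segments(
            np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]),
            np.array([True, True, True, False, False, False]),
        )
        assert t[0] == pytest.approx(-3.674, abs=1e-3)
        ref = sps.ttest_ind([1, 2, 3], [4, 5, 6])
        assert t[0] == pytest.approx(ref.statistic, rel=1e-12)
        assert p[0] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_equal_groups_give_zero(self, rng):
        vals = np.vstack([rng.standard_normal(5)] * 6)
        t, p = ttest_segments(vals, np.array([True] * 3 + [False] * 3))
        np.testing.assert_allclose(t, 0.0, atol=1e-12)
        np.testing.assert_allclose(p, 1.0)

    def test_label_swap_antisymmetry(self, rng):
        vals = rng.standard_normal((12, 7))
        g = np.array([True] * 6 + [False] * 6)
        t1, p1 = ttest_segments(vals, g)
        t2, p2 = ttest_segments(vals, ~g)
        np.testing.assert_allclose(t1, -t2, atol=1e-12)
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestPermutationFWE:
    def test_extreme_observed_statistic_boundary(self, rng):
        vals = rng.standard_normal((16, 20))
        vals[:8, 3] += 50.0  # one overwhelming effect
        cfg = StatsConfig(n_permutations=500, seed=1)
        res = permutation_fwe(vals, np.array([True] * 8 + [False] * 8), cfg)
        assert not res.exhaustive
        assert res.p_fwe[3] == pytest.approx(1.0 / 501.0)

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        """Sampled request on 4+4 subjects falls back to exact enumeration."""
        vals = rng.standard_normal((8, 3))
        g = np.array([True] * 4 + [False] * 4)
        cfg = StatsConfig(n_permutations=5000, seed=0)
        res = permutation_fwe(vals, g, cfg)
        assert res.exhaustive and res.n_permutations_used == math.comb(8, 4)
        t_obs, _ = ttest_segments(vals, g)
        for j in range(3):
            count = 0
            for combo in itertools.combinations(range(8), 4):
                mask = np.zeros(8, bool)
                mask[list(combo)] = True
                t_perm, _ = ttest_segments(vals, mask)
                if np.abs(t_perm).max() >= abs(t_obs[j]) - 1e-12:
                    count += 1
            assert res.p_fwe[j] == pytest.approx(
                max(count / math.comb(8, 4), res.p_uncorrected[j])
            )

    def test_seeded_determinism(self, rng):
        vals = rng.standard_normal((20, 30))
        g = np.array([True] * 10 + [False] * 10)
        cfg = StatsConfig(n_permutations=300, seed=7)
        r1 = permutation_fwe(vals, g, cfg)
        r2 = permutation_fwe(vals, g, cfg)
        np.testing.assert_array_equal(r1.p_fwe, r2.p_fwe)
        np.testing.assert_array_equal(r1.max_t_null, r2.max_t_null)

    def test_monotone_in_observed_statistic(self, rng):
        vals = rng.standard_normal((20, 30))
        g = np.array([True] * 10 + [False] * 10)
        res = permutation_fwe(vals, g, StatsConfig(n_permutations=300, seed=3))
        order = np.argsort(np.abs(res.t_obs))
        assert np.all(np.diff(res.p_fwe[order]) <= 1e-12)

    def test_p_fwe_dominates_uncorrected(self, rng):
        vals = rng.standard_normal((16, 40))
        g = np.array([True] * 8 + [False] * 8)
        res = permutation_fwe(vals, g, StatsConfig(n_permutations=200, seed=5))
        assert np.all(res.p_fwe >= res.p_uncorrected - 1e-15)


class TestClusterFilter:
    def test_window_examples(self):
        assert cluster_filter([0, 0, 1, 1, 1, 1, 1, 0], 5) == [(2, 7)]
        assert cluster_filter([0, 1, 1, 0], 5) == []
        assert cluster_filter([0, 1, 1, 0], 2) == [(1, 3)]

    def test_matches_runlength_oracle(self, rng):
        for _ in range(50):
            mask = rng.random(30) < 0.4
            got = cluster_filter(mask, 3)
            runs, start = [], None
            for i, v in enumerate(list(mask) + [False]):
                if v and start is None:
                    start = i
                elif not v and start is not None:
                    if i - start >= 3:
                        runs.append((start, i))
                    start = None
            assert got == runs


class TestEffectSizes:
    def test_cohens_d_zero_and_symmetry(self):
        assert cohens_d_from_t(0.0, 19, 19) == 0.0
        assert cohens_d_from_t(-3.0, 19, 19) == cohens_d_from_t(3.0, 19, 19)

    def test_cohens_f2_values(self):
        assert cohens_f2(0.0) == 0.0
        assert cohens_f2(0.545) == pytest.approx(0.4226, abs=2e-4)
        with pytest.warns(UserWarning):
            assert math.isinf(cohens_f2(1.0))

    def test_power_null_equals_alpha(self):
        assert posthoc_power(0.0, 19, 19, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_power_monotone_in_effect_size(self):
        powers = [posthoc_power(d, 19, 19) for d in np.linspace(0, 3, 13)]
        assert np.all(np.diff(powers) > 0)

    def test_power_matches_distributional_simulation(self, rng):
        """Noncentral-t power equals a 1e6-draw sampling-distribution oracle."""
        d, n = 1.0, 19
        reps = 1_000_000
        diff = rng.normal(d, np.sqrt(2 / n), reps)
        sp2 = rng.chisquare(2 * n - 2, reps) / (2 * n - 2)
        t = diff / np.sqrt(sp2 * 2 / n)
        t_crit = sps.t.ppf(0.975, 2 * n - 2)
        mc = (np.abs(t) > t_crit).mean()
        assert posthoc_power(d, n, n, 0.05) == pytest.approx(mc, abs=0.005)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            posthoc_power(1.0, 19, 19, alpha=1.5)


class TestCorrelations:
    def test_pvalue_examples(self):
        assert correlation_pvalue(0.0, 38) == pytest.approx(1.0)
        assert correlation_pvalue(0.545, 38) == pytest.approx(4.03e-4, rel=0.01)
        ps = [correlation_pvalue(r, 38) for r in np.linspace(0, 0.999, 30)]
        assert np.all(np.diff(ps) < 0)

    def test_exact_linear_relation_gives_unit_r(self, rng):
        hl = rng.uniform(5, 40, 12)
        others = rng.standard_normal((12, 2))
        Y = (3.0 * hl)[:, None] * np.ones((1, 4))
        r = semipartial_correlation(Y, hl, others)
        np.testing.assert_allclose(r, 1.0, atol=1e-10)

    def test_orthogonal_cofactor_near_zero(self, rng):
        n = 4000
        Y = rng.standard_normal((n, 2))
        r = semipartial_correlation(Y, rng.standard_normal(n), rng.standard_normal((n, 2)))
        assert np.abs(r).max() < 0.05

    def test_matches_normal_equations_oracle(self, rng):
        """n=8, 2 other confounds: explicit algebra reproduces r to 1e-10."""
        n = 8
        x = rng.uniform(0, 30, n)
        others = rng.standard_normal((n, 2))
        Y = rng.standard_normal((n, 5))
        got = semipartial_correlation(Y, x, others)
        X = np.column_stack([np.ones(n), x, others])
        beta = np.linalg.solve(X.T @ X, X.T @ Y)  # normal equations
        adjusted = Y - others @ beta[2:]
        expected = np.array(
            [np.corrcoef(x, adjusted[:, j])[0, 1] for j in range(Y.shape[1])]
        )
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_constant_cofactor_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            semipartial_correlation(rng.standard_normal((8, 2)), np.ones(8),
                                    rng.standard_normal((8, 1)))

    def test_permutation_corrected_correlations(self, rng):
        n = 30
        x = rng.uniform(0, 30, n)
        others = rng.standard_normal((n, 2))
        Y = rng.standard_normal((n, 10))
        Y[:, 4] += 0.2 * x  # one real association
        cfg = StatsConfig(n_permutations=300, n_metrics_bonferroni=1, seed=2)
        res = correlation_permutation_fwe(Y, x, others, cfg)
        assert res.p_fwe[4] == res.p_fwe.min()
        assert np.all(res.p_fwe >= 1 / 301)


class TestAnalyzeGroupDifferences:
    @pytest.fixture()
    def cohort(self, rng):
        from tractoprofile.synthetic import CohortSpec, sample_confounds

        return sample_confounds(CohortSpec(n_per_group=10, seed=1), rng)

    def test_output_contract(self, cohort, rng):
        mats = {"b1": rng.standard_normal((20, 100)), "b2": rng.standard_normal((20, 100))}
        cfg = StatsConfig(n_permutations=100, seed=1)
        table = gs.analyze_group_differences(mats, cohort, cfg, metric_name="AFD")
        assert len(table) == 200
        assert set(table["bundle"]) == {"b1", "b2"}
        assert table["p_fwe"].between(0, 1).all()
        assert (table["d"] >= 0).all()

    def test_missing_segments_reported_not_imputed(self, cohort, rng):
        mat = rng.standard_normal((20, 100))
        mat[3, 17] = np.nan
        table = gs.analyze_group_differences(
            {"b1": mat}, cohort, StatsConfig(n_permutations=50, seed=1), metric_name="FA"
        )
        row = table[(table.bundle == "b1") & (table.segment == 17)].iloc[0]
        assert np.isnan(row["t"]) and not row["significant"]

    def test_small_clusters_demoted(self, cohort, rng):
        mat = rng.normal(0, 0.1, (20, 100))
        tin = (cohort["group"] == "tinnitus").to_numpy()
        mat[tin, 50:53] += 5.0  # strong but only 3 segments wide
        cfg = StatsConfig(n_permutations=200, cluster_extent_min=5,
                          n_metrics_bonferroni=1, seed=1)
        table = gs.analyze_group_differences({"b1": mat}, cohort, cfg, metric_name="AFD")
        assert (table["p_fwe"] < 0.05).any()
        assert not table["significant"].any()
        cfg2 = StatsConfig(n_permutations=200, cluster_extent_min=2,
                           n_metrics_bonferroni=1, seed=1)
        table2 = gs.analyze_group_differences({"b1": mat}, cohort, cfg2, metric_name="AFD")
        assert table2["significant"].sum() == 3
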