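"""Permutation chi-squared test, FDR, classification, extrapolation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gynngy.regulation import (
    ExtrapolationFit,
    analyze_regulation,
    bh_fdr,
    classify_regulation,
    fit_extrapolation,
    pearson_chi2,
    permutation_chisq,
    tissue_subsample_curve,
)


def exact_strict_p(table: np.ndarray) -> float:
    """Exact conditional P(chi2 > observed) under fixed margins.

    Enumerates every first row compatible with the margins; each table's
    probability is prod_t C(c_t, x_t) / C(n, r1) (multivariate
    hypergeometric).  Independent of the sampling implementation.
    """
    obs = np.asarray(table, dtype=int)
    r1 = int(obs[0].sum())
    col = obs.sum(axis=0)
    n = int(col.sum())
    chi2_obs = pearson_chi2(obs)
    denom = math.comb(n, r1)
    p = 0.0
    ranges = [range(0, int(c) + 1) for c in col]
    for x in itertools.product(*ranges):
        if sum(x) != r1:
            continue
        weight = 1.0
        for c, xi in zip(col, x):
            weight *= math.comb(int(c), xi)
        weight /= denom
        t = np.vstack([x, col - np.array(x)])
        if pearson_chi2(t) > chi2_obs * (1 + 1e-12) + 1e-12:
            p += weight
    return p


class TestPermutationChisq:
    def test_uniform_table_has_zero_statistic_and_large_p(self):
        res = permutation_chisq(np.array([[10, 10], [10, 10]]), 2000, seed=1)
        assert res.chi2 == pytest.approx(0.0)
        # every permuted table with any imbalance strictly exceeds 0
        assert res.p == pytest.approx(exact_strict_p([[10, 10], [10, 10]]), abs=0.05)

    def test_diagonal_table_maximal_statistic(self):
        """[[10,0],[0,10]] attains the maximal chi-squared for its
        margins, so no permuted table can strictly exceed it."""
        res = permutation_chisq(np.array([[10, 0], [0, 10]]), 10_000, seed=2)
        assert res.chi2 == pytest.approx(20.0)
        assert res.M == 0 and res.p == 0.0
        # the exact conditional mass at-or-above the observed value is
        # 2 / C(20, 10), i.e. the two extreme diagonal tables
        assert 2 / math.comb(20, 10) == pytest.approx(1.082e-5, rel=1e-3)

    def test_single_tissue_is_untestable(self):
        res = permutation_chisq(np.array([[12], [3]]), 100, seed=0)
        assert not res.testable and math.isnan(res.p)

    def test_one_sided_row_is_untestable(self):
        res = permutation_chisq(np.array([[30, 40], [0, 0]]), 100, seed=0)
        assert not res.testable

    def test_add_one_correction_avoids_zero_p(self):
        res = permutation_chisq(np.array([[10, 0], [0, 10]]), 1000, seed=3, add_one=True)
        assert res.p == pytest.approx(1 / 1001)

    def test_estimate_tracks_exact_on_a_2x3_table(self):
        table = np.array([[12, 4, 9], [3, 11, 6]])
        p_exact = exact_strict_p(table)
        res = permutation_chisq(table, 20_000, seed=4)
        assert abs(res.p - p_exact) <= 4 * math.sqrt(max(p_exact, 1e-12) / 20_000)

    def test_deterministic_for_fixed_seed(self):
        t = np.array([[20, 10, 5], [10, 15, 12]])
        a = permutation_chisq(t, 5000, seed=9)
        b = permutation_chisq(t, 5000, seed=9)
        assert a.M == b.M and a.p == b.p


class TestBhFdr:
    def brute_force(self, p):
        """Definitional BH: q_(i) = min_{j>=i} p_(j) * n / j, capped."""
        p = np.asarray(p, float)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(n)
        prev = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            val = min(prev, p[i] * n / rank)
            q[i] = min(val, 1.0)
            prev = q[i]
        return q

    def test_hand_example(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_passthrough(self):
        assert bh_fdr([1.0]) == pytest.approx([1.0])

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_matches_definition_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = rng.uniform(size=100)
            assert np.allclose(bh_fdr(p), self.brute_force(p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestClassification:
    @pytest.mark.parametrize(
        "fdr, delta, expected",
        [
            (0.5, 0.6, "unregulated"),
            (0.001, 0.12, "medium"),
            (0.001, 0.25, "strong"),  # boundary inclusive
            (0.001, 0.24999, "medium"),
            (0.001, 0.07, "weak"),
            (0.001, 0.01, "very_weak"),
            (0.010, 0.3, "strong"),  # FDR boundary inclusive
            (0.011, 0.3, "unregulated"),
        ],
    )
    def test_examples(self, fdr, delta, expected):
        assert classify_regulation(fdr, delta) == expected

    @settings(max_examples=300, deadline=None)
    @given(
        st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
    )
    def test_partitions_unit_square(self, fdr, delta):
        assert classify_regulation(fdr, delta) in {
            "strong",
            "medium",
            "weak",
            "very_weak",
            "unregulated",
        }


def _simulate_counts(rng, thetas, depth=200):
    """Long count table for sites with given per-tissue proximal usage."""
    rows = []
    for i, th in enumerate(thetas):
        for t, theta in enumerate(th):
            prox = rng.binomial(depth, theta)
            rows.append(
                {
                    "site_id": f"s{i:04d}",
                    "tissue": f"t{t:02d}",
                    "distal_reads": depth - prox,
                    "proximal_reads": prox,
                }
            )
    return pd.DataFrame(rows)


class TestAnalyzeRegulation:
    def test_power_to_call_strong_at_step_profile(self):
        """delta-UMS 0.4 at 200 reads/tissue over 8 tissues: at least
        90% of regulated sites are called strong (regression guard)."""
        rng = np.random.default_rng(5)
        thetas = [[0.05] * 4 + [0.45] * 4 for _ in range(30)]
        counts = _simulate_counts(rng, thetas)
        res = analyze_regulation(counts, n_permutations=2000, seed=1)
        assert (res["class"] == "strong").mean() >= 0.9

    def test_constant_usage_is_unregulated(self):
        rng = np.random.default_rng(6)
        thetas = [[0.3] * 8 for _ in range(20)]
        counts = _simulate_counts(rng, thetas)
        res = analyze_regulation(counts, n_permutations=2000, seed=2)
        assert (res["class"] == "unregulated").mean() >= 0.9

    def test_low_depth_tissues_are_excluded(self):
        counts = pd.DataFrame(
            {
                "site_id": ["s"] * 3,
                "tissue": ["t1", "t2", "t3"],
                "distal_reads": [50, 5, 40],
                "proximal_reads": [10, 3, 20],
            }
        )
        res = analyze_regulation(counts, n_permutations=500, seed=0)
        # t2 has 8 < 10 reads: the table is 2 x 2, still testable
        assert res.iloc[0].testable

    def test_single_qualifying_tissue_untestable(self):
        counts = pd.DataFrame(
            {
                "site_id": ["s"] * 2,
                "tissue": ["t1", "t2"],
                "distal_reads": [50, 4],
                "proximal_reads": [10, 3],
            }
        )
        res = analyze_regulation(counts, n_permutations=500, seed=0)
        assert res.iloc[0]["class"] == "untestable"


class TestSubsampleCurve:
    def test_full_tissue_count_reproduces_full_analysis(self):
        rng = np.random.default_rng(7)
        thetas = [[0.05] * 3 + [0.45] * 3 for _ in range(6)] + [[0.2] * 6] * 6
        counts = _simulate_counts(rng, thetas)
        full = analyze_regulation(counts, n_permutations=1000, seed=3)
        testable = full[full.testable]
        expected = (testable["class"] == "strong").mean()
        got = tissue_subsample_curve(counts, k=6, seed=3, n_permutations=1000)
        assert got == pytest.approx(expected)

    def test_k_out_of_range_raises(self):
        rng = np.random.default_rng(8)
        counts = _simulate_counts(rng, [[0.2] * 4])
        with pytest.raises(ValueError):
            tissue_subsample_curve(counts, k=5)


class TestExtrapolation:
    def test_recovers_model1_parameters(self):
        rng = np.random.default_rng(9)
        x = np.arange(2, 17)
        y = 0.20 - 0.18 * np.exp(-0.30 * x) + rng.normal(0, 1e-3, len(x))
        fits = fit_extrapolation(x, y)
        assert fits["model1"].asymptote == pytest.approx(0.20, abs=0.01)

    def test_constant_data_degenerates_gracefully(self):
        x = np.arange(2, 10)
        y = np.full(len(x), 0.1)
        fits = fit_extrapolation(x, y)
        a, b, _ = fits["model1"].params
        assert a == pytest.approx(0.1, abs=1e-4)
        assert abs(b) < 1e-4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_extrapolation([2, 3, 4], [0.1, 0.2, 0.3])

    def test_model2_data_prefers_model2_by_aic(self):
        rng = np.random.default_rng(10)
        x = np.arange(2, 17).astype(float)
        wins = 0
        for _ in range(20):
            y = 0.2 * x / (3 + x) + rng.normal(0, 1e-3, len(x))
            fits = fit_extrapolation(x, y)
            wins += fits["best"].model == 2
        assert wins >= 18
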