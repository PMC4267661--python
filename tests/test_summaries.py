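"""Proportion tables, contingency/correlation tests, profiles."""

import math

import numpy as np
import pandas as pd
import pytest

from gynngy.summaries import (
    GroupCounts,
    cds_distribution_compare,
    conservation_profile,
    contingency_test,
    format_p,
    max_ums_tissue_distribution,
    motif_enrichment,
    proportion_summary,
    spearman_correlation,
    splicing_status_conservation,
)


class TestGroupCounts:
    def test_percentages_round_half_up(self):
        assert GroupCounts("x", 277, 621, decimals=0).proportion == 45.0
        assert GroupCounts("x", 75, 510).proportion == 14.71
        assert GroupCounts("x", 0, 100).proportion == 0.0

    def test_proportion_recomputes_from_counts(self):
        gc = GroupCounts("x", 118, 621)
        assert gc.proportion == pytest.approx(100 * 118 / 621, abs=0.005)


class TestProportionSummary:
    def test_by_region(self):
        table = pd.DataFrame(
            {
                "region": ["CDS"] * 4 + ["UTR"] * 2,
                "as_flag": [True, False, False, False, True, True],
            }
        )
        out = {g.label: g for g in proportion_summary(table, "region", "as_flag")}
        assert out["CDS"].numerator == 1 and out["CDS"].denominator == 4
        assert out["UTR"].proportion == 100.0

    def test_unknown_key_raises(self):
        with pytest.raises(KeyError):
            proportion_summary(pd.DataFrame({"a": [1]}), "region", "as_flag")


class TestContingency:
    def test_balanced_table_has_zero_statistic(self):
        chi2, p = contingency_test([[5, 5], [5, 5]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_published_human_as_contrast_is_below_floor(self):
        chi2, p = contingency_test([[621, 106600], [175, 14802]])
        assert p < 2.2e-16
        assert "<" in format_p(p)

    def test_chisq_matches_classical_2x2_formula(self):
        """(ad-bc)^2 * n / (margin product) on random tables."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 60, size=4)
            chi2, _ = contingency_test([[a, b], [c, d]])
            n = a + b + c + d
            classical = (
                (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            assert chi2 == pytest.approx(classical)

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = [[3, 1], [1, 3]]
        _, p = contingency_test(table, method="fisher")
        # enumerate all tables with margins (4,4)/(4,4); two-sided p sums
        # probabilities of tables no more likely than the observed one
        probs = {
            x: math.comb(4, x) * math.comb(4, 4 - x) / math.comb(8, 4)
            for x in range(5)
        }
        p_obs = probs[3]
        expected = sum(v for v in probs.values() if v <= p_obs + 1e-12)
        assert p == pytest.approx(expected)

    def test_fisher_symmetric_under_transposition(self):
        t = [[7, 2], [3, 9]]
        _, p1 = contingency_test(t, method="fisher")
        _, p2 = contingency_test(np.transpose(t), method="fisher")
        assert p1 == pytest.approx(p2)

    def test_fisher_needs_2x2(self):
        with pytest.raises(ValueError):
            contingency_test([[1, 2, 3], [4, 5, 6]], method="fisher")


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_correlation(x, x * 2 + 1)[0] == pytest.approx(1.0)
        assert spearman_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_tie_heavy_matches_rank_formula(self):
        """Pearson correlation of average ranks (the definitional
        route) on a tie-heavy vector."""
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 1.0, 3.0, 3.0, 2.0, 4.0, 4.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman_correlation(x, y)
        assert rho == pytest.approx(expected)

    def test_constant_vector_is_undefined(self):
        rho, p = spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho) and math.isnan(p)


class TestConservationProfile:
    def _sites(self):
        return pd.DataFrame(
            {
                "chrom": ["c", "c"],
                "strand": ["+", "-"],
                "distal_donor": [10, 40],
            }
        )

    def test_constant_track_gives_constant_profile(self):
        track = {"c": np.full(100, 0.8)}
        prof = conservation_profile(self._sites().iloc[:1], track, window=10)
        assert np.allclose(prof["mean_score"], 0.8)

    def test_single_site_profile_equals_track_slice(self):
        track = {"c": np.arange(100, dtype=float)}
        prof = conservation_profile(self._sites().iloc[:1], track, window=5)
        # 6-mer occupies [10, 16); downstream positions are 16..20
        assert list(prof["mean_score"]) == [16, 17, 18, 19, 20]

    def test_opposite_strands_average_by_hand(self):
        track = {"c": np.arange(100, dtype=float)}
        prof = conservation_profile(self._sites(), track, window=3)
        # '+' site: positions 16,17,18; '-' site (donor 40, 6-mer
        # [35,41)): downstream walks left from 34: 34,33,32
        assert list(prof["mean_score"]) == [
            (16 + 34) / 2,
            (17 + 33) / 2,
            (18 + 32) / 2,
        ]

    def test_missing_coverage_counts_as_missing(self):
        arr = np.full(100, 0.5)
        arr[17] = np.nan
        prof = conservation_profile(self._sites().iloc[:1], {"c": arr}, window=3)
        assert prof["n_sites"].tolist() == [1, 0, 1]


class TestMotifEnrichment:
    def _hits(self, strong_rate, other_rate, n=10):
        return pd.DataFrame(
            {
                "group": ["strong"] * n + ["other"] * n,
                "hit": [True] * int(strong_rate * n)
                + [False] * (n - int(strong_rate * n))
                + [True] * int(other_rate * n)
                + [False] * (n - int(other_rate * n)),
            }
        )

    def test_identical_rates_give_p_one(self):
        out = motif_enrichment(self._hits(0.5, 0.5), "group", "hit", "strong")
        assert out.iloc[0].fisher_p == pytest.approx(1.0)

    def test_all_vs_none_matches_enumeration(self):
        out = motif_enrichment(self._hits(1.0, 0.0), "group", "hit", "strong")
        # one-sided tail of [[10,0],[0,10]] doubles into the two-sided p:
        # only the two extreme tables are as unlikely as observed
        expected = 2 / math.comb(20, 10)
        assert out.iloc[0].fisher_p == pytest.approx(expected)

    def test_enriched_fixture_is_significant(self):
        out = motif_enrichment(self._hits(0.9, 0.1), "group", "hit", "strong")
        assert out.iloc[0].fisher_p < 0.01

    def test_missing_target_group_is_error(self):
        with pytest.raises(ValueError):
            motif_enrichment(self._hits(0.5, 0.5), "group", "hit", "absent")


class TestMaxUmsDistribution:
    def test_concentrated_and_tied_credit(self):
        ums = pd.DataFrame(
            {
                "site_id": ["a"] * 2 + ["b"] * 2,
                "tissue": ["t1", "t2"] * 2,
                "ums": [0.4, 0.1, 0.3, 0.3],
            }
        )
        dist = max_ums_tissue_distribution(ums)
        assert dist["t1"] == pytest.approx(1.5)  # a outright + half of b
        assert dist["t2"] == pytest.approx(0.5)
        assert dist.sum() == pytest.approx(2.0)

    def test_uniform_theta_is_approximately_uniform(self):
        rng = np.random.default_rng(3)
        n_sites, T = 400, 8
        rows = []
        for i in range(n_sites):
            u = rng.uniform(0.1, 0.3, size=T)
            for t in range(T):
                rows.append({"site_id": f"s{i}", "tissue": f"t{t}", "ums": u[t]})
        dist = max_ums_tissue_distribution(pd.DataFrame(rows))
        from scipy import stats

        chi2 = ((dist - n_sites / T) ** 2 / (n_sites / T)).sum()
        p = stats.chi2.sf(chi2, T - 1)
        assert p > 0.01


class TestCdsDistributionCompare:
    def test_identical_samples(self):
        x = np.linspace(0.05, 0.95, 20)
        stat, p = cds_distribution_compare(x, x)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, _ = cds_distribution_compare(
            np.linspace(0.0, 0.3, 10), np.linspace(0.7, 1.0, 10), alternative="greater"
        )
        assert stat == pytest.approx(1.0)

    def test_statistic_matches_ecdf_supremum(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(size=30)
        b = rng.uniform(size=25) ** 2
        stat, _ = cds_distribution_compare(a, b, alternative="greater")
        grid = np.concatenate([a, b])
        ecdf_a = np.array([(a <= g).mean() for g in grid])
        ecdf_b = np.array([(b <= g).mean() for g in grid])
        # one-sided 'greater': supremum of (ecdf_a - ecdf_b)
        assert stat == pytest.approx(np.max(ecdf_a - ecdf_b))

    def test_undersized_group_is_error(self):
        with pytest.raises(ValueError):
            cds_distribution_compare([0.1, 0.2], [0.3, 0.4, 0.5, 0.6, 0.7])


class TestSplicingStatusConservation:
    def _orthology(self):
        """The published human panel: conserved/total per class."""
        published = {
            "strong": (26, 73),
            "medium": (16, 64),
            "weak": (5, 38),
            "very_weak": (3, 41),
            "unregulated": (43, 279),
        }
        rows = []
        for label, (cons, total) in published.items():
            rows += [{"class": label, "conserved": True}] * cons
            rows += [{"class": label, "conserved": False}] * (total - cons)
        return pd.DataFrame(rows)

    def test_published_proportions_reproduce(self):
        table, p = splicing_status_conservation(self._orthology())
        by_class = table.set_index("class")["proportion"]
        assert by_class["strong"] == 35.62
        assert by_class["medium"] == 25.00
        assert by_class["weak"] == 13.16
        assert by_class["very_weak"] == 7.32
        assert by_class["unregulated"] == 15.41

    def test_strong_vs_pooled_fisher_matches_enumeration(self):
        """The pooled strong-vs-others contrast equals an independent
        hypergeometric enumeration of the 2x2 and is highly significant."""
        _, p = splicing_status_conservation(self._orthology())
        a, b = 26, 73 - 26          # strong: conserved / not
        c, d = 67, 422 - 67         # pooled others
        n, r1, c1 = a + b + c + d, a + b, a + c

        def prob(x):
            return (
                math.comb(c1, x)
                * math.comb(n - c1, r1 - x)
                / math.comb(n, r1)
            )

        p_obs = prob(a)
        expected = sum(
            prob(x)
            for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            if prob(x) <= p_obs * (1 + 1e-9)
        )
        assert p == pytest.approx(expected)
        assert p < 0.01

    def test_zero_conserved_gives_zero_proportions(self):
        df = self._orthology()
        df["conserved"] = False
        table, _ = splicing_status_conservation(df)
        assert (table["proportion"] == 0).all()

    def test_missing_class_is_error(self):
        df = self._orthology()
        with pytest.raises(ValueError, match="missing class"):
            splicing_status_conservation(df[df["class"] != "weak"])
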