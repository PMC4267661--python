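"""Summary statistics over the site catalog and regulation calls.

Proportion tables (AS frequency by region, regulation strength by
region, conservation of splicing status, protein-change categories),
contingency tests, Spearman correlations against gene attributes,
downstream-intron conservation profiles, motif-hit enrichment, the
distribution of peak-UMS tissues, and the comparison of site positions
along the CDS.  Percentages are rounded half-up to the configured
number of decimals so they can be compared against printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gynngy.util import percent

P_FLOOR = 2.2e-16  # conventional reporting floor for tiny p-values


@dataclass
class GroupCounts:
    label: str
    numerator: int
    denominator: int
    decimals: int = 2

    @property
    def proportion(self) -> float:
        """Percentage, rounded half-up to `decimals`."""
        return percent(self.numerator, self.denominator, self.decimals)

    def __str__(self) -> str:
        return f"{self.label}: {self.numerator}/{self.denominator} = {self.proportion}%"


def proportion_summary(
    table: pd.DataFrame,
    group_col: str,
    flag_col: str,
    decimals: int = 2,
) -> list[GroupCounts]:
    """Per-group counts and percentages of a boolean site property.

    `table` has one row per site; `group_col` defines the cells (e.g.
    region), `flag_col` is the boolean numerator property (e.g. AS
    status, strong regulation).  Unknown columns are an error.
    """
    for col in (group_col, flag_col):
        if col not in table.columns:
            raise KeyError(f"unknown grouping key {col!r}")
    out = []
    for label, grp in table.groupby(group_col, sort=True):
        out.append(
            GroupCounts(
                label=str(label),
                numerator=int(grp[flag_col].sum()),
                denominator=len(grp),
                decimals=decimals,
            )
        )
    return out


def contingency_test(table, method: str = "chisq") -> tuple[float, float]:
    """Chi-squared (no continuity correction) or Fisher's exact test.

    Returns (statistic, p).  Fisher is restricted to 2 x 2 tables and
    reports the two-sided exact hypergeometric p (odds ratio as the
    statistic).
    """
    obs = np.asarray(table, dtype=np.int64)
    if np.any(obs < 0):
        raise ValueError("contingency table must be non-negative")
    if method == "chisq":
        chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
        return float(chi2), float(p)
    if method == "fisher":
        if obs.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2 x 2 table")
        odds, p = stats.fisher_exact(obs, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError(f"unknown method {method!r}")


def format_p(p: float) -> str:
    """Human-readable p-value with the conventional < 2.2e-16 floor."""
    return f"< {P_FLOOR:.1e}" if p < P_FLOOR else f"{p:.3g}"


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, p); a constant vector has undefined rho (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def read_bedgraph(path: str) -> dict[str, np.ndarray]:
    """Per-base score arrays from a bedGraph file (missing bases NaN)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "score"],
    )
    tracks: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom"):
        length = int(grp["end"].max())
        arr = np.full(length, np.nan)
        for _, row in grp.iterrows():
            arr[int(row.start) : int(row.end)] = row.score
        tracks[chrom] = arr
    return tracks


def conservation_profile(
    sites: pd.DataFrame, track: dict[str, np.ndarray], window: int = 50
) -> pd.DataFrame:
    """Mean conservation at each of the `window` intronic positions
    downstream of the 6-mer end, averaged over sites (strand-aware).

    `sites` needs chrom, strand and distal_donor columns.  Positions a
    site's track does not cover count as missing for that site.
    Returns a frame with offset (1-based), mean score and site count.
    """
    acc = np.zeros(window)
    cnt = np.zeros(window, dtype=int)
    for row in sites.itertuples():
        arr = track.get(row.chrom)
        if arr is None:
            continue
        # first base after the 6-mer, walking downstream in tx sense
        if row.strand == "+":
            start = row.distal_donor + 6
            scores = arr[start : start + window]
        else:
            stop = row.distal_donor - 5
            scores = arr[max(0, stop - window) : stop][::-1]
        for i, v in enumerate(scores):
            if not np.isnan(v):
                acc[i] += v
                cnt[i] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame(
        {"offset": np.arange(1, window + 1), "mean_score": mean, "n_sites": cnt}
    )


def motif_enrichment(
    hits: pd.DataFrame, group_col: str, hit_col: str, target_group: str
) -> pd.DataFrame:
    """Fisher's exact enrichment of motif hits in one group vs each other.

    `hits` has one row per site with a boolean `hit_col` (externally
    produced motif-scan calls) and a `group_col` label.  Returns one row
    per contrast group with the 2 x 2 table and the two-sided Fisher p.
    """
    if target_group not in set(hits[group_col]):
        raise ValueError(f"no sites in target group {target_group!r}")
    tgt = hits[hits[group_col] == target_group]
    rows = []
    for label, grp in hits[hits[group_col] != target_group].groupby(group_col):
        if len(grp) == 0:
            raise ValueError(f"group {label!r} has zero sites")
        table = [
            [int(tgt[hit_col].sum()), int((~tgt[hit_col]).sum())],
            [int(grp[hit_col].sum()), int((~grp[hit_col]).sum())],
        ]
        _, p = contingency_test(table, method="fisher")
        rows.append(
            {
                "contrast": f"{target_group}_vs_{label}",
                "target_hits": table[0][0],
                "target_miss": table[0][1],
                "other_hits": table[1][0],
                "other_miss": table[1][1],
                "fisher_p": p,
            }
        )
    return pd.DataFrame(rows)


def max_ums_tissue_distribution(ums_long: pd.DataFrame) -> pd.Series:
    """How many sites attain their maximum UMS in each tissue.

    Each site credits one tissue; exact ties are split fractionally so
    the counts sum to the site count.
    """
    credit: dict[str, float] = {}
    for _, grp in ums_long.groupby("site_id"):
        defined = grp.dropna(subset=["ums"])
        if defined.empty:
            continue
        peak = defined["ums"].max()
        winners = defined[defined["ums"] == peak]["tissue"]
        share = 1.0 / len(winners)
        for t in winners:
            credit[t] = credit.get(t, 0.0) + share
    return pd.Series(credit).sort_index()


def cds_distribution_compare(
    positions_a, positions_b, alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided two-sample Kolmogorov-Smirnov test on raw CDS fractions.

    Groups need >= 5 sites each; the test runs on the continuous
    fractions, not the binned deciles.
    """
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each group needs >= 5 sites")
    res = stats.ks_2samp(a, b, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def splicing_status_conservation(
    orthology: pd.DataFrame,
    class_col: str = "class",
    conserved_col: str = "conserved",
    decimals: int = 2,
) -> tuple[pd.DataFrame, float]:
    """Conserved counts/proportions per regulation class, plus the
    Fisher contrast of the strong class against all others pooled.

    `orthology` has one row per site with its regulation class and a
    boolean conservation call (splicing-status- or sequence-based,
    produced upstream).  Missing class labels are an error.
    """
    required = {"strong", "medium", "weak", "very_weak", "unregulated"}
    present = set(orthology[class_col])
    missing = required - present
    if missing:
        raise ValueError(f"missing class labels: {sorted(missing)}")
    rows = []
    for label in ["strong", "medium", "weak", "very_weak", "unregulated"]:
        grp = orthology[orthology[class_col] == label]
        gc = GroupCounts(
            label=label,
            numerator=int(grp[conserved_col].sum()),
            denominator=len(grp),
            decimals=decimals,
        )
        rows.append(
            {
                "class": label,
                "conserved": gc.numerator,
                "total": gc.denominator,
                "proportion": gc.proportion,
            }
        )
    strong = orthology[orthology[class_col] == "strong"]
    others = orthology[orthology[class_col] != "strong"]
    table = [
        [int(strong[conserved_col].sum()), int((~strong[conserved_col]).sum())],
        [int(others[conserved_col].sum()), int((~others[conserved_col]).sum())],
    ]
    _, p = contingency_test(table, method="fisher")
    return pd.DataFrame(rows), p
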