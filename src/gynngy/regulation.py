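"""Tissue-dependent regulation of tandem-donor usage.

The test asks whether minor-isoform usage is constant across tissues.
For each site a 2 x T table (rows: distal/proximal donor reads, columns:
tissues with >= 10 reads at the site) is scored with the Pearson
chi-squared statistic; the null distribution is obtained by shuffling
reads across tissues and isoforms while preserving both the per-tissue
totals and the per-isoform totals.  Margin-preserving shuffling is
equivalent to drawing the first row from a multivariate hypergeometric
distribution given the margins, which we sample column-by-column in
O(T) per permutation instead of relabelling individual reads.  The
p-value is M/N with M the number of permuted statistics strictly
exceeding the observed one; an optional add-one correction guards
against p = 0.  p-values are converted to Benjamini-Hochberg FDR, and
sites are classified by (FDR, delta-UMS): FDR above the threshold is
'unregulated', otherwise strong (>= 0.25), medium [0.1, 0.25), weak
[0.05, 0.1) or very weak (< 0.05).

The expected saturation of the regulated proportion with tissue number
is estimated by subsampling k of the T tissues and refitting, then
extrapolated with two saturating models compared by AIC:
Model 1  y = a + b*exp(c*x)   (asymptote a, needs c < 0)
Model 2  y = a*x/(b + x)      (asymptote a)
with AIC = n*log(RSS/n) + 2k under the Gaussian-residual convention.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.stats.multitest import multipletests

UNTESTABLE = "untestable"
CLASSES = ("strong", "medium", "weak", "very_weak", "unregulated")


@dataclass
class PermutationResult:
    chi2: float
    M: int
    N: int
    p: float
    testable: bool


def pearson_chi2(table: np.ndarray) -> float:
    """Pearson chi-squared statistic of a contingency table (no
    continuity correction); cells with zero expectation contribute 0."""
    obs = np.asarray(table, dtype=float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (obs - expected) ** 2 / expected
    return float(np.nansum(np.where(expected > 0, terms, 0.0)))


def permutation_chisq(
    table: np.ndarray,
    n_permutations: int = 100_000,
    seed: int = 0,
    add_one: bool = False,
) -> PermutationResult:
    """Margin-preserving permutation chi-squared test on a 2 x T table.

    Untestable tables (fewer than 2 columns, or an all-zero row, i.e. no
    alternative splicing among the included tissues) yield an explicit
    untestable result rather than an exception.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError(f"expected a 2 x T table, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("negative counts in table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if obs.shape[1] < 2 or row.min() == 0:
        return PermutationResult(float("nan"), 0, n_permutations, float("nan"), False)

    chi2_obs = pearson_chi2(obs)
    rng = np.random.default_rng(seed)
    N = n_permutations
    # draw row-1 counts column-by-column from the conditional
    # hypergeometric, vectorised across permutations
    x = np.empty((N, obs.shape[1]), dtype=np.int64)
    remaining_good = np.full(N, row[0], dtype=np.int64)
    remaining_total = int(col.sum())
    for t, c_t in enumerate(col):
        nbad = remaining_total - remaining_good
        x[:, t] = rng.hypergeometric(remaining_good, nbad, int(c_t))
        remaining_good -= x[:, t]
        remaining_total -= int(c_t)
    # chi-squared of each permuted table from its first row only (margins
    # are fixed, so expectations are those of the observed table)
    e1 = row[0] * col / obs.sum()
    e2 = row[1] * col / obs.sum()
    chi2_perm = (((x - e1) ** 2) / e1 + ((col - x - e2) ** 2) / e2).sum(axis=1)
    M = int(np.sum(chi2_perm > chi2_obs * (1 + 1e-12) + 1e-12))
    p = (M + 1) / (N + 1) if add_one else M / N
    return PermutationResult(chi2_obs, M, N, float(p), True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_regulation(
    fdr: float,
    delta_ums: float,
    fdr_threshold: float = 0.01,
    delta_bins: tuple[float, float, float] = (0.05, 0.1, 0.25),
) -> str:
    """Regulation strength from (FDR, delta-UMS)."""
    if not (0 <= fdr <= 1):
        raise ValueError(f"fdr out of [0, 1]: {fdr}")
    if not (0 <= delta_ums <= 1):
        raise ValueError(f"delta_ums out of [0, 1]: {delta_ums}")
    if fdr > fdr_threshold:
        return "unregulated"
    weak, medium, strong = delta_bins
    if delta_ums >= strong:
        return "strong"
    if delta_ums >= medium:
        return "medium"
    if delta_ums >= weak:
        return "weak"
    return "very_weak"


def _site_seed(seed: int, site_id: str) -> int:
    """Stable per-site RNG seed (reproducible under parallel execution)."""
    return (seed + zlib.crc32(site_id.encode())) % (2**31)


def site_table(
    grp: pd.DataFrame, tissues: list[str] | None = None, min_reads_per_tissue: int = 10
) -> tuple[np.ndarray, list[str]]:
    """2 x T count table of one site restricted to qualifying tissues."""
    g = grp if tissues is None else grp[grp["tissue"].isin(tissues)]
    total = g["distal_reads"] + g["proximal_reads"]
    keep = g[total >= min_reads_per_tissue]
    table = np.vstack(
        [keep["distal_reads"].to_numpy(np.int64), keep["proximal_reads"].to_numpy(np.int64)]
    )
    return table, list(keep["tissue"])


def _delta_ums_from_table(table: np.ndarray) -> float:
    """Delta-UMS within the included tissues (minor donor by mean usage)."""
    total = table.sum(axis=0).astype(float)
    usage_distal = table[0] / total
    mean_distal = usage_distal.mean()
    ums = usage_distal if mean_distal < 1 - mean_distal else 1 - usage_distal
    return float(ums.max() - ums.min())


def analyze_regulation(
    counts: pd.DataFrame,
    n_permutations: int = 100_000,
    seed: int = 0,
    min_reads_per_tissue: int = 10,
    fdr_threshold: float = 0.01,
    delta_bins: tuple[float, float, float] = (0.05, 0.1, 0.25),
    tissues: list[str] | None = None,
    add_one: bool = False,
) -> pd.DataFrame:
    """Run the permutation test over all sites of a long count table.

    `counts` has columns site_id, tissue, distal_reads, proximal_reads
    (the catalog output).  Returns one row per site with chi2, M, N, p,
    fdr, delta_ums and the regulation class ('untestable' where fewer
    than two tissues pass the depth rule or only one donor is used).
    """
    rows = []
    for site_id, grp in counts.groupby("site_id", sort=True):
        table, _ = site_table(grp, tissues, min_reads_per_tissue)
        res = permutation_chisq(
            table, n_permutations, seed=_site_seed(seed, site_id), add_one=add_one
        )
        rows.append(
            {
                "site_id": site_id,
                "chi2": res.chi2,
                "M": res.M,
                "N": res.N,
                "p": res.p,
                "delta_ums": _delta_ums_from_table(table) if res.testable else float("nan"),
                "testable": res.testable,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        out["class"] = []
        return out
    out["fdr"] = np.nan
    mask = out["testable"].to_numpy()
    if mask.any():
        out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    out["class"] = [
        classify_regulation(r.fdr, r.delta_ums, fdr_threshold, delta_bins)
        if r.testable
        else UNTESTABLE
        for r in out.itertuples()
    ]
    return out


def tissue_subsample_curve(
    counts: pd.DataFrame,
    k: int,
    n_subsets: int = 100,
    seed: int = 0,
    n_permutations: int = 10_000,
    min_reads_per_tissue: int = 10,
    fdr_threshold: float = 0.01,
    delta_bins: tuple[float, float, float] = (0.05, 0.1, 0.25),
) -> float:
    """Mean proportion of strongly regulated sites using k random tissues.

    For each subset, testability, the permutation test, BH FDR and
    classification are rerun restricted to those tissues; the proportion
    is strong calls over testable sites.  k equal to the tissue count
    reproduces the full-data proportion (single subset).
    """
    all_tissues = sorted(counts["tissue"].unique())
    T = len(all_tissues)
    if not (2 <= k <= T):
        raise ValueError(f"k must be in [2, {T}], got {k}")
    rng = np.random.default_rng(seed)
    n_draws = 1 if k == T else n_subsets
    props = []
    for i in range(n_draws):
        subset = (
            all_tissues
            if k == T
            else sorted(rng.choice(all_tissues, size=k, replace=False))
        )
        res = analyze_regulation(
            counts,
            n_permutations=n_permutations,
            seed=seed + i,
            min_reads_per_tissue=min_reads_per_tissue,
            fdr_threshold=fdr_threshold,
            delta_bins=delta_bins,
            tissues=subset,
        )
        testable = res[res["testable"]]
        if len(testable) == 0:
            continue
        props.append((testable["class"] == "strong").mean())
    return float(np.mean(props)) if props else float("nan")


@dataclass
class ExtrapolationFit:
    model: int
    params: tuple[float, ...]
    aic: float
    asymptote: float
    fitted: np.ndarray


def _model1(x, a, b, c):
    return a + b * np.exp(c * x)


def _model2(x, a, b):
    return a * x / (b + x)


def fit_extrapolation(x, y) -> dict:
    """Fit both saturation models and choose by AIC.

    Returns {'model1': fit, 'model2': fit, 'best': fit}.  Raises
    RuntimeError with diagnostics if a model fails to converge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct x values to fit both models")
    fits = {}
    span = y[-1] - y[0]
    candidates = [
        (1, _model1, [y.max() if span >= 0 else y.min(), -span if span else -0.1, -0.3]),
        (2, _model2, [max(y.max(), 1e-6), max(x.mean(), 1e-6)]),
    ]
    for model_id, fn, p0 in candidates:
        try:
            params, _ = curve_fit(fn, x, y, p0=p0, maxfev=20_000)
        except RuntimeError as exc:
            raise RuntimeError(
                f"model {model_id} failed to converge on n={len(x)} points "
                f"(p0={p0}): {exc}"
            ) from exc
        fitted = fn(x, *params)
        rss = float(np.sum((y - fitted) ** 2))
        n = len(x)
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * len(params)
        fits[f"model{model_id}"] = ExtrapolationFit(
            model=model_id,
            params=tuple(float(v) for v in params),
            aic=float(aic),
            asymptote=float(params[0]),
            fitted=fitted,
        )
    fits["best"] = min((fits["model1"], fits["model2"]), key=lambda f: f.aic)
    return fits
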