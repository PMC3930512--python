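"""Parental differential expression and hybrid misexpression.

Misexpression means expression outside the range delimited by both
parental strains, by magnitude and significance criteria:

* F1 groups (with replicates): mean outside both parental means, both
  F1-vs-parent Welch tests significant at the q <= fdr level, and both
  mean differences > delta (log2).
* Individual F2s (single value each): value outside both parental
  means, with the distance to the nearer parental mean exceeding both
  delta and k standard errors of that parental group mean.

Counts of misexpressed transcripts per F2, split over/under x
autosome/X, become square-root-transformed phenotypes for QTL mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cross import ExpressionData
from .genoprob import GenotypeProbabilities
from .scan import (
    NullDistribution,
    PermutationThresholds,
    ScanResult,
    nqrank,
    permutation_threshold,
    scan_single,
    storey_qvalues,
)

CONTROL_GROUPS = ("parentA", "parentB", "F1_DxM", "F1_MxD")


def group_stats(expr: ExpressionData, groups: tuple[str, ...] = CONTROL_GROUPS) -> pd.DataFrame:
    """Per-probe mean, SE of the mean, and n for each control group.

    Columns are a (group, statistic) MultiIndex.
    """
    pieces = {}
    for g in groups:
        vals = expr.group_values(g)
        n = vals.shape[1]
        if n < 2:
            raise ValueError(f"group {g!r} has n={n}; need >=2 for group statistics")
        pieces[(g, "mean")] = vals.mean(axis=1)
        pieces[(g, "se")] = vals.std(axis=1, ddof=1) / np.sqrt(n)
        pieces[(g, "n")] = float(n)
    out = pd.DataFrame(pieces)
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out


def differential_expression(
    expr: ExpressionData, group_a: str, group_b: str, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-probe Welch t-tests between two sample groups with Storey
    q-values; ``significant`` marks q <= fdr."""
    a = expr.group_values(group_a).to_numpy(dtype=float)
    b = expr.group_values(group_b).to_numpy(dtype=float)
    for name, block in ((group_a, a), (group_b, b)):
        if block.shape[1] < 2:
            raise ValueError(f"group {name!r} has n={block.shape[1]}; need >=2")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero variance in both groups with equal means: no evidence at all
    degenerate = np.isnan(p)
    p = np.where(degenerate, 1.0, p)
    t = np.where(degenerate, 0.0, t)
    q, _ = storey_qvalues(p)
    return pd.DataFrame(
        {"t": t, "p": p, "q": q, "significant": q <= fdr}, index=expr.values.index
    )


def classify_f1_misexpression(
    expr: ExpressionData,
    f1_group: str = "F1_MxD",
    delta: float = 0.5,
    fdr: float = 0.05,
) -> pd.Series:
    """Classify each probe as over / under / none in an F1 group."""
    st = group_stats(expr, ("parentA", "parentB", f1_group))
    vs_a = differential_expression(expr, f1_group, "parentA", fdr)
    vs_b = differential_expression(expr, f1_group, "parentB", fdr)
    f1 = st[(f1_group, "mean")]
    pa = st[("parentA", "mean")]
    pb = st[("parentB", "mean")]
    sig = vs_a["significant"] & vs_b["significant"]
    big = (np.abs(f1 - pa) > delta) & (np.abs(f1 - pb) > delta)
    over = (f1 > pa) & (f1 > pb) & sig & big
    under = (f1 < pa) & (f1 < pb) & sig & big
    out = pd.Series("none", index=expr.values.index)
    out[over] = "over"
    out[under] = "under"
    return out


def classify_f2_misexpression(
    value: float,
    parent_a_mean: float,
    parent_a_se: float,
    parent_b_mean: float,
    parent_b_se: float,
    delta: float = 0.5,
    k_se: float = 2.0,
) -> str:
    """Classify one F2 expression value against the parental ranges.

    The SE guard uses the standard error of the nearer parental group
    mean (an F2 contributes a single observation, so it has no SE of
    its own).
    """
    hi_mean, hi_se = max(
        (parent_a_mean, parent_a_se), (parent_b_mean, parent_b_se)
    )
    lo_mean, lo_se = min(
        (parent_a_mean, parent_a_se), (parent_b_mean, parent_b_se)
    )
    if value > hi_mean and (value - hi_mean) > max(delta, k_se * hi_se):
        return "over"
    if value < lo_mean and (lo_mean - value) > max(delta, k_se * lo_se):
        return "under"
    return "none"


def classify_f2_matrix(
    expr: ExpressionData, delta: float = 0.5, k_se: float = 2.0
) -> pd.DataFrame:
    """Vectorized F2 classification: probe x F2-sample matrix of
    {+1 over, -1 under, 0 none}."""
    st = group_stats(expr, ("parentA", "parentB"))
    means = np.column_stack([st[("parentA", "mean")], st[("parentB", "mean")]])
    ses = np.column_stack([st[("parentA", "se")], st[("parentB", "se")]])
    hi = np.argmax(means, axis=1)
    hi_mean = means[np.arange(means.shape[0]), hi]
    hi_se = ses[np.arange(means.shape[0]), hi]
    lo_mean = means[np.arange(means.shape[0]), 1 - hi]
    lo_se = ses[np.arange(means.shape[0]), 1 - hi]
    vals = expr.f2_values.to_numpy(dtype=float)
    over = (vals > hi_mean[:, None]) & (
        vals - hi_mean[:, None] > np.maximum(delta, k_se * hi_se)[:, None]
    )
    under = (vals < lo_mean[:, None]) & (
        lo_mean[:, None] - vals > np.maximum(delta, k_se * lo_se)[:, None]
    )
    out = np.zeros(vals.shape, dtype=np.int8)
    out[over] = 1
    out[under] = -1
    return pd.DataFrame(out, index=expr.values.index, columns=expr.group_ids("F2"))


@dataclass
class MisexpressionCounts:
    """Per-F2 misexpression counts, split over/under x autosome/X, the
    derived sqrt phenotypes, and per-probe F2 prevalence."""

    counts: pd.DataFrame  # index F2 id; over_autosome, under_autosome, over_X, under_X
    phenotypes: pd.DataFrame  # sqrt-transformed counts, same columns
    prevalence: pd.Series  # per probe: fraction of F2s misexpressed (either direction)
    calls: pd.DataFrame  # probe x F2 sample, {-1, 0, +1}


def misexpression_counts(
    expr: ExpressionData, delta: float = 0.5, k_se: float = 2.0
) -> MisexpressionCounts:
    calls = classify_f2_matrix(expr, delta, k_se)
    on_x = (expr.probes["chr"] == "X").to_numpy()
    data = {}
    for direction, sign in (("over", 1), ("under", -1)):
        hit = (calls.to_numpy() == sign)
        data[f"{direction}_autosome"] = hit[~on_x].sum(axis=0)
        data[f"{direction}_X"] = hit[on_x].sum(axis=0)
    counts = pd.DataFrame(data, index=calls.columns)
    prevalence = (calls != 0).mean(axis=1)
    return MisexpressionCounts(counts, np.sqrt(counts), prevalence, calls)


def map_misexpression_qtl(
    counts: MisexpressionCounts,
    probs: GenotypeProbabilities,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "hk",
) -> dict[str, tuple[ScanResult, PermutationThresholds, NullDistribution]]:
    """Map the four sqrt-count misexpression phenotypes genome-wide."""
    out = {}
    for i, col in enumerate(counts.phenotypes.columns):
        y = counts.phenotypes[col].to_numpy(dtype=float)
        if np.all(y == y[0]):  # constant phenotype cannot map
            continue
        scan = scan_single(y, probs, method=method, trait_name=col)
        thr, null = permutation_threshold(
            y, probs, method="hk", n_perm_auto=n_perm, alpha=alpha, seed=seed + i
        )
        out[col] = (scan, thr, null)
    return out


def correlate_with_phenotype(
    expr: ExpressionData,
    phenotype: pd.Series,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of every probe's F2 expression with a
    phenotype, plus per-chromosome signed significant fractions.

    Returns (per-probe table, per-chromosome summary). Zero-variance
    probes are excluded with a logged count.
    """
    f2 = expr.f2_values
    common = [i for i in f2.columns if i in phenotype.index and not np.isnan(phenotype[i])]
    if len(common) < 10:
        raise ValueError(f"only {len(common)} paired observations; need >=10")
    x = phenotype[common].to_numpy(dtype=float)
    mat = f2[common].to_numpy(dtype=float)
    n = x.size
    mat_c = mat - mat.mean(axis=1, keepdims=True)
    x_c = x - x.mean()
    denom = np.sqrt((mat_c**2).sum(axis=1) * (x_c**2).sum())
    ok = denom > 0
    r = np.full(mat.shape[0], np.nan)
    r[ok] = (mat_c @ x_c)[ok] / denom[ok]
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    q = np.full_like(p, np.nan)
    q[ok], _ = storey_qvalues(p[ok])
    tbl = pd.DataFrame(
        {"r": r, "p": p, "q": q, "significant": (q <= fdr) & ok},
        index=expr.values.index,
    )
    chrom = expr.probes["chr"]
    summary = (
        tbl.assign(chrom=chrom.to_numpy())
        .groupby("chrom")
        .apply(
            lambda d: pd.Series(
                {
                    "n_probes": len(d),
                    "frac_positive": float(((d["r"] > 0) & d["significant"]).mean()),
                    "frac_negative": float(((d["r"] < 0) & d["significant"]).mean()),
                }
            ),
            include_groups=False,
        )
    )
    return tbl, summary
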