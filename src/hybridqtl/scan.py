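"""Single-QTL genome scans with permutation significance machinery.

Two scan methods are offered at every marker/pseudomarker grid position:

* Haley-Knott (HK): regression of the trait on expected genotype-class
  probabilities, LOD = (n/2) log10(RSS_null / RSS_model).
* EM interval mapping: a normal mixture with class-specific means and a
  common SD, the class priors being the HMM genotype probabilities.

Autosomal positions use a 2-df genotype model (AB and BB class columns);
the hemizygous male X uses a single B-class column. Covariate models
(for conditional mapping) add covariate class indicators, and the full
model additionally adds covariate-indicator x genotype-dosage products,
so the additive model is nested in the full model by construction.

Genome-wide significance is assessed by permutation with the X treated
as its own stratum: the genome-wide alpha is split between autosomes and
X in proportion to map length, and the X permutation count is scaled up
by the inverse length ratio so the extreme quantile is resolvable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genoprob import GenotypeProbabilities, genotype_at_marker

_DEGENERATE_RSS = 1e-12


@dataclass(frozen=True)
class CovariateSpec:
    """Conditioning on the genotype at a typed marker.

    kind: 'additive' (covariate main effect) or 'full' (main effect plus
    covariate x QTL interaction).
    """

    kind: str
    chrom: str
    marker: str

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "full"):
            raise ValueError(f"covariate kind must be additive|full, got {self.kind!r}")


@dataclass
class ScanResult:
    trait: str
    table: pd.DataFrame  # columns: chr, pos, lod (NaN = masked), degenerate
    method: str
    covariate: CovariateSpec | None = None

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chr"] == chrom]

    def max_lod(self, chrom: str | None = None) -> float:
        tbl = self.table if chrom is None else self.chrom_table(chrom)
        return float(np.nanmax(tbl["lod"].to_numpy()))

    def peak(self, chrom: str) -> tuple[float, float]:
        """(position, LOD) of the left-most maximum on a chromosome."""
        tbl = self.chrom_table(chrom)
        lod = tbl["lod"].to_numpy()
        i = int(np.nanargmax(lod))
        return float(tbl["pos"].to_numpy()[i]), float(lod[i])


@dataclass
class NullDistribution:
    """Sorted per-permutation maximum LOD values per stratum."""

    autosome: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.autosome = np.sort(np.asarray(self.autosome, dtype=float))
        self.x = np.sort(np.asarray(self.x, dtype=float))


@dataclass
class PermutationThresholds:
    autosome: float
    x: float
    alpha: float
    n_perm_autosome: int
    n_perm_x: int
    seed: int
    scope: str = "single_transcript"  # or "dataset"

    def for_chrom(self, is_x: bool) -> float:
        return self.x if is_x else self.autosome


# ---------------------------------------------------------------------------
# Trait transform
# ---------------------------------------------------------------------------


def nqrank(values: np.ndarray | pd.Series) -> np.ndarray:
    """Normal quantile-rank transform: x_i -> Phi^-1((rank_i - 0.5)/n).

    Ties receive their average rank; missing values stay missing. All
    traits transformed this way share one distribution, which is what
    allows a single-transcript permutation threshold to serve dataset-wide.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >=3 non-missing values, got {n}")
    x = arr[ok]
    if np.all(x == x[0]):
        warnings.warn("all values identical; transform is all zeros", stacklevel=2)
        out[ok] = 0.0
        return out
    ranks = stats.rankdata(x, method="average")
    out[ok] = stats.norm.ppf((ranks - 0.5) / n)
    return out


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def _genotype_columns(probs: GenotypeProbabilities, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """(class columns, additive dosage) at every position of a chromosome.

    Autosome: columns (pAB, pBB), dosage pAB + 2 pBB in {0..2};
    X male: column (pB,), dosage pB.
    """
    cp = probs.chroms[chrom]
    p = cp.probs
    if cp.is_x:
        cols = p[:, :, 1:2]
        dosage = p[:, :, 1]
    else:
        cols = p[:, :, 1:3]
        dosage = p[:, :, 1] + 2.0 * p[:, :, 2]
    return cols, dosage


def covariate_columns(
    probs: GenotypeProbabilities, cov: CovariateSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Covariate design (class indicators) and a keep-mask of individuals.

    The covariate genotype is the most probable class at the typed
    marker; ties or missing-dominated calls are dropped from the scan.
    """
    codes = genotype_at_marker(probs, cov.chrom, cov.marker)
    keep = codes >= 0
    is_x = probs.chroms[cov.chrom].is_x
    if is_x:
        cols = (codes[keep] == 1).astype(float)[:, None]
    else:
        cols = np.column_stack(
            [(codes[keep] == 1).astype(float), (codes[keep] == 2).astype(float)]
        )
    return cols, keep


def _rss_batch(design: np.ndarray, y2: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sums of squares of every column of Y on one design."""
    q, _ = np.linalg.qr(design)
    qt_y = q.T @ Y
    rss = y2 - np.einsum("kt,kt->t", qt_y, qt_y)
    return np.maximum(rss, 0.0)


def _hk_lod_chrom(
    Y: np.ndarray,  # (n, T) complete traits
    gcols: np.ndarray,  # (n, P, g)
    dosage: np.ndarray,  # (n, P)
    cov_cols: np.ndarray | None,
    full: bool,
    rss_null: np.ndarray,  # (T,)
) -> tuple[np.ndarray, np.ndarray]:
    """(LOD matrix (T, P), degenerate flags (T, P)) for one chromosome."""
    n, T = Y.shape
    P = gcols.shape[1]
    ones = np.ones((n, 1))
    y2 = np.einsum("nt,nt->t", Y, Y)
    lod = np.empty((T, P))
    degen = np.zeros((T, P), dtype=bool)
    for j in range(P):
        parts = [ones]
        if cov_cols is not None:
            parts.append(cov_cols)
        parts.append(gcols[:, j, :])
        if full:
            assert cov_cols is not None
            parts.append(cov_cols * dosage[:, j][:, None])
        design = np.hstack(parts)
        rss = _rss_batch(design, y2, Y)
        bad = rss < _DEGENERATE_RSS
        degen[:, j] = bad
        rss = np.where(bad, _DEGENERATE_RSS, rss)
        lod[:, j] = (n / 2.0) * np.log10(rss_null / rss)
    return lod, degen


def _null_rss(Y: np.ndarray, cov_cols: np.ndarray | None) -> np.ndarray:
    n = Y.shape[0]
    y2 = np.einsum("nt,nt->t", Y, Y)
    if cov_cols is None:
        design = np.ones((n, 1))
    else:
        design = np.hstack([np.ones((n, 1)), cov_cols])
    rss = _rss_batch(design, y2, Y)
    return np.maximum(rss, _DEGENERATE_RSS)


@dataclass
class LodMatrices:
    """Batched scan output: per-chromosome (traits x positions) LOD."""

    trait_names: list[str]
    chrom_positions: dict[str, np.ndarray]
    chrom_is_x: dict[str, bool]
    lod: dict[str, np.ndarray]
    degenerate: dict[str, np.ndarray]
    method: str
    covariate: CovariateSpec | None = None

    def max_per_stratum(self) -> tuple[np.ndarray, np.ndarray]:
        """(autosome maxima, X maxima) per trait; empty stratum -> -inf."""
        T = len(self.trait_names)
        auto = np.full(T, -np.inf)
        x = np.full(T, -np.inf)
        for chrom, m in self.lod.items():
            cmax = np.nanmax(m, axis=1) if m.size else np.full(T, -np.inf)
            if self.chrom_is_x[chrom]:
                x = np.maximum(x, cmax)
            else:
                auto = np.maximum(auto, cmax)
        return auto, x

    def to_scan_result(self, trait: str) -> ScanResult:
        i = self.trait_names.index(trait)
        frames = []
        for chrom, positions in self.chrom_positions.items():
            frames.append(
                pd.DataFrame(
                    {
                        "chr": chrom,
                        "pos": positions,
                        "lod": self.lod[chrom][i],
                        "degenerate": self.degenerate[chrom][i],
                    }
                )
            )
        return ScanResult(trait, pd.concat(frames, ignore_index=True), self.method, self.covariate)


def scan_batch(
    Y: pd.DataFrame | np.ndarray,
    probs: GenotypeProbabilities,
    covariate: CovariateSpec | None = None,
    chromosomes: list[str] | None = None,
    trait_names: list[str] | None = None,
) -> LodMatrices:
    """Haley-Knott scan of many complete traits at once.

    ``Y`` is individuals x traits, rows ordered like the cross
    individuals. Missing values are not allowed here (use
    :func:`scan_single` for traits with missing entries).
    """
    if isinstance(Y, pd.DataFrame):
        trait_names = trait_names or [str(c) for c in Y.columns]
        Y = Y.to_numpy(dtype=float)
    else:
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        trait_names = trait_names or [f"trait{i}" for i in range(Y.shape[1])]
    if np.isnan(Y).any():
        raise ValueError("scan_batch requires complete traits")
    if chromosomes is None:
        chromosomes = list(probs.chroms)

    cov_cols = None
    keep = np.ones(Y.shape[0], dtype=bool)
    full = False
    if covariate is not None:
        cov_cols, keep = covariate_columns(probs, covariate)
        if keep.mean() < 0.8:
            raise ValueError(
                f"covariate marker {covariate.marker} missing for >20% of individuals"
            )
        full = covariate.kind == "full"
    Yk = Y[keep]
    Yk = Yk - Yk.mean(axis=0)  # centring improves conditioning only
    rss_null = _null_rss(Yk, cov_cols)

    lod: dict[str, np.ndarray] = {}
    degen: dict[str, np.ndarray] = {}
    positions: dict[str, np.ndarray] = {}
    is_x: dict[str, bool] = {}
    for chrom in chromosomes:
        gcols, dosage = _genotype_columns(probs, chrom)
        lod_c, degen_c = _hk_lod_chrom(
            Yk, gcols[keep], dosage[keep], cov_cols, full, rss_null
        )
        lod[chrom] = lod_c
        degen[chrom] = degen_c
        positions[chrom] = probs.chroms[chrom].positions
        is_x[chrom] = probs.chroms[chrom].is_x
    spec = covariate
    return LodMatrices(trait_names, positions, is_x, lod, degen, "hk", spec)


def _em_lod_position(
    y: np.ndarray, priors: np.ndarray, tol: float = 1e-6, max_iter: int = 1000
) -> float:
    """EM normal-mixture LOD at one position (class means, common SD)."""
    n = y.size
    k = priors.shape[1]
    w = priors / priors.sum(axis=1, keepdims=True)
    mu = np.array([np.average(y, weights=np.maximum(w[:, c], 1e-12)) for c in range(k)])
    resid2 = ((y[:, None] - mu[None, :]) ** 2 * w).sum()
    sigma2 = max(resid2 / n, _DEGENERATE_RSS)
    ll_prev = -np.inf
    for _ in range(max_iter):
        dens = np.exp(-0.5 * (y[:, None] - mu[None, :]) ** 2 / sigma2) / np.sqrt(
            2 * np.pi * sigma2
        )
        mix = priors * dens
        rowsum = mix.sum(axis=1)
        rowsum = np.maximum(rowsum, 1e-300)
        ll = float(np.log(rowsum).sum())
        w = mix / rowsum[:, None]
        cls_w = w.sum(axis=0)
        mu = np.where(cls_w > 1e-12, (w * y[:, None]).sum(axis=0) / np.maximum(cls_w, 1e-12), mu)
        sigma2 = max(((y[:, None] - mu[None, :]) ** 2 * w).sum() / n, _DEGENERATE_RSS)
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            break
        ll_prev = ll
    sigma2_null = max(np.var(y), _DEGENERATE_RSS)
    ll_null = -0.5 * n * (np.log(2 * np.pi * sigma2_null) + 1.0)
    return max((ll - ll_null) / np.log(10.0), 0.0)


def scan_single(
    trait: pd.Series | np.ndarray,
    probs: GenotypeProbabilities,
    method: str = "hk",
    covariate: CovariateSpec | None = None,
    chromosomes: list[str] | None = None,
    trait_name: str = "trait",
) -> ScanResult:
    """Scan one trait; missing trait values drop those individuals."""
    if isinstance(trait, pd.Series):
        trait_name = str(trait.name) if trait.name is not None else trait_name
        order = {i: j for j, i in enumerate(probs.individual_ids)}
        y = np.full(len(probs.individual_ids), np.nan)
        for i, v in trait.items():
            if str(i) in order:
                y[order[str(i)]] = v
    else:
        y = np.asarray(trait, dtype=float)
    ok = ~np.isnan(y)
    sub = _subset_probs(probs, ok)
    if method == "hk":
        mats = scan_batch(y[ok][:, None], sub, covariate, chromosomes, [trait_name])
        return mats.to_scan_result(trait_name)
    if method != "em":
        raise ValueError(f"unknown method {method!r}")
    if covariate is not None:
        raise NotImplementedError("EM scans support covariate=None only; use HK")
    if chromosomes is None:
        chromosomes = list(sub.chroms)
    frames = []
    yv = y[ok]
    for chrom in chromosomes:
        cp = sub.chroms[chrom]
        lods = np.array(
            [_em_lod_position(yv, cp.probs[:, j, :]) for j in range(cp.positions.size)]
        )
        frames.append(
            pd.DataFrame({"chr": chrom, "pos": cp.positions, "lod": lods, "degenerate": False})
        )
    return ScanResult(trait_name, pd.concat(frames, ignore_index=True), "em", None)


def _subset_probs(probs: GenotypeProbabilities, keep: np.ndarray) -> GenotypeProbabilities:
    if keep.all():
        return probs
    from dataclasses import replace

    chroms = {
        name: replace(cp, probs=cp.probs[keep]) for name, cp in probs.chroms.items()
    }
    ids = [i for i, k in zip(probs.individual_ids, keep) if k]
    return GenotypeProbabilities(chroms, ids, probs.step_cm, probs.error_rate, probs.map_function)


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------


def stratum_lengths(probs: GenotypeProbabilities) -> tuple[float, float]:
    la = sum(
        float(c.positions[-1] - c.positions[0])
        for c in probs.chroms.values()
        if not c.is_x
    )
    lx = sum(
        float(c.positions[-1] - c.positions[0]) for c in probs.chroms.values() if c.is_x
    )
    return la, lx


def split_alpha(alpha: float, probs: GenotypeProbabilities) -> tuple[float, float]:
    """Partition genome-wide alpha between autosomes and X by map length."""
    la, lx = stratum_lengths(probs)
    total = la + lx
    if total == 0:
        raise ValueError("empty map")
    return alpha * la / total, alpha * lx / total


def scaled_x_perms(n_perm_auto: int, probs: GenotypeProbabilities) -> int:
    """X-stratum permutation count scaled by the autosome/X length ratio,
    so the much smaller X alpha remains estimable."""
    la, lx = stratum_lengths(probs)
    if lx == 0:
        return 0
    return int(round(n_perm_auto * la / lx))


def _null_quantile(null: np.ndarray, alpha: float) -> float:
    return float(np.quantile(null, 1.0 - alpha, method="higher"))


def _perm_matrix(y: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    return np.column_stack([y[rng.permutation(y.size)] for _ in range(n_perm)])


def permutation_threshold(
    trait: np.ndarray | pd.Series,
    probs: GenotypeProbabilities,
    method: str = "hk",
    covariate: CovariateSpec | None = None,
    n_perm_auto: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    n_perm_x: int | None = None,
) -> tuple[PermutationThresholds, NullDistribution]:
    """Single-transcript permutation threshold with a separate X stratum.

    The trait is shuffled across individuals; per permutation the maximum
    LOD over autosomes (and, under an independent stream, over the X) is
    recorded. Thresholds are upper (1 - alpha_stratum) quantiles with the
    genome-wide alpha split by map length.
    """
    if n_perm_auto < 20:
        raise ValueError("need at least 20 permutations")
    y = np.asarray(trait, dtype=float)
    if np.isnan(y).any():
        raise ValueError("permutation thresholds require a complete trait")
    alpha_a, alpha_x = split_alpha(alpha, probs)
    autosomes = probs.autosome_names()
    x_chroms = probs.x_names()
    if n_perm_x is None:
        n_perm_x = scaled_x_perms(n_perm_auto, probs) if x_chroms else 0

    rng_a = np.random.default_rng([seed, 0])
    null_a = np.full(n_perm_auto, -np.inf)
    if autosomes:
        Yp = _perm_matrix(y, n_perm_auto, rng_a)
        mats = scan_batch(Yp, probs, covariate, autosomes)
        null_a, _ = mats.max_per_stratum()
    rng_x = np.random.default_rng([seed, 1])
    null_x = np.full(max(n_perm_x, 1), np.inf)
    thr_x = np.inf
    if x_chroms and n_perm_x:
        Yp = _perm_matrix(y, n_perm_x, rng_x)
        mats = scan_batch(Yp, probs, covariate, x_chroms)
        _, null_x = mats.max_per_stratum()
        thr_x = _null_quantile(null_x, min(alpha_x, 1.0))
    thr_a = _null_quantile(null_a, min(alpha_a, 1.0)) if autosomes else np.inf
    thresholds = PermutationThresholds(
        thr_a, thr_x, alpha, n_perm_auto, n_perm_x, seed, "single_transcript"
    )
    return thresholds, NullDistribution(null_a, null_x)


def dataset_threshold(
    Y: pd.DataFrame | np.ndarray,
    probs: GenotypeProbabilities,
    n_perm: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[PermutationThresholds, NullDistribution]:
    """Dataset-wide threshold: permute the individual-id <-> expression
    column assignment once per replicate (preserving inter-transcript
    correlation), scan every trait, and record the maximum LOD over all
    transcripts per stratum.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    if isinstance(Y, pd.DataFrame):
        Y = Y.to_numpy(dtype=float)
    n = Y.shape[0]
    alpha_a, alpha_x = split_alpha(alpha, probs)
    autosomes = probs.autosome_names()
    x_chroms = probs.x_names()
    rng_a = np.random.default_rng([seed, 0])
    rng_x = np.random.default_rng([seed, 1])
    null_a = np.full(n_perm, -np.inf)
    null_x = np.full(n_perm, -np.inf)
    for p in range(n_perm):
        if autosomes:
            Yp = Y[rng_a.permutation(n)]
            mats = scan_batch(Yp, probs, chromosomes=autosomes)
            a, _ = mats.max_per_stratum()
            null_a[p] = a.max()
        if x_chroms:
            Yp = Y[rng_x.permutation(n)]
            mats = scan_batch(Yp, probs, chromosomes=x_chroms)
            _, x = mats.max_per_stratum()
            null_x[p] = x.max()
    thr_a = _null_quantile(null_a, min(alpha_a, 1.0)) if autosomes else np.inf
    thr_x = _null_quantile(null_x, min(alpha_x, 1.0)) if x_chroms else np.inf
    thresholds = PermutationThresholds(thr_a, thr_x, alpha, n_perm, n_perm, seed, "dataset")
    return thresholds, NullDistribution(null_a, null_x if x_chroms else np.full(1, np.inf))


# ---------------------------------------------------------------------------
# P values, q values, support intervals
# ---------------------------------------------------------------------------


def perm_pvalues(observed: np.ndarray, null_sorted: np.ndarray) -> np.ndarray:
    """Permutation-tail P: (1 + #{null >= obs}) / (n_perm + 1)."""
    null_sorted = np.sort(np.asarray(null_sorted, dtype=float))
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    n = null_sorted.size
    n_ge = n - np.searchsorted(null_sorted, obs, side="left")
    p = (1.0 + n_ge) / (n + 1.0)
    if np.any((p <= 0) | (p > 1)):
        raise RuntimeError("permutation P value outside (0, 1]")
    return p


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """pi0 by the smoother method: pi0(lambda) on a grid, cubic smooth,
    evaluated at the largest lambda; clamped to (0, 1]."""
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return float(min(max(pi0, 1e-8), 1.0))


def storey_qvalues(p: np.ndarray) -> tuple[np.ndarray, float]:
    """Storey q-values: q_i = min over p_j >= p_i of pi0 * n * p_j / rank_j."""
    p = np.asarray(p, dtype=float)
    pi0 = storey_pi0(p)
    n = p.size
    order = np.argsort(p)
    ranked = pi0 * n * p[order] / (np.arange(n) + 1.0)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q, pi0


def lod_to_pq(
    max_lods: np.ndarray, null: NullDistribution, stratum: str = "autosome"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Chromosome-maximum LODs -> permutation P values -> Storey q-values."""
    null_vals = null.autosome if stratum == "autosome" else null.x
    p = perm_pvalues(max_lods, null_vals)
    q, pi0 = storey_qvalues(p)
    return p, q, pi0


def lod_support_interval(
    scan: ScanResult, chrom: str, drop: float = 1.5
) -> tuple[float, float]:
    """LOD support interval: outermost grid positions within ``drop`` of
    the peak, each extended outward by one grid position when available."""
    tbl = scan.chrom_table(chrom)
    pos = tbl["pos"].to_numpy()
    lod = tbl["lod"].to_numpy()
    finite = np.nan_to_num(lod, nan=-np.inf)
    peak = finite.max()
    if peak <= 0:
        warnings.warn(
            f"flat LOD profile on chromosome {chrom}; whole-chromosome interval",
            stacklevel=2,
        )
        return float(pos[0]), float(pos[-1])
    inside = np.flatnonzero(finite >= peak - drop)
    lo_i = max(inside[0] - 1, 0)
    hi_i = min(inside[-1] + 1, pos.size - 1)
    return float(pos[lo_i]), float(pos[hi_i])
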