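"""Covariate-conditional eQTL mapping and the epistatic network.

For a genotype covariate at a typed marker, each trait is scanned under
an additive model (covariate main effect) and a full model (adding
covariate x QTL interaction terms); LOD_i = LOD_f - LOD_a measures the
interaction evidence. Thresholds come from permutations in which the
same shuffled trait is scanned under both models, so LOD_i nulls are
internally paired. An interaction eQTL requires both LOD_f and LOD_i to
clear their thresholds. Interaction-eQTL peaks are clustered into
hotspots with the trans-hotspot machinery, and covariate -> peak edges
are assembled into a network whose nodes merge nearby genomic regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross import GeneticMap, cm_to_mb
from .catalog import EqtlRecord
from .genoprob import GenotypeProbabilities
from .hotspots import Hotspot, call_hotspots, hotspot_null_thresholds, window_counts
from .scan import (
    CovariateSpec,
    LodMatrices,
    NullDistribution,
    _perm_matrix,
    _null_quantile,
    scan_batch,
    split_alpha,
    scaled_x_perms,
)


@dataclass
class ConditionalScanResult:
    trait: str
    covariate: CovariateSpec
    table: pd.DataFrame  # chr, pos, lod_f, lod_a, lod_i (NaN where masked)

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chr"] == chrom]


@dataclass
class InteractionEqtl:
    trait: str
    covariate_marker: str
    covariate_chrom: str
    chrom: str
    pos_cm: float
    lod_f: float
    lod_i: float


@dataclass
class InteractionThresholds:
    lod_f: dict[str, float]  # per stratum: autosome, X
    lod_a: dict[str, float]
    lod_i: dict[str, float]
    alpha: float
    n_perm: int
    seed: int


def _self_mask(
    probs: GenotypeProbabilities, cov: CovariateSpec, guard_cm: float = 5.0
) -> dict[str, np.ndarray]:
    """Positions within the guard window of the covariate marker are
    masked to prevent trivial self-interaction signals."""
    masks = {}
    cov_cm = None
    cp = probs.chroms[cov.chrom]
    j = cp.marker_names.index(cov.marker)
    cov_cm = cp.positions[j]
    for chrom, c in probs.chroms.items():
        m = np.zeros(c.positions.size, dtype=bool)
        if chrom == cov.chrom:
            m = np.abs(c.positions - cov_cm) < guard_cm
        masks[chrom] = m
    return masks


def conditional_scan_batch(
    Y: pd.DataFrame | np.ndarray,
    probs: GenotypeProbabilities,
    cov_chrom: str,
    cov_marker: str,
    guard_cm: float = 5.0,
    trait_names: list[str] | None = None,
) -> tuple[LodMatrices, LodMatrices, dict[str, np.ndarray]]:
    """(full-model LODs, additive-model LODs, self-mask) for many traits."""
    add = CovariateSpec("additive", cov_chrom, cov_marker)
    full = CovariateSpec("full", cov_chrom, cov_marker)
    mats_a = scan_batch(Y, probs, add, trait_names=trait_names)
    mats_f = scan_batch(Y, probs, full, trait_names=trait_names)
    masks = _self_mask(probs, add, guard_cm)
    for chrom, m in masks.items():
        if m.any():
            mats_a.lod[chrom][:, m] = np.nan
            mats_f.lod[chrom][:, m] = np.nan
    return mats_f, mats_a, masks


def conditional_scan(
    trait: np.ndarray | pd.Series,
    probs: GenotypeProbabilities,
    cov_chrom: str,
    cov_marker: str,
    guard_cm: float = 5.0,
    trait_name: str = "trait",
) -> ConditionalScanResult:
    """Additive and full scans of one trait; LOD_i is their difference."""
    y = np.asarray(trait, dtype=float)
    mats_f, mats_a, _ = conditional_scan_batch(
        y[:, None], probs, cov_chrom, cov_marker, guard_cm, [trait_name]
    )
    frames = []
    for chrom in mats_f.lod:
        lf = mats_f.lod[chrom][0]
        la = mats_a.lod[chrom][0]
        frames.append(
            pd.DataFrame(
                {
                    "chr": chrom,
                    "pos": mats_f.chrom_positions[chrom],
                    "lod_f": lf,
                    "lod_a": la,
                    "lod_i": lf - la,
                }
            )
        )
    return ConditionalScanResult(
        trait_name,
        CovariateSpec("full", cov_chrom, cov_marker),
        pd.concat(frames, ignore_index=True),
    )


def interaction_thresholds(
    trait: np.ndarray | pd.Series,
    probs: GenotypeProbabilities,
    cov_chrom: str,
    cov_marker: str,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    guard_cm: float = 5.0,
    n_perm_x: int | None = None,
) -> InteractionThresholds:
    """Same-seed permutation thresholds for LOD_f, LOD_a and LOD_i.

    Each permutation's shuffled trait is scanned under both models, and
    that permutation's LOD_i profile is the paired difference — maxima
    are never mixed across permutations. The genome-wide alpha is split
    between autosome and X strata by map length, as in the marginal
    scans.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    y = np.asarray(trait, dtype=float)
    alpha_a, alpha_x = split_alpha(alpha, probs)
    strata = {"autosome": (probs.autosome_names(), alpha_a, n_perm)}
    x_names = probs.x_names()
    if x_names:
        npx = n_perm_x if n_perm_x is not None else scaled_x_perms(n_perm, probs)
        strata["X"] = (x_names, alpha_x, npx)

    thr_f: dict[str, float] = {}
    thr_a: dict[str, float] = {}
    thr_i: dict[str, float] = {}
    for si, (name, (chroms, a_str, n_p)) in enumerate(strata.items()):
        if not chroms:
            continue
        rng = np.random.default_rng([seed, si])
        Yp = _perm_matrix(y, n_p, rng)
        mats_f, mats_a, _ = conditional_scan_batch(
            Yp, probs, cov_chrom, cov_marker, guard_cm
        )
        max_f = np.full(n_p, -np.inf)
        max_a = np.full(n_p, -np.inf)
        max_i = np.full(n_p, -np.inf)
        for chrom in chroms:
            lf = mats_f.lod[chrom]
            la = mats_a.lod[chrom]
            li = lf - la
            with np.errstate(invalid="ignore"):
                max_f = np.fmax(max_f, np.nanmax(lf, axis=1))
                max_a = np.fmax(max_a, np.nanmax(la, axis=1))
                max_i = np.fmax(max_i, np.nanmax(li, axis=1))
        a_eff = min(a_str, 1.0)
        thr_f[name] = _null_quantile(max_f, a_eff)
        thr_a[name] = _null_quantile(max_a, a_eff)
        thr_i[name] = _null_quantile(max_i, a_eff)
    return InteractionThresholds(thr_f, thr_a, thr_i, alpha, n_perm, seed)


def call_interaction_eqtl(
    cond: ConditionalScanResult,
    thresholds: InteractionThresholds,
    chrom_is_x: dict[str, bool],
) -> list[InteractionEqtl]:
    """Per chromosome, the maximum-LOD_f position among positions where
    both LOD_f and LOD_i clear their stratum thresholds; at most one
    record per trait per chromosome."""
    out: list[InteractionEqtl] = []
    for chrom in cond.table["chr"].unique():
        stratum = "X" if chrom_is_x[chrom] else "autosome"
        if stratum not in thresholds.lod_f:
            continue
        tbl = cond.chrom_table(chrom)
        lf = tbl["lod_f"].to_numpy()
        li = tbl["lod_i"].to_numpy()
        ok = (lf >= thresholds.lod_f[stratum]) & (li >= thresholds.lod_i[stratum])
        ok &= ~np.isnan(lf)
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        best = idx[np.argmax(lf[idx])]
        out.append(
            InteractionEqtl(
                trait=cond.trait,
                covariate_marker=cond.covariate.marker,
                covariate_chrom=cond.covariate.chrom,
                chrom=str(chrom),
                pos_cm=float(tbl["pos"].to_numpy()[best]),
                lod_f=float(lf[best]),
                lod_i=float(li[best]),
            )
        )
    return out


def interaction_hotspots(
    records: list[InteractionEqtl],
    gmap: GeneticMap,
    probes: pd.DataFrame,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    window_cm: float = 4.0,
    step_cm: float = 2.0,
) -> list[Hotspot]:
    """Cluster interaction-eQTL peaks with the trans-hotspot machinery."""
    if not records:
        return []
    as_eqtl = [
        EqtlRecord(probe=r.trait, chrom=r.chrom, pos_cm=r.pos_cm, lod=r.lod_f)
        for r in records
    ]
    counts = window_counts(as_eqtl, gmap, window_cm, step_cm)
    thresholds = hotspot_null_thresholds(
        as_eqtl,
        gmap,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
        window_cm=window_cm,
        step_cm=step_cm,
        probes=probes,
    )
    return call_hotspots(counts, thresholds, as_eqtl, gmap)


# ---------------------------------------------------------------------------
# Network assembly and covariate summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkNode:
    chrom: str
    lo_mb: float
    hi_mb: float
    sterile_allele: str = "undetermined"

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.lo_mb:.2f}-{self.hi_mb:.2f}"


@dataclass
class NetworkEdge:
    source: NetworkNode
    target: NetworkNode
    count: int
    reciprocal: bool = False


def _merge_regions(
    regions: list[tuple[str, float, float, str]], merge_mb: float
) -> list[NetworkNode]:
    """Single-linkage merge of same-chromosome regions whose gap is
    below the merge distance; order-independent."""
    nodes: list[NetworkNode] = []
    by_chrom: dict[str, list[tuple[float, float, str]]] = {}
    for chrom, lo, hi, allele in regions:
        by_chrom.setdefault(chrom, []).append((lo, hi, allele))
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom])
        groups: list[list[tuple[float, float, str]]] = [[items[0]]]
        for item in items[1:]:
            if item[0] - max(h for _, h, _ in groups[-1]) < merge_mb:
                groups[-1].append(item)
            else:
                groups.append([item])
        for g in groups:
            alleles = {a for _, _, a in g if a != "undetermined"}
            allele = alleles.pop() if len(alleles) == 1 else (
                "mixed" if alleles else "undetermined"
            )
            nodes.append(
                NetworkNode(chrom, min(l for l, _, _ in g), max(h for _, h, _ in g), allele)
            )
    return nodes


def build_network(
    hotspots_by_covariate: dict[tuple[str, str], list[Hotspot]],
    gmap: GeneticMap,
    merge_mb: float = 12.8,
    sterile_alleles: dict[str, str] | None = None,
) -> tuple[list[NetworkNode], list[NetworkEdge]]:
    """Assemble covariate -> interaction-hotspot edges into a network.

    Keys of ``hotspots_by_covariate`` are (covariate chromosome, marker);
    covariate positions and hotspot spans become genomic regions, and
    same-chromosome regions closer than ``merge_mb`` collapse into one
    node. ``sterile_alleles`` optionally colors covariate regions by
    marker name.
    """
    sterile_alleles = sterile_alleles or {}
    regions: list[tuple[str, float, float, str]] = []
    cov_region: dict[tuple[str, str], tuple[str, float, float]] = {}
    for (chrom, marker), hs_list in hotspots_by_covariate.items():
        _, m = gmap.marker(marker)
        mb = m.mb if not np.isnan(m.mb) else cm_to_mb(gmap, chrom, m.cm)
        cov_region[(chrom, marker)] = (chrom, mb, mb)
        regions.append((chrom, mb, mb, sterile_alleles.get(marker, "undetermined")))
        for h in hs_list:
            regions.append((h.chrom, h.lo_mb, h.hi_mb, h.sterile_allele))
    nodes = _merge_regions(regions, merge_mb)

    def node_of(chrom: str, lo: float, hi: float) -> NetworkNode:
        for nd in nodes:
            if nd.chrom == chrom and nd.lo_mb <= lo and hi <= nd.hi_mb:
                return nd
        raise RuntimeError("region not covered by any node")

    edge_counts: dict[tuple[NetworkNode, NetworkNode], int] = {}
    for key, hs_list in hotspots_by_covariate.items():
        src = node_of(*cov_region[key])
        for h in hs_list:
            dst = node_of(h.chrom, h.lo_mb, h.hi_mb)
            edge_counts[(src, dst)] = edge_counts.get((src, dst), 0) + h.count
    edges = []
    for (src, dst), count in edge_counts.items():
        edges.append(
            NetworkEdge(src, dst, count, reciprocal=(dst, src) in edge_counts)
        )
    return nodes, edges


def to_networkx(nodes: list[NetworkNode], edges: list[NetworkEdge]):
    """Directed graph for visualization tools."""
    import networkx as nx

    g = nx.DiGraph()
    for nd in nodes:
        g.add_node(nd.label, chrom=nd.chrom, lo_mb=nd.lo_mb, hi_mb=nd.hi_mb,
                   sterile_allele=nd.sterile_allele)
    for e in edges:
        g.add_edge(e.source.label, e.target.label, count=e.count, reciprocal=e.reciprocal)
    return g


def edges_table(edges: list[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "src_chr": e.source.chrom,
                "src_lo": e.source.lo_mb,
                "src_hi": e.source.hi_mb,
                "dst_chr": e.target.chrom,
                "dst_lo": e.target.lo_mb,
                "dst_hi": e.target.hi_mb,
                "count": e.count,
                "reciprocal": e.reciprocal,
                "sterile_src": e.source.sterile_allele,
            }
            for e in edges
        ]
    )


@dataclass
class CovariateSummary:
    covariate_marker: str
    n_interaction_eqtl: int
    n_hotspots: int
    n_chromosomes_with_hotspots: int
    pct_covariate_marginal: float
    pct_peak_marginal: float
    pct_reciprocal: float


def covariate_summary(
    records: list[InteractionEqtl],
    hotspots: list[Hotspot],
    original: list[EqtlRecord],
    all_records: list[InteractionEqtl],
    gmap: GeneticMap,
    match_cm: float = 5.0,
) -> CovariateSummary:
    """Summarize one covariate's conditional-mapping results.

    pct_covariate_marginal / pct_peak_marginal: fraction of interaction
    eQTL whose trait had a significant eQTL in the original (no
    covariate) catalog within ``match_cm`` of the covariate / the peak.
    pct_reciprocal: fraction with a significant interaction eQTL in the
    reversed covariate/peak configuration anywhere in ``all_records``.
    """
    if not records:
        return CovariateSummary("", 0, len(hotspots), 0, 0.0, 0.0, 0.0)
    marker = records[0].covariate_marker
    cov_chrom, cov_m = records[0].covariate_chrom, None
    _, m = gmap.marker(marker)
    cov_cm = m.cm

    orig_by_trait: dict[str, list[EqtlRecord]] = {}
    for r in original:
        orig_by_trait.setdefault(r.probe, []).append(r)

    def has_original(trait: str, chrom: str, pos: float) -> bool:
        return any(
            r.chrom == chrom and abs(r.pos_cm - pos) < match_cm
            for r in orig_by_trait.get(trait, [])
        )

    def has_reverse(rec: InteractionEqtl) -> bool:
        for other in all_records:
            if other.trait != rec.trait:
                continue
            _, om = gmap.marker(other.covariate_marker)
            if (
                other.covariate_chrom == rec.chrom
                and abs(om.cm - rec.pos_cm) < match_cm
                and other.chrom == rec.covariate_chrom
                and abs(other.pos_cm - cov_cm) < match_cm
            ):
                return True
        return False

    n = len(records)
    cov_marg = sum(has_original(r.trait, cov_chrom, cov_cm) for r in records)
    peak_marg = sum(has_original(r.trait, r.chrom, r.pos_cm) for r in records)
    recip = sum(has_reverse(r) for r in records)
    return CovariateSummary(
        covariate_marker=marker,
        n_interaction_eqtl=n,
        n_hotspots=len(hotspots),
        n_chromosomes_with_hotspots=len({h.chrom for h in hotspots}),
        pct_covariate_marginal=100.0 * cov_marg / n,
        pct_peak_marginal=100.0 * peak_marg / n,
        pct_reciprocal=100.0 * recip / n,
    )
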