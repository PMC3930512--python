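"""From genome scans to an annotated eQTL table.

Per transcript and chromosome, the maximum-LOD grid position becomes an
eQTL record when it clears the stratum permutation threshold. Records
are classified cis (peak within the cis window of the probe, same
chromosome), trans (different chromosome), or excluded (same chromosome
but outside the window), and annotated with a dominance class and an
effect size measured between extreme genotype-class means at the peak's
nearest typed marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cross import GeneticMap, cm_to_mb
from .genoprob import GenotypeProbabilities, genotype_at_marker
from .scan import LodMatrices, PermutationThresholds

DOMINANCE_CLASSES = (
    "additive",
    "dominant_A",
    "dominant_B",
    "overdominant",
    "underdominant",
    "unclassified",
    "additive_hemizygous",
)


@dataclass
class EqtlRecord:
    probe: str
    chrom: str
    pos_cm: float
    lod: float
    pos_mb: float = float("nan")
    kind: str = "unclassified"  # cis | trans | excluded
    dominance: str = "unclassified"
    effect: float = float("nan")
    high_allele: str = ""  # A | B | het
    low_class: str = ""  # genotype class with the lowest mean
    peak_marker: str = ""
    class_means: dict = field(default_factory=dict)


def extract_peaks(
    mats: LodMatrices, thresholds: PermutationThresholds
) -> list[EqtlRecord]:
    """At most one record per trait per chromosome: the left-most maximum
    if it exceeds the stratum threshold."""
    records: list[EqtlRecord] = []
    for chrom, lod in mats.lod.items():
        thr = thresholds.for_chrom(mats.chrom_is_x[chrom])
        positions = mats.chrom_positions[chrom]
        finite = np.nan_to_num(lod, nan=-np.inf)
        best = np.argmax(finite, axis=1)  # argmax returns first (left-most) max
        best_lod = finite[np.arange(lod.shape[0]), best]
        for ti in np.flatnonzero(best_lod > thr):
            records.append(
                EqtlRecord(
                    probe=mats.trait_names[ti],
                    chrom=chrom,
                    pos_cm=float(positions[best[ti]]),
                    lod=float(best_lod[ti]),
                )
            )
    records.sort(key=lambda r: (r.probe, r.chrom))
    return records


def classify_cis_trans(
    record: EqtlRecord, probes: pd.DataFrame, cis_window_cm: float = 5.0
) -> str:
    """cis if same chromosome and |peak - probe| < window; trans if a
    different chromosome; excluded otherwise (same chromosome, far)."""
    ann = probes.loc[record.probe]
    if str(ann["chr"]) != record.chrom:
        return "trans"
    if abs(float(ann["cM"]) - record.pos_cm) < cis_window_cm:
        return "cis"
    return "excluded"


def classify_dominance_effect(
    trait: np.ndarray,
    classes: np.ndarray,
    is_x: bool,
    se_multiplier: float = 2.0,
    min_class_n: int = 3,
) -> tuple[str, float, str, str, dict]:
    """Dominance from genotype-class means at the peak marker.

    ``classes`` are integer codes (autosome 0=AA,1=AB,2=BB; X 0=A,1=B;
    -1 missing). Returns (dominance, effect size, high allele,
    low class, class means). The heterozygote mean is compared to each
    homozygote mean in units of that class pair's combined standard
    error of the difference.
    """
    y = np.asarray(trait, dtype=float)
    ok = (classes >= 0) & ~np.isnan(y)
    y, g = y[ok], classes[ok]

    def class_stats(code: int) -> tuple[float, float, int]:
        vals = y[g == code]
        n = vals.size
        if n == 0:
            return np.nan, np.nan, 0
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return float(vals.mean()), se, n

    if is_x:
        m_a, _, n_a = class_stats(0)
        m_b, _, n_b = class_stats(1)
        means = {"A": m_a, "B": m_b}
        if min(n_a, n_b) < min_class_n:
            return "unclassified", np.nan, "", "", means
        effect = abs(m_b - m_a)
        high, low = ("B", "A") if m_b >= m_a else ("A", "B")
        return "additive_hemizygous", effect, high, low, means

    (m_aa, se_aa, n_aa) = class_stats(0)
    (m_ab, se_ab, n_ab) = class_stats(1)
    (m_bb, se_bb, n_bb) = class_stats(2)
    means = {"AA": m_aa, "het": m_ab, "BB": m_bb}
    if min(n_aa, n_ab, n_bb) < min_class_n:
        return "unclassified", np.nan, "", "", means
    effect = abs(m_bb - m_aa)
    order = {"A": m_aa, "het": m_ab, "B": m_bb}
    high = max(order, key=order.get)
    low = min(order, key=order.get)

    def sed(se1: float, se2: float) -> float:
        return float(np.hypot(se1, se2))

    d_a = abs(m_ab - m_aa)
    d_b = abs(m_ab - m_bb)
    far_a = d_a > se_multiplier * sed(se_ab, se_aa)
    far_b = d_b > se_multiplier * sed(se_ab, se_bb)
    lo_hom, hi_hom = min(m_aa, m_bb), max(m_aa, m_bb)
    if lo_hom <= m_ab <= hi_hom:
        if far_a and far_b:
            return "additive", effect, high, low, means
        if far_a and not far_b:
            return "dominant_B", effect, high, low, means
        if far_b and not far_a:
            return "dominant_A", effect, high, low, means
        return "unclassified", effect, high, low, means
    extreme = hi_hom if m_ab > hi_hom else lo_hom
    se_ext = se_bb if extreme == m_bb else se_aa
    if abs(m_ab - extreme) > se_multiplier * sed(se_ab, se_ext):
        mode = "overdominant" if m_ab > hi_hom else "underdominant"
        return mode, effect, high, low, means
    return "unclassified", effect, high, low, means


def annotate_records(
    records: list[EqtlRecord],
    expr_f2: pd.DataFrame,  # probe x F2 sample, columns ordered like probs individuals
    probs: GenotypeProbabilities,
    gmap: GeneticMap,
    probes: pd.DataFrame,
    cis_window_cm: float = 5.0,
    se_multiplier: float = 2.0,
) -> list[EqtlRecord]:
    """Fill kind, Mb position, dominance, effect size and allele labels."""
    geno_cache: dict[tuple[str, str], np.ndarray] = {}
    for rec in records:
        rec.kind = classify_cis_trans(rec, probes, cis_window_cm)
        try:
            rec.pos_mb = cm_to_mb(gmap, rec.chrom, rec.pos_cm)
        except ValueError:
            rec.pos_mb = float("nan")
        cp = probs.chroms[rec.chrom]
        rec.peak_marker = cp.nearest_marker(rec.pos_cm)
        key = (rec.chrom, rec.peak_marker)
        if key not in geno_cache:
            geno_cache[key] = genotype_at_marker(probs, rec.chrom, rec.peak_marker)
        y = expr_f2.loc[rec.probe].to_numpy(dtype=float)
        dom, eff, high, low, means = classify_dominance_effect(
            y, geno_cache[key], cp.is_x, se_multiplier
        )
        rec.dominance, rec.effect, rec.high_allele, rec.low_class = dom, eff, high, low
        rec.class_means = means
    return records


def records_table(records: list[EqtlRecord], probes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for r in records:
        ann = probes.loc[r.probe]
        rows.append(
            {
                "probe": r.probe,
                "probe_chr": ann["chr"],
                "probe_cM": ann["cM"],
                "eqtl_chr": r.chrom,
                "eqtl_cM": r.pos_cm,
                "eqtl_Mb": r.pos_mb,
                "LOD": r.lod,
                "class": r.kind,
                "dominance": r.dominance,
                "effect": r.effect,
                "high_allele": r.high_allele,
            }
        )
    return pd.DataFrame(rows)


def enrichment_test(
    qtt: set[str], annotation: set[str], universe: set[str], n_tests: int = 1
) -> tuple[float, float]:
    """Upper-tail hypergeometric enrichment with Bonferroni adjustment."""
    if not universe:
        raise ValueError("empty probe universe")
    if not qtt <= universe or not annotation <= universe:
        raise ValueError("qtt and annotation sets must be subsets of the universe")
    overlap = len(qtt & annotation)
    p = float(sps.hypergeom.sf(overlap - 1, len(universe), len(annotation), len(qtt)))
    return p, min(1.0, p * n_tests)


def infer_sterile_allele(
    member_records: list[EqtlRecord],
    f1_calls: pd.Series,  # probe -> over|under|none (sterile-F1 pattern)
    min_members: int = 20,
    concordance_cutoff: float = 0.60,
    het_dominance_fraction: float = 0.50,
    phenotype_correlations: pd.Series | None = None,
) -> tuple[str, dict[str, float]]:
    """Infer which genotype class at a hotspot carries the "sterile"
    expression pattern.

    Each member transcript votes: if it is underexpressed in the sterile
    F1, its low-expression class at the hotspot is the candidate sterile
    class; if overexpressed, its high class. The majority class wins at
    >= ``concordance_cutoff`` of votes; 'het' is eligible only when at
    least half the member eQTL are over- or underdominant. Returns the
    allele (A | B | het | undetermined) and the vote fractions; when
    phenotype correlations are supplied, the fraction of voting members
    positively correlated with fertility is reported under 'frac_fertility_pos'.
    """
    info: dict[str, float] = {}
    if len(member_records) < min_members:
        return "undetermined", info
    dom_frac = float(
        np.mean([r.dominance in ("overdominant", "underdominant") for r in member_records])
    )
    het_ok = dom_frac >= het_dominance_fraction
    votes: dict[str, int] = {"A": 0, "B": 0, "het": 0}
    voters: list[EqtlRecord] = []
    for rec in member_records:
        call = f1_calls.get(rec.probe, "none")
        if call == "under":
            cls = rec.low_class
        elif call == "over":
            cls = rec.high_allele
        else:
            continue
        if cls in votes:
            votes[cls] += 1
            voters.append(rec)
    if not het_ok:
        votes.pop("het")
    total = sum(votes.values())
    info = {f"frac_{k}": (v / total if total else 0.0) for k, v in votes.items()}
    info["n_votes"] = float(total)
    info["frac_overunderdominant"] = dom_frac
    if phenotype_correlations is not None and voters:
        rs = [
            phenotype_correlations.get(r.probe, np.nan)
            for r in voters
            if f1_calls.get(r.probe) == "under"
        ]
        rs = [r for r in rs if not np.isnan(r)]
        info["frac_fertility_pos"] = float(np.mean([r > 0 for r in rs])) if rs else np.nan
    if total == 0:
        return "undetermined", info
    winner = max(votes, key=votes.get)
    if votes[winner] / total >= concordance_cutoff:
        return winner, info
    return "undetermined", info
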