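"""Synthetic F2 intercrosses with known genetic architecture.

The generator emulates a cross between two diverged inbred lines
("A" = domesticus-like, "B" = musculus-like): male F2s genotyped on a
sparse SNP map (19 autosomes + X), expression traits with cis effects,
trans master-regulator loci of configurable dominance (including the
underdominant pattern characteristic of hybrid incompatibility), purely
epistatic locus pairs with zero marginal effects, parental/F1 control
groups, and Gaussian sterility phenotypes.

Crossovers are laid down interval-by-interval with independent
recombination events (no interference), so the Markov assumption of the
genotype-probability HMM holds exactly for a matched map function.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cross import (
    Chromosome,
    CrossData,
    ExpressionData,
    GeneticMap,
    Marker,
)
from .genoprob import map_to_recfrac

EFFECT_MODES = ("additive", "dominant_A", "dominant_B", "overdominant", "underdominant")

# per-mode multiplier of the effect for autosomal classes (AA, AB, BB).
# over- and underdominant both shift heterozygotes only: the effect's
# sign carries the direction (positive -> het above the homozygotes,
# negative -> het below), the mode name documents the intent.
_MODE_WEIGHTS = {
    "additive": (0.0, 0.5, 1.0),
    "dominant_A": (0.0, 0.0, 1.0),
    "dominant_B": (0.0, 1.0, 1.0),
    "overdominant": (0.0, 1.0, 0.0),
    "underdominant": (0.0, 1.0, 0.0),
}


@dataclass(frozen=True)
class CisEffect:
    probe: str
    marker: str
    additive: float  # half the homozygote difference, log2 units
    dominance: float = 0.0


@dataclass(frozen=True)
class MasterLocus:
    """A trans-acting regulator: one marker shifting many probes."""

    marker: str
    probes: tuple[str, ...]
    effect: float  # log2 shift applied per the mode weights
    mode: str = "additive"

    def __post_init__(self) -> None:
        if self.mode not in EFFECT_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class EpistaticPair:
    """Two-locus effect applied only to named two-locus genotype classes.

    ``effects`` maps (genotype1, genotype2) string codes to a log2 delta;
    unlisted classes get zero, so marginal effects can be exactly zero by
    construction (e.g. the product pattern from :func:`product_epistasis`).
    """

    marker1: str
    marker2: str
    probes: tuple[str, ...]
    effects: dict[tuple[str, str], float]


@dataclass(frozen=True)
class PhenotypeQtl:
    """Single-locus phenotype effect, or — when ``partner_marker`` and
    ``two_locus_class`` are set — a Dobzhansky-Muller-style effect
    applied only to one two-locus genotype class."""

    marker: str
    trait: str
    effect: float
    mode: str = "additive"
    partner_marker: str | None = None
    two_locus_class: tuple[str, str] | None = None


@dataclass
class SimArchitecture:
    cis_effects: list[CisEffect] = field(default_factory=list)
    master_loci: list[MasterLocus] = field(default_factory=list)
    epistatic_pairs: list[EpistaticPair] = field(default_factory=list)
    phenotype_qtl: list[PhenotypeQtl] = field(default_factory=list)
    baseline_a: dict[str, float] = field(default_factory=dict)  # per-probe parent-A level
    baseline_b: dict[str, float] = field(default_factory=dict)
    probes: list[str] = field(default_factory=list)
    noise_sd: float = 0.25
    trait_baselines: dict[str, float] = field(default_factory=dict)
    trait_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD cannot be negative")
        if not self.probes:
            self.probes = sorted(
                {e.probe for e in self.cis_effects}
                | {p for m in self.master_loci for p in m.probes}
                | {p for e in self.epistatic_pairs for p in e.probes}
                | set(self.baseline_a)
            )
        seen: dict[str, str] = {}
        for e in self.cis_effects:
            if e.probe in seen and seen[e.probe] != e.marker:
                raise ValueError(f"probe {e.probe!r} has conflicting cis entries")
            seen[e.probe] = e.marker

    def validate_against(self, gmap: GeneticMap) -> None:
        markers = set(gmap.marker_names)
        refs = (
            [e.marker for e in self.cis_effects]
            + [m.marker for m in self.master_loci]
            + [m for e in self.epistatic_pairs for m in (e.marker1, e.marker2)]
            + [q.marker for q in self.phenotype_qtl]
            + [q.partner_marker for q in self.phenotype_qtl if q.partner_marker]
        )
        missing = sorted(set(refs) - markers)
        if missing:
            raise ValueError(f"architecture references unknown markers: {missing}")


@dataclass
class GroundTruth:
    architecture: SimArchitecture
    seed: int
    genotypes: pd.DataFrame | None = None


def product_epistasis(effect: float) -> dict[tuple[str, str], float]:
    """Symmetric +/- two-locus pattern with exactly zero marginal means
    for unlinked loci: delta = effect * u(g1) * u(g2), u = (-1, 0, +1)."""
    u = {"AA": -1.0, "AB": 0.0, "BB": 1.0}
    return {
        (g1, g2): effect * u[g1] * u[g2]
        for g1 in u
        for g2 in u
        if u[g1] * u[g2] != 0.0
    }


def dmi_epistasis(effect: float, cls: tuple[str, str] = ("AA", "BB")) -> dict[tuple[str, str], float]:
    """Dobzhansky-Muller-style incompatibility: a single deleterious
    two-locus class."""
    return {cls: effect}


# ---------------------------------------------------------------------------
# Map and genotypes
# ---------------------------------------------------------------------------

# autosome lengths loosely mouse-like: longest first, ~50-100 cM
_DEFAULT_AUTOSOME_LENGTHS = tuple(np.round(np.linspace(98.0, 54.0, 19), 1))


def simulate_map(
    n_autosomes: int = 19,
    lengths_cm: tuple[float, ...] | None = None,
    marker_spacing_cm: float = 8.0,
    x_length_cm: float = 70.0,
    mb_per_cm: float = 2.0,
) -> GeneticMap:
    """Evenly spaced markers on ``n_autosomes`` autosomes plus an X.

    Mb positions default to 2 x cM. The defaults give a 20-chromosome,
    ~200-marker map resembling a sparse mouse SNP panel.
    """
    if lengths_cm is None:
        lengths_cm = _DEFAULT_AUTOSOME_LENGTHS[:n_autosomes]
    if len(lengths_cm) != n_autosomes:
        raise ValueError("need one length per autosome")
    chroms: list[Chromosome] = []
    for ci, length in enumerate(list(lengths_cm) + [x_length_cm], start=1):
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
        if marker_spacing_cm > length:
            raise ValueError(
                f"marker spacing {marker_spacing_cm} exceeds chromosome length {length}"
            )
        name = "X" if ci == n_autosomes + 1 else str(ci)
        kind = "X" if name == "X" else "autosome"
        positions = np.arange(0.0, length + 1e-9, marker_spacing_cm)
        markers = [
            Marker(f"M{name}_{i}", float(p), float(p) * mb_per_cm)
            for i, p in enumerate(positions)
        ]
        chroms.append(Chromosome(name, kind, markers))
    return GeneticMap(chroms)


def _gamete(cm: np.ndarray, rng: np.random.Generator, map_function: str) -> np.ndarray:
    """One recombinant F1 gamete: allele (0/1) per marker."""
    alleles = np.empty(cm.size, dtype=np.int8)
    alleles[0] = rng.integers(2)
    rs = np.array([map_to_recfrac(d, map_function) for d in np.diff(cm)])
    flips = rng.random(rs.size) < rs
    alleles[1:] = alleles[0] ^ np.cumsum(flips, dtype=np.int8) % 2
    return alleles


def simulate_f2(
    gmap: GeneticMap,
    n: int = 300,
    seed: int = 0,
    direction_mix: float = 0.5,
    map_function: str = "haldane",
    genotyping_error_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> tuple[CrossData, GroundTruth]:
    """Simulate ``n`` F2 males from an F1 sibling mating.

    Each autosome receives two independent recombinant F1 gametes; the
    male X is a single recombinant maternal gamete (hemizygous). Optional
    genotyping errors replace a code with a uniformly chosen wrong code.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"F2_{i:04d}" for i in range(1, n + 1)]
    rows: list[np.ndarray] = []
    index: list[str] = []
    geno_blocks: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosomes:
        cm = chrom.cm_positions
        if chrom.is_x:
            codes = np.array(["A", "B"])
            mat = np.empty((cm.size, n), dtype=object)
            for j in range(n):
                mat[:, j] = codes[_gamete(cm, rng, map_function)]
        else:
            codes = np.array(["AA", "AB", "BB"])
            mat = np.empty((cm.size, n), dtype=object)
            for j in range(n):
                g = _gamete(cm, rng, map_function) + _gamete(cm, rng, map_function)
                mat[:, j] = codes[g]
        geno_blocks[chrom.name] = mat
        index.extend(m.name for m in chrom.markers)
        rows.append(mat)
    geno = pd.DataFrame(np.vstack(rows), index=index, columns=ids)
    truth_geno = geno.copy()

    if genotyping_error_rate > 0:
        for chrom in gmap.chromosomes:
            names = [m.name for m in chrom.markers]
            valid = ["A", "B"] if chrom.is_x else ["AA", "AB", "BB"]
            block = geno.loc[names].to_numpy()
            hit = rng.random(block.shape) < genotyping_error_rate
            for (i, j) in zip(*np.nonzero(hit)):
                wrong = [c for c in valid if c != block[i, j]]
                block[i, j] = wrong[rng.integers(len(wrong))]
            geno.loc[names] = block
    if missing_rate > 0:
        drop = rng.random(geno.shape) < missing_rate
        geno = geno.mask(drop)

    directions = np.where(rng.random(n) < direction_mix, "MxD", "DxM")
    individuals = pd.DataFrame({"id": ids, "sex": "male", "cross_direction": directions})
    cross = CrossData(gmap, individuals, geno)
    return cross, GroundTruth(SimArchitecture(noise_sd=1.0), seed, truth_geno)


# ---------------------------------------------------------------------------
# Expression and phenotypes
# ---------------------------------------------------------------------------


def _class_weight(code: str, mode: str, is_x: bool) -> float:
    if is_x:  # hemizygous: two classes, additive by definition
        return {"A": 0.0, "B": 1.0}[code]
    return _MODE_WEIGHTS[mode][("AA", "AB", "BB").index(code)]


def _genetic_matrix(
    probes: list[str],
    geno: pd.DataFrame,  # marker x sample genotype codes (strings)
    is_x_of: dict[str, bool],
    arch: SimArchitecture,
) -> np.ndarray:
    """Genotype-dependent log2 contributions, probes x samples."""
    probe_idx = {p: i for i, p in enumerate(probes)}
    out = np.zeros((len(probes), geno.shape[1]))

    def weights(marker: str, mode: str) -> np.ndarray:
        codes = geno.loc[marker].to_numpy()
        return np.array([_class_weight(g, mode, is_x_of[marker]) for g in codes])

    for e in arch.cis_effects:
        codes = geno.loc[e.marker].to_numpy()
        if is_x_of[e.marker]:
            contrib = np.where(codes == "B", 2.0 * e.additive, 0.0)
        else:
            lut = {"AA": -e.additive, "AB": e.dominance, "BB": e.additive}
            contrib = np.array([lut[g] for g in codes])
        out[probe_idx[e.probe]] += contrib
    for m in arch.master_loci:
        w = m.effect * weights(m.marker, m.mode)
        rows = [probe_idx[p] for p in m.probes]
        out[rows] += w[None, :]
    for ep in arch.epistatic_pairs:
        g1 = geno.loc[ep.marker1].to_numpy()
        g2 = geno.loc[ep.marker2].to_numpy()
        delta = np.array(
            [ep.effects.get((a, b), 0.0) for a, b in zip(g1, g2)]
        )
        rows = [probe_idx[p] for p in ep.probes]
        out[rows] += delta[None, :]
    return out


def _fixed_genotype(group: str, is_x: bool) -> str:
    """Genotype of control samples: inbred parents and F1 males.

    F1 males carry the X of their mother: parent A for DxM, B for MxD.
    """
    if group == "parentA":
        return "A" if is_x else "AA"
    if group == "parentB":
        return "B" if is_x else "BB"
    if group == "F1_DxM":
        return "A" if is_x else "AB"
    if group == "F1_MxD":
        return "B" if is_x else "AB"
    raise ValueError(group)


def default_probe_annotation(gmap: GeneticMap, arch: SimArchitecture, rng: np.random.Generator) -> pd.DataFrame:
    """Place probes on the map: cis probes at their marker, others random."""
    cis_marker = {e.probe: e.marker for e in arch.cis_effects}
    marker_pos = {m.name: (c.name, m.cm, m.mb) for c in gmap.chromosomes for m in c.markers}
    autosomes = [c for c in gmap.chromosomes if not c.is_x]
    rows = []
    for probe in arch.probes:
        if probe in cis_marker:
            chrom, cm, mb = marker_pos[cis_marker[probe]]
        else:
            c = autosomes[rng.integers(len(autosomes))]
            cm = float(np.round(rng.uniform(0, c.length_cm), 2))
            chrom = c.name
            mb = float(np.interp(cm, c.cm_positions, c.mb_positions))
        rows.append({"probe_id": probe, "gene": probe, "chr": chrom, "cM": cm, "Mb": mb})
    return pd.DataFrame(rows).set_index("probe_id")


def simulate_expression(
    cross: CrossData,
    arch: SimArchitecture,
    n_parent_a: int = 8,
    n_parent_b: int = 8,
    n_f1_dxm: int = 6,
    n_f1_mxd: int = 4,
    seed: int = 0,
    probe_annotation: pd.DataFrame | None = None,
) -> tuple[ExpressionData, GroundTruth]:
    """Log2 expression for F2s plus parental and reciprocal-F1 controls.

    value = lineage baseline + genotype-dependent effects + N(0, noise_sd).
    Parents take their own per-probe baseline; F1s and F2s take the
    parental midpoint, so under a pure-noise architecture F2 values are
    centred between the parental means.
    """
    arch.validate_against(cross.map)
    rng = np.random.default_rng(seed)
    gmap = cross.map
    is_x_of = {m.name: c.is_x for c in gmap.chromosomes for m in c.markers}

    probes = list(arch.probes)
    base_a = np.array([arch.baseline_a.get(p, 8.0) for p in probes])
    base_b = np.array([arch.baseline_b.get(p, 8.0) for p in probes])
    base_mid = 0.5 * (base_a + base_b)

    f2_ids = list(cross.individuals["id"])
    f2_genetic = _genetic_matrix(probes, cross.genotypes, is_x_of, arch)
    blocks = [base_mid[:, None] + f2_genetic]
    sample_rows = [{"id": i, "group": "F2"} for i in f2_ids]

    control_groups = [
        ("parentA", n_parent_a, base_a),
        ("parentB", n_parent_b, base_b),
        ("F1_DxM", n_f1_dxm, base_mid),
        ("F1_MxD", n_f1_mxd, base_mid),
    ]
    markers = cross.map.marker_names
    for group, count, base in control_groups:
        if count == 0:
            continue
        fixed = pd.DataFrame(
            {f"{group}_{i}": [_fixed_genotype(group, is_x_of[mk]) for mk in markers]
             for i in range(1, count + 1)},
            index=markers,
        )
        genetic = _genetic_matrix(probes, fixed, is_x_of, arch)
        blocks.append(base[:, None] + genetic)
        sample_rows.extend({"id": c, "group": group} for c in fixed.columns)

    samples = pd.DataFrame(sample_rows)
    values = pd.DataFrame(
        np.hstack(blocks), index=probes, columns=list(samples["id"])
    )
    values = values + rng.normal(0.0, arch.noise_sd, size=values.shape)
    if probe_annotation is None:
        probe_annotation = default_probe_annotation(gmap, arch, rng)
    expr = ExpressionData(samples, values, probe_annotation.loc[probes])
    return expr, GroundTruth(arch, seed)


DEFAULT_STERILITY_TRAITS = (
    "testis_weight",
    "sperm_density",
    "abnormal_sperm",
    "tubule_area",
)


def simulate_phenotypes(
    cross: CrossData,
    arch: SimArchitecture,
    seed: int = 0,
    traits: tuple[str, ...] = DEFAULT_STERILITY_TRAITS,
) -> pd.DataFrame:
    """Gaussian sterility phenotypes with genotype-dependent means.

    An underdominant QTL with negative effect depresses the trait in
    heterozygotes only, emulating heterosis-breaking incompatibility at
    a hybrid-sterility locus.
    """
    for q in arch.phenotype_qtl:
        if q.trait not in traits:
            raise ValueError(f"unknown trait {q.trait!r} in architecture")
    arch.validate_against(cross.map)
    rng = np.random.default_rng(seed)
    is_x_of = {m.name: c.is_x for c in cross.map.chromosomes for m in c.markers}
    n = cross.n_individuals
    data = {}
    for trait in traits:
        mean = np.full(n, arch.trait_baselines.get(trait, 0.0))
        for q in arch.phenotype_qtl:
            if q.trait != trait:
                continue
            codes = cross.genotypes.loc[q.marker].to_numpy()
            if q.partner_marker is not None:
                codes2 = cross.genotypes.loc[q.partner_marker].to_numpy()
                w = np.array(
                    [
                        1.0 if (g1, g2) == q.two_locus_class else 0.0
                        for g1, g2 in zip(codes, codes2)
                    ]
                )
            else:
                w = np.array(
                    [_class_weight(g, q.mode, is_x_of[q.marker]) for g in codes]
                )
            mean = mean + q.effect * w
        data[trait] = mean + rng.normal(0.0, arch.trait_noise_sd, size=n)
    return pd.DataFrame(data, index=list(cross.individuals["id"]))
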