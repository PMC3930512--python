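"""Core data containers for an F2 intercross: genetic map, genotypes,
expression matrix, phenotypes, and the file formats that carry them.

Coordinates are chromosome-local centimorgans (cM) with the origin at the
first marker; physical megabase (Mb) positions are carried alongside for
reporting and are obtained from the cM grid by linear interpolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOME_CODES = ("AA", "AB", "BB")
X_MALE_CODES = ("A", "B")
MISSING_TOKENS = {"-", "", "NA", "nan", "N"}


@dataclass(frozen=True)
class Marker:
    name: str
    cm: float
    mb: float = float("nan")


@dataclass
class Chromosome:
    """An ordered run of markers; ``kind`` is 'autosome' or 'X'."""

    name: str
    kind: str
    markers: list[Marker]

    @property
    def cm_positions(self) -> np.ndarray:
        return np.array([m.cm for m in self.markers], dtype=float)

    @property
    def mb_positions(self) -> np.ndarray:
        return np.array([m.mb for m in self.markers], dtype=float)

    @property
    def length_cm(self) -> float:
        return self.markers[-1].cm - self.markers[0].cm

    @property
    def is_x(self) -> bool:
        return self.kind == "X"


@dataclass
class GeneticMap:
    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for chrom in self.chromosomes:
            if chrom.kind not in ("autosome", "X"):
                raise ValueError(f"unknown chromosome kind {chrom.kind!r}")
            if len(chrom.markers) < 2:
                raise ValueError(
                    f"chromosome {chrom.name} has {len(chrom.markers)} marker(s); "
                    "at least 2 required"
                )
            prev = -np.inf
            for m in chrom.markers:
                if m.name in seen:
                    raise ValueError(f"duplicate marker name {m.name!r}")
                seen.add(m.name)
                if m.cm < prev:
                    raise ValueError(
                        f"cM positions decrease at marker {m.name!r} on "
                        f"chromosome {chrom.name}"
                    )
                prev = m.cm
            mb = chrom.mb_positions
            ok = mb[~np.isnan(mb)]
            if ok.size and np.any(np.diff(ok) < 0):
                raise ValueError(f"Mb positions decrease on chromosome {chrom.name}")

    def chromosome(self, name: str) -> Chromosome:
        for chrom in self.chromosomes:
            if chrom.name == name:
                return chrom
        raise KeyError(f"no chromosome named {name!r}")

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def marker_names(self) -> list[str]:
        return [m.name for c in self.chromosomes for m in c.markers]

    def marker(self, name: str) -> tuple[Chromosome, Marker]:
        for chrom in self.chromosomes:
            for m in chrom.markers:
                if m.name == name:
                    return chrom, m
        raise KeyError(f"no marker named {name!r}")

    def autosome_length_cm(self) -> float:
        return sum(c.length_cm for c in self.chromosomes if not c.is_x)

    def x_length_cm(self) -> float:
        return sum(c.length_cm for c in self.chromosomes if c.is_x)


@dataclass
class CrossData:
    """Genotypes and phenotypes for a set of F2 males.

    ``genotypes`` is a marker x individual frame of string codes
    (AA/AB/BB on autosomes, A/B on the hemizygous male X; NaN missing).
    """

    map: GeneticMap
    individuals: pd.DataFrame  # columns: id, sex, cross_direction
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = list(self.individuals["id"])
        if list(self.genotypes.columns) != ids:
            raise ValueError("genotype columns do not match individual ids")
        if list(self.genotypes.index) != self.map.marker_names:
            raise ValueError("genotype rows do not match map markers")
        for chrom in self.map.chromosomes:
            names = [m.name for m in chrom.markers]
            block = self.genotypes.loc[names]
            valid = set(X_MALE_CODES if chrom.is_x else AUTOSOME_CODES)
            bad = ~block.isin(valid) & block.notna()
            if bad.to_numpy().any():
                marker = bad.index[bad.any(axis=1)][0]
                indiv = bad.columns[bad.loc[marker]][0]
                raise ValueError(
                    f"invalid genotype code at marker {marker!r}, "
                    f"individual {indiv!r} on {chrom.kind} chromosome {chrom.name}"
                )
        if self.phenotypes is not None:
            unknown = set(self.phenotypes.index) - set(ids)
            if unknown:
                raise ValueError(f"phenotype rows for unknown individuals: {sorted(unknown)[:5]}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def chromosome_genotypes(self, name: str) -> pd.DataFrame:
        chrom = self.map.chromosome(name)
        return self.genotypes.loc[[m.name for m in chrom.markers]]


@dataclass
class ExpressionData:
    """Log2 expression (probe x sample) with probe genomic annotation.

    Samples carry a ``group`` label: F2, parentA, parentB, F1_DxM, F1_MxD.
    """

    samples: pd.DataFrame  # columns: id, group
    values: pd.DataFrame  # probe x sample
    probes: pd.DataFrame  # index probe_id; columns: gene, chr, cM, Mb

    GROUPS = ("F2", "parentA", "parentB", "F1_DxM", "F1_MxD")

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples["id"]):
            raise ValueError("expression columns do not match sample ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        bad = set(self.samples["group"]) - set(self.GROUPS)
        if bad:
            raise ValueError(f"unknown sample groups: {sorted(bad)}")
        if self.probes["chr"].isna().any() or self.probes["cM"].isna().any():
            raise ValueError("every probe needs a chromosome and cM position")

    def group_ids(self, group: str) -> list[str]:
        return list(self.samples.loc[self.samples["group"] == group, "id"])

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.group_ids(group)]

    @property
    def f2_values(self) -> pd.DataFrame:
        return self.group_values("F2")


@dataclass(frozen=True)
class SterilityQtlInterval:
    """A previously mapped sterility QTL: peak and 1.5-LOD support interval."""

    trait: str
    chrom: str
    peak_cm: float
    lo_cm: float
    hi_cm: float
    sterile_allele: str  # A | B | het

    def __post_init__(self) -> None:
        if not (self.lo_cm <= self.peak_cm <= self.hi_cm):
            raise ValueError(
                f"interval for {self.trait}: need lo <= peak <= hi, got "
                f"{self.lo_cm}, {self.peak_cm}, {self.hi_cm}"
            )
        if self.sterile_allele not in ("A", "B", "het"):
            raise ValueError(f"bad sterile allele {self.sterile_allele!r}")


@dataclass
class AnalysisConfig:
    """Tuning constants shared across pipeline stages.

    Defaults: 2 cM probability grid, genotyping error 1e-3, 5 cM cis
    window, 0.5 log2 misexpression delta with a 2-SE guard, 4 cM hotspot
    windows, 12.8 Mb network node merging, alpha 0.05.
    """

    grid_step_cm: float = 2.0
    genotyping_error_rate: float = 0.001
    cis_window_cm: float = 5.0
    misexpression_delta: float = 0.5
    se_multiplier: float = 2.0
    hotspot_window_cm: float = 4.0
    node_merge_mb: float = 12.8
    alpha: float = 0.05
    map_function: str = "carter_falconer"
    n_perm_single: int = 200
    n_perm_dataset: int = 50
    n_perm_hotspot: int = 200
    n_perm_coloc: int = 100
    n_perm_interaction: int = 100
    fertile_percentile: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        positives = dict(
            grid_step_cm=self.grid_step_cm,
            cis_window_cm=self.cis_window_cm,
            misexpression_delta=self.misexpression_delta,
            se_multiplier=self.se_multiplier,
            hotspot_window_cm=self.hotspot_window_cm,
            node_merge_mb=self.node_merge_mb,
        )
        for key, val in positives.items():
            if val <= 0:
                raise ValueError(f"{key} must be positive, got {val}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.genotyping_error_rate < 0:
            raise ValueError("genotyping error rate cannot be negative")


# ---------------------------------------------------------------------------
# File IO: "rotated-header" cross CSV, phenotype CSV, probe/expression TSV
# ---------------------------------------------------------------------------


def _norm_code(code: object) -> object:
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return np.nan
    text = str(code).strip()
    if text in MISSING_TOKENS:
        return np.nan
    return text


def read_cross(
    geno_path: str | Path,
    pheno_path: str | Path | None = None,
    map_path: str | Path | None = None,
    x_name: str = "X",
) -> CrossData:
    """Read a cross CSV (rotated-header dialect) and optional phenotype CSV.

    Layout: row 1 = id column header then marker names, row 2 = chromosome
    labels, row 3 = cM positions, remaining rows = one individual each.
    Unknown genotype codes are converted to missing with a logged count.
    An optional ``map_path`` TSV (marker, chr, cM, Mb) supplies physical
    positions, which the cross CSV does not carry.
    """
    raw = pd.read_csv(geno_path, header=None, dtype=str)
    marker_names = [str(v) for v in raw.iloc[0, 1:]]
    if len(set(marker_names)) != len(marker_names):
        dupes = sorted({m for m in marker_names if marker_names.count(m) > 1})
        raise ValueError(f"duplicate marker names in {geno_path}: {dupes}")
    chrom_labels = [str(v) for v in raw.iloc[1, 1:]]
    cms = [float(v) for v in raw.iloc[2, 1:]]

    mb_lookup: dict[str, float] = {}
    if map_path is not None:
        map_tbl = pd.read_csv(map_path, sep="\t")
        mb_lookup = dict(zip(map_tbl["marker"], map_tbl["Mb"].astype(float)))

    chromosomes: list[Chromosome] = []
    for label in dict.fromkeys(chrom_labels):
        idx = [i for i, c in enumerate(chrom_labels) if c == label]
        markers = []
        prev = -np.inf
        for i in idx:
            if cms[i] < prev:
                raise ValueError(
                    f"cM decreasing at marker {marker_names[i]!r} on chromosome {label}"
                )
            prev = cms[i]
            markers.append(
                Marker(marker_names[i], cms[i], mb_lookup.get(marker_names[i], float("nan")))
            )
        kind = "X" if label == x_name else "autosome"
        chromosomes.append(Chromosome(label, kind, markers))
    gmap = GeneticMap(chromosomes)

    ids = [str(v) for v in raw.iloc[3:, 0]]
    geno = raw.iloc[3:, 1:].T
    geno.index = marker_names
    geno.columns = ids
    geno = geno.map(_norm_code)

    # unknown codes -> missing with a warning count; invalid-for-chromosome
    # codes (AB on the male X) stay and trip validation as a hard error
    n_unknown = 0
    all_codes = set(AUTOSOME_CODES) | set(X_MALE_CODES)
    unknown_mask = ~geno.isin(all_codes) & geno.notna()
    n_unknown = int(unknown_mask.to_numpy().sum())
    if n_unknown:
        logger.warning("%d unknown genotype codes set to missing", n_unknown)
        geno = geno.where(~unknown_mask)

    # reorder rows to map order (grouped-by-chromosome order of the header)
    geno = geno.loc[gmap.marker_names]

    individuals = pd.DataFrame(
        {"id": ids, "sex": "male", "cross_direction": "DxM"}
    )
    phenotypes = None
    if pheno_path is not None:
        phenotypes = pd.read_csv(pheno_path)
        phenotypes["id"] = phenotypes["id"].astype(str)
        if "cross_direction" in phenotypes.columns:
            directions = dict(zip(phenotypes["id"], phenotypes["cross_direction"]))
            individuals["cross_direction"] = [
                directions.get(i, "DxM") for i in ids
            ]
            phenotypes = phenotypes.drop(columns=["cross_direction"])
        phenotypes = phenotypes.set_index("id")
    return CrossData(gmap, individuals, geno, phenotypes)


def write_cross(cross: CrossData, geno_path: str | Path, pheno_path: str | Path | None = None) -> None:
    """Write the rotated-header cross CSV (and optional phenotype CSV)."""
    chrom_of = {
        m.name: c.name for c in cross.map.chromosomes for m in c.markers
    }
    cm_of = {m.name: m.cm for c in cross.map.chromosomes for m in c.markers}
    markers = cross.map.marker_names
    lines = ["id," + ",".join(markers)]
    lines.append("," + ",".join(chrom_of[m] for m in markers))
    lines.append("," + ",".join(_fmt_num(cm_of[m]) for m in markers))
    geno = cross.genotypes.fillna("-")
    for ind in cross.individuals["id"]:
        lines.append(str(ind) + "," + ",".join(str(v) for v in geno[ind]))
    Path(geno_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if pheno_path is not None and cross.phenotypes is not None:
        tbl = cross.phenotypes.copy()
        tbl.insert(
            0,
            "cross_direction",
            [
                cross.individuals.set_index("id").loc[i, "cross_direction"]
                for i in tbl.index
            ],
        )
        tbl.to_csv(pheno_path, index_label="id")


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    rows = [
        {"marker": m.name, "chr": c.name, "cM": m.cm, "Mb": m.mb}
        for c in gmap.chromosomes
        for m in c.markers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_expression(expr: ExpressionData, values_path: str | Path, probes_path: str | Path, samples_path: str | Path | None = None) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="probe_id")
    expr.probes.to_csv(probes_path, sep="\t", index_label="probe_id")
    if samples_path is not None:
        expr.samples.to_csv(samples_path, sep="\t", index=False)


def read_expression(values_path: str | Path, probes_path: str | Path, samples_path: str | Path) -> ExpressionData:
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    values.columns = [str(c) for c in values.columns]
    probes = pd.read_csv(probes_path, sep="\t", index_col="probe_id", dtype={"chr": str})
    samples = pd.read_csv(samples_path, sep="\t", dtype={"id": str})
    return ExpressionData(samples, values, probes)


# ---------------------------------------------------------------------------
# Coordinate utilities and sample-subset selection
# ---------------------------------------------------------------------------


def cm_to_mb(gmap: GeneticMap, chrom: str, pos_cm: float) -> float:
    """Interpolate a physical Mb position from a cM position.

    Linear interpolation between the flanking markers; positions outside
    the marker range are clamped to the terminal markers with a warning.
    """
    c = gmap.chromosome(chrom)
    cm = c.cm_positions
    mb = c.mb_positions
    ok = ~np.isnan(mb)
    if ok.sum() < 2:
        raise ValueError(f"chromosome {chrom} has <2 markers with Mb positions")
    cm, mb = cm[ok], mb[ok]
    if pos_cm < cm[0] or pos_cm > cm[-1]:
        warnings.warn(
            f"position {pos_cm} cM outside marker range on chromosome {chrom}; clamped",
            stacklevel=2,
        )
    return float(np.interp(pos_cm, cm, mb))


def select_fertile_subset(
    phenotypes: pd.DataFrame,
    traits: Sequence[str],
    percentile: float = 0.20,
) -> set[str]:
    """Select individuals above a percentile of the first principal
    component of the sterility traits.

    Complete cases only; traits are standardized; PC1 is oriented so the
    first listed trait (conventionally testis weight) loads positively,
    making higher scores "more fertile". Returns ids with PC1 strictly
    above the given percentile of the PC1 scores.
    """
    tbl = phenotypes[list(traits)].dropna()
    if len(tbl) < 5:
        raise ValueError(f"only {len(tbl)} complete individuals; need >=5 for PCA")
    x = tbl.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.all(sd == 0):
        warnings.warn("all sterility traits constant; returning full set", stacklevel=2)
        return set(tbl.index)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=0)) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    load = vt[0]
    if load[0] < 0:
        load = -load
    scores = z @ load
    cutoff = float(np.quantile(scores, percentile))
    return set(tbl.index[scores > cutoff])
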