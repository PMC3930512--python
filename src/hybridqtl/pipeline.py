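"""End-to-end orchestration: simulate a cross to disk, analyze it in
stages, and rerun the eQTL stages on a fertile subset.

Every stage derives its seed from the master seed by a fixed offset, so
stages rerun independently yet reproducibly and two runs from one master
seed produce byte-identical outputs. A JSON manifest records the config
snapshot, executed stages, per-stage seeds, and SHA-256 digests of every
file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import hotspots as hot
from . import interactions as ixn
from . import misexpression as mis
from .cross import (
    AnalysisConfig,
    CrossData,
    ExpressionData,
    SterilityQtlInterval,
    read_cross,
    read_expression,
    select_fertile_subset,
    write_cross,
    write_expression,
    write_map,
)
from .genoprob import calc_genoprob
from .scan import (
    PermutationThresholds,
    lod_support_interval,
    nqrank,
    permutation_threshold,
    scan_batch,
    scan_single,
)
from .simulate import (
    CisEffect,
    EpistaticPair,
    MasterLocus,
    PhenotypeQtl,
    SimArchitecture,
    product_epistasis,
    simulate_expression,
    simulate_f2,
    simulate_map,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the master seed
STAGE_SEEDS = {
    "cross": 1,
    "expression": 2,
    "phenotypes": 3,
    "threshold": 10,
    "dataset_threshold": 11,
    "misexpression_qtl": 12,
    "sterility_scan": 13,
    "hotspot_null": 20,
    "colocalization": 21,
    "interaction": 30,
}

ALL_STAGES = (
    "scan",
    "misexpression",
    "catalog",
    "hotspots",
    "colocalize",
    "interactions",
    "network",
)


@dataclass
class SimSettings:
    """Simulation scale: a mouse-like 20-chromosome map with ~200 markers
    and the default control-group sizes (8 per parent, 6 + 4 F1s)."""

    n_f2: int = 300
    n_autosomes: int = 19
    marker_spacing_cm: float = 8.0
    x_length_cm: float = 70.0
    n_parent_a: int = 8
    n_parent_b: int = 8
    n_f1_dxm: int = 6
    n_f1_mxd: int = 4
    n_cis: int = 40
    n_master_probes: int = 60
    n_epistatic_probes: int = 20
    n_null_probes: int = 60
    cis_effect: float = 1.0
    master_effect: float = 1.0
    epistatic_effect: float = 1.2
    sterility_effect: float = -2.0
    noise_sd: float = 0.25
    map_function: str = "haldane"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: list[str] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)
    version: str = "hybridqtl-0.1.0"

    def record(self, outdir: Path, *names: str) -> None:
        for n in names:
            self.digests[n] = _sha256(outdir / n)

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def demo_architecture(gmap, sim: SimSettings, seed: int) -> SimArchitecture:
    """A study-like architecture: cis effects spread over the genome, an
    underdominant trans master regulator coupled to a sterility QTL at
    the same marker (a hybrid-incompatibility locus), one purely
    epistatic pair with zero marginal effects, and null probes."""
    rng = np.random.default_rng(seed)
    markers = [(c, m) for c in gmap.chromosomes for m in c.markers]
    autosomal = [(c, m) for c, m in markers if not c.is_x]

    cis = []
    for i in range(sim.n_cis):
        c, m = autosomal[rng.integers(len(autosomal))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        cis.append(CisEffect(f"cis_{i:03d}", m.name, sign * sim.cis_effect))

    # master regulator on the first autosome, epistatic pair on two others
    autos = [c for c in gmap.chromosomes if not c.is_x]
    if len(autos) < 3:
        raise ValueError("demo architecture needs at least 3 autosomes")
    mchrom = autos[0]
    mmarker = mchrom.markers[len(mchrom.markers) // 2]
    master_probes = tuple(f"trans_{i:03d}" for i in range(sim.n_master_probes))
    master = MasterLocus(mmarker.name, master_probes, sim.master_effect, "underdominant")

    c1, c2 = autos[len(autos) // 2], autos[-1]
    e1 = c1.markers[len(c1.markers) // 2]
    e2 = c2.markers[len(c2.markers) // 2]
    epi_probes = tuple(f"epi_{i:03d}" for i in range(sim.n_epistatic_probes))
    pair = EpistaticPair(e1.name, e2.name, epi_probes, product_epistasis(sim.epistatic_effect))

    null_probes = [f"null_{i:03d}" for i in range(sim.n_null_probes)]
    probes = (
        [c.probe for c in cis] + list(master_probes) + list(epi_probes) + null_probes
    )
    pheno_qtl = [
        PhenotypeQtl(mmarker.name, "testis_weight", sim.sterility_effect, "underdominant"),
        PhenotypeQtl(mmarker.name, "sperm_density", sim.sterility_effect, "underdominant"),
    ]
    return SimArchitecture(
        cis_effects=cis,
        master_loci=[master],
        epistatic_pairs=[pair],
        phenotype_qtl=pheno_qtl,
        probes=probes,
        noise_sd=sim.noise_sd,
        trait_baselines={"testis_weight": 10.0, "sperm_density": 5.0},
    )


def simulate_to_dir(
    outdir: str | Path,
    sim: SimSettings | None = None,
    config: AnalysisConfig | None = None,
    force: bool = False,
) -> RunManifest:
    """Generate a full synthetic data set on disk."""
    sim = sim or SimSettings()
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty; use force=True")
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    gmap = simulate_map(
        sim.n_autosomes,
        marker_spacing_cm=sim.marker_spacing_cm,
        x_length_cm=sim.x_length_cm,
    )
    arch = demo_architecture(gmap, sim, seed)
    cross, truth = simulate_f2(
        gmap, sim.n_f2, seed + STAGE_SEEDS["cross"], map_function=sim.map_function
    )
    expr, _ = simulate_expression(
        cross,
        arch,
        sim.n_parent_a,
        sim.n_parent_b,
        sim.n_f1_dxm,
        sim.n_f1_mxd,
        seed + STAGE_SEEDS["expression"],
    )
    pheno = simulate_phenotypes(cross, arch, seed + STAGE_SEEDS["phenotypes"])
    cross.phenotypes = pheno
    cross.validate()

    manifest = RunManifest(config={"analysis": asdict(config), "simulation": asdict(sim)})
    manifest.stages.append("simulate")
    manifest.seeds = {k: seed + v for k, v in STAGE_SEEDS.items()}
    write_cross(cross, outdir / "cross.csv", outdir / "phenotypes.csv")
    write_map(gmap, outdir / "map.tsv")
    write_expression(
        expr, outdir / "expression.tsv", outdir / "probes.tsv", outdir / "samples.tsv"
    )
    truth_doc = {
        "seed": seed,
        "map_function": sim.map_function,
        "cis_effects": [asdict(c) for c in arch.cis_effects],
        "master_loci": [
            {**asdict(m), "probes": list(m.probes)} for m in arch.master_loci
        ],
        "epistatic_pairs": [
            {
                "marker1": p.marker1,
                "marker2": p.marker2,
                "probes": list(p.probes),
                "effects": {f"{a}|{b}": v for (a, b), v in p.effects.items()},
            }
            for p in arch.epistatic_pairs
        ],
        "phenotype_qtl": [asdict(q) for q in arch.phenotype_qtl],
        "noise_sd": arch.noise_sd,
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth_doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    manifest.record(
        outdir,
        "cross.csv",
        "phenotypes.csv",
        "map.tsv",
        "expression.tsv",
        "probes.tsv",
        "samples.tsv",
        "ground_truth.json",
    )
    manifest.write(outdir / "manifest.json")
    return manifest


@dataclass
class AnalysisResult:
    thresholds: PermutationThresholds
    records: list
    hotspots: list
    coloc: object | None
    sterility_qtl: list
    interaction_records: dict
    summaries: list
    outputs: list[str]


def load_dataset(data_dir: str | Path) -> tuple[CrossData, ExpressionData]:
    d = Path(data_dir)
    cross = read_cross(d / "cross.csv", d / "phenotypes.csv", d / "map.tsv")
    expr = read_expression(d / "expression.tsv", d / "probes.tsv", d / "samples.tsv")
    return cross, expr


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(6)


def analyze(
    data_dir: str | Path,
    config: AnalysisConfig | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
    out_subdir: str = "results",
    individuals: set[str] | None = None,
) -> AnalysisResult:
    """Run the analysis stages in dependency order, writing TSV reports.

    ``individuals`` restricts the F2 set (used by the fertile-subset
    rerun); thresholds and permutations are recomputed on the subset.
    """
    config = config or AnalysisConfig()
    d = Path(data_dir)
    outdir = d / out_subdir
    outdir.mkdir(parents=True, exist_ok=True)
    cross, expr = load_dataset(d)
    seed = config.seed

    if individuals is not None:
        keep = cross.individuals["id"].isin(individuals).to_numpy()
        cross = CrossData(
            cross.map,
            cross.individuals[keep].reset_index(drop=True),
            cross.genotypes.loc[:, keep],
            cross.phenotypes.loc[[i for i in cross.phenotypes.index if i in individuals]]
            if cross.phenotypes is not None
            else None,
        )

    probs = calc_genoprob(
        cross, config.grid_step_cm, config.genotyping_error_rate, config.map_function
    )
    f2_ids = list(cross.individuals["id"])
    f2_expr = expr.values[f2_ids]
    Yt = pd.DataFrame(
        {p: nqrank(f2_expr.loc[p].to_numpy(dtype=float)) for p in f2_expr.index}
    )
    chrom_is_x = {c.name: c.is_x for c in cross.map.chromosomes}
    outputs: list[str] = []

    need = set(stages)
    if need & {"catalog", "hotspots", "colocalize", "interactions", "network"}:
        need.add("scan")
    if need & {"hotspots", "colocalize", "interactions", "network"}:
        need.add("catalog")
    if need & {"colocalize", "interactions", "network"}:
        need.add("hotspots")
    if need & {"network"}:
        need.add("interactions")

    thresholds = records = hotspot_list = coloc = None
    sterility_qtl: list[SterilityQtlInterval] = []
    interaction_records: dict = {}
    summaries: list = []

    mats = None
    if "scan" in need:
        mats = scan_batch(Yt, probs)
        thresholds, _ = permutation_threshold(
            Yt.iloc[:, 0].to_numpy(),
            probs,
            n_perm_auto=config.n_perm_single,
            alpha=config.alpha,
            seed=seed + STAGE_SEEDS["threshold"],
        )
        scan_tbl = []
        for chrom, lod in mats.lod.items():
            best = np.argmax(np.nan_to_num(lod, nan=-np.inf), axis=1)
            scan_tbl.append(
                pd.DataFrame(
                    {
                        "trait": mats.trait_names,
                        "chr": chrom,
                        "peak_cM": mats.chrom_positions[chrom][best],
                        "max_LOD": lod[np.arange(lod.shape[0]), best],
                    }
                )
            )
        _float_fmt(pd.concat(scan_tbl, ignore_index=True)).to_csv(
            outdir / "scan_peaks.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                {
                    "stratum": "autosome",
                    "lod_threshold": thresholds.autosome,
                    "n_perm": thresholds.n_perm_autosome,
                },
                {"stratum": "X", "lod_threshold": thresholds.x, "n_perm": thresholds.n_perm_x},
            ]
        ).round(4).to_csv(outdir / "thresholds.tsv", sep="\t", index=False)
        outputs += ["scan_peaks.tsv", "thresholds.tsv"]

    f1_calls = None
    if "misexpression" in stages or "catalog" in need:
        f1_calls = mis.classify_f1_misexpression(
            expr, "F1_MxD", config.misexpression_delta
        )
    if "misexpression" in stages:
        counts = mis.misexpression_counts(
            expr, config.misexpression_delta, config.se_multiplier
        )
        counts.counts.to_csv(outdir / "misexpression_counts.tsv", sep="\t", index_label="id")
        f1_calls.to_frame("f1_mxd_call").to_csv(
            outdir / "misexpression_f1.tsv", sep="\t", index_label="probe"
        )
        qtl = mis.map_misexpression_qtl(
            counts,
            probs,
            n_perm=config.n_perm_single,
            alpha=config.alpha,
            seed=seed + STAGE_SEEDS["misexpression_qtl"],
        )
        rows = []
        for name, (scan, thr, _) in qtl.items():
            for chrom in scan.table["chr"].unique():
                pos, lod = scan.peak(chrom)
                if lod > thr.for_chrom(chrom_is_x[chrom]):
                    lo, hi = lod_support_interval(scan, chrom)
                    rows.append(
                        {
                            "phenotype": name,
                            "chr": chrom,
                            "peak_cM": pos,
                            "LOD": lod,
                            "lo_cM": lo,
                            "hi_cM": hi,
                        }
                    )
        pd.DataFrame(rows).round(4).to_csv(
            outdir / "misexpression_qtl.tsv", sep="\t", index=False
        )
        outputs += [
            "misexpression_counts.tsv",
            "misexpression_f1.tsv",
            "misexpression_qtl.tsv",
        ]
        if cross.phenotypes is not None and len(cross.phenotypes.columns):
            fertility_trait = cross.phenotypes.columns[0]
            try:
                _, corr_summary = mis.correlate_with_phenotype(
                    expr, cross.phenotypes[fertility_trait], config.alpha
                )
            except ValueError:
                pass
            else:
                corr_summary.round(4).to_csv(
                    outdir / "phenotype_correlation.tsv", sep="\t",
                    index_label="chr",
                )
                outputs.append("phenotype_correlation.tsv")

    if "catalog" in need:
        records = cat.extract_peaks(mats, thresholds)
        records = cat.annotate_records(
            records,
            f2_expr,
            probs,
            cross.map,
            expr.probes,
            config.cis_window_cm,
            config.se_multiplier,
        )
        _float_fmt(cat.records_table(records, expr.probes)).to_csv(
            outdir / "eqtl_catalog.tsv", sep="\t", index=False
        )
        strata = pd.DataFrame(
            [
                {
                    "class": k,
                    "autosome": sum(
                        1 for r in records if r.kind == k and not chrom_is_x[r.chrom]
                    ),
                    "X": sum(1 for r in records if r.kind == k and chrom_is_x[r.chrom]),
                }
                for k in ("cis", "trans", "excluded")
            ]
        )
        strata.to_csv(outdir / "eqtl_strata.tsv", sep="\t", index=False)
        outputs += ["eqtl_catalog.tsv", "eqtl_strata.tsv"]

    if "hotspots" in need:
        trans = [r for r in records if r.kind == "trans"]
        counts = hot.window_counts(
            trans, cross.map, config.hotspot_window_cm, config.grid_step_cm
        )
        if trans:
            thr = hot.hotspot_null_thresholds(
                trans,
                cross.map,
                n_perm=config.n_perm_hotspot,
                alpha=config.alpha,
                seed=seed + STAGE_SEEDS["hotspot_null"],
                window_cm=config.hotspot_window_cm,
                step_cm=config.grid_step_cm,
                probes=expr.probes,
            )
            hotspot_list = hot.call_hotspots(counts, thr, trans, cross.map)
        else:
            hotspot_list = []
        for h in hotspot_list:
            h.sterile_allele, _ = cat.infer_sterile_allele(h.members, f1_calls)
        hot.hotspots_table(hotspot_list).round(4).to_csv(
            outdir / "hotspots.tsv", sep="\t", index=False
        )
        hot.write_hotspots_bed(hotspot_list, outdir / "hotspots.bed")
        outputs += ["hotspots.tsv", "hotspots.bed"]

    if "colocalize" in need and cross.phenotypes is not None:
        sterility_qtl = map_sterility_qtl(
            cross, probs, config, seed + STAGE_SEEDS["sterility_scan"]
        )
        pd.DataFrame(
            [
                {
                    "trait": q.trait,
                    "chr": q.chrom,
                    "peak_cM": q.peak_cm,
                    "lo_cM": q.lo_cm,
                    "hi_cM": q.hi_cm,
                    "sterile_allele": q.sterile_allele,
                }
                for q in sterility_qtl
            ]
        ).round(4).to_csv(outdir / "sterility_qtl.tsv", sep="\t", index=False)
        outputs.append("sterility_qtl.tsv")
        if hotspot_list and sterility_qtl:
            coloc = hot.colocalization_test(
                hotspot_list,
                sterility_qtl,
                cross.map,
                n_perm=config.n_perm_coloc,
                seed=seed + STAGE_SEEDS["colocalization"],
                step_cm=config.grid_step_cm,
            )
            pd.DataFrame([asdict(coloc)]).round(6).to_csv(
                outdir / "colocalization.tsv", sep="\t", index=False
            )
            outputs.append("colocalization.tsv")

    if "interactions" in need:
        covariates = [(h.chrom, probs.chroms[h.chrom].nearest_marker(
            0.5 * (h.lo_cm + h.hi_cm))) for h in (hotspot_list or [])]
        seen = set()
        covariates = [
            c for c in covariates if not (c in seen or seen.add(c))
        ]
        all_ixn: list[ixn.InteractionEqtl] = []
        hotspots_by_cov: dict[tuple[str, str], list] = {}
        for k, (cchrom, cmarker) in enumerate(covariates):
            thr_i = ixn.interaction_thresholds(
                Yt.iloc[:, 0].to_numpy(),
                probs,
                cchrom,
                cmarker,
                n_perm=config.n_perm_interaction,
                alpha=config.alpha,
                seed=seed + STAGE_SEEDS["interaction"] + k,
            )
            mats_f, mats_a, _ = ixn.conditional_scan_batch(Yt, probs, cchrom, cmarker)
            recs: list[ixn.InteractionEqtl] = []
            for t in Yt.columns:
                cond = _cond_from_mats(mats_f, mats_a, str(t))
                recs.extend(ixn.call_interaction_eqtl(cond, thr_i, chrom_is_x))
            interaction_records[(cchrom, cmarker)] = recs
            all_ixn.extend(recs)
            hs = ixn.interaction_hotspots(
                recs,
                cross.map,
                expr.probes,
                n_perm=max(config.n_perm_hotspot, 100),
                alpha=config.alpha,
                seed=seed + STAGE_SEEDS["interaction"] + 100 + k,
                window_cm=config.hotspot_window_cm,
                step_cm=config.grid_step_cm,
            )
            hotspots_by_cov[(cchrom, cmarker)] = hs
        for (cchrom, cmarker), recs in interaction_records.items():
            summaries.append(
                ixn.covariate_summary(
                    recs,
                    hotspots_by_cov[(cchrom, cmarker)],
                    records,
                    all_ixn,
                    cross.map,
                    config.cis_window_cm,
                )
            )
        pd.DataFrame(
            [
                {
                    "trait": r.trait,
                    "covariate": r.covariate_marker,
                    "chr": r.chrom,
                    "peak_cM": r.pos_cm,
                    "LOD_f": r.lod_f,
                    "LOD_i": r.lod_i,
                }
                for r in all_ixn
            ]
        ).round(4).to_csv(outdir / "interaction_eqtl.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(s) for s in summaries]).round(2).to_csv(
            outdir / "covariate_summary.tsv", sep="\t", index=False
        )
        outputs += ["interaction_eqtl.tsv", "covariate_summary.tsv"]

        if "network" in need:
            sterile_by_marker = {
                m: next(
                    (h.sterile_allele for h in hotspot_list if h.chrom == c),
                    "undetermined",
                )
                for c, m in hotspots_by_cov
            }
            nodes, edges = ixn.build_network(
                hotspots_by_cov, cross.map, config.node_merge_mb, sterile_by_marker
            )
            ixn.edges_table(edges).round(4).to_csv(
                outdir / "network_edges.tsv", sep="\t", index=False
            )
            outputs.append("network_edges.tsv")

    manifest = RunManifest(config={"analysis": asdict(config)})
    manifest.stages = sorted(need)
    manifest.seeds = {k: seed + v for k, v in STAGE_SEEDS.items()}
    manifest.record(outdir, *outputs)
    manifest.write(outdir / "manifest.json")
    return AnalysisResult(
        thresholds,
        records or [],
        hotspot_list or [],
        coloc,
        sterility_qtl,
        interaction_records,
        summaries,
        outputs,
    )


def _cond_from_mats(mats_f, mats_a, trait: str):
    from .interactions import ConditionalScanResult

    i = mats_f.trait_names.index(trait)
    frames = []
    for chrom in mats_f.lod:
        lf = mats_f.lod[chrom][i]
        la = mats_a.lod[chrom][i]
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
        trait, mats_f.covariate, pd.concat(frames, ignore_index=True)
    )


def map_sterility_qtl(
    cross: CrossData,
    probs,
    config: AnalysisConfig,
    seed: int,
    traits: tuple[str, ...] | None = None,
) -> list[SterilityQtlInterval]:
    """Map the sterility phenotypes and return 1.5-LOD support intervals
    for significant peaks; the sterile allele is the genotype class with
    the least-fertile mean at the peak's nearest typed marker."""
    from .catalog import classify_dominance_effect
    from .genoprob import genotype_at_marker

    if cross.phenotypes is None:
        return []
    traits = traits or tuple(cross.phenotypes.columns)
    chrom_is_x = {c.name: c.is_x for c in cross.map.chromosomes}
    out: list[SterilityQtlInterval] = []
    for k, trait in enumerate(traits):
        y = cross.phenotypes[trait].reindex(cross.individuals["id"]).to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 20 or np.nanstd(y) == 0:
            continue
        scan = scan_single(y, probs, trait_name=trait)
        thr, _ = permutation_threshold(
            y[ok] if ok.all() else y[ok],
            probs,
            n_perm_auto=config.n_perm_single,
            alpha=config.alpha,
            seed=seed + k,
        )
        for chrom in scan.table["chr"].unique():
            pos, lod = scan.peak(chrom)
            if lod <= thr.for_chrom(chrom_is_x[chrom]):
                continue
            lo, hi = lod_support_interval(scan, chrom)
            marker = probs.chroms[chrom].nearest_marker(pos)
            classes = genotype_at_marker(probs, chrom, marker)
            _, _, high, low, _ = classify_dominance_effect(
                y, classes, chrom_is_x[chrom], config.se_multiplier
            )
            # lower phenotype value = more sterile for these fertility traits
            sterile = low if low else "het"
            sterile = {"A": "A", "B": "B", "het": "het"}.get(sterile, "het")
            out.append(SterilityQtlInterval(trait, chrom, pos, lo, hi, sterile))
    return out


def fertile_subset_run(
    data_dir: str | Path,
    config: AnalysisConfig | None = None,
    traits: tuple[str, ...] | None = None,
) -> dict:
    """Rerun scan + catalog + hotspots on the fertile F2 subset and
    report the contrast against the full-data run."""
    config = config or AnalysisConfig()
    d = Path(data_dir)
    cross, _ = load_dataset(d)
    if cross.phenotypes is None:
        raise ValueError("sterility phenotypes required for the fertile subset")
    traits = traits or tuple(cross.phenotypes.columns[:4])
    fertile = select_fertile_subset(
        cross.phenotypes, traits, config.fertile_percentile
    )
    full = analyze(d, config, ("scan", "catalog", "hotspots"), out_subdir="results_full")
    sub = analyze(
        d,
        config,
        ("scan", "catalog", "hotspots"),
        out_subdir="results_fertile",
        individuals=fertile,
    )

    def n_kind(recs, kind):
        return sum(1 for r in recs if r.kind == kind)

    report = {
        "n_full": len(load_dataset(d)[0].individuals),
        "n_fertile": len(fertile),
        "full_cis": n_kind(full.records, "cis"),
        "fertile_cis": n_kind(sub.records, "cis"),
        "full_trans": n_kind(full.records, "trans"),
        "fertile_trans": n_kind(sub.records, "trans"),
        "full_hotspots": len(full.hotspots),
        "fertile_hotspots": len(sub.hotspots),
    }
    pd.DataFrame([report]).to_csv(
        d / "results_fertile" / "fertile_contrast.tsv", sep="\t", index=False
    )
    return report
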