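import numpy as np
import pandas as pd
import pytest

from hybridqtl.cross import ExpressionData
from hybridqtl.misexpression import (
    classify_f1_misexpression,
    classify_f2_matrix,
    classify_f2_misexpression,
    correlate_with_phenotype,
    differential_expression,
    group_stats,
    map_misexpression_qtl,
    misexpression_counts,
)
from hybridqtl.simulate import SimArchitecture, MasterLocus, simulate_expression, simulate_f2

from conftest import make_map


def build_expr(values: dict[str, np.ndarray], groups: dict[str, int], probes=None):
    """Expression matrix from per-group probe x n blocks."""
    cols, ids, rows = [], [], []
    for g, n in groups.items():
        for i in range(n):
            ids.append(f"{g}_{i}")
            rows.append({"id": f"{g}_{i}", "group": g})
    samples = pd.DataFrame(rows)
    mat = np.hstack([values[g] for g in groups])
    probe_ids = [f"p{i}" for i in range(mat.shape[0])]
    vals = pd.DataFrame(mat, index=probe_ids, columns=ids)
    if probes is None:
        probes = pd.DataFrame(
            {"gene": probe_ids, "chr": "1", "cM": 10.0, "Mb": 20.0}, index=probe_ids
        )
        probes.index.name = "probe_id"
    return ExpressionData(samples, vals, probes)


class TestF2Rule:
    # parents 5.0 (SE 0.1) and 6.0 (SE 0.1) unless stated
    @pytest.mark.parametrize(
        "value,pa,sa,pb,sb,expected",
        [
            (6.6, 5.0, 0.1, 6.0, 0.1, "over"),  # 0.6 > 0.5 and > 0.2
            (6.4, 5.0, 0.1, 6.0, 0.1, "none"),  # 0.4 < 0.5
            (6.7, 5.0, 0.4, 6.0, 0.4, "none"),  # 0.7 > 0.5 but < 2*0.4
            (4.4, 5.0, 0.1, 6.0, 0.1, "under"),
            (5.5, 5.0, 0.1, 6.0, 0.1, "none"),  # inside parental range
        ],
    )
    def test_hand_trace(self, value, pa, sa, pb, sb, expected):
        assert classify_f2_misexpression(value, pa, sa, pb, sb) == expected

    def test_antisymmetry_negation_swaps_over_under(self):
        rng = np.random.default_rng(4)
        vals = {
            "parentA": rng.normal(5, 0.3, size=(30, 8)),
            "parentB": rng.normal(6, 0.3, size=(30, 8)),
            "F2": rng.normal(5.5, 1.2, size=(30, 40)),
        }
        expr = build_expr(vals, {"parentA": 8, "parentB": 8, "F2": 40})
        neg = build_expr(
            {g: -v for g, v in vals.items()}, {"parentA": 8, "parentB": 8, "F2": 40}
        )
        assert classify_f2_matrix(expr).to_numpy() == pytest.approx(
            -classify_f2_matrix(neg).to_numpy()
        )

    def test_null_f2_prevalence_below_5pct(self):
        """F2s drawn at the parental midpoint with parental noise rarely
        clear the delta + SE rule."""
        rng = np.random.default_rng(9)
        n_probe = 400
        vals = {
            "parentA": rng.normal(7.0, 0.25, size=(n_probe, 8)),
            "parentB": rng.normal(7.0, 0.25, size=(n_probe, 8)),
            "F2": rng.normal(7.0, 0.25, size=(n_probe, 100)),
        }
        expr = build_expr(vals, {"parentA": 8, "parentB": 8, "F2": 100})
        counts = misexpression_counts(expr)
        assert counts.prevalence.mean() < 0.05


class TestF1Rule:
    def _expr(self, f1_mean, pa=5.0, pb=6.0, sd=0.05):
        rng = np.random.default_rng(11)
        vals = {
            "parentA": rng.normal(pa, sd, size=(1, 8)),
            "parentB": rng.normal(pb, sd, size=(1, 8)),
            "F1_MxD": rng.normal(f1_mean, sd, size=(1, 6)),
        }
        return build_expr(vals, {"parentA": 8, "parentB": 8, "F1_MxD": 6})

    def test_clear_overexpression(self):
        calls = classify_f1_misexpression(self._expr(6.8))
        assert calls.iloc[0] == "over"

    def test_between_parents_is_none(self):
        assert classify_f1_misexpression(self._expr(5.5)).iloc[0] == "none"

    def test_small_delta_is_none(self):
        # 6.4: diff to nearer parent 0.4 < 0.5
        assert classify_f1_misexpression(self._expr(6.4)).iloc[0] == "none"

    def test_underexpression(self):
        assert classify_f1_misexpression(self._expr(4.2)).iloc[0] == "under"


class TestDifferentialExpression:
    def test_null_and_signal_probes(self):
        rng = np.random.default_rng(21)
        n = 2000
        a = rng.normal(0, 1, size=(n, 8))
        b = rng.normal(0, 1, size=(n, 8))
        b[:100] += 2.0  # 2-SD shift in the first 100 probes
        expr = build_expr({"parentA": a, "parentB": b}, {"parentA": 8, "parentB": 8})
        res = differential_expression(expr, "parentA", "parentB", fdr=0.05)
        assert res["significant"].iloc[:100].mean() > 0.5  # power for 2-SD shift
        # false positives among the 1900 null probes stay near the FDR level
        assert res["significant"].iloc[100:].mean() < 0.05

    def test_single_sample_group_errors(self):
        expr = build_expr(
            {"parentA": np.zeros((3, 1)), "parentB": np.zeros((3, 4))},
            {"parentA": 1, "parentB": 4},
        )
        with pytest.raises(ValueError, match="parentA"):
            differential_expression(expr, "parentA", "parentB")


class TestCounts:
    def test_hand_built_fixture(self):
        # parents tight around 5.0 and 6.0; 3 probes x 2 F2s
        pa = np.tile([[5.0], [5.0], [5.0]], (1, 8)) + 0.001 * np.arange(8)
        pb = np.tile([[6.0], [6.0], [6.0]], (1, 8)) + 0.001 * np.arange(8)
        f2 = np.array([[6.8, 5.5], [4.2, 6.8], [5.5, 5.5]])
        probes = pd.DataFrame(
            {"gene": ["g0", "g1", "g2"], "chr": ["1", "X", "1"],
             "cM": 1.0, "Mb": 2.0},
            index=["p0", "p1", "p2"],
        )
        expr = build_expr(
            {"parentA": pa, "parentB": pb, "F2": f2},
            {"parentA": 8, "parentB": 8, "F2": 2},
            probes,
        )
        counts = misexpression_counts(expr)
        tbl = counts.counts
        assert tbl.loc["F2_0", "over_autosome"] == 1  # p0 over
        assert tbl.loc["F2_0", "under_X"] == 1  # p1 under
        assert tbl.loc["F2_1", "over_X"] == 1  # p1 over
        assert tbl.loc["F2_1", "over_autosome"] == 0
        assert counts.phenotypes.loc["F2_0", "over_autosome"] == pytest.approx(1.0)
        # sqrt applied exactly once
        assert (counts.phenotypes.to_numpy() == np.sqrt(tbl.to_numpy())).all()

    def test_counts_invariant_to_probe_order(self):
        rng = np.random.default_rng(31)
        vals = {
            "parentA": rng.normal(5, 0.2, size=(20, 8)),
            "parentB": rng.normal(6, 0.2, size=(20, 8)),
            "F2": rng.normal(5.5, 1.5, size=(20, 10)),
        }
        expr = build_expr(vals, {"parentA": 8, "parentB": 8, "F2": 10})
        base = misexpression_counts(expr).counts
        perm = np.random.default_rng(1).permutation(20)
        expr2 = ExpressionData(
            expr.samples, expr.values.iloc[perm], expr.probes.iloc[perm]
        )
        assert misexpression_counts(expr2).counts.equals(base)


class TestMisexpressionQtl:
    def test_het_triggered_x_overexpression_maps_to_marker(self):
        """A locus whose heterozygotes overexpress many X transcripts is
        recovered as a QTL for the sqrt X-overexpression count."""
        gmap = make_map(
            {"1": tuple(np.arange(0, 61.0, 10)), "2": tuple(np.arange(0, 61.0, 10)),
             "X": tuple(np.arange(0, 41.0, 10))}
        )
        cross, _ = simulate_f2(gmap, n=300, seed=77)
        probes = [f"x{i}" for i in range(60)]
        arch = SimArchitecture(
            master_loci=[MasterLocus("M1_3", tuple(probes), 1.0, "overdominant")],
            noise_sd=0.25,
        )
        ann = pd.DataFrame(
            {"gene": probes, "chr": "X",
             "cM": np.linspace(0, 40, 60), "Mb": np.linspace(0, 80, 60)},
            index=probes,
        )
        expr, _ = simulate_expression(cross, arch, seed=78, probe_annotation=ann)
        counts = misexpression_counts(expr)
        from hybridqtl.genoprob import calc_genoprob

        gp = calc_genoprob(cross, 2.0, 0.001, "haldane")
        out = map_misexpression_qtl(counts, gp, n_perm=100, seed=79)
        scan, thr, _ = out["over_X"]
        pos, lod = scan.peak("1")
        assert lod > thr.autosome
        assert abs(pos - 30.0) <= 15.0

    def test_constant_counts_not_mapped(self, mini_probs):
        from hybridqtl.misexpression import MisexpressionCounts

        n = len(mini_probs.individual_ids)
        zeros = pd.DataFrame(
            {k: np.zeros(n, dtype=int) for k in
             ("over_autosome", "under_autosome", "over_X", "under_X")},
            index=mini_probs.individual_ids,
        )
        counts = MisexpressionCounts(zeros, np.sqrt(zeros), pd.Series(dtype=float), pd.DataFrame())
        assert map_misexpression_qtl(counts, mini_probs, n_perm=20) == {}


class TestCorrelation:
    def _expr(self, f2_block):
        rng = np.random.default_rng(41)
        n_probe = f2_block.shape[0]
        vals = {
            "parentA": rng.normal(5, 0.2, size=(n_probe, 8)),
            "parentB": rng.normal(6, 0.2, size=(n_probe, 8)),
            "F2": f2_block,
        }
        return build_expr(vals, {"parentA": 8, "parentB": 8, "F2": f2_block.shape[1]})

    def test_probe_equal_to_phenotype(self):
        rng = np.random.default_rng(42)
        pheno = rng.normal(size=30)
        block = np.vstack([pheno, -pheno + rng.normal(0, 0.01, 30), rng.normal(size=30)])
        expr = self._expr(block)
        ids = expr.group_ids("F2")
        tbl, summary = correlate_with_phenotype(
            expr, pd.Series(pheno, index=ids), fdr=0.05
        )
        assert tbl["r"].iloc[0] == pytest.approx(1.0)
        assert tbl["r"].iloc[1] == pytest.approx(-1.0, abs=0.01)
        assert summary.loc["1", "n_probes"] == 3

    def test_null_probes_rarely_significant(self):
        rng = np.random.default_rng(43)
        block = rng.normal(size=(500, 40))
        expr = self._expr(block)
        pheno = pd.Series(rng.normal(size=40), index=expr.group_ids("F2"))
        tbl, _ = correlate_with_phenotype(expr, pheno, fdr=0.05)
        assert tbl["significant"].mean() <= 0.05

    def test_too_few_pairs_errors(self):
        rng = np.random.default_rng(44)
        expr = self._expr(rng.normal(size=(3, 5)))
        pheno = pd.Series(rng.normal(size=5), index=expr.group_ids("F2"))
        with pytest.raises(ValueError, match=">=10"):
            correlate_with_phenotype(expr, pheno)
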