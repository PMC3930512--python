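import numpy as np
import pandas as pd
import pytest

from hybridqtl.catalog import EqtlRecord
from hybridqtl.genoprob import calc_genoprob, genotype_at_marker
from hybridqtl.hotspots import Hotspot
from hybridqtl.interactions import (
    InteractionEqtl,
    build_network,
    call_interaction_eqtl,
    conditional_scan,
    covariate_summary,
    interaction_thresholds,
)
from hybridqtl.scan import scan_batch, nqrank
from hybridqtl.simulate import (
    EpistaticPair,
    SimArchitecture,
    product_epistasis,
    simulate_expression,
    simulate_f2,
)

from conftest import make_map


@pytest.fixture(scope="module")
def epi_setup():
    """n=300 cross with one purely epistatic probe pair (M1_2 x M3_2)."""
    gmap = make_map(
        {
            "1": tuple(np.arange(0.0, 61.0, 10.0)),
            "2": tuple(np.arange(0.0, 61.0, 10.0)),
            "3": tuple(np.arange(0.0, 61.0, 10.0)),
        }
    )
    cross, _ = simulate_f2(gmap, n=300, seed=202)
    arch = SimArchitecture(
        epistatic_pairs=[
            EpistaticPair("M1_2", "M3_2", ("epi",), product_epistasis(1.2))
        ],
        noise_sd=0.25,
    )
    expr, _ = simulate_expression(cross, arch, seed=203)
    probs = calc_genoprob(cross, 2.0, 0.001, "haldane")
    y = nqrank(expr.f2_values.loc["epi"].to_numpy(dtype=float))
    return cross, probs, y


class TestConditionalScan:
    def test_lod_i_is_difference(self, epi_setup):
        _, probs, y = epi_setup
        cond = conditional_scan(y, probs, "1", "M1_2")
        tbl = cond.table.dropna()
        assert tbl["lod_i"].to_numpy() == pytest.approx(
            (tbl["lod_f"] - tbl["lod_a"]).to_numpy()
        )

    def test_nested_models_everywhere(self, epi_setup):
        _, probs, y = epi_setup
        cond = conditional_scan(y, probs, "1", "M1_2")
        assert np.nanmin(cond.table["lod_i"].to_numpy()) >= -1e-6

    def test_self_window_masked(self, epi_setup):
        _, probs, y = epi_setup
        cond = conditional_scan(y, probs, "1", "M1_2", guard_cm=5.0)
        tbl = cond.chrom_table("1")
        near = np.abs(tbl["pos"].to_numpy() - 20.0) < 5.0
        assert np.isnan(tbl["lod_f"].to_numpy()[near]).all()
        assert not np.isnan(tbl["lod_f"].to_numpy()[~near]).any()

    def test_additive_covariate_trait_no_interaction(self, epi_setup):
        """A trait driven additively by the covariate marker shows no
        interaction signal once the additive model absorbs it."""
        cross, probs, _ = epi_setup
        rng = np.random.default_rng(11)
        dosage = cross.genotypes.loc["M1_2"].map({"AA": 0, "AB": 1, "BB": 2})
        y = dosage.to_numpy(dtype=float) + rng.normal(0, 0.5, size=300)
        cond = conditional_scan(y, probs, "1", "M1_2")
        thr = interaction_thresholds(y, probs, "1", "M1_2", n_perm=100, seed=12)
        chrom_is_x = {c: False for c in probs.chroms}
        assert call_interaction_eqtl(cond, thr, chrom_is_x) == []
        assert np.nanmean(cond.table["lod_i"].to_numpy()) < 0.5

    def test_pure_epistasis_recovered_only_conditionally(self, epi_setup):
        """The marginal scan misses a purely epistatic pair; conditioning
        on one partner reveals the other."""
        _, probs, y = epi_setup
        marginal = scan_batch(y[:, None], probs)
        a, _ = marginal.max_per_stratum()
        thr = interaction_thresholds(y, probs, "1", "M1_2", n_perm=100, seed=13)
        cond = conditional_scan(y, probs, "1", "M1_2")
        chrom_is_x = {c: False for c in probs.chroms}
        calls = call_interaction_eqtl(cond, thr, chrom_is_x)
        assert a.max() < 3.7  # marginal scan: nothing
        assert any(c.chrom == "3" and abs(c.pos_cm - 20.0) <= 15.0 for c in calls)


class TestInteractionThresholds:
    def test_determinism(self, epi_setup):
        _, probs, y = epi_setup
        t1 = interaction_thresholds(y, probs, "1", "M1_2", n_perm=100, seed=5)
        t2 = interaction_thresholds(y, probs, "1", "M1_2", n_perm=100, seed=5)
        assert t1.lod_f == t2.lod_f and t1.lod_i == t2.lod_i

    def test_thresholds_positive_and_ordered(self, epi_setup):
        _, probs, y = epi_setup
        t = interaction_thresholds(y, probs, "1", "M1_2", n_perm=100, seed=6)
        assert t.lod_f["autosome"] > t.lod_i["autosome"] > 0


class TestCallInteractionEqtl:
    def _cond(self, lod_f, lod_i):
        from hybridqtl.interactions import ConditionalScanResult
        from hybridqtl.scan import CovariateSpec

        tbl = pd.DataFrame(
            {
                "chr": "2",
                "pos": [0.0, 10.0],
                "lod_f": [lod_f, 1.0],
                "lod_a": [lod_f - lod_i, 0.5],
                "lod_i": [lod_i, 0.5],
            }
        )
        return ConditionalScanResult("t", CovariateSpec("full", "1", "m"), tbl)

    THR = {"autosome": 6.0}

    def _thr(self, f=6.0, i=3.5):
        from hybridqtl.interactions import InteractionThresholds

        return InteractionThresholds(
            {"autosome": f}, {"autosome": 1.0}, {"autosome": i}, 0.05, 100, 0
        )

    def test_both_exceed_gives_record(self):
        calls = call_interaction_eqtl(self._cond(9.0, 4.0), self._thr(), {"2": False})
        assert len(calls) == 1 and calls[0].pos_cm == 0.0

    def test_low_lod_i_rejected(self):
        assert call_interaction_eqtl(self._cond(9.0, 2.0), self._thr(), {"2": False}) == []

    def test_low_lod_f_rejected(self):
        assert call_interaction_eqtl(self._cond(5.0, 4.0), self._thr(), {"2": False}) == []


class TestNetwork:
    MAP = make_map({"7": tuple(np.arange(0.0, 71.0, 10.0)),
                    "13": tuple(np.arange(0.0, 71.0, 10.0))})

    def _hs(self, chrom, lo_mb, hi_mb, count=10):
        return Hotspot(chrom, lo_mb / 2, hi_mb / 2, count, 3, lo_mb=lo_mb, hi_mb=hi_mb)

    def test_close_regions_merge_to_one_node(self):
        by_cov = {
            ("13", "M13_1"): [self._hs("7", 122.6, 125.8)],
            ("13", "M13_2"): [self._hs("7", 124.0, 126.5)],
        }
        nodes, edges = build_network(by_cov, self.MAP, merge_mb=12.8)
        chr7_nodes = [n for n in nodes if n.chrom == "7"]
        assert len(chr7_nodes) == 1
        assert chr7_nodes[0].lo_mb == pytest.approx(122.6)
        assert chr7_nodes[0].hi_mb == pytest.approx(126.5)

    def test_reciprocal_edges_flagged(self):
        by_cov = {
            ("7", "M7_1"): [self._hs("13", 19.0, 21.0)],
            ("13", "M13_1"): [self._hs("7", 19.0, 21.0)],
        }
        nodes, edges = build_network(by_cov, self.MAP, merge_mb=12.8)
        assert len(edges) == 2
        assert all(e.reciprocal for e in edges)

    def test_merge_order_independent(self):
        rng = np.random.default_rng(8)
        base = {
            ("13", "M13_1"): [self._hs("7", 10.0, 20.0), self._hs("7", 25.0, 30.0)],
            ("13", "M13_3"): [self._hs("7", 50.0, 60.0)],
            ("7", "M7_2"): [self._hs("13", 100.0, 110.0)],
        }
        nodes1, _ = build_network(base, self.MAP, merge_mb=12.8)
        for _ in range(5):
            keys = list(base)
            rng.shuffle(keys)
            shuffled = {k: list(reversed(base[k])) for k in keys}
            nodes2, _ = build_network(shuffled, self.MAP, merge_mb=12.8)
            assert sorted(n.label for n in nodes2) == sorted(n.label for n in nodes1)


class TestCovariateSummary:
    MAP = make_map({"1": tuple(np.arange(0.0, 41.0, 10.0)),
                    "2": tuple(np.arange(0.0, 41.0, 10.0))})

    def _ixn(self, trait, cov_marker, cov_chrom, chrom, pos):
        return InteractionEqtl(trait, cov_marker, cov_chrom, chrom, pos, 8.0, 4.0)

    def test_quarter_covariate_marginal(self):
        records = [self._ixn(f"t{i}", "M1_1", "1", "2", 20.0) for i in range(4)]
        # only t0 has an original eQTL near the covariate (chr1 @ 10)
        original = [EqtlRecord(probe="t0", chrom="1", pos_cm=12.0, lod=5.0)]
        s = covariate_summary(records, [], original, records, self.MAP)
        assert s.pct_covariate_marginal == pytest.approx(25.0)
        assert s.pct_peak_marginal == pytest.approx(0.0)

    def test_empty_records(self):
        s = covariate_summary([], [], [], [], self.MAP)
        assert s.n_interaction_eqtl == 0
        assert s.pct_reciprocal == 0.0

    def test_reciprocal_hand_fixture(self):
        # t0: covariate M1_1 (chr1@10) -> peak chr2@20; reversed record
        # exists (covariate M2_2 = chr2@20 -> peak chr1@10); t1 has none
        fwd = [
            self._ixn("t0", "M1_1", "1", "2", 20.0),
            self._ixn("t1", "M1_1", "1", "2", 30.0),
        ]
        rev = [self._ixn("t0", "M2_2", "2", "1", 10.0)]
        s = covariate_summary(fwd, [], [], fwd + rev, self.MAP)
        assert s.pct_reciprocal == pytest.approx(50.0)
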