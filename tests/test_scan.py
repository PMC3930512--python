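import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridqtl.genoprob import calc_genoprob
from hybridqtl.scan import (
    CovariateSpec,
    NullDistribution,
    ScanResult,
    dataset_threshold,
    lod_support_interval,
    lod_to_pq,
    nqrank,
    perm_pvalues,
    permutation_threshold,
    scan_batch,
    scan_single,
    storey_pi0,
    storey_qvalues,
)
from hybridqtl.simulate import simulate_f2, simulate_map

from conftest import make_cross, make_map


class TestNqrank:
    def test_three_values_closed_form(self):
        # ranks 3,1,2 of [3,1,2] -> Phi^-1 at 5/6, 1/6, 1/2
        got = nqrank([3.0, 1.0, 2.0])
        assert got == pytest.approx([0.9674, -0.9674, 0.0], abs=1e-4)

    def test_rank_preserving(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        assert np.array_equal(np.argsort(nqrank(x)), np.argsort(x))

    def test_symmetric_zero_mean(self):
        out = nqrank(np.arange(21, dtype=float))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out == pytest.approx(-out[::-1])

    def test_missing_stays_missing(self):
        out = nqrank([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1]) and not np.isnan(out[[0, 2, 3]]).any()

    def test_constant_warns_zeros(self):
        with pytest.warns(UserWarning):
            assert nqrank([2.0, 2.0, 2.0]) == pytest.approx([0, 0, 0])


def closed_form_hk_lod(y, classes):
    """Independent least-squares oracle at a fully typed marker: the
    genotype-class-mean model vs the grand-mean null."""
    y = np.asarray(y, dtype=float)
    rss0 = np.sum((y - y.mean()) ** 2)
    rss1 = 0.0
    for c in np.unique(classes):
        sub = y[classes == c]
        rss1 += np.sum((sub - sub.mean()) ** 2)
    return (y.size / 2.0) * np.log10(rss0 / rss1)


def _typed_cross(classes, gmap_spec={"1": (0.0, 20.0, 40.0)}):
    """A cross whose first marker carries the given classes, fully typed."""
    gmap = make_map(gmap_spec)
    codes = {0: "AA", 1: "AB", 2: "BB"}
    geno = {}
    rng = np.random.default_rng(99)
    for i, c in enumerate(classes):
        geno[f"i{i}"] = [codes[c]] * len(gmap.marker_names)
    return make_cross(gmap, geno)


class TestHkOracle:
    def test_six_individual_example(self):
        classes = np.array([0, 0, 1, 1, 2, 2])
        y = np.array([0.0, 0.2, 1.0, 1.1, 2.0, 2.3])
        cross = _typed_cross(classes)
        probs = calc_genoprob(cross, step_cm=20.0, error_rate=0.0)
        scan = scan_single(y, probs)
        got = scan.chrom_table("1")["lod"].iloc[0]
        assert got == pytest.approx(closed_form_hk_lod(y, classes), abs=1e-8)

    def test_random_fixtures_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            classes = np.concatenate([[0, 1, 2], rng.integers(0, 3, size=17)])
            rng.shuffle(classes)
            y = rng.normal(size=20) + 0.5 * classes
            cross = _typed_cross(classes)
            probs = calc_genoprob(cross, step_cm=20.0, error_rate=0.0)
            got = scan_single(y, probs).chrom_table("1")["lod"].iloc[0]
            assert got == pytest.approx(closed_form_hk_lod(y, classes), abs=1e-8)

    def test_em_agrees_with_hk_at_typed_markers(self):
        rng = np.random.default_rng(7)
        classes = np.concatenate([[0, 1, 2], rng.integers(0, 3, size=27)])
        y = rng.normal(size=30) + 0.8 * classes
        cross = _typed_cross(classes)
        probs = calc_genoprob(cross, step_cm=20.0, error_rate=0.0)
        hk = scan_single(y, probs, method="hk").chrom_table("1")["lod"].iloc[0]
        em = scan_single(y, probs, method="em").chrom_table("1")["lod"].iloc[0]
        assert em == pytest.approx(hk, abs=0.01)

    def test_perfect_fit_flagged_degenerate(self):
        classes = np.array([0, 0, 1, 1, 2, 2])
        y = classes.astype(float)  # exact additive dosage
        cross = _typed_cross(classes)
        probs = calc_genoprob(cross, step_cm=20.0, error_rate=0.0)
        scan = scan_single(y, probs)
        tbl = scan.chrom_table("1")
        assert bool(tbl["degenerate"].iloc[0])
        assert np.isfinite(tbl["lod"].iloc[0])

    def test_null_trait_modest_lod(self, mini_probs):
        rng = np.random.default_rng(3)
        maxes = []
        for _ in range(10):
            y = rng.normal(size=300)
            mats = scan_batch(y[:, None], mini_probs)
            a, x = mats.max_per_stratum()
            maxes.append(max(a.max(), x.max()))
        assert np.median(maxes) < 4.0

    def test_nested_covariate_models(self, mini_cross, mini_probs):
        rng = np.random.default_rng(8)
        y = rng.normal(size=300)
        add = scan_batch(
            y[:, None], mini_probs, CovariateSpec("additive", "2", "M2_3")
        )
        full = scan_batch(
            y[:, None], mini_probs, CovariateSpec("full", "2", "M2_3")
        )
        for chrom in add.lod:
            assert np.all(full.lod[chrom] >= add.lod[chrom] - 1e-6)


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self):
        """With the whole alpha in one stratum, alpha -> 1 degrades the
        threshold to the minimum of the null distribution."""
        gmap = make_map({"1": (0.0, 10.0, 20.0), "2": (0.0, 10.0, 20.0)})
        cross, _ = simulate_f2(gmap, n=100, seed=1)
        probs = calc_genoprob(cross, 5.0, 0.001, "haldane")
        rng = np.random.default_rng(1)
        y = rng.normal(size=100)
        thr, null = permutation_threshold(
            y, probs, n_perm_auto=30, alpha=1.0, seed=5
        )
        assert thr.autosome == pytest.approx(null.autosome[0])

    def test_seed_determinism(self, mini_probs):
        rng = np.random.default_rng(2)
        y = rng.normal(size=300)
        a = permutation_threshold(y, mini_probs, n_perm_auto=40, seed=9)[0]
        b = permutation_threshold(y, mini_probs, n_perm_auto=40, seed=9)[0]
        assert (a.autosome, a.x) == (b.autosome, b.x)

    def test_larger_genome_larger_threshold(self):
        """More chromosomes -> more multiple testing -> higher threshold."""
        rng = np.random.default_rng(12)
        small = simulate_map(2, (60.0, 60.0), 10.0, 40.0)
        big = simulate_map(8, tuple([60.0] * 8), 10.0, 40.0)
        thr = {}
        for name, gmap in (("small", small), ("big", big)):
            cross, _ = simulate_f2(gmap, n=200, seed=4)
            probs = calc_genoprob(cross, 2.0, 0.001, "haldane")
            y = rng.normal(size=200)
            thr[name], _ = permutation_threshold(
                y, probs, n_perm_auto=200, seed=6, n_perm_x=20
            )
        assert thr["big"].autosome >= thr["small"].autosome

    def test_dataset_reduces_to_single_transcript(self, mini_probs):
        """With one transcript and matching permutation counts the dataset
        threshold equals the single-transcript threshold."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=300)
        single, _ = permutation_threshold(
            y, mini_probs, n_perm_auto=40, seed=17, n_perm_x=40
        )
        ds, _ = dataset_threshold(y[:, None], mini_probs, n_perm=40, seed=17)
        assert ds.autosome == pytest.approx(single.autosome)
        assert ds.x == pytest.approx(single.x)

    def test_dataset_geq_single(self, mini_probs):
        """Maxima over more transcripts dominate the single-trait maxima."""
        rng = np.random.default_rng(21)
        Y = rng.normal(size=(300, 50))
        single, _ = permutation_threshold(
            Y[:, 0], mini_probs, n_perm_auto=40, seed=13, n_perm_x=40
        )
        ds, _ = dataset_threshold(Y, mini_probs, n_perm=40, seed=13)
        assert ds.autosome >= single.autosome

    def test_dataset_determinism(self, mini_probs):
        rng = np.random.default_rng(30)
        Y = rng.normal(size=(300, 10))
        a, _ = dataset_threshold(Y, mini_probs, n_perm=25, seed=2)
        b, _ = dataset_threshold(Y, mini_probs, n_perm=25, seed=2)
        assert (a.autosome, a.x) == (b.autosome, b.x)


class TestPq:
    def test_p_bound_when_observed_exceeds_null(self):
        null = NullDistribution(np.arange(100, dtype=float), np.array([1.0]))
        p, q, pi0 = lod_to_pq(np.array([1000.0]), null)
        assert p[0] == pytest.approx(1.0 / 101.0)

    def test_p_counts_ties_as_extreme(self):
        p = perm_pvalues(np.array([5.0]), np.array([1.0, 5.0, 9.0]))
        assert p[0] == pytest.approx(3.0 / 4.0)

    def test_uniform_pvalues_pi0_near_one(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=1000)
        assert 0.8 <= storey_pi0(p) <= 1.0

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(15)
        p = np.concatenate([rng.uniform(size=500), rng.uniform(0, 1e-3, size=50)])
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_signal_gets_small_q(self):
        rng = np.random.default_rng(16)
        p = np.concatenate([rng.uniform(size=900), np.full(100, 1e-6)])
        q, pi0 = storey_qvalues(p)
        assert q[-1] < 0.01
        assert pi0 < 1.0 + 1e-9


class TestSupportInterval:
    @staticmethod
    def _scan(positions, lods, chrom="1"):
        tbl = pd.DataFrame(
            {"chr": chrom, "pos": positions, "lod": lods, "degenerate": False}
        )
        return ScanResult("t", tbl, "hk")

    def test_basic_rule(self):
        scan = self._scan([0, 10, 20, 30, 40], [1, 3, 5, 3, 1])
        assert lod_support_interval(scan, "1", 1.5) == (10.0, 30.0)

    def test_clipped_at_chromosome_end(self):
        scan = self._scan([0, 10, 20], [5, 3, 1])
        assert lod_support_interval(scan, "1", 1.5) == (0.0, 10.0)

    def test_two_peak_profile_spans_both(self):
        # outermost-position rule: a secondary peak within drop of the
        # maximum extends the interval across the valley
        scan = self._scan(
            [0, 10, 20, 30, 40, 50, 60, 70, 80],
            [0.5, 1, 5, 1, 1, 1, 4.8, 1, 0.5],
        )
        assert lod_support_interval(scan, "1", 1.5) == (10.0, 70.0)

    def test_flat_profile_warns_whole_chromosome(self):
        scan = self._scan([0, 10, 20], [0.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="flat"):
            assert lod_support_interval(scan, "1") == (0.0, 20.0)
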