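"""Coverage, cross-omics agreement, Mantel, diversity and growth fitting."""

import numpy as np
import pandas as pd
import pytest

import syncomics as sc
from syncomics.concordance import DistanceMatrix, SigmoidFit
from syncomics.errors import AlignmentError, InsufficientDataError

from .conftest import make_counts


def profile(values: dict, index) -> sc.SpeciesProfile:
    return sc.SpeciesProfile("metagenome", pd.DataFrame(values, index=index))


class TestGeneCoverage:
    def test_fraction_of_genes_hit(self, two_species):
        counts = make_counts(
            two_species, "metagenome", {"s1": [1.0, 2.0, 3.0, 0.0, 0, 0, 0, 0]}
        )
        cov, cov_max = sc.gene_coverage(counts, two_species)
        assert cov.loc["sp01", "s1"] == 0.75  # 3 of 4 genes
        assert cov.loc["sp02", "s1"] == 0.0
        assert cov_max["sp01"] == 0.75

    def test_full_hit_gives_one(self, two_species):
        counts = make_counts(two_species, "metagenome", {"s1": [1.0] * 8})
        cov, _ = sc.gene_coverage(counts, two_species)
        assert (cov["s1"] == 1.0).all()

    def test_monotone_under_added_counts(self, two_species):
        lo = make_counts(two_species, "metagenome", {"s1": [1.0, 0, 0, 0, 1.0, 0, 0, 0]})
        hi = make_counts(two_species, "metagenome", {"s1": [1.0, 1.0, 0, 0, 1.0, 1.0, 0, 0]})
        cov_lo, _ = sc.gene_coverage(lo, two_species)
        cov_hi, _ = sc.gene_coverage(hi, two_species)
        assert (cov_hi["s1"] >= cov_lo["s1"]).all()


class TestPathwayCoverage:
    def test_detected_over_size(self):
        pmap = {"p1": frozenset(f"K{i}" for i in range(10))}
        cov = sc.pathway_coverage({"K0", "K1", "K2", "K3"}, pmap)
        assert cov["p1"] == 0.4

    def test_nothing_detected(self):
        cov = sc.pathway_coverage(set(), {"p1": {"K0"}})
        assert cov["p1"] == 0.0

    def test_empty_pathway_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            cov = sc.pathway_coverage({"K0"}, {"p1": set(), "p2": {"K0"}})
        assert "p1" not in cov.index

    def test_metabolite_counted_once_despite_two_ions(self):
        # coverage counts unique pathway members, not their supporting ions
        pmap = {"p1": {"metA", "metB"}}
        cov = sc.pathway_coverage({"metA"}, pmap)
        assert cov["p1"] == 0.5


class TestCrossOmicsSpearman:
    def test_identical_profiles(self):
        idx = [f"sp{i}" for i in range(5)]
        vals = {f"s{j}": np.arange(5) + j for j in range(4)}
        assert sc.cross_omics_spearman(profile(vals, idx), profile(vals, idx)) == 1.0

    def test_rank_reversed_profiles(self):
        idx = [f"sp{i}" for i in range(5)]
        a = {f"s{j}": np.arange(5.0) + 1 for j in range(4)}
        b = {f"s{j}": np.arange(5.0)[::-1] + 1 for j in range(4)}
        assert sc.cross_omics_spearman(profile(a, idx), profile(b, idx)) == -1.0

    def test_insufficient_shared_samples(self):
        idx = ["sp1", "sp2"]
        a = profile({"s1": [1, 2], "s2": [2, 1]}, idx)
        with pytest.raises(InsufficientDataError):
            sc.cross_omics_spearman(a, a)

    def test_min_abundance_filter_drops_low_pairs(self):
        idx = [f"sp{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        base = rng.random((6, 4))
        a = profile({f"s{j}": base[:, j] for j in range(4)}, idx)
        noisy = base.copy()
        noisy[base < 0.3] = rng.random((base < 0.3).sum())  # scramble low pairs
        b = profile({f"s{j}": noisy[:, j] for j in range(4)}, idx)
        full = sc.cross_omics_spearman(a, b)
        filtered = sc.cross_omics_spearman(a, b, min_abundance=0.3)
        assert filtered >= full


class TestSampleDistanceAndMantel:
    def random_dm(self, seed, n=12, n_features=30):
        rng = np.random.default_rng(seed)
        feats = pd.DataFrame(
            rng.lognormal(0, 1, size=(n_features, n)),
            columns=[f"s{i}" for i in range(n)],
        )
        return sc.sample_distance(feats)

    def test_duplicate_samples_have_zero_distance(self):
        feats = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0], "c": [9.0, 1.0, 4.0]})
        dm = sc.sample_distance(feats)
        assert dm.values[0, 1] == pytest.approx(0.0)

    def test_floor_drops_features(self):
        feats = pd.DataFrame(
            {"a": [1.0, 1e-9, 3.0], "b": [2.0, 2e-9, 1.0], "c": [3.0, 1e-9, 2.0]}
        )
        dm_all = sc.sample_distance(feats, mean_abundance_floor=0.0)
        dm_floor = sc.sample_distance(feats, mean_abundance_floor=1e-7)
        assert not np.allclose(dm_all.values, dm_floor.values)

    def test_identical_matrices_give_r_one(self):
        dm = self.random_dm(1)
        r, p = sc.mantel(dm, dm, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_r_invariant_to_joint_relabeling(self):
        da, db = self.random_dm(1), self.random_dm(2)
        r1, _ = sc.mantel(da, db, n_perm=19, seed=0)
        perm = np.random.default_rng(3).permutation(len(da.sample_ids))
        relabel = lambda dm: DistanceMatrix(
            [dm.sample_ids[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        r2, _ = sc.mantel(relabel(da), relabel(db), n_perm=19, seed=0)
        assert r1 == pytest.approx(r2)

    def test_sample_set_mismatch_raises(self):
        da = self.random_dm(1)
        db = self.random_dm(2, n=10)
        with pytest.raises(AlignmentError):
            sc.mantel(da, db)

    def test_matches_skbio_mantel_statistic(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        da, db = self.random_dm(4), self.random_dm(5)
        r_ours, _ = sc.mantel(da, db, n_perm=9, seed=0)
        dm_a = skbio_distance.DistanceMatrix(da.values, ids=da.sample_ids)
        dm_b = skbio_distance.DistanceMatrix(db.values, ids=db.sample_ids)
        r_skbio = skbio_distance.mantel(dm_a, dm_b, method="pearson", permutations=0)[0]
        assert r_ours == pytest.approx(float(r_skbio), abs=1e-12)


class TestDiversity:
    def test_inverse_simpson_known_values(self):
        assert sc.inverse_simpson(np.ones(7) / 7) == pytest.approx(7.0)
        assert sc.inverse_simpson([0.5, 0.5]) == pytest.approx(2.0)
        assert sc.inverse_simpson([0.9, 0.1]) == pytest.approx(1 / 0.82)

    def test_inverse_simpson_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(8))
            assert sc.inverse_simpson(p) >= 1.0
        assert sc.inverse_simpson([1.0]) == pytest.approx(1.0)

    def test_bray_curtis_known_values(self):
        assert sc.bray_curtis([1.0, 2.0], [1.0, 2.0]) == pytest.approx(0.0)
        assert sc.bray_curtis([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)
        assert sc.bray_curtis([2.0, 1.0], [1.0, 1.0]) == pytest.approx(1 / 5)


class TestSigmoidGrowth:
    def test_noise_free_parameter_recovery(self):
        t = np.arange(0.0, 24.0, 0.5)
        y = 2.5 / (1 + np.exp(-0.8 * (t - 5.0)))
        fit = sc.fit_sigmoid_growth(t, y)
        assert fit.success
        assert fit.L == pytest.approx(2.5, abs=1e-6)
        assert fit.k == pytest.approx(0.8, abs=1e-6)
        assert fit.t0 == pytest.approx(5.0, abs=1e-6)
        np.testing.assert_allclose(fit.normalized["od_normalized"].max(), 1.0, atol=1e-6)

    def test_recovers_treatment_time_from_simulated_od(self, truth, small_community, noise_free):
        od = sc.simulate_layer_observations(truth, small_community, "OD", 0, noise_free, seed=1)
        fit = sc.fit_sigmoid_growth(od["time_h"], od["od"])
        assert fit.success
        assert fit.t0 == pytest.approx(5.0, abs=0.05)  # drug added 5 h after passage

    def test_decreasing_series_flags_failure(self):
        fit = sc.fit_sigmoid_growth(np.arange(6.0), np.linspace(2.0, 0.5, 6))
        assert isinstance(fit, SigmoidFit) and not fit.success


class TestLaggedFoldChangeCorrelation:
    def test_shifted_series_puts_unity_off_diagonal(self):
        rng = np.random.default_rng(0)
        tp = [0.0, 1.0, 2.0, 3.0]
        tf = pd.DataFrame(rng.normal(size=(20, 4)), columns=tp)
        pf = tf.shift(1, axis=1)
        mat = sc.lagged_fc_correlation(tf, pf)
        for i in range(len(tp) - 1):
            assert mat.iloc[i, i + 1] == pytest.approx(1.0)

    def test_independent_noise_stays_near_zero(self):
        rng = np.random.default_rng(1)
        tp = [0.0, 1.0, 2.0]
        tf = pd.DataFrame(rng.normal(size=(200, 3)), columns=tp)
        pf = pd.DataFrame(rng.normal(size=(200, 3)), columns=tp)
        mat = sc.lagged_fc_correlation(tf, pf)
        assert mat.abs().max().max() < 0.25

    def test_insufficient_shared_features_raises(self):
        tf = pd.DataFrame(np.ones((3, 2)), columns=[0.0, 1.0])
        with pytest.raises(InsufficientDataError):
            sc.lagged_fc_correlation(tf, tf)
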