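"""Alpha/beta diversity, NMDS and the permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from otunet import diversity
from otunet.diversity import OrdinationResult
from otunet.tables_io import OtuTable


def _dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


def _groups(ids, labels):
    return pd.Series(labels, index=ids)


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert diversity.shannon([10, 10, 10, 10]) == pytest.approx(np.log(4))

    def test_single_taxon_is_zero(self):
        assert diversity.shannon([7, 0, 0]) == 0.0

    def test_hand_value(self):
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        assert diversity.shannon([3, 1]) == pytest.approx(expected)

    def test_base_conversion(self):
        assert diversity.shannon([1, 1], base=2) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            diversity.shannon([0, 0])

    def test_uniform_maximal_over_random_compositions(self):
        rng = np.random.default_rng(5)
        k = 6
        hmax = diversity.shannon([1] * k)
        for _ in range(20):
            assert diversity.shannon(rng.integers(1, 50, k)) <= hmax + 1e-12


class TestRarefiedRichness:
    def test_depth_equal_total_gives_observed_richness(self):
        assert diversity.rarefied_richness([5, 3, 2], depth=10) == pytest.approx(3.0)

    def test_closed_form_two_taxa(self):
        # (5,5) at depth 5: 2 * (1 - C(5,5)/C(10,5)) = 2 * (1 - 1/252)
        assert diversity.rarefied_richness([5, 5], depth=5) == pytest.approx(
            2 * (1 - 1 / 252)
        )

    def test_total_below_depth_rejected(self):
        with pytest.raises(ValueError, match="below depth"):
            diversity.rarefied_richness([10, 10], depth=100)

    def test_monte_carlo_agreement(self):
        # closed form vs 10,000 explicit uniform subsamples
        counts = np.array([50, 20, 10, 5, 2, 1, 1, 1])
        depth = 30
        rng = np.random.default_rng(12)
        sub = rng.multivariate_hypergeometric(counts, depth, size=10_000)
        richness = (sub > 0).sum(axis=1)
        se = richness.std(ddof=1) / np.sqrt(len(richness))
        expected = diversity.rarefied_richness(counts, depth=depth)
        assert abs(richness.mean() - expected) <= 3 * se


class TestBrayCurtis:
    def test_identical_samples_zero(self, toy_meta):
        counts = pd.DataFrame({"a": [3, 3, 3, 3], "b": [1, 1, 1, 1]}, index=toy_meta.index)
        dm = diversity.bray_curtis(OtuTable(counts, toy_meta))
        assert np.allclose(dm.data, 0)

    def test_disjoint_supports_one(self, toy_meta):
        counts = pd.DataFrame(
            {"a": [5, 5, 0, 0], "b": [0, 0, 7, 7]}, index=toy_meta.index
        )
        dm = diversity.bray_curtis(OtuTable(counts, toy_meta))
        assert dm["s1", "s3"] == pytest.approx(1.0)

    def test_hand_value(self, toy_meta):
        counts = pd.DataFrame(
            {"a": [6, 2, 6, 6], "b": [2, 2, 2, 2]}, index=toy_meta.index
        )
        dm = diversity.bray_curtis(OtuTable(counts, toy_meta))
        assert dm["s1", "s2"] == pytest.approx(1 / 3)

    def test_symmetry_bounds_and_zero_diagonal(self, filtered_study):
        table, _ = filtered_study
        dm = diversity.bray_curtis(table)
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)
        assert dm.data.max() <= 1.0 + 1e-12

    def test_all_zero_sample_rejected(self, toy_meta):
        counts = pd.DataFrame({"a": [0, 1, 1, 1], "b": [0, 1, 1, 1]}, index=toy_meta.index)
        with pytest.raises(ValueError):
            diversity.bray_curtis(OtuTable(counts, toy_meta))


class TestNMDS:
    def test_perfectly_embeddable_configuration(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [2, 0.5]])
        res = diversity.nmds(_dm(pts), n_restarts=4, seed=0)
        assert res.stress < 1e-3

    def test_best_of_restarts_is_minimum(self):
        rng = np.random.default_rng(3)
        res = diversity.nmds(_dm(rng.normal(size=(9, 5))), n_restarts=5, seed=1)
        assert res.stress == pytest.approx(min(res.restart_stresses))
        assert res.stress >= 0

    def test_same_seed_identical_coordinates(self):
        rng = np.random.default_rng(4)
        d = _dm(rng.normal(size=(8, 4)))
        a = diversity.nmds(d, n_restarts=3, seed=9)
        b = diversity.nmds(d, n_restarts=3, seed=9)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            diversity.nmds(_dm(np.eye(3)), k=2)


class TestAnosim:
    def test_complete_separation_r_equals_one(self):
        pts = [[0], [0.1], [0.2], [10], [10.1], [10.2]]
        ids = [f"s{i}" for i in range(6)]
        res = diversity.anosim(_dm(pts, ids), _groups(ids, list("aaabbb")), nperm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 4))
        ids = [f"s{i}" for i in range(12)]
        groups = list("aaaabbbbcccc")
        d = _dm(pts, ids)
        ours = diversity.anosim(d, _groups(ids, groups), nperm=99, seed=0)
        theirs = skbio_anosim(d, np.array(groups), permutations=9)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_invariant_to_group_renaming_and_seeded(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 3))
        ids = [f"s{i}" for i in range(10)]
        d = _dm(pts, ids)
        g1 = _groups(ids, list("aaaaabbbbb"))
        g2 = _groups(ids, list("xxxxxyyyyy"))
        r1 = diversity.anosim(d, g1, nperm=199, seed=5)
        r2 = diversity.anosim(d, g2, nperm=199, seed=5)
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value
        assert 1 / 200 <= r1.p_value <= 1.0

    def test_singleton_group_rejected(self):
        pts = [[0], [1], [2]]
        ids = ["a", "b", "c"]
        with pytest.raises(ValueError):
            diversity.anosim(_dm(pts, ids), _groups(ids, ["g1", "g1", "g2"]))


class TestPermanova:
    def test_matches_skbio_pseudo_f(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(14, 5))
        ids = [f"s{i}" for i in range(14)]
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 4
        d = _dm(pts, ids)
        ours = diversity.permanova(d, _groups(ids, groups), nperm=99, seed=0)
        theirs = skbio_permanova(d, np.array(groups), permutations=9)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_degenerate_separation(self):
        # duplicated identical points within groups, distinct between
        pts = [[0], [0], [0], [5], [5], [5]]
        ids = [f"s{i}" for i in range(6)]
        res = diversity.permanova(_dm(pts, ids), _groups(ids, list("aaabbb")), nperm=199, seed=0)
        assert np.isinf(res.statistic)  # SS_within = 0
        assert res.extras["R2"] == pytest.approx(1.0)

    def test_r_squared_decomposition(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(12, 4))
        ids = [f"s{i}" for i in range(12)]
        res = diversity.permanova(
            _dm(pts, ids), _groups(ids, list("aaaabbbbcccc")), nperm=99, seed=1
        )
        # R^2 + SS_within/SS_total = 1 is implicit in the computation; check range
        assert 0 <= res.extras["R2"] <= 1


class TestEnvfit:
    def _ordination(self, coords, ids):
        df = pd.DataFrame(coords, index=ids, columns=["NMDS1", "NMDS2"])
        return OrdinationResult(df, stress=0.1, restart_stresses=[0.1], seed=0)

    def test_each_sample_its_own_centroid(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(6)]
        ordn = self._ordination(rng.normal(size=(6, 2)), ids)
        res = diversity.envfit_factor(ordn, _groups(ids, ids), nperm=999, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_identical_coordinates_rejected(self):
        ids = ["a", "b", "c", "d"]
        ordn = self._ordination(np.ones((4, 2)), ids)
        with pytest.raises(ValueError):
            diversity.envfit_factor(ordn, _groups(ids, ["x", "x", "y", "y"]))

    def test_single_group_rejected(self):
        rng = np.random.default_rng(1)
        ids = ["a", "b", "c", "d"]
        ordn = self._ordination(rng.normal(size=(4, 2)), ids)
        with pytest.raises(ValueError):
            diversity.envfit_factor(ordn, _groups(ids, ["x"] * 4))


class TestDispersion:
    def test_identical_group_has_zero_dissimilarities(self, toy_meta):
        counts = pd.DataFrame(
            {"a": [5, 5, 1, 9], "b": [2, 2, 8, 4]}, index=toy_meta.index
        )
        dm = diversity.bray_curtis(OtuTable(counts, toy_meta))
        res = diversity.intragroup_dispersion(dm, toy_meta["group"])
        assert np.allclose(res.within["A"], 0)
        assert (res.within["B"] > 0).all()

    def test_planted_high_variance_group_flagged(self):
        # one group with 3x the dispersion of the others
        rng = np.random.default_rng(42)
        hits = 0
        for rep in range(50):
            pts = np.vstack(
                [
                    rng.normal(0, 1, size=(8, 3)),
                    rng.normal(0, 1, size=(8, 3)),
                    rng.normal(0, 3, size=(8, 3)),
                ]
            )
            ids = [f"s{i}" for i in range(24)]
            groups = _groups(ids, ["a"] * 8 + ["b"] * 8 + ["c"] * 8)
            dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
            res = diversity.intragroup_dispersion(dm, groups)
            if res.comparison.p < 0.05:
                hits += 1
        assert hits >= 45  # >= 90% power at this effect size
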