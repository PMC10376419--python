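import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from gutsem.diversity import (DistanceMatrix, alpha_diversity, bray_curtis,
                              nmds, permanova)
from gutsem.exceptions import DomainError, InsufficientDataError


class TestAlphaDiversity:
    def test_uniform_ten_genera(self):
        a = alpha_diversity(np.array([[3] * 10]))
        assert a["shannon"][0] == pytest.approx(np.log(10), abs=1e-12)
        assert a["pielou"][0] == pytest.approx(1.0, abs=1e-12)
        assert a["simpson"][0] == pytest.approx(0.9, abs=1e-12)
        assert a["richness"][0] == 10

    def test_single_genus_degenerate(self):
        a = alpha_diversity(np.array([[7, 0, 0]]))
        assert a["shannon"][0] == 0.0
        assert a["simpson"][0] == 0.0
        assert a["richness"][0] == 1
        assert np.isnan(a["pielou"][0])  # undefined at richness 1

    def test_hand_computed_shannon(self):
        a = alpha_diversity(np.array([[2, 1, 1]]))  # p = (.5, .25, .25)
        assert a["shannon"][0] == pytest.approx(1.0397, abs=5e-5)

    def test_invariants_on_random_counts(self, planted_dataset):
        a = alpha_diversity(planted_dataset.counts)
        assert ((a["simpson"] >= 0) & (a["simpson"] < 1)).all()
        assert ((a["pielou"] >= 0) & (a["pielou"] <= 1)).all()
        assert (a["shannon"] <= np.log(a["richness"]) + 1e-12).all()

    def test_all_zero_sample_rejected(self):
        with pytest.raises(DomainError):
            alpha_diversity(np.array([[0, 0]]))


class TestBrayCurtis:
    def test_known_pairs(self):
        d = bray_curtis(np.array([[2, 0], [0, 2], [1, 1], [1, 1]]))
        assert d.values[0, 1] == pytest.approx(1.0)   # disjoint supports
        assert d.values[2, 3] == pytest.approx(0.0)   # identical
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)
        assert ((d.values >= 0) & (d.values <= 1)).all()

    def test_matches_formula(self, planted_dataset):
        x = planted_dataset.counts.counts[:5].astype(float)
        d = bray_curtis(x)
        a, b = x[0], x[3]
        expected = 1 - 2 * np.minimum(a, b).sum() / (a.sum() + b.sum())
        assert d.values[0, 3] == pytest.approx(expected, abs=1e-12)


class TestNmds:
    def test_perfect_embedding_low_stress(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1.2, 1.1]])
        d = DistanceMatrix(list("abcd"), squareform(pdist(pts)))
        ordn = nmds(d, k=2, n_restarts=20, seed=0)
        assert ordn.stress < 0.01
        assert np.allclose(ordn.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_duplicated_sample_maps_together(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        X = np.vstack([X, X[0]])  # duplicate
        d = DistanceMatrix([f"s{i}" for i in range(9)],
                           squareform(pdist(X)))
        ordn = nmds(d, k=2, n_restarts=20, seed=2)
        c = ordn.coordinates
        diam = np.max(pdist(c))
        assert np.linalg.norm(c[0] - c[8]) < 1e-3 * diam

    def test_stress_non_increasing_in_k(self):
        rng = np.random.default_rng(0)
        d = DistanceMatrix([f"s{i}" for i in range(12)],
                           squareform(pdist(rng.normal(size=(12, 6)))))
        stresses = [nmds(d, k=k, n_restarts=10, seed=1).stress for k in (1, 2, 3)]
        assert stresses[0] >= stresses[1] >= stresses[2]

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        d = DistanceMatrix([f"s{i}" for i in range(7)],
                           squareform(pdist(rng.normal(size=(7, 4)))))
        a = nmds(d, seed=5)
        b = nmds(d, seed=5)
        assert a.stress == b.stress
        np.testing.assert_array_equal(a.coordinates, b.coordinates)


class TestPermanova:
    @staticmethod
    def _two_cluster_dm(sep: float, n: int = 5, seed: int = 0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 0.05, (n, 3)),
                       rng.normal(sep, 0.05, (n, 3))])
        return DistanceMatrix([f"s{i}" for i in range(2 * n)],
                              squareform(pdist(np.abs(X), metric="braycurtis")))

    def test_separated_clusters_min_p(self):
        d = self._two_cluster_dm(sep=3.0)
        labels = ["a"] * 5 + ["b"] * 5
        # exhaustive enumeration: only the observed partition (2 of the 252
        # label assignments: the split and its mirror) reaches F_obs
        res_ex = permanova(d, labels, exhaustive=True)
        assert res_ex.p_value == pytest.approx(2 / 252)
        # Monte-Carlo permutations re-draw the observed partition with
        # probability 2/252 per draw, so p lands just above 1/(n_perm + 1)
        res = permanova(d, labels, n_permutations=999, seed=0)
        assert 1 / 1000 <= res.p_value < 0.03
        assert res.pseudo_F > 1

    def test_exhaustive_matches_bruteforce_enumeration(self):
        from itertools import combinations
        rng = np.random.default_rng(4)
        X = np.abs(rng.normal(1, 0.5, (6, 4)))
        d = DistanceMatrix(list("abcdef"),
                           squareform(pdist(X, metric="braycurtis")))
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = permanova(d, labels, exhaustive=True)
        assert res.n_permutations == 20

        # independent brute-force oracle over all 20 splits
        def pseudo_f(lab):
            d2 = d.values ** 2
            n = 6
            sst = d2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for g in ("a", "b"):
                idx = np.flatnonzero(lab == g)
                ssw += d2[np.ix_(idx, idx)][np.triu_indices(3, 1)].sum() / 3
            return ((sst - ssw) / 1) / (ssw / 4)

        f_obs = pseudo_f(labels)
        fs = []
        for pick in combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(pick)] = "a"
            fs.append(pseudo_f(lab))
        expected_p = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert res.p_value == pytest.approx(expected_p)

    def test_agrees_with_skbio_statistic(self):
        skbio = pytest.importorskip("skbio")
        d = self._two_cluster_dm(sep=1.0, seed=2)
        labels = ["a"] * 5 + ["b"] * 5
        res = permanova(d, labels, n_permutations=99, seed=1)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.sample_ids), labels, permutations=99)
        assert res.pseudo_F == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_label_name_invariance(self):
        d = self._two_cluster_dm(sep=1.0, seed=3)
        labels1 = np.array(["a"] * 5 + ["b"] * 5)
        labels2 = np.array(["x"] * 5 + ["y"] * 5)
        r1 = permanova(d, labels1, n_permutations=199, seed=9)
        r2 = permanova(d, labels2, n_permutations=199, seed=9)
        assert r1.p_value == r2.p_value and r1.pseudo_F == r2.pseudo_F

    def test_degenerate_grouping_rejected(self):
        d = self._two_cluster_dm(sep=1.0)
        with pytest.raises(InsufficientDataError):
            permanova(d, ["a"] * 9 + ["b"], n_permutations=99)
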