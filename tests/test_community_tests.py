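import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from metacom import OtuTable, bray_curtis, permanova_one_way, permanova_two_way, simper
from metacom.data_model import DesignError


@pytest.fixture
def two_group_dm():
    """Within-group d=1, between-group d=2: SS_total=4.5, SS_within=1, F=7."""
    d = np.array(
        [[0, 1, 2, 2], [1, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0]], dtype=float
    )
    return DistanceMatrix(d, ids=list("abcd"))


class TestPermanovaOneWay:
    def test_hand_computation_and_exact_enumeration(self, two_group_dm):
        r = permanova_one_way(two_group_dm, ["g1", "g1", "g2", "g2"])
        assert r.ss_total == pytest.approx(4.5)
        assert r.ss_within == pytest.approx(1.0)
        assert r.pseudo_f == pytest.approx(7.0)
        assert r.exact and r.n_permutations == 6
        assert r.p_value == pytest.approx(2 / 6)

    def test_partition_identity(self, two_group_dm):
        r = permanova_one_way(two_group_dm, ["g1", "g1", "g2", "g2"])
        assert r.ss_between + r.ss_within == pytest.approx(r.ss_total, abs=1e-9)

    def test_single_group_rejected(self, two_group_dm):
        with pytest.raises(DesignError):
            permanova_one_way(two_group_dm, ["g"] * 4)

    def test_small_group_rejected(self, two_group_dm):
        with pytest.raises(DesignError):
            permanova_one_way(two_group_dm, ["g1", "g2", "g2", "g2"])

    def test_invariant_to_relabeling_and_order(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((10, 2))
        dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(10)])
        labels = ["a"] * 5 + ["b"] * 5
        r1 = permanova_one_way(dm, labels, n_perm=99, seed=0, exact_cap=1)
        r2 = permanova_one_way(dm, ["B" if l == "a" else "A" for l in labels],
                               n_perm=99, seed=0, exact_cap=1)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f)
        perm = rng.permutation(10)
        dm_p = DistanceMatrix(dm.data[np.ix_(perm, perm)],
                              ids=[str(i) for i in perm])
        r3 = permanova_one_way(dm_p, [labels[i] for i in perm],
                               n_perm=99, seed=0, exact_cap=1)
        assert r1.pseudo_f == pytest.approx(r3.pseudo_f)

    def test_matches_skbio_pseudo_f(self):
        """Independent implementation check of the observed statistic."""
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(7)
        x = rng.standard_normal((12, 3)) + np.repeat([[0], [1]], 6, axis=0)
        dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(12)])
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova_one_way(dm, labels, n_perm=99, seed=0, exact_cap=1)
        theirs = skbio_permanova(dm, grouping=np.array(labels), permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_euclidean_partition_matches_coordinate_anova(self):
        """For Euclidean distances the distance-based SS equal coordinate SS."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal((9, 2))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(9)])
        r = permanova_one_way(dm, labels, n_perm=9, seed=0, exact_cap=1)
        ss_total = ((x - x.mean(0)) ** 2).sum()
        ss_within = sum(
            ((x[i::3] - x[i::3].mean(0)) ** 2).sum() for i in [0]
        )
        grouped = [x[:3], x[3:6], x[6:]]
        ss_within = sum(((g - g.mean(0)) ** 2).sum() for g in grouped)
        assert r.ss_total == pytest.approx(ss_total, abs=1e-9)
        assert r.ss_within == pytest.approx(ss_within, abs=1e-9)

    def test_monte_carlo_matches_exact(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((8, 2))
        dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(8)])
        labels = ["a"] * 4 + ["b"] * 4
        exact = permanova_one_way(dm, labels, exact_cap=100)
        assert exact.exact
        mc = permanova_one_way(dm, labels, n_perm=10_000, seed=9, exact_cap=1)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 10_000)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 1e-4

    def test_deterministic_given_seed(self, two_group_dm):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((10, 2))
        dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(10)])
        labels = ["a"] * 5 + ["b"] * 5
        p1 = permanova_one_way(dm, labels, n_perm=199, seed=5, exact_cap=1).p_value
        p2 = permanova_one_way(dm, labels, n_perm=199, seed=5, exact_cap=1).p_value
        assert p1 == p2


class TestPermanovaTwoWay:
    @staticmethod
    def _crossed_data(effect_a=2.0, effect_b=0.0, seed=0, reps=4):
        rng = np.random.default_rng(seed)
        rows, fa, fb = [], [], []
        for a in (0, 1):
            for b in (0, 1):
                for _ in range(reps):
                    rows.append(
                        effect_a * a + effect_b * b + rng.standard_normal(2) * 0.5
                    )
                    fa.append(f"A{a}")
                    fb.append(f"B{b}")
        x = np.array(rows)
        dm = DistanceMatrix(
            squareform(pdist(x)), ids=[str(i) for i in range(len(x))]
        )
        return dm, fa, fb

    def test_pure_a_effect_detected_b_not(self):
        dm, fa, fb = self._crossed_data(effect_a=2.0, effect_b=0.0, seed=1)
        res = {r.term: r for r in permanova_two_way(dm, fa, fb, n_perm=999, seed=3)}
        assert res["A"].p_value <= 0.05
        assert res["B"].p_value > 0.1

    def test_single_level_factor_rejected(self):
        dm, fa, fb = self._crossed_data()
        with pytest.raises(DesignError, match="single level"):
            permanova_two_way(dm, fa, ["B0"] * len(fb))

    def test_empty_cell_rejected(self):
        dm, fa, fb = self._crossed_data()
        fb = ["B0" if a == "A0" else "B1" for a in fa]
        with pytest.raises(DesignError, match="empty design cell"):
            permanova_two_way(dm, fa, fb)

    def test_ss_partition_closes(self):
        dm, fa, fb = self._crossed_data(effect_a=1.0, effect_b=1.0, seed=4)
        res = permanova_two_way(dm, fa, fb, n_perm=9, seed=0)
        ss_terms = sum(r.ss_between for r in res)
        ss_res = res[0].ss_within
        assert ss_terms + ss_res == pytest.approx(res[0].ss_total, abs=1e-9)


class TestSimper:
    def test_single_pair_hand_oracle(self, toy_table):
        res = simper(toy_table, ["A", "B"])
        contrib = dict(zip(res.taxon_ids, res.contributions))
        assert contrib["t1"] == pytest.approx(0.25)
        assert contrib["t2"] == pytest.approx(0.0)
        assert contrib["t3"] == pytest.approx(0.25)
        assert res.overall_dissimilarity == pytest.approx(0.5)
        assert sorted(res.percent, reverse=True)[:2] == [
            pytest.approx(50.0), pytest.approx(50.0)
        ]

    def test_identical_groups_all_zero(self):
        t = OtuTable(["a", "b"], ["s1", "s2"], np.array([[3, 3], [2, 2]]))
        res = simper(t, ["A", "B"])
        assert res.overall_dissimilarity == pytest.approx(0.0)
        np.testing.assert_allclose(res.contributions, 0.0)

    def test_conservation_identity_random_table(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 40, size=(15, 8))
        counts[0] += 1
        t = OtuTable([f"t{i}" for i in range(15)],
                     [f"s{j}" for j in range(8)], counts)
        labels = ["A"] * 4 + ["B"] * 4
        res = simper(t, labels)
        dm = bray_curtis(t)
        between = [dm[f"s{i}", f"s{j}"] for i in range(4) for j in range(4, 8)]
        assert res.contributions.sum() == pytest.approx(np.mean(between), abs=1e-10)
        assert res.percent.sum() == pytest.approx(100.0, abs=1e-8)
        assert all(np.diff(res.contributions) <= 1e-15)

    def test_top_taxon_carries_group_difference(self):
        rng = np.random.default_rng(9)
        base = rng.integers(10, 20, size=(10, 6))
        counts = base.copy()
        counts[0, 3:] += 500  # one taxon drives the whole difference
        t = OtuTable([f"t{i}" for i in range(10)],
                     [f"s{j}" for j in range(6)], counts)
        res = simper(t, ["A"] * 3 + ["B"] * 3)
        assert res.taxon_ids[0] == "t0"

    def test_three_groups_rejected(self, toy_table):
        t = OtuTable(["a"], ["s1", "s2", "s3"], np.array([[1, 2, 3]]))
        with pytest.raises(DesignError):
            simper(t, ["A", "B", "C"])
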