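import math
from itertools import permutations

import dendropy
import numpy as np
import pytest

from metacom import (
    OtuTable,
    beta_mntd,
    beta_nti,
    classify,
    mntd,
    patristic_distances,
    process_fractions,
    ses_mntd,
    simulate_tree,
)
from metacom.phylo import (
    HETEROGENEOUS,
    HOMOGENEOUS,
    STOCHASTIC,
    PhyloDistances,
    PhyloError,
)


class TestPatristicDistances:
    def test_cherry(self):
        tree = dendropy.Tree.get(data="(A:1,B:2);", schema="newick")
        pd_ = patristic_distances(tree)
        assert pd_.matrix[0, 1] == pytest.approx(3.0)

    def test_three_taxon_path_sums(self, small_tree):
        pd_ = patristic_distances(small_tree)
        d = {(a, b): pd_.matrix[i, j]
             for i, a in enumerate(pd_.taxon_ids)
             for j, b in enumerate(pd_.taxon_ids)}
        assert d[("A", "B")] == pytest.approx(2.0)
        assert d[("A", "C")] == pytest.approx(4.0)
        assert d[("B", "C")] == pytest.approx(4.0)

    def test_star_tree_all_pairs_2b(self):
        tree = dendropy.Tree.get(data="(A:1.5,B:1.5,C:1.5,D:1.5);", schema="newick")
        pd_ = patristic_distances(tree)
        off = pd_.matrix[np.triu_indices(4, 1)]
        np.testing.assert_allclose(off, 3.0)

    def test_negative_branch_length_policy(self):
        tree = dendropy.Tree.get(data="(A:1,B:-0.5);", schema="newick")
        with pytest.raises(PhyloError):
            patristic_distances(tree)
        tree2 = dendropy.Tree.get(data="(A:1,B:-0.5);", schema="newick")
        pd_ = patristic_distances(tree2, clamp_negative=True)
        assert pd_.matrix[0, 1] == pytest.approx(1.0)

    def test_four_point_condition_on_random_tree(self):
        tree = simulate_tree(8, seed=4)
        m = patristic_distances(tree).matrix
        # for any quartet the two largest of the three pair-sums are equal
        from itertools import combinations

        for q in combinations(range(8), 4):
            i, j, k, l = q
            sums = sorted([m[i, j] + m[k, l], m[i, k] + m[j, l], m[i, l] + m[j, k]])
            assert sums[2] - sums[1] < 1e-9


class TestMntd:
    def test_two_taxon_community(self):
        pd_ = PhyloDistances(["A", "B"], np.array([[0.0, 4.0], [4.0, 0.0]]))
        assert mntd(["A", "B"], pd_) == pytest.approx(4.0)

    def test_row_minimum_oracle(self, triangle_distances):
        # mean(min(2,6), min(2,4), min(6,4)) = (2+2+4)/3
        assert mntd(["x1", "x2", "x3"], triangle_distances) == pytest.approx(8 / 3)

    def test_singleton_community_flagged(self, triangle_distances):
        with pytest.raises(PhyloError):
            mntd(["x1"], triangle_distances)

    def test_abundance_weighted_variant(self, triangle_distances):
        # weights (0.5, 0.25, 0.25) on nearest distances (2, 2, 4)
        val = mntd({"x1": 2, "x2": 1, "x3": 1}, triangle_distances,
                   abundance_weighted=True)
        assert val == pytest.approx(0.5 * 2 + 0.25 * 2 + 0.25 * 4)


class TestSesMntd:
    def test_whole_pool_community_is_degenerate(self, triangle_distances):
        table = OtuTable(["x1", "x2", "x3"], ["s"], np.array([[1], [1], [1]]))
        res = ses_mntd(table, triangle_distances, n_runs=99, seed=0)[0]
        assert res.degenerate and res.nti is None

    def test_monte_carlo_matches_enumeration_small_pool(self):
        tree = simulate_tree(4, seed=1)
        pd_ = patristic_distances(tree)
        taxa = pd_.taxon_ids
        counts = np.array([[1], [1], [0], [0]])
        table = OtuTable(taxa, ["s"], counts)
        exact = ses_mntd(table, pd_, n_runs=99, seed=0, enum_cap=50)[0]
        assert exact.n_null_runs == math.factorial(4)
        mc = ses_mntd(table, pd_, n_runs=999, seed=3, enum_cap=2)[0]
        se = exact.null_sd / np.sqrt(999)
        assert abs(mc.null_mean - exact.null_mean) < 3 * se

    def test_enumeration_matches_brute_force(self):
        """Null moments equal direct enumeration over all label permutations."""
        tree = simulate_tree(5, seed=2)
        pd_ = patristic_distances(tree)
        idx = np.array([0, 2, 3])
        nulls = []
        for p in permutations(range(5)):
            p = np.array(p)
            sub = pd_.matrix[np.ix_(p[idx], p[idx])].copy()
            np.fill_diagonal(sub, np.inf)
            nulls.append(sub.min(axis=1).mean())
        counts = np.zeros((5, 1), dtype=int)
        counts[idx] = 1
        table = OtuTable(pd_.taxon_ids, ["s"], counts)
        res = ses_mntd(table, pd_, n_runs=10, seed=0, enum_cap=200)[0]
        assert res.null_mean == pytest.approx(np.mean(nulls))
        assert res.null_sd == pytest.approx(np.std(nulls, ddof=1))

    def test_clustered_community_positive_nti(self):
        # two near taxa plus one distant outlier in the pool
        pd_ = PhyloDistances(
            ["a", "b", "c", "d"],
            np.array(
                [
                    [0.0, 0.1, 0.1, 10.0],
                    [0.1, 0.0, 0.1, 10.0],
                    [0.1, 0.1, 0.0, 10.0],
                    [10.0, 10.0, 10.0, 0.0],
                ]
            ),
        )
        table = OtuTable(["a", "b", "c", "d"], ["s"],
                         np.array([[1], [1], [0], [0]]))
        res = ses_mntd(table, pd_, n_runs=99, seed=0, enum_cap=50)[0]
        assert res.nti is not None and res.nti > 0
        assert res.nti == pytest.approx(-res.z)


class TestBetaMntd:
    def test_identical_singletons(self):
        pd_ = PhyloDistances(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert beta_mntd([1, 0], [1, 0], pd_) == pytest.approx(0.0)

    def test_disjoint_singletons(self):
        pd_ = PhyloDistances(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert beta_mntd([1, 0], [0, 1], pd_) == pytest.approx(3.0)

    def test_hand_oracle_unweighted(self, triangle_distances):
        # j={x1,x2}, k={x2,x3}: 0.5*[(2+0)/2 + (0+4)/2] = 1.5
        val = beta_mntd([1, 1, 0], [0, 1, 1], triangle_distances,
                        abundance_weighted=False)
        assert val == pytest.approx(1.5)

    def test_weighted_uses_relative_abundances(self, triangle_distances):
        # j: x1 w=0.75 (min d=2), x2 w=0.25 (min 0); k: x2 w=0.5, x3 w=0.5 (min 4)
        val = beta_mntd([3, 1, 0], [0, 1, 1], triangle_distances,
                        abundance_weighted=True)
        assert val == pytest.approx(0.5 * (0.75 * 2) + 0.5 * (0.5 * 4))

    def test_empty_sample_rejected(self, triangle_distances):
        with pytest.raises(PhyloError):
            beta_mntd([0, 0, 0], [1, 0, 0], triangle_distances)


class TestClassification:
    @pytest.mark.parametrize(
        "z,label",
        [
            (-3.0, HOMOGENEOUS),
            (2.5, HETEROGENEOUS),
            (0.5, STOCHASTIC),
            (-2.0, STOCHASTIC),  # boundary: strict inequalities for selection
            (2.0, STOCHASTIC),
        ],
    )
    def test_thresholds(self, z, label):
        assert classify(z) == label


class TestBetaNti:
    def test_group_of_nine_yields_36_pairs(self, neutral_dataset, neutral_pdist):
        table = neutral_dataset.table
        fish = [s for s in table.sample_ids if "fish" in s and s.startswith("FTS")]
        assert len(fish) == 9
        sets = beta_nti(table, neutral_pdist, {"FTS|8": fish},
                        n_runs=49, seed=0)
        assert sets[0].n_pairs == 36

    def test_null_moments_match_enumeration_small_pool(self):
        tree = simulate_tree(5, seed=6)
        pd_ = patristic_distances(tree)
        counts = np.array([[5, 0], [3, 2], [0, 4], [1, 0], [0, 3]])
        table = OtuTable(pd_.taxon_ids, ["sa", "sb"], counts)
        exact = beta_nti(table, pd_, {"g": ["sa", "sb"]}, n_runs=10, seed=0,
                         enum_cap=200)[0]
        mc = beta_nti(table, pd_, {"g": ["sa", "sb"]}, n_runs=1999, seed=1,
                      enum_cap=2)[0]
        se = exact.null_sd[0] / np.sqrt(1999)
        assert abs(mc.null_mean[0] - exact.null_mean[0]) < 3 * se

    def test_invariant_to_taxon_order(self, triangle_distances):
        counts = np.array([[4, 0], [2, 3], [0, 5]])
        t1 = OtuTable(["x1", "x2", "x3"], ["sa", "sb"], counts)
        perm = [2, 0, 1]
        t2 = OtuTable([["x1", "x2", "x3"][i] for i in perm], ["sa", "sb"],
                      counts[perm])
        pd2 = triangle_distances.subset(t2.taxon_ids)
        r1 = beta_nti(t1, triangle_distances, {"g": ["sa", "sb"]},
                      n_runs=10, seed=0, enum_cap=10)[0]
        r2 = beta_nti(t2, pd2, {"g": ["sa", "sb"]}, n_runs=10, seed=0,
                      enum_cap=10)[0]
        assert r1.observed[0] == pytest.approx(r2.observed[0])
        assert r1.null_mean[0] == pytest.approx(r2.null_mean[0])

    def test_deterministic_given_seed(self, neutral_dataset, neutral_pdist):
        table = neutral_dataset.table
        fish = [s for s in table.sample_ids if "fish" in s][:4]
        a = beta_nti(table, neutral_pdist, {"g": fish}, n_runs=29, seed=11)[0]
        b = beta_nti(table, neutral_pdist, {"g": fish}, n_runs=29, seed=11)[0]
        np.testing.assert_array_equal(a.beta_nti, b.beta_nti)


class TestProcessFractions:
    def _mk(self, labels, group="g"):
        from metacom.phylo import BetaNtiSet

        n = len(labels)
        z = np.array([{"h": -3.0, "x": 3.0, "s": 0.0}[l] for l in labels])
        lab = [{"h": HOMOGENEOUS, "x": HETEROGENEOUS, "s": STOCHASTIC}[l]
               for l in labels]
        return BetaNtiSet(
            group=group,
            pairs=[(f"a{i}", f"b{i}") for i in range(n)],
            observed=np.zeros(n),
            null_mean=np.zeros(n),
            null_sd=np.ones(n),
            beta_nti=z,
            labels=lab,
            n_degenerate=0,
        )

    def test_counting(self):
        df = process_fractions([self._mk(list("sshs"))])
        assert df.loc["g", STOCHASTIC] == pytest.approx(0.75)
        assert df.loc["g", HOMOGENEOUS] == pytest.approx(0.25)

    def test_all_one_class(self):
        df = process_fractions([self._mk(["h"] * 36)])
        assert df.loc["g", HOMOGENEOUS] == pytest.approx(1.0)
        assert df.loc["g", "n_pairs"] == 36

    def test_fractions_sum_to_one(self):
        df = process_fractions([self._mk(list("sxhsx"))])
        total = sum(df.loc["g", p] for p in (HOMOGENEOUS, HETEROGENEOUS, STOCHASTIC))
        assert total == pytest.approx(1.0)
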