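"""Co-occurrence tabulation, the sister-pair statistic, permutation null."""
import itertools

import numpy as np
import pytest

from radsig.core import LineageTable, RadsigError
from radsig.library import (
    LibraryTest,
    build_cooccurrence,
    n_conspecific_pairs,
    permutation_test,
    sister_pair_statistic,
)
from radsig.simulate import SimConfig, simulate_library
from radsig.tree import parse_newick


def table_from(pairs):
    return LineageTable([(lid, sp, cl) for lid, sp, cl in pairs])


class TestCooccurrence:
    def test_multi_clade_species(self):
        # a species spanning three clades, as co-occurring lineages can
        table = table_from(
            [
                ("tc_A", "T.castaneum", "B"),
                ("tc_B", "T.castaneum", "A"),
                ("tc_C", "T.castaneum", "D"),
                ("nv_A", "N.vitripennis", "D"),
            ]
        )
        cm = build_cooccurrence(table)
        assert cm.frame.loc["T.castaneum"].sum() == 3
        assert set(cm.frame.columns) >= {"A", "B", "D"}
        assert cm.multiple_species == ["T.castaneum"]

    def test_single_lineage_not_flagged(self):
        cm = build_cooccurrence(table_from([("x_A", "x", "A")]))
        assert cm.multiple_species == []

    def test_empty_table(self):
        cm = build_cooccurrence(LineageTable([]))
        assert cm.frame.empty and cm.multiple_species == []


class TestSisterStatistic:
    def test_both_pairs_sisters(self):
        tree = parse_newick(
            "((sp1_A:1,sp1_B:1):1,(sp2_A:1,sp2_B:1):1);", support_dialect="none"
        )
        table = table_from(
            [("sp1_A", "sp1", "A"), ("sp1_B", "sp1", "A"),
             ("sp2_A", "sp2", "A"), ("sp2_B", "sp2", "A")]
        )
        assert sister_pair_statistic(tree, table) == 2

    def test_interleaved_pairs(self):
        tree = parse_newick(
            "((sp1_A:1,sp2_A:1):1,(sp1_B:1,sp2_B:1):1);", support_dialect="none"
        )
        table = table_from(
            [("sp1_A", "sp1", "A"), ("sp1_B", "sp1", "A"),
             ("sp2_A", "sp2", "A"), ("sp2_B", "sp2", "A")]
        )
        assert sister_pair_statistic(tree, table) == 0

    def test_caterpillar_separation(self):
        tree = parse_newick(
            "(((sp1_A:1,sp2_A:1):1,sp1_B:1):1,sp3_A:1);", support_dialect="none"
        )
        table = table_from(
            [("sp1_A", "sp1", "A"), ("sp1_B", "sp1", "A"),
             ("sp2_A", "sp2", "A"), ("sp3_A", "sp3", "A")]
        )
        # sp1's pair MRCA contains sp2_A, so it does not count
        assert sister_pair_statistic(tree, table) == 0

    def test_conspecific_trio_counts_pairs(self):
        tree = parse_newick(
            "(((sp1_A:1,sp1_B:1):1,sp1_C:1):1,(sp2_A:1,sp2_B:1):1);",
            support_dialect="none",
        )
        table = table_from(
            [("sp1_A", "sp1", "A"), ("sp1_B", "sp1", "A"), ("sp1_C", "sp1", "A"),
             ("sp2_A", "sp2", "A"), ("sp2_B", "sp2", "A")]
        )
        # all three sp1 pairs live in all-sp1 clades, plus the sp2 cherry
        assert sister_pair_statistic(tree, table) == 4

    def test_missing_leaf_named(self):
        tree = parse_newick("((a:1,b:1):1,c:1);", support_dialect="none")
        with pytest.raises(RadsigError, match="ghost"):
            sister_pair_statistic(tree, table_from([("a", "s", "A"), ("ghost", "s", "A")]))


class TestPermutationTest:
    def test_exhaustive_matches_independent_enumeration(self):
        tree = parse_newick(
            "(((sp1_A:1,sp2_A:1):1,(sp1_B:1,sp2_B:1):1):1,(sp3_A:1,sp3_B:1):1);",
            support_dialect="none",
        )
        records = [
            ("sp1_A", "sp1", "A"), ("sp1_B", "sp1", "A"),
            ("sp2_A", "sp2", "A"), ("sp2_B", "sp2", "A"),
            ("sp3_A", "sp3", "A"), ("sp3_B", "sp3", "A"),
        ]
        table = LineageTable(records)
        res = LibraryTest(tree, table).fit(exhaustive=True)
        # independent oracle: enumerate every permutation of the species
        # multiset and recount with a from-scratch MRCA routine
        lids = [r[0] for r in records]
        species = [r[1] for r in records]
        leaf_sets = []
        # clades of the fixed 6-leaf tree, written out by hand
        for group in (
            {"sp1_A", "sp2_A"}, {"sp1_B", "sp2_B"}, {"sp3_A", "sp3_B"},
            {"sp1_A", "sp2_A", "sp1_B", "sp2_B"},
            {"sp1_A", "sp2_A", "sp1_B", "sp2_B", "sp3_A", "sp3_B"},
        ):
            leaf_sets.append(group)

        def count_s(assign):
            by_sp = {}
            for lid, sp in assign.items():
                by_sp.setdefault(sp, []).append(lid)
            s = 0
            for sp, ls in by_sp.items():
                for x, y in itertools.combinations(sorted(ls), 2):
                    mrca = min(
                        (g for g in leaf_sets if x in g and y in g), key=len
                    )
                    if all(assign[m] == sp for m in mrca):
                        s += 1
            return s

        null = [
            count_s(dict(zip(lids, perm)))
            for perm in sorted(set(itertools.permutations(species)))
        ]
        s_obs = count_s(dict(zip(lids, species)))
        p_oracle = (1 + sum(1 for v in null if v <= s_obs)) / (len(null) + 1)
        assert res.statistic == s_obs == 1  # sp3's cherry pair
        assert sorted(res.null_distribution) == sorted(null)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_seed_reproducible_and_add_one(self):
        tree, table = simulate_library(4, 2, SimConfig(seed=3))
        r1 = permutation_test(tree, table, n_perm=100, seed=7)
        r2 = permutation_test(tree, table, n_perm=100, seed=7)
        assert r1.p_value == r2.p_value > 0
        assert np.array_equal(r1.null_distribution, r2.null_distribution)

    def test_duplication_mode_maximal_clustering(self):
        tree, table = simulate_library(6, 2, SimConfig(seed=5), mode="duplication")
        res = LibraryTest(tree, table).fit(n_perm=200, seed=0)
        assert res.statistic == res.n_conspecific_pairs == 6
        assert res.p_value > 0.95

    def test_library_mode_never_clusters(self):
        for seed in range(10):
            tree, table = simulate_library(5, 2, SimConfig(seed=seed))
            assert sister_pair_statistic(tree, table) == 0

    def test_stratified_shuffle_keeps_margins(self):
        tree, table = simulate_library(4, 2, SimConfig(seed=1))
        res = permutation_test(tree, table, n_perm=100, seed=2, stratify_by_clade=True)
        assert res.stratified
        assert 0 < res.p_value <= 1

    def test_min_permutations_enforced(self):
        tree, table = simulate_library(4, 2, SimConfig(seed=1))
        with pytest.raises(RadsigError, match="100"):
            permutation_test(tree, table, n_perm=50, seed=0)

    def test_no_conspecific_pairs_error(self):
        tree = parse_newick("((a:1,b:1):1,c:1);", support_dialect="none")
        table = table_from([("a", "s1", "A"), ("b", "s2", "A"), ("c", "s3", "A")])
        with pytest.raises(RadsigError, match="two or more"):
            LibraryTest(tree, table).fit(n_perm=100, seed=0)

    def test_calibration_under_exchangeable_null(self):
        # lineages assigned to species at random: p should be roughly uniform
        rng = np.random.default_rng(10)
        pvals = []
        from radsig.distance import DistanceMatrix, neighbor_joining

        for rep in range(40):
            n = 8
            ids = [f"l{i}" for i in range(n)]
            M = rng.uniform(0.1, 1.0, size=(n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            tree = neighbor_joining(DistanceMatrix(ids, D))
            species = [f"sp{i // 2 + 1}" for i in range(n)]
            perm = rng.permutation(n)
            table = LineageTable(
                [(ids[i], species[perm[i]], "A") for i in range(n)]
            )
            res = LibraryTest(tree, table).fit(n_perm=200, seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        # conservative sanity band on the mean of ~uniform p-values
        assert 0.3 < float(np.mean(pvals)) < 0.8
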