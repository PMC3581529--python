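"""Quartet sampling, ML weights, simplex classification, run comparison."""
import numpy as np
import pytest

from radsig.core import ProteinAlignment, RadsigError
from radsig.quartets import (
    Quartet,
    QuartetMapping,
    QuartetWeights,
    RegionCounts,
    classify_region,
    compare_runs_chi2,
    quartet_ml,
    sample_quartets_clustered,
    sample_quartets_random,
    summarize_run,
)
from radsig.simulate import SimConfig, evolve_alignment
from radsig.substitution import poisson_model
from radsig.tree import parse_newick


class TestSampling:
    def test_four_taxa_forced(self):
        qs = sample_quartets_random(["a", "b", "c", "d"], 3, seed=0)
        assert len(qs) == 3
        assert all(sorted(q.taxa) == ["a", "b", "c", "d"] for q in qs)

    def test_too_few_taxa(self):
        with pytest.raises(RadsigError):
            sample_quartets_random(["a", "b", "c"], 1, seed=0)

    def test_seed_reproducible(self):
        taxa = [f"t{i}" for i in range(87)]
        a = sample_quartets_random(taxa, 50, seed=11)
        b = sample_quartets_random(taxa, 50, seed=11)
        assert a == b
        assert len(sample_quartets_random(taxa, 5000, seed=1)) == 5000

    def test_clustered_one_per_cluster(self):
        cmap = {f"t{i}": i % 4 + 1 for i in range(8)}
        qs = sample_quartets_clustered(cmap, 100, seed=3)
        for q in qs:
            assert tuple(cmap[t] for t in q.taxa) == (1, 2, 3, 4)

    def test_clustered_empty_cluster_error(self):
        cmap = {"a": 1, "b": 2, "c": 3}
        with pytest.raises(RadsigError, match="4"):
            sample_quartets_clustered(cmap, 10, seed=0)

    def test_clustered_inclusion_balance(self):
        # clusters of size 2: each member fills its slot about half the time
        cmap = {f"t{i}": i // 2 + 1 for i in range(8)}
        qs = sample_quartets_clustered(cmap, 1000, seed=5)
        for taxon in cmap:
            freq = sum(taxon in q.taxa for q in qs) / 1000
            sigma = np.sqrt(0.25 / 1000)
            assert abs(freq - 0.5) <= 3 * sigma


class TestQuartetML:
    def test_identical_sequences_uniform_weights(self):
        aln = ProteinAlignment(list("abcd"), ["ARNDARND"] * 4)
        w = quartet_ml(aln, Quartet(("a", "b", "c", "d")), poisson_model())
        assert w.weights == pytest.approx((1 / 3, 1 / 3, 1 / 3), abs=1e-6)

    def test_softmax_limit(self):
        w = QuartetWeights(Quartet(("a", "b", "c", "d")), (-10.0, -10.0, -np.inf))
        assert w.weights == pytest.approx((0.5, 0.5, 0.0), abs=1e-12)

    def test_all_gap_error(self):
        aln = ProteinAlignment(list("abcd"), ["--", "--", "--", "--"])
        with pytest.raises(RadsigError, match="usable"):
            quartet_ml(aln, Quartet(("a", "b", "c", "d")), poisson_model())

    def test_resolved_topology_dominates(self):
        tree = parse_newick(
            "((a:0.2,b:0.2):0.6,(c:0.2,d:0.2):1e-9);", support_dialect="none"
        )
        cfg = SimConfig(seed=42, n_tips=4, n_sites=500, model="poisson", k=1)
        aln = evolve_alignment(tree, cfg)
        w = quartet_ml(aln, Quartet(("a", "b", "c", "d")), poisson_model())
        assert w.weights[0] > 0.95

    def test_weights_invariants(self):
        tree = parse_newick(
            "((a:0.3,b:0.3):0.2,(c:0.3,d:0.3):1e-9);", support_dialect="none"
        )
        cfg = SimConfig(seed=7, n_tips=4, n_sites=100, model="poisson", k=1)
        aln = evolve_alignment(tree, cfg)
        w = quartet_ml(aln, Quartet(("a", "b", "c", "d")), poisson_model())
        assert all(p >= 0 for p in w.weights)
        assert sum(w.weights) == pytest.approx(1.0, abs=1e-12)


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "weights,expected",
        [
            ((1.0, 0.0, 0.0), "corner1"),
            ((0.0, 1.0, 0.0), "corner2"),
            ((1 / 3, 1 / 3, 1 / 3), "center"),
            ((0.5, 0.45, 0.05), "edge12"),
            ((0.45, 0.1, 0.45), "center"),
            ((0.6, 0.2, 0.2), "corner1"),
            ((0.34, 0.56, 0.10), "edge12"),
        ],
    )
    def test_examples(self, weights, expected):
        assert classify_region(weights) == expected

    def test_partition_of_simplex(self):
        # every simplex point gets exactly one of the seven labels
        rng = np.random.default_rng(0)
        pts = rng.dirichlet(np.ones(3), size=100_000)
        labels = [classify_region(tuple(p)) for p in pts]
        counts = summarize_run(labels)
        assert counts.n_quartets == 100_000
        assert sum(counts.counts.values()) == 100_000


class TestSummarize:
    def test_all_corner(self):
        rc = summarize_run(["corner1"] * 10)
        assert rc.percentages()["resolved"] == 100.0

    def test_reported_percentages_format(self):
        # 4145/265/590 of 5000 gives the 82.9/5.3/11.8 split
        rc = RegionCounts(
            {"corner1": 4145, "edge12": 265, "center": 590}, 5000
        )
        p = rc.percentages()
        assert (round(p["resolved"], 1), round(p["conflicting"], 1), round(p["unresolved"], 1)) == (
            82.9, 5.3, 11.8,
        )

    def test_empty_error(self):
        with pytest.raises(RadsigError):
            summarize_run([])


class TestChi2:
    @staticmethod
    def _rc(resolved, conflicting, unresolved):
        return RegionCounts(
            {"corner1": resolved, "edge12": conflicting, "center": unresolved},
            resolved + conflicting + unresolved,
        )

    def test_identical_runs_zero(self):
        a = self._rc(4145, 265, 590)
        res = compare_runs_chi2(a, a)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 2

    def test_hand_computed_statistic(self):
        ref = self._rc(4145, 265, 590)
        test = self._rc(3415, 495, 1085)
        res = compare_runs_chi2(ref, test)
        # spreadsheet-style oracle: sum (O-E)^2 / E over the three cells
        props = np.array([4145, 265, 590]) / 5000
        obs = np.array([3415, 495, 1085])
        expected = obs.sum() * props
        oracle = float(((obs - expected) ** 2 / expected).sum())
        assert res.statistic == pytest.approx(oracle, rel=1e-12)
        assert res.p_value < 0.001

    def test_doubling_counts_doubles_statistic(self):
        ref = self._rc(400, 50, 50)
        test = self._rc(300, 100, 100)
        ref2 = self._rc(800, 100, 100)
        test2 = self._rc(600, 200, 200)
        r1 = compare_runs_chi2(ref, test)
        r2 = compare_runs_chi2(ref2, test2)
        assert r2.statistic == pytest.approx(2 * r1.statistic, rel=1e-12)

    def test_zero_reference_category_flagged(self):
        ref = self._rc(100, 0, 0)
        test = self._rc(90, 10, 0)
        res = compare_runs_chi2(ref, test)
        assert res.infinite and np.isinf(res.statistic)


class TestMappingModel:
    def test_clustered_beats_random_on_true_clades(self):
        # four 2-taxon clades; the deep split pairs clusters (1,2) vs (3,4)
        nwk = (
            "(((a1:0.1,a2:0.1):0.3,(b1:0.1,b2:0.1):0.3):0.5,"
            "((c1:0.1,c2:0.1):0.3,(d1:0.1,d2:0.1):0.3):1e-9);"
        )
        tree = parse_newick(nwk, support_dialect="none")
        cfg = SimConfig(seed=9, n_tips=8, n_sites=300, model="poisson", k=1)
        aln = evolve_alignment(tree, cfg)
        clusters = {f"{c}{i}": k + 1 for k, c in enumerate("abcd") for i in (1, 2)}
        mapping = QuartetMapping(aln, poisson_model(), clusters=clusters)
        random_run = mapping.fit(n=40, seed=1, sampling="random")
        clustered_run = mapping.fit(n=40, seed=2, sampling="clustered")

        def true_corner_fraction(run):
            hits = 0
            for w, label in zip(run.weights, run.labels):
                groups = [clusters[t] for t in w.quartet.taxa]
                side = [g in (1, 2) for g in groups]
                if sum(side) != 2:
                    continue  # no topology matches the deep split
                pairs = {
                    "corner1": ((0, 1), (2, 3)),
                    "corner2": ((0, 2), (1, 3)),
                    "corner3": ((0, 3), (1, 2)),
                }
                if label in pairs:
                    (i, j), (k_, l) = pairs[label]
                    if side[i] == side[j] and side[k_] == side[l]:
                        hits += 1
            return hits / len(run.weights)

        assert true_corner_fraction(clustered_run) > true_corner_fraction(random_run)

    def test_summary_mentions_counts(self, small_alignment):
        mapping = QuartetMapping(small_alignment, poisson_model())
        res = mapping.fit(n=3, seed=0)
        assert "3 quartets" in res.summary()
        frame = res.to_frame()
        assert list(frame.columns)[:4] == ["taxon_a", "taxon_b", "taxon_c", "taxon_d"]
        assert len(frame) == 3
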