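"""Zinc-finger scanning, clade typing, target sites, junctions, families."""
import pytest

from radsig.annotate import (
    ZincFingerGrammar,
    call_clade,
    cluster_families,
    detect_insertion_junctions,
    find_target_sites,
    pairwise_identity,
    scan_zinc_fingers,
)
from radsig.core import NucSequence, RadsigError
from radsig.simulate import ZF_PATTERNS, make_r2_protein, make_rdna_locus

GRAMMAR = ZincFingerGrammar(c_c=(1, 5), c_h=(8, 17), h_h=(2, 6))


class TestZincFingerScan:
    def test_constructed_cchh(self):
        s = "C" + "AA" + "C" + "A" * 12 + "H" + "AAA" + "H"
        motifs = scan_zinc_fingers(s, window=len(s), grammar=GRAMMAR)
        assert len(motifs) == 1
        assert motifs[0].type == "CCHH"
        assert motifs[0].span == (0, len(s))

    def test_constructed_cchc(self):
        s = "C" + "AA" + "C" + "A" * 12 + "H" + "AAA" + "C"
        motifs = scan_zinc_fingers(s, window=len(s), grammar=GRAMMAR)
        assert [m.type for m in motifs] == ["CCHC"]

    def test_no_motif(self):
        assert scan_zinc_fingers("AAAA" * 20) == []

    def test_empty_protein_error(self):
        with pytest.raises(RadsigError):
            scan_zinc_fingers("")

    def test_residue_offsets_point_at_coordinators(self):
        s = "GGG" + "C" + "AA" + "C" + "A" * 12 + "H" + "AAA" + "H" + "GGG"
        (m,) = scan_zinc_fingers(s, grammar=GRAMMAR)
        assert [s[o] for o in m.residue_offsets] == ["C", "C", "H", "H"]

    def test_window_limits_scan(self):
        s = "A" * 30 + "C" + "AA" + "C" + "A" * 12 + "H" + "AAA" + "H"
        assert scan_zinc_fingers(s, window=20, grammar=GRAMMAR) == []

    @pytest.mark.parametrize("pattern", sorted(ZF_PATTERNS))
    def test_recovers_planted_patterns(self, pattern):
        for seed in range(50):
            protein, truth = make_r2_protein(pattern, seed=seed)
            motifs = scan_zinc_fingers(protein)
            assert [m.type for m in motifs] == [t.type for t in truth]
            assert [m.span for m in motifs] == [t.span for t in truth]


class TestCladeCall:
    @pytest.mark.parametrize(
        "types,clade,classes",
        [
            (["CCHH", "CCHC", "CCHH"], "A", ("I", "II", "III")),
            (["CCHC", "CCHH"], "B", ("II", "III")),
            (["CCHH", "CCHH"], "C", ("I", "III")),
            (["CCHH"], "D", ("III",)),
            (["CCHC"], "unknown", ()),
            ([], "unknown", ()),
            (["CCHH", "CCHC", "CCHH", "CCHH"], "unknown", ()),
        ],
    )
    def test_mapping(self, types, clade, classes):
        ann = call_clade(types)
        assert ann.clade_call == clade
        assert ann.position_classes == classes

    @pytest.mark.parametrize("pattern", sorted(ZF_PATTERNS))
    def test_planted_pattern_round_trip(self, pattern):
        protein, _ = make_r2_protein(pattern, seed=99)
        ann = call_clade(scan_zinc_fingers(protein))
        assert ann.clade_call == pattern


class TestTargetSites:
    def test_exact_hit_with_flanks(self):
        seq = NucSequence("s", "A" * 20 + "TTAAGGTAGCCA" + "A" * 20)
        hits = find_target_sites(seq, max_mismatch=0)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        h = fwd[0]
        assert h.cleavage == 26
        assert len(h.upstream_flank) == len(h.downstream_flank) == 20
        assert not h.truncated_flank
        assert h.upstream_flank.endswith("TTAAGG")
        assert h.downstream_flank.startswith("TAGCCA")

    def test_mismatch_tolerance(self):
        seq = NucSequence("s", "A" * 20 + "TTATGGTAGCCA" + "A" * 20)
        assert not [h for h in find_target_sites(seq, max_mismatch=0) if h.strand == "+"]
        hits = [h for h in find_target_sites(seq, max_mismatch=1) if h.strand == "+"]
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_two_hits_in_order(self):
        seq = NucSequence("s", "TTAAGGTAGCCA" + "C" * 30 + "TTAAGGTAGCCA")
        fwd = [h for h in find_target_sites(seq) if h.strand == "+"]
        assert [h.cleavage for h in fwd] == [6, 48]
        assert fwd[0].truncated_flank  # only 6 nt upstream available

    def test_reverse_strand_hit(self):
        from radsig.annotate import revcomp

        core = "TTAAGGTAGCCA"
        seq = NucSequence("s", "G" * 15 + revcomp(core) + "G" * 15)
        hits = find_target_sites(seq)
        assert len(hits) == 1 and hits[0].strand == "-"
        assert hits[0].start == 15

    def test_short_sequence_empty(self):
        assert find_target_sites(NucSequence("s", "TTAAGG")) == []

    def test_naive_scan_equivalence(self):
        import numpy as np

        rng = np.random.default_rng(0)
        motif = "TTAAGGTAGCCA"
        for _ in range(20):
            s = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
            seq = NucSequence("x", s)
            naive = {i for i in range(len(s) - 11) if s[i : i + 12] == motif}
            found = {h.start for h in find_target_sites(seq, both_strands=False)}
            assert found == naive


class TestJunctions:
    def test_single_insertion(self):
        locus, truth = make_rdna_locus(1, {0}, element_length=1000, seed=1)
        hits = detect_insertion_junctions(locus)
        assert len(hits) == 1
        assert hits[0].interval == truth[0].interval
        assert hits[0].element_length == 1000

    def test_uninserted_site(self):
        locus, truth = make_rdna_locus(1, set(), element_length=500, seed=2)
        hits = detect_insertion_junctions(locus)
        assert len(hits) == 1 and hits[0].uninserted
        assert hits[0].cleavage == truth[0].cleavage

    def test_two_insertions(self):
        locus, truth = make_rdna_locus(3, {0, 2}, element_length=400, seed=3)
        hits = detect_insertion_junctions(locus)
        assert [h.interval for h in hits] == [t.interval for t in truth]
        inserted = [h for h in hits if not h.uninserted]
        assert len(inserted) == 2

    def test_mismatched_context(self):
        locus, _ = make_rdna_locus(1, set(), element_length=500, seed=4)
        s = locus.seq
        j = detect_insertion_junctions(locus)[0].cleavage
        mutated = s[: j - 6] + "C" + s[j - 5 :]  # point mutation in the TT context
        assert detect_insertion_junctions(NucSequence("m", mutated)) == []
        hits = detect_insertion_junctions(NucSequence("m", mutated), max_mismatch=1)
        assert len(hits) == 1 and hits[0].mismatches == 1


class TestFamilies:
    def test_identical_pair_one_family(self):
        seqs = [NucSequence("b", "ACGT" * 30), NucSequence("a", "ACGT" * 30)]
        fams = cluster_families(seqs)
        assert fams == {"a": ["a", "b"]}

    def test_distant_pair_two_families(self):
        import numpy as np

        rng = np.random.default_rng(1)
        s1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        s2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        fams = cluster_families([NucSequence("a", s1), NucSequence("b", s2)])
        assert sorted(fams) == ["a", "b"]

    def test_single_linkage_chain(self):
        import numpy as np

        rng = np.random.default_rng(3)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))

        def mutate(s, positions):
            out = list(s)
            for p in positions:
                out[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[p]]
            return "".join(out)

        a = base
        b = mutate(base, range(0, 8))      # ~93% identity to a
        c = mutate(base, range(0, 16))     # ~87% to a, ~93% to b
        assert pairwise_identity(a, b) > 0.90
        assert pairwise_identity(b, c) > 0.90
        assert pairwise_identity(a, c) < 0.90
        fams = cluster_families(
            [NucSequence("a", a), NucSequence("b", b), NucSequence("c", c)]
        )
        assert fams == {"a": ["a", "b", "c"]}
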