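import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_digest, count_substring, rc
from conftest import random_genome
from fourcscape.genome_builder import (
    Genome,
    InsertionEvent,
    build_modified_genome,
    digest,
    flag_unique_ends,
    identity_map,
    match_common_ends,
)


def seq_of(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestBuildModifiedGenome:
    def test_no_insertions_is_identity(self):
        g = Genome({"c": "A" * 20}, build_label="base")
        mod, cmap = build_modified_genome(g, [])
        assert mod.sequences == g.sequences
        blocks = cmap.blocks["c"]
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.base_start, b.base_end, b.mod_start, b.mod_end, b.kind) == (0, 20, 0, 20, "collinear")

    def test_single_insert_blocks(self):
        g = Genome({"c": "A" * 20})
        mod, cmap = build_modified_genome(g, [InsertionEvent("c", 10, "NNNNN", "x")])
        assert len(mod.sequences["c"]) == 25
        got = [
            (b.base_start, b.base_end, b.mod_start, b.mod_end, b.kind)
            for b in cmap.blocks["c"]
        ]
        assert got == [
            (0, 10, 0, 10, "collinear"),
            (10, 10, 10, 15, "insert"),
            (10, 20, 15, 25, "collinear"),
        ]

    def test_two_insertions_accumulate_offsets(self):
        g = Genome({"c": "A" * 20})
        mod, cmap = build_modified_genome(
            g,
            [InsertionEvent("c", 4, "CCCCC"), InsertionEvent("c", 10, "GGGGG")],
        )
        assert cmap.project("c", 12, "base_to_modified") == 22

    def test_insert_sequence_lands_at_position(self):
        g = Genome({"c": "ACGTACGTAC"})
        mod, _ = build_modified_genome(g, [InsertionEvent("c", 4, "TTTT")])
        assert mod.sequences["c"] == "ACGT" + "TTTT" + "ACGTAC"

    def test_position_out_of_range_rejected(self):
        g = Genome({"c": "A" * 20})
        with pytest.raises(ValueError, match="out of range"):
            build_modified_genome(g, [InsertionEvent("c", 21, "TT")])

    def test_duplicate_position_rejected(self):
        g = Genome({"c": "A" * 20})
        with pytest.raises(ValueError, match="duplicate"):
            build_modified_genome(
                g, [InsertionEvent("c", 5, "TT"), InsertionEvent("c", 5, "GG")]
            )


class TestProject:
    def test_identity_map(self):
        g = Genome({"c": "A" * 20})
        cmap = identity_map(g)
        assert cmap.project("c", 7, "base_to_modified") == 7
        assert cmap.project("c", 7, "modified_to_base") == 7

    def test_insert_interior_has_no_base_counterpart(self):
        g = Genome({"c": "A" * 20})
        _, cmap = build_modified_genome(g, [InsertionEvent("c", 10, "NNNNN")])
        assert cmap.project("c", 12, "modified_to_base") is None

    def test_round_trip_across_insert(self):
        g = Genome({"c": "A" * 20})
        _, cmap = build_modified_genome(g, [InsertionEvent("c", 10, "NNNNN")])
        assert cmap.project("c", 10, "base_to_modified") == 15
        assert cmap.project("c", 15, "modified_to_base") == 10

    def test_outside_blocks_raises(self):
        g = Genome({"c": "A" * 20})
        cmap = identity_map(g)
        with pytest.raises(ValueError, match="outside"):
            cmap.project("c", 50, "base_to_modified")

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_is_identity_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(50, 300))
        g = Genome({"c": seq_of(length, rng)})
        n_ins = int(rng.integers(1, 4))
        positions = sorted(rng.choice(length + 1, size=n_ins, replace=False))
        events = [
            InsertionEvent("c", int(p), seq_of(int(rng.integers(1, 20)), rng))
            for p in positions
        ]
        _, cmap = build_modified_genome(g, events)
        for pos in range(length + 1):
            mod = cmap.project("c", pos, "base_to_modified")
            assert cmap.project("c", mod, "modified_to_base") == pos


class TestDigest:
    def test_no_motifs_gives_single_blind_fragment(self):
        fm = digest(Genome({"c": "AAAAAA"}), "GTAC", 1, "CATG", 4)
        assert len(fm) == 2
        assert all(e.blind for e in fm.ends)
        assert all((e.fragment_start, e.fragment_end) == (0, 6) for e in fm.ends)

    def test_hand_worked_two_cutter_example(self):
        fm = digest(Genome({"c": "AAGTACAACATGAAGTACAA"}), "GTAC", 1, "CATG", 4)
        frags = sorted({(e.fragment_start, e.fragment_end) for e in fm.ends})
        assert frags == [(0, 3), (3, 15), (15, 20)]
        non_blind = {(e.end_start, e.end_end) for e in fm.non_blind()}
        assert non_blind == {(3, 12), (12, 15)}
        blind_frags = {(e.fragment_start, e.fragment_end) for e in fm.ends if e.blind}
        assert blind_frags == {(0, 3), (15, 20)}

    def test_adjacent_primary_cuts(self):
        fm = digest(Genome({"c": "GTACGTAC"}), "GTAC", 1, "CATG", 4)
        frags = sorted({(e.fragment_start, e.fragment_end) for e in fm.ends})
        assert frags == [(0, 1), (1, 5), (5, 8)]

    def test_non_palindromic_motif_cut_on_reverse_strand(self):
        # GGTCTC on the reverse strand appears as GAGACC on the forward one
        seq = "AAAAGAGACCAAAAA"
        fm = digest(Genome({"c": seq}), "GGTCTC", 1, "CATG", 4)
        # reverse-strand cut mirrors the offset: start + len - offset = 4 + 6 - 1
        frags = sorted({(e.fragment_start, e.fragment_end) for e in fm.ends})
        assert frags == [(0, 9), (9, 15)]

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            Genome({})

    def test_bad_offset_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="offset"):
            digest(toy_genome, "GTAC", 5, "CATG", 4)

    @given(st.integers(0, 100_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_partition(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(200, 2000))
        seq = seq_of(length, rng)
        fm = digest(Genome({"c": seq}), "GTAC", 1, "CATG", 4)
        expected = brute_digest(seq, "GTAC", 1, "CATG", 4)
        got = sorted(
            (e.fragment_start, e.fragment_end, e.side, e.end_start, e.end_end, e.blind)
            for e in fm.ends
        )
        want = sorted(
            (d["frag"][0], d["frag"][1], d["side"], d["region"][0], d["region"][1], d["blind"])
            for d in expected
        )
        assert got == want

    def test_fragments_tile_chromosome(self, toy_genome, toy_fragmap):
        frags = sorted({(e.fragment_start, e.fragment_end) for e in toy_fragmap.ends})
        assert frags[0][0] == 0
        assert frags[-1][1] == toy_genome.length("chrS")
        for (s1, e1), (s2, e2) in zip(frags[:-1], frags[1:]):
            assert e1 == s2


class TestFlagUniqueEnds:
    def test_duplicated_segment_flags_non_unique(self):
        rng = np.random.default_rng(3)
        # fragment with a non-blind left end [3..] duplicated verbatim elsewhere
        core = "AAGTACAACATGAA"  # end region AGTACAACA... region [3,12)
        filler = seq_of(400, rng).replace("GTAC", "AAAA").replace("CATG", "AAAA")
        dup = core[3:12]
        seq = core + filler + dup + filler[:50]
        g = Genome({"c": seq})
        fm = flag_unique_ends(digest(g), g)
        end = next(e for e in fm.ends if (e.end_start, e.end_end) == (3, 12))
        assert end.unique is False
        # independent exhaustive check
        region = seq[3:12]
        assert count_substring(seq, region) + (
            count_substring(seq, rc(region)) if rc(region) != region else 0
        ) > 1

    def test_random_sequence_all_unique(self):
        rng = np.random.default_rng(5)
        g = random_genome(rng, 5000)
        fm = flag_unique_ends(digest(g), g)
        for e in fm.non_blind():
            region = g.sequences[e.chrom][e.end_start:e.end_end]
            hits = count_substring(g.sequences[e.chrom], region)
            if rc(region) != region:
                hits += count_substring(g.sequences[e.chrom], rc(region))
            assert e.unique == (hits <= 1)

    def test_zero_length_end_region_is_blind(self):
        # secondary cut exactly at the primary cut: CATG^ cut at 4 == G^TAC cut at 4
        seq = "AAACATGTACAACATGAA"
        g = Genome({"c": seq})
        fm = flag_unique_ends(digest(g), g)
        zero = [e for e in fm.ends if e.end_start == e.end_end]
        assert zero
        assert all(e.blind for e in zero)


class TestMatchCommonEnds:
    def test_identical_genomes_all_common(self, toy_genome, toy_fragmap):
        cmap = identity_map(toy_genome)
        table = match_common_ends(toy_fragmap, cmap, toy_fragmap, cmap)
        assert (table["status"] == "common").all()
        assert len(table) == len(toy_fragmap)
        assert (table["end_id_a"] == table["end_id_b"]).all()

    def test_insert_internal_ends_are_build_specific(self, toy_genome, toy_fragmap):
        # insert carrying its own cut sites at 25 kb in build B only
        insert = "GTAC" + "A" * 200 + "CATG" + "C" * 200 + "GTAC"
        mod, cmap_b = build_modified_genome(
            toy_genome, [InsertionEvent("chrS", 25_000, insert, "enh")]
        )
        fm_b = digest(mod)
        cmap_a = identity_map(toy_genome)
        table = match_common_ends(toy_fragmap, cmap_a, fm_b, cmap_b)
        b_only = table[table["status"] == "B_only"]
        assert len(b_only) > 0
        # every end of A finds a partner or is junction-adjacent; far-away ends all match
        far = table[(table["status"] == "common") & (table["base_cut"] < 20_000)]
        assert len(far) > 0

    def test_junction_spanning_end_flagged(self, toy_genome, toy_fragmap):
        # cut-free insert placed inside an end region: the host end now spans
        # the insertion junction and must not pair across builds
        target = next(
            e for e in toy_fragmap.non_blind()
            if e.end_end - e.end_start > 10 and e.end_start > 20_000
        )
        pos = (e_mid := (target.end_start + target.end_end) // 2)
        mod, cmap_b = build_modified_genome(
            toy_genome, [InsertionEvent("chrS", pos, "A" * 50, "neutral")]
        )
        fm_b = digest(mod)
        table = match_common_ends(toy_fragmap, identity_map(toy_genome), fm_b, cmap_b)
        assert table["junction_spanning"].any()
        # the disrupted end must not appear as common on either side
        common = table[table["status"] == "common"]
        assert target.end_id not in set(common["end_id_a"])

    def test_symmetry(self, toy_genome, toy_fragmap):
        mod, cmap_b = build_modified_genome(
            toy_genome, [InsertionEvent("chrS", 25_000, "T" * 100)]
        )
        fm_b = digest(mod)
        cmap_a = identity_map(toy_genome)
        ab = match_common_ends(toy_fragmap, cmap_a, fm_b, cmap_b)
        ba = match_common_ends(fm_b, cmap_b, toy_fragmap, cmap_a)
        pairs_ab = set(zip(ab.loc[ab.status == "common", "end_id_a"], ab.loc[ab.status == "common", "end_id_b"]))
        pairs_ba = set(zip(ba.loc[ba.status == "common", "end_id_b"], ba.loc[ba.status == "common", "end_id_a"]))
        assert pairs_ab == pairs_ba

    def test_mismatched_base_builds_rejected(self, toy_genome, toy_fragmap):
        other = Genome({"chrS": toy_genome.sequences["chrS"]}, build_label="other-build")
        with pytest.raises(ValueError, match="different base builds"):
            match_common_ends(
                toy_fragmap, identity_map(toy_genome), digest(other), identity_map(other)
            )
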