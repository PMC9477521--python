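"""Toy aligner vs brute-force oracle, strand symmetry, SAM ingestion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tecount.align import (
    MATE1,
    MATE2,
    SINGLE,
    Aligner,
    AlignParams,
    align_fragment,
    brute_force_align,
    read_sam,
    revcomp,
)
from tecount.errors import DataError
from tecount.reference import Category

from conftest import make_ref, random_dna


def placement_keys(frag):
    """Canonical representation for set comparison of placements."""
    return {
        (p.ref_id, p.mates[0].start, p.mates[0].strand, p.score)
        for p in frag.placements
    }


class TestToyAligner:
    def test_exact_substring_single_placement(self, rng):
        te = random_dna(rng, 200)
        ref = make_ref(TE={"TE1": te})
        frag = align_fragment(te[10:60], ref)
        assert len(frag.placements) == 1
        p = frag.placements[0]
        assert (p.ref_id, p.mates[0].start, p.mates[0].strand, p.score) == (
            "TE1", 10, "+", 50,
        )

    def test_shared_segment_two_equal_placements(self, rng):
        te = random_dna(rng, 200)
        gene = random_dna(rng, 100) + te[50:150] + random_dna(rng, 100)
        ref = make_ref(TE={"TE1": te}, CODING={"G1": gene})
        frag = align_fragment(te[60:110], ref)
        assert placement_keys(frag) == {("TE1", 60, "+", 50), ("G1", 110, "+", 50)}

    def test_reverse_complement_maps_minus_strand(self, rng):
        te = random_dna(rng, 200)
        ref = make_ref(TE={"TE1": te})
        frag = align_fragment(revcomp(te[10:60]), ref)
        assert placement_keys(frag) == {("TE1", 10, "-", 50)}

    def test_invalid_read_characters_rejected(self, rng):
        ref = make_ref(TE={"TE1": random_dna(rng, 100)})
        with pytest.raises(DataError, match="invalid characters"):
            align_fragment("ACGTX" + "A" * 20, ref)

    def test_read_below_threshold_unmapped(self, rng):
        ref = make_ref(TE={"TE1": random_dna(rng, 500)})
        read = random_dna(np.random.default_rng(7), 50)  # unrelated sequence
        frag = align_fragment(read, ref)
        assert frag.placements == []

    def test_mismatches_lower_score(self, rng):
        te = random_dna(rng, 200)
        ref = make_ref(TE={"TE1": te})
        read = te[10:60]
        mutated = read[:20] + ("A" if read[20] != "A" else "C") + read[21:]
        frag = align_fragment(mutated, ref)
        assert frag.placements[0].score == 48  # 49 matches - 1 mismatch

    def test_all_n_read_has_no_placement(self, rng):
        ref = make_ref(TE={"TE1": random_dna(rng, 100)})
        frag = align_fragment("N" * 50, ref)
        assert frag.placements == []

    def test_results_sorted_by_score_then_ref(self, rng):
        te = random_dna(rng, 300)
        gene = te[100:150] + random_dna(rng, 200)
        ref = make_ref(TE={"TE1": te}, CODING={"G1": gene})
        read = te[100:150]
        frag = align_fragment(read, ref)
        scores = [p.score for p in frag.placements]
        assert scores == sorted(scores, reverse=True)


class TestPairedAlignment:
    def _pair_from(self, seq, start, insert, rl=50):
        return seq[start : start + rl], revcomp(seq[start + insert - rl : start + insert])

    def test_pair_combines_scores_on_same_reference(self, rng):
        te = random_dna(rng, 1000)
        ref = make_ref(TE={"TE1": te})
        r1, r2 = self._pair_from(te, 100, 300)
        frag = Aligner(ref).align_fragment("p1", r1, r2)
        assert frag.paired
        assert len(frag.placements) == 1
        p = frag.placements[0]
        assert p.score == 100
        assert {a.mate for a in p.mates} == {MATE1, MATE2}
        assert {a.strand for a in p.mates} == {"+", "-"}

    def test_one_mate_unplaceable_yields_unmapped(self, rng):
        te = random_dna(rng, 1000)
        ref = make_ref(TE={"TE1": te})
        r1 = te[100:150]
        r2 = random_dna(np.random.default_rng(3), 50)
        frag = Aligner(ref).align_fragment("p1", r1, r2)
        assert frag.placements == []

    def test_span_beyond_max_insert_rejected(self, rng):
        te = random_dna(rng, 5000)
        ref = make_ref(TE={"TE1": te})
        r1, r2 = self._pair_from(te, 0, 3000)
        frag = Aligner(ref, AlignParams(max_insert=1000)).align_fragment("p1", r1, r2)
        assert frag.placements == []
        frag = Aligner(ref, AlignParams(max_insert=4000)).align_fragment("p1", r1, r2)
        assert len(frag.placements) == 1

    def test_same_strand_mates_not_paired(self, rng):
        te = random_dna(rng, 1000)
        ref = make_ref(TE={"TE1": te})
        frag = Aligner(ref).align_fragment("p1", te[100:150], te[300:350])
        assert frag.placements == []


class TestOracleEquivalence:
    def _random_instance(self, seed):
        rng = np.random.default_rng(seed)
        n_refs = int(rng.integers(2, 5))
        records = {f"R{i}": random_dna(rng, int(rng.integers(100, 2000)))
                   for i in range(n_refs)}
        ref = make_ref(TE=records)
        src = records[f"R{int(rng.integers(0, n_refs))}"]
        length = int(rng.integers(30, 101))
        start = int(rng.integers(0, len(src) - length + 1))
        read = list(src[start : start + length])
        for i in range(length):  # up to 5% substitution errors
            if rng.random() < 0.05:
                read[i] = "ACGT"[int(rng.integers(0, 4))]
        read = "".join(read)
        if rng.random() < 0.5:
            read = revcomp(read)
        return ref, read

    @pytest.mark.parametrize("seed", range(40))
    def test_seeded_matches_brute_force(self, seed):
        ref, read = self._random_instance(seed)
        seeded = align_fragment(read, ref)
        brute = brute_force_align(read, ref)
        assert placement_keys(seeded) == placement_keys(brute)

    def test_brute_force_rejects_huge_reference(self, rng):
        ref = make_ref(TE={"TE1": "ACGT" * 300_000})
        with pytest.raises(DataError, match="1e6"):
            brute_force_align("ACGT" * 10, ref)


class TestProperties:
    def test_strand_symmetry(self, rng):
        te = random_dna(rng, 500)
        gene = te[100:180] + random_dna(rng, 300)
        ref = make_ref(TE={"TE1": te}, CODING={"G1": gene})
        read = te[110:160]
        fwd = placement_keys(align_fragment(read, ref))
        rev = placement_keys(align_fragment(revcomp(read), ref))
        flip = {"+": "-", "-": "+"}
        assert {(r, s, flip[st_], sc) for r, s, st_, sc in fwd} == rev

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), pos=st.integers(0, 49))
    def test_score_monotone_in_mismatches(self, seed, pos):
        rng = np.random.default_rng(seed)
        te = random_dna(rng, 300)
        ref = make_ref(TE={"TE1": te})
        read = te[25:75]
        base_scores = {
            (p.ref_id, p.mates[0].start): p.score
            for p in align_fragment(read, ref).placements
        }
        flipped = "ACGT"["ACGT".index(read[pos]) - 1]
        mutated = read[:pos] + flipped + read[pos + 1 :]
        for p in align_fragment(mutated, ref).placements:
            key = (p.ref_id, p.mates[0].start)
            if key in base_scores:
                assert p.score <= base_scores[key]


SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:TE1\tLN:200\n@SQ\tSN:G1\tLN:300\n"


def _write_sam(path, body):
    path.write_text(SAM_HEADER + body)
    return path


class TestReadSam:
    def test_groups_secondary_alignments(self, tmp_path, rng):
        ref = make_ref(TE={"TE1": random_dna(rng, 200)}, CODING={"G1": random_dna(rng, 300)})
        body = (
            "R1\t0\tTE1\t11\t255\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\tAS:i:50\n"
            "R1\t256\tG1\t21\t0\t50M\t*\t0\t0\t*\t*\tAS:i:50\n"
            "R1\t256\tG1\t91\t0\t50M\t*\t0\t0\t*\t*\tAS:i:50\n"
        )
        frags = list(read_sam(_write_sam(tmp_path / "a.sam", body), ref))
        assert len(frags) == 1
        assert len(frags[0].placements) == 3
        assert not frags[0].paired

    def test_unmapped_record_yields_empty_placements(self, tmp_path, rng):
        ref = make_ref(TE={"TE1": random_dna(rng, 200)})
        body = "R2\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
        frags = list(read_sam(_write_sam(tmp_path / "b.sam", body), ref))
        assert len(frags) == 1
        assert frags[0].placements == []

    def test_paired_mates_sum_scores(self, tmp_path, rng):
        ref = make_ref(CODING={"G1": random_dna(rng, 300)}, TE={"TE1": random_dna(rng, 200)})
        # combined score checked by hand: 47 + 45 = 92
        body = (
            "P1\t99\tG1\t11\t255\t50M\t=\t211\t250\t" + "A" * 50 + "\t" + "I" * 50 + "\tAS:i:47\n"
            "P1\t147\tG1\t211\t255\t50M\t=\t11\t-250\t" + "A" * 50 + "\t" + "I" * 50 + "\tAS:i:45\n"
        )
        frags = list(read_sam(_write_sam(tmp_path / "c.sam", body), ref))
        assert len(frags) == 1
        assert frags[0].paired
        assert [p.score for p in frags[0].placements] == [92]

    def test_unknown_reference_rejected(self, tmp_path, rng):
        ref = make_ref(TE={"TE9": random_dna(rng, 200)})
        sam = tmp_path / "d.sam"
        sam.write_text(
            "@SQ\tSN:TE1\tLN:200\n"
            "R1\t0\tTE1\t1\t255\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\tAS:i:50\n"
        )
        with pytest.raises(DataError, match="TE1"):
            list(read_sam(sam, ref))

    def test_missing_score_tag_names_record(self, tmp_path, rng):
        ref = make_ref(TE={"TE1": random_dna(rng, 200)})
        body = "R7\t0\tTE1\t1\t255\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
        with pytest.raises(DataError, match="R7"):
            list(read_sam(_write_sam(tmp_path / "e.sam", body), ref))

    def test_file_order_of_first_appearance(self, tmp_path, rng):
        ref = make_ref(TE={"TE1": random_dna(rng, 200)})
        row = "\t0\tTE1\t1\t255\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\tAS:i:50\n"
        body = "RB" + row + "RA" + row + "RB" + row.replace("\t1\t", "\t5\t", 1)
        frags = list(read_sam(_write_sam(tmp_path / "f.sam", body), ref))
        assert [f.read_id for f in frags] == ["RB", "RA"]
        assert len(frags[0].placements) == 2
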