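import numpy as np
import pytest

from ampindel.align import (REJECTED_IMPROPER_ORIENTATION,
                            REJECTED_MATE_UNALIGNED, UNALIGNED_NO_ANCHOR,
                            UNALIGNED_TOO_MANY_MISMATCHES, AlignmentScoring,
                            AnchorHit, PairRejected, ReadAlignment, Unaligned,
                            align_pair, align_read, find_terminal_anchors,
                            select_anchor_pair, smith_waterman_segment)
from ampindel.errors import ConfigurationError
from ampindel.preprocess import ReadPair, ReadRecord
from ampindel.reference import build_index, revcomp
from conftest import random_dna
from oracles import global_affine_score


def mk_read(seq, read_id="r0", mate=1):
    return ReadRecord(read_id, mate, seq, tuple([38] * len(seq)))


def plant_subs(rng, seq, n, lo, hi):
    """Plant n substitutions at distinct positions in [lo, hi)."""
    out = list(seq)
    for pos in rng.choice(np.arange(lo, hi), size=n, replace=False):
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


class TestScoring:
    def test_defaults(self, scoring):
        assert (scoring.match, scoring.mismatch) == (2, -3)
        assert (scoring.gap_open, scoring.gap_extend) == (-6, -1)
        assert scoring.max_mismatches == 4
        assert scoring.anchor_k == scoring.max_softclip == 10

    def test_gap_cost(self, scoring):
        assert scoring.gap_cost(1) == -6
        assert scoring.gap_cost(7) == -12

    def test_validation(self):
        with pytest.raises(ConfigurationError):
            AlignmentScoring(match=-1)
        with pytest.raises(ConfigurationError):
            AlignmentScoring(gap_open=-1, gap_extend=-2)


class TestAnchors:
    def test_perfect_read_anchors_at_zero_softclip(self, reference, index, scoring):
        read = reference.sequence[20:140]
        left, right = find_terminal_anchors(read, index, scoring)
        assert left[0].softclip == 0 and left[0].ref_positions == (20,)
        assert right[0].softclip == 0 and right[0].ref_positions == (130,)

    def test_foreign_prefix_found_at_softclip_4(self, reference, index, scoring):
        # Prepend 4 bases chosen so the terminal 10-mers at s=0..3 are absent.
        read = "NNNN" + reference.sequence[20:140]
        left, _ = find_terminal_anchors(read, index, scoring)
        assert left[0].softclip == 4
        assert left[0].ref_positions == (20,)

    def test_repeated_terminal_kmer_returns_both_positions(self, scoring):
        text = "TTTT" + "ACGTACGTGA" + "CCCC" + "ACGTACGTGA" + "GGGG"
        idx = build_index(text)
        read = "ACGTACGTGA" + "CCCC" + "ACGTACGTGA"
        left, right = find_terminal_anchors(read, idx, scoring)
        assert left[0].ref_positions == (4, 18)
        assert right[0].ref_positions == (4, 18)

    def test_select_forced_pair(self, scoring):
        lh = [AnchorHit("left", 0, 0, (20,))]
        rh = [AnchorHit("right", 0, 110, (130,))]
        sel = select_anchor_pair(lh, rh, 120, scoring)
        assert sel is not None and (sel[2], sel[3]) == (20, 130)

    def test_select_maximizes_span(self, scoring):
        lh = [AnchorHit("left", 0, 0, (20, 60))]
        rh = [AnchorHit("right", 0, 110, (130,))]
        sel = select_anchor_pair(lh, rh, 120, scoring)
        assert (sel[2], sel[3]) == (20, 130)

    def test_equal_span_prefers_smaller_softclip(self, scoring):
        lh = [AnchorHit("left", 0, 0, (20,)), AnchorHit("left", 3, 3, (30,))]
        rh = [AnchorHit("right", 0, 110, (130,)), AnchorHit("right", 3, 107, (140,))]
        # spans: (20,130)->120, (30,140)->120, (20,140)->130, (30,130)->110
        sel = select_anchor_pair(lh, rh, 120, scoring)
        assert (sel[2], sel[3]) == (20, 140)  # max span wins first
        # restrict to the two equal-span combinations
        sel = select_anchor_pair([lh[0]], [rh[0]], 120, scoring)
        tied = select_anchor_pair(lh, [rh[0]], 120, scoring)
        assert tied[0].softclip == 0

    def test_no_consistent_pair(self, scoring):
        lh = [AnchorHit("left", 0, 0, (100,))]
        rh = [AnchorHit("right", 0, 110, (50,))]
        assert select_anchor_pair(lh, rh, 120, scoring) is None


class TestSmithWatermanSegment:
    def test_single_deletion_score_12(self, scoring):
        score, ops, mism = smith_waterman_segment("ACGTCGTAC", "ACGTACGTAC", scoring)
        assert score == 9 * 2 - 6 == 12
        assert mism == 0
        assert ops == (("M", 4), ("D", 1), ("M", 5))

    def test_identity_50mer(self, rng, scoring):
        seq = random_dna(rng, 50)
        score, ops, mism = smith_waterman_segment(seq, seq, scoring)
        assert score == 100 and ops == (("M", 50),) and mism == 0

    def test_planted_insertion_recovered_verbatim(self, rng, scoring):
        ref = random_dna(rng, 80)
        ins = "TGACGT"
        read = ref[:37] + ins + ref[37:]
        score, ops, mism = smith_waterman_segment(read, ref, scoring)
        inserted = [op for op in ops if op[0] == "I"]
        assert len(inserted) == 1
        assert inserted[0][1] == 6
        # left-shifting may rotate the insertion within a repeat context, but
        # the alignment must reproduce an equivalent allele of length 6
        assert score == 80 * 2 + scoring.gap_cost(6)

    def test_matches_full_dp_oracle(self, rng, scoring):
        for _ in range(25):
            ref = random_dna(rng, 90)
            read = ref[:40] + ref[52:]  # 12 bp deletion
            score, _, _ = smith_waterman_segment(read, ref, scoring)
            assert score == global_affine_score(read, ref)

    def test_mismatch_counted(self, scoring):
        score, ops, mism = smith_waterman_segment("ACGTACGTAC", "ACGTACCTAC", scoring)
        assert mism == 1 and score == 9 * 2 - 3

    def test_homopolymer_deletion_left_shifted(self, scoring):
        #        0123456789
        ref = "GCAAAATC"
        read = "GCAATC"
        score, ops, _ = smith_waterman_segment(read, ref, scoring)
        assert ops == (("M", 2), ("D", 2), ("M", 4))


class TestAlignRead:
    def test_perfect_read(self, reference, index, scoring):
        read = mk_read(reference.sequence[20:140])
        aln = align_read(read, reference.sequence, index, scoring)
        assert isinstance(aln, ReadAlignment)
        assert (aln.ref_start, aln.ref_end) == (20, 140)
        assert aln.n_mismatches == 0 and aln.ops == (("M", 120),)
        assert aln.strand == "+"

    def test_minus_strand_read(self, reference, index, scoring):
        read = mk_read(revcomp(reference.sequence[20:140]))
        aln = align_read(read, reference.sequence, index, scoring)
        assert aln.strand == "-"
        assert (aln.ref_start, aln.ref_end) == (20, 140)

    def test_four_mismatches_accepted(self, rng, reference, index, scoring):
        seq = plant_subs(rng, reference.sequence[20:140], 4, 15, 105)
        aln = align_read(mk_read(seq), reference.sequence, index, scoring)
        assert isinstance(aln, ReadAlignment)
        assert aln.n_mismatches == 4

    def test_five_mismatches_rejected(self, rng, reference, index, scoring):
        seq = plant_subs(rng, reference.sequence[20:140], 5, 15, 105)
        result = align_read(mk_read(seq), reference.sequence, index, scoring)
        assert result == Unaligned("r0", 1, UNALIGNED_TOO_MANY_MISMATCHES)

    def test_random_read_unaligned_no_anchor(self, reference, index, scoring):
        result = align_read(mk_read("AT" * 30), reference.sequence, index, scoring)
        assert isinstance(result, Unaligned)
        assert result.reason == UNALIGNED_NO_ANCHOR

    def test_95bp_deletion_single_op(self, reference, index, scoring):
        hap = reference.sequence[:70] + reference.sequence[165:]
        read = mk_read(hap[:120])
        aln = align_read(read, reference.sequence, index, scoring)
        assert isinstance(aln, ReadAlignment)
        dels = [op for op in aln.ops if op[0] == "D"]
        assert dels == [("D", 95)]

    def test_strand_symmetry(self, rng, reference, index, scoring):
        seq = reference.sequence[30:150]
        seq = seq[:50] + seq[53:]  # 3 bp deletion
        fwd = align_read(mk_read(seq), reference.sequence, index, scoring)
        rev = align_read(mk_read(revcomp(seq)), reference.sequence, index, scoring)
        assert fwd.score == rev.score
        assert (fwd.ref_start, fwd.ref_end) == (rev.ref_start, rev.ref_end)
        assert fwd.ops == rev.ops
        assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_mismatch_cap_monotonicity(self, rng, reference, index):
        reads = []
        for i in range(30):
            n = int(rng.integers(0, 7))
            seq = plant_subs(rng, reference.sequence[20:140], n, 15, 105)
            reads.append(mk_read(seq, read_id=f"m{i}"))
        accepted = []
        for cap in (0, 2, 4, 6):
            sc = AlignmentScoring(max_mismatches=cap)
            n_ok = sum(isinstance(align_read(r, reference.sequence, index, sc),
                                  ReadAlignment) for r in reads)
            accepted.append(n_ok)
        assert accepted == sorted(accepted)

    def test_cigar_conservation_invariants(self, rng, reference, index, scoring):
        for i in range(40):
            start = int(rng.integers(0, 60))
            end = int(rng.integers(start + 60, min(start + 160, 240)))
            seq = reference.sequence[start:end]
            if rng.random() < 0.5 and end - start > 80:
                cut = int(rng.integers(20, end - start - 40))
                dlen = int(rng.integers(1, 12))
                seq = seq[:cut] + seq[cut + dlen:]
            aln = align_read(mk_read(seq, read_id=f"c{i}"), reference.sequence,
                             index, scoring)
            if isinstance(aln, ReadAlignment):
                aln.validate(len(seq))  # raises AssertionError on violation


class TestAnchoredVsOracle:
    def test_oracle_equivalence_on_planted_variants(self, rng, reference, index, scoring):
        """Anchored DP must match the unconstrained full-DP optimum when the
        anchors are correct (smaller version of the acceptance run)."""
        checked = 0
        while checked < 60:
            ref = random_dna(rng, 160)
            idx = build_index(ref)
            a, b = 20, 140
            seq = ref[a:b]
            # plant <=2 indels and <=4 substitutions, away from the termini
            n_indel = int(rng.integers(0, 3))
            for _ in range(n_indel):
                cut = int(rng.integers(20, len(seq) - 30))
                if rng.random() < 0.5:
                    dlen = int(rng.integers(1, 15))
                    seq = seq[:cut] + seq[cut + dlen:]
                else:
                    ilen = int(rng.integers(1, 8))
                    seq = seq[:cut] + random_dna(rng, ilen) + seq[cut:]
            n_sub = int(rng.integers(0, 5))
            if n_sub:
                seq = plant_subs(rng, seq, n_sub, 12, len(seq) - 12)
            if len(set(ref[i:i + 10] for i in range(len(ref) - 9))) != len(ref) - 9:
                continue  # ambiguous anchors: oracle precondition not met
            aln = align_read(mk_read(seq), ref, idx, AlignmentScoring(max_mismatches=99))
            if not isinstance(aln, ReadAlignment) or aln.softclip_left or aln.softclip_right:
                continue
            core = seq
            segment = ref[aln.ref_start: aln.ref_end]
            assert aln.score == global_affine_score(core, segment)
            checked += 1


class TestAlignPair:
    def simulate_fr_pair(self, reference):
        frag = reference.sequence[10:190]
        r1 = mk_read(frag[:120], read_id="p", mate=1)
        r2 = mk_read(revcomp(frag)[:120], read_id="p", mate=2)
        return ReadPair(r1, r2)

    def test_fr_pair_accepted(self, reference, index, scoring):
        result = align_pair(self.simulate_fr_pair(reference), reference.sequence,
                            index, scoring)
        assert not isinstance(result, PairRejected)
        a1, a2 = result
        assert a1.strand == "+" and a2.strand == "-"

    def test_ff_pair_rejected(self, reference, index, scoring):
        frag = reference.sequence[10:190]
        pair = ReadPair(mk_read(frag[:120], read_id="p", mate=1),
                        mk_read(frag[60:180], read_id="p", mate=2))
        result = align_pair(pair, reference.sequence, index, scoring)
        assert result == PairRejected("p", REJECTED_IMPROPER_ORIENTATION)

    def test_unalignable_mate_rejected(self, reference, index, scoring):
        frag = reference.sequence[10:190]
        pair = ReadPair(mk_read(frag[:120], read_id="p", mate=1),
                        mk_read("AT" * 60, read_id="p", mate=2))
        result = align_pair(pair, reference.sequence, index, scoring)
        assert result == PairRejected("p", REJECTED_MATE_UNALIGNED)
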