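"""Anchored Smith-Waterman alignment of amplicon reads.

Each read terminus is anchored in the reference by exact 10-mer lookup,
sliding inward one base at a time up to a 10 bp soft-clip limit, on both
strands. The maximally distanced consistent anchor pair delimits a reduced
state space, and an optimal affine-gap dynamic-programming alignment is run
globally between the read core (anchored termini included) and the spanned
reference segment. Alignments with more than ``max_mismatches`` substitutions
are rejected after the fact, keeping the DP itself optimal.

Gap placement is canonicalized by left-shifting indels so that identical
alleles observed in different reads produce identical operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError
from .preprocess import ReadPair, ReadRecord
from .reference import SuffixArrayIndex, locate_exact, revcomp

NEG_INF = -(1 << 30)

UNALIGNED_NO_ANCHOR = "no_anchor"
UNALIGNED_ANCHOR_CONFLICT = "anchor_conflict"
UNALIGNED_TOO_MANY_MISMATCHES = "too_many_mismatches"
REJECTED_MATE_UNALIGNED = "mate_unaligned"
REJECTED_IMPROPER_ORIENTATION = "improper_orientation"


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring chosen for sensitive detection of short and long indels:
    cheap gap extension keeps long deletions affordable while the mismatch
    penalty and post-hoc cap bound substitution noise."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -6   # charged for a gap's first base
    gap_extend: int = -1  # each further base
    max_mismatches: int = 4
    anchor_k: int = 10
    max_softclip: int = 10

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ConfigurationError("require match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ConfigurationError("require gap_open <= gap_extend < 0")
        if self.anchor_k < 1 or self.max_softclip < 0 or self.max_mismatches < 0:
            raise ConfigurationError("anchor_k/max_softclip/max_mismatches out of range")

    def gap_cost(self, length: int) -> int:
        return self.gap_open + (length - 1) * self.gap_extend


@dataclass(frozen=True)
class AnchorHit:
    """An exact ``anchor_k``-mer match of one read terminus, found after
    soft-clipping ``softclip`` bases from that end."""

    read_end: str  # "left" | "right"
    softclip: int
    read_offset: int  # start of the anchored k-mer in the (oriented) read
    ref_positions: tuple[int, ...]


@dataclass(frozen=True)
class Unaligned:
    read_id: str
    mate: int
    reason: str


@dataclass(frozen=True)
class PairRejected:
    pair_id: str
    reason: str


@dataclass(frozen=True)
class ReadAlignment:
    """A gapped alignment of one read against the forward reference.

    ``ops`` covers the read core (between soft-clips) against
    ``[ref_start, ref_end)``; entries are ``("M", length)``,
    ``("D", length)`` or ``("I", length, inserted_seq)``. Soft-clips are in
    oriented (reference-forward) read coordinates.
    """

    read_id: str
    mate: int
    strand: str
    ref_start: int
    ref_end: int
    ops: tuple[tuple, ...]
    score: int
    n_mismatches: int
    softclip_left: int
    softclip_right: int

    @property
    def read_core_len(self) -> int:
        return sum(op[1] for op in self.ops if op[0] in ("M", "I"))

    @property
    def ref_span_len(self) -> int:
        return sum(op[1] for op in self.ops if op[0] in ("M", "D"))

    def cigar(self) -> str:
        parts = []
        if self.softclip_left:
            parts.append(f"{self.softclip_left}S")
        parts.extend(f"{op[1]}{op[0]}" for op in self.ops)
        if self.softclip_right:
            parts.append(f"{self.softclip_right}S")
        return "".join(parts)

    def validate(self, read_len: int) -> None:
        if self.read_core_len + self.softclip_left + self.softclip_right != read_len:
            raise AssertionError(
                f"{self.read_id}/{self.mate}: M+I ({self.read_core_len}) + softclips "
                f"!= read length {read_len}"
            )
        if self.ref_span_len != self.ref_end - self.ref_start:
            raise AssertionError(
                f"{self.read_id}/{self.mate}: M+D ({self.ref_span_len}) != reference span "
                f"{self.ref_end - self.ref_start}"
            )


def find_terminal_anchors(
    seq: str, index: SuffixArrayIndex, scoring: AlignmentScoring
) -> tuple[list[AnchorHit], list[AnchorHit]]:
    """Anchor candidates for both termini of an oriented read sequence.

    For soft-clip s = 0..max_softclip, the k-mer starting s bases in from
    each end is looked up; hits are returned in ascending soft-clip order.
    """
    k = scoring.anchor_k
    n = len(seq)
    left: list[AnchorHit] = []
    right: list[AnchorHit] = []
    for s in range(scoring.max_softclip + 1):
        if s + k <= n:
            hits = locate_exact(index, seq[s: s + k])
            if hits:
                left.append(AnchorHit("left", s, s, tuple(hits)))
        start = n - k - s
        if start >= 0:
            hits = locate_exact(index, seq[start: start + k])
            if hits:
                right.append(AnchorHit("right", s, start, tuple(hits)))
    return left, right


def select_anchor_pair(
    left: Sequence[AnchorHit],
    right: Sequence[AnchorHit],
    read_len: int,
    scoring: AlignmentScoring,
) -> tuple[AnchorHit, AnchorHit, int, int] | None:
    """Best consistent anchor pair: maximal reference span, then smaller
    total soft-clip, then leftmost left anchor.

    Consistency requires disjoint anchored segments on both the read and the
    reference, in left-to-right order. Returns (left_hit, right_hit,
    left_ref_pos, right_ref_pos) or None.
    """
    k = scoring.anchor_k
    best = None
    best_key = None
    for lh in left:
        for rh in right:
            if lh.read_offset + k > rh.read_offset:
                continue  # anchored read segments overlap
            for pl in lh.ref_positions:
                for pr in rh.ref_positions:
                    if pl + k > pr:
                        continue  # anchored reference segments overlap
                    span = pr + k - pl
                    key = (span, -(lh.softclip + rh.softclip), -pl)
                    if best_key is None or key > best_key:
                        best_key = key
                        best = (lh, rh, pl, pr)
    return best


def smith_waterman_segment(
    read_core: str, ref_segment: str, scoring: AlignmentScoring
) -> tuple[int, tuple[tuple, ...], int]:
    """Optimal global affine-gap alignment of the inter-anchor segment.

    Returns (score, ops, n_mismatches) with indels left-shifted into
    canonical form. Adjacent insertion/deletion transitions are disallowed
    (a substitution is always cheaper under the default scoring).
    """
    if read_core == ref_segment:
        if not read_core:
            return 0, (), 0
        return scoring.match * len(read_core), (("M", len(read_core)),), 0
    score, raw_ops = _affine_global(read_core, ref_segment, scoring)
    ops = _left_shift_ops(raw_ops, read_core, ref_segment)
    n_mism = _count_mismatches(ops, read_core, ref_segment)
    return score, tuple(_freeze_ops(ops, read_core)), n_mism


def _affine_global(read: str, ref: str, sc: AlignmentScoring) -> tuple[int, list[list]]:
    n, m = len(read), len(ref)
    go, ge = sc.gap_open, sc.gap_extend
    H = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    I = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)  # consumes read (insertion)
    D = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)  # consumes ref (deletion)
    H[0, 0] = 0
    if m:
        D[0, 1:] = go + ge * np.arange(m)
    if n:
        I[1:, 0] = go + ge * np.arange(n)

    ref_arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    read_arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
    n_code = ord("N")
    j_idx = np.arange(1, m + 1, dtype=np.int64)

    for i in range(1, n + 1):
        rb = read_arr[i - 1]
        eq = (ref_arr == rb) & (ref_arr != n_code) & (rb != n_code)
        sub = np.where(eq, sc.match, sc.mismatch)
        prev_best = np.maximum(np.maximum(H[i - 1], I[i - 1]), D[i - 1])
        H[i, 1:] = prev_best[:-1] + sub
        I[i, 1:] = np.maximum(H[i - 1, 1:] + go, I[i - 1, 1:] + ge)
        # D within the row via a prefix-max scan:
        # D[i,j] = ge*j + max_{k<j}(H[i,k] + go - ge*(k+1))
        t = H[i, :-1] + go - ge * np.arange(1, m + 1)
        D[i, 1:] = np.maximum.accumulate(t) + ge * j_idx

    end_scores = (H[n, m], D[n, m], I[n, m])
    score = int(max(end_scores))
    state = ("H", "D", "I")[int(np.argmax(end_scores))]

    # Traceback (prefer closing gaps / diagonal on ties for determinism;
    # canonical placement is restored by the left-shift pass afterwards).
    ops: list[list] = []
    i, j = n, m

    def emit(kind: str) -> None:
        if ops and ops[-1][0] == kind:
            ops[-1][1] += 1
        else:
            ops.append([kind, 1])

    go_, ge_ = sc.gap_open, sc.gap_extend
    while i > 0 or j > 0:
        if state == "H":
            prev = (H[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            target = H[i, j] - (sc.match if _bases_match(read[i - 1], ref[j - 1]) else sc.mismatch)
            emit("M")
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for cand, name in zip(prev, ("H", "D", "I")):
                if cand == target:
                    state = name
                    break
        elif state == "D":
            close = H[i, j - 1] + go_ == D[i, j]
            emit("D")
            j -= 1
            state = "H" if close else "D"
        else:  # "I"
            close = H[i - 1, j] + go_ == I[i, j]
            emit("I")
            i -= 1
            state = "H" if close else "I"
        if i == 0 and j == 0:
            break
        if state == "H" and (i == 0 or j == 0):
            state = "D" if i == 0 else "I"

    ops.reverse()
    return score, ops


def _bases_match(a: str, b: str) -> bool:
    return a == b and a != "N"


def _left_shift_ops(ops: list[list], read: str, ref: str) -> list[list]:
    """Shift each indel as far left as score-equivalence allows, then merge."""
    ops = [list(op) for op in ops]
    changed = True
    while changed:
        changed = False
        # compute (read, ref) start offsets for each op
        starts = []
        i = j = 0
        for kind, length in ((op[0], op[1]) for op in ops):
            starts.append((i, j))
            if kind == "M":
                i += length
                j += length
            elif kind == "I":
                i += length
            else:
                j += length
        for idx in range(1, len(ops)):
            kind, length = ops[idx][0], ops[idx][1]
            if kind == "M":
                continue
            prev = ops[idx - 1]
            if prev[0] != "M" or prev[1] < 1:
                continue
            oi, oj = starts[idx]
            if kind == "D":
                if oj >= 1 and ref[oj - 1] == ref[oj + length - 1]:
                    prev[1] -= 1
                    if idx + 1 < len(ops) and ops[idx + 1][0] == "M":
                        ops[idx + 1][1] += 1
                    else:
                        ops.insert(idx + 1, ["M", 1])
                    changed = True
                    break
            else:  # "I"
                if oi >= 1 and read[oi - 1] == read[oi + length - 1]:
                    prev[1] -= 1
                    if idx + 1 < len(ops) and ops[idx + 1][0] == "M":
                        ops[idx + 1][1] += 1
                    else:
                        ops.insert(idx + 1, ["M", 1])
                    changed = True
                    break
        if changed:
            ops = [op for op in ops if op[1] > 0]
            ops = _merge_ops(ops)
    return _merge_ops([op for op in ops if op[1] > 0])


def _merge_ops(ops: list[list]) -> list[list]:
    merged: list[list] = []
    for op in ops:
        if merged and merged[-1][0] == op[0]:
            merged[-1][1] += op[1]
        else:
            merged.append(op)
    return merged


def _count_mismatches(ops: list[list], read: str, ref: str) -> int:
    i = j = mism = 0
    for kind, length in ((op[0], op[1]) for op in ops):
        if kind == "M":
            mism += sum(1 for a, b in zip(read[i:i + length], ref[j:j + length])
                        if not _bases_match(a, b))
            i += length
            j += length
        elif kind == "I":
            i += length
        else:
            j += length
    return mism


def _freeze_ops(ops: list[list], read: str) -> list[tuple]:
    out: list[tuple] = []
    i = 0
    for kind, length in ((op[0], op[1]) for op in ops):
        if kind == "I":
            out.append(("I", length, read[i:i + length]))
            i += length
        elif kind == "M":
            out.append(("M", length))
            i += length
        else:
            out.append(("D", length))
    return out


def align_read(
    read: ReadRecord,
    ref_seq: str,
    index: SuffixArrayIndex,
    scoring: AlignmentScoring,
) -> ReadAlignment | Unaligned:
    """Anchor, select the maximal-span anchor pair, align, filter.

    Both strands are attempted; the highest-scoring accepted alignment wins
    ('+' preferred on exact score ties). Failure reasons: ``no_anchor``
    (no strand anchors both ends), ``anchor_conflict`` (anchors exist but no
    consistent pair), ``too_many_mismatches``.
    """
    best: ReadAlignment | None = None
    both_ends_anchored = False
    for strand in ("+", "-"):
        oriented = read.sequence if strand == "+" else revcomp(read.sequence)
        left, right = find_terminal_anchors(oriented, index, scoring)
        if not (left and right):
            continue
        both_ends_anchored = True
        sel = select_anchor_pair(left, right, len(oriented), scoring)
        if sel is None:
            continue
        lh, rh, pl, pr = sel
        k = scoring.anchor_k
        s_l = lh.softclip
        s_r = rh.softclip
        core = oriented[s_l: len(oriented) - s_r]
        segment = ref_seq[pl: pr + k]
        score, ops, n_mism = smith_waterman_segment(core, segment, scoring)
        aln = ReadAlignment(
            read_id=read.read_id, mate=read.mate, strand=strand,
            ref_start=pl, ref_end=pr + k, ops=ops, score=score,
            n_mismatches=n_mism, softclip_left=s_l, softclip_right=s_r,
        )
        aln.validate(len(read))
        if best is None or aln.score > best.score:
            best = aln
    if best is None:
        reason = UNALIGNED_ANCHOR_CONFLICT if both_ends_anchored else UNALIGNED_NO_ANCHOR
        return Unaligned(read.read_id, read.mate, reason)
    if best.n_mismatches > scoring.max_mismatches:
        return Unaligned(read.read_id, read.mate, UNALIGNED_TOO_MANY_MISMATCHES)
    return best


def align_pair(
    pair: ReadPair,
    ref_seq: str,
    index: SuffixArrayIndex,
    scoring: AlignmentScoring,
    max_fragment_span: int | None = None,
) -> tuple[ReadAlignment, ReadAlignment] | PairRejected:
    """Align both mates and require proper FR orientation.

    Proper orientation: mates on opposite strands with the leftmost-aligned
    mate on '+', and a union reference span no longer than
    ``max_fragment_span`` (default: amplicon length + 50 bp).
    """
    if max_fragment_span is None:
        max_fragment_span = len(ref_seq) + 50
    a1 = align_read(pair.r1, ref_seq, index, scoring)
    a2 = align_read(pair.r2, ref_seq, index, scoring)
    if isinstance(a1, Unaligned) or isinstance(a2, Unaligned):
        return PairRejected(pair.pair_id, REJECTED_MATE_UNALIGNED)
    if a1.strand == a2.strand:
        return PairRejected(pair.pair_id, REJECTED_IMPROPER_ORIENTATION)
    leftmost = a1 if a1.ref_start <= a2.ref_start else a2
    rightmost = a2 if leftmost is a1 else a1
    if leftmost.ref_start < rightmost.ref_start and leftmost.strand != "+":
        return PairRejected(pair.pair_id, REJECTED_IMPROPER_ORIENTATION)
    span = max(a1.ref_end, a2.ref_end) - min(a1.ref_start, a2.ref_start)
    if span > max_fragment_span:
        return PairRejected(pair.pair_id, REJECTED_IMPROPER_ORIENTATION)
    return a1, a2
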