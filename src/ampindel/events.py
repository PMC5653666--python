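"""Indel event extraction, mate reconciliation, window summarization and
frameshift classification.

Events are kept in left-aligned canonical form against the full reference so
that the same allele observed in reads with different anchors compares
equal. A read pair is counted at the locus only if at least one mate's
alignment overlaps the sgRNA+PAM window by the configured minimum; within a
counted pair, mutant status and the net indel length consider only
window-overlapping events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .align import ReadAlignment
from .errors import ConservationError
from .reference import AmpliconReference, WindowSpec

STATUS_WT = "wt"
STATUS_MUTANT = "mutant"
STATUS_DISCORDANT = "discordant"
STATUS_OFF_WINDOW = "off_window"
STATUS_UNALIGNED = "unaligned"

FRAME_FS = "FS"
FRAME_NFS = "NFS"


@dataclass(frozen=True, order=True)
class IndelEvent:
    """One insertion or deletion in left-aligned canonical form.

    ``ref_pos`` is the 0-based position of the first deleted base (del) or
    of the reference base before which the insertion occurs (ins).
    """

    ref_pos: int
    kind: str  # "ins" | "del"
    length: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del"):
            raise ValueError(f"kind must be 'ins' or 'del', got {self.kind!r}")
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if self.kind == "ins" and len(self.inserted_seq) != self.length:
            raise ValueError("inserted_seq length must equal event length")
        if self.kind == "del" and self.inserted_seq:
            raise ValueError("deletions carry no inserted sequence")

    @property
    def net(self) -> int:
        return self.length if self.kind == "ins" else -self.length

    @property
    def ref_interval(self) -> tuple[int, int]:
        """Reference footprint: [pos, pos+len) for del, [pos, pos] for ins."""
        if self.kind == "del":
            return (self.ref_pos, self.ref_pos + self.length)
        return (self.ref_pos, self.ref_pos)

    def key(self) -> str:
        if self.kind == "del":
            return f"del@{self.ref_pos}:{self.length}"
        return f"ins@{self.ref_pos}:{self.inserted_seq}"


def normalize_event(event: IndelEvent, ref_seq: str) -> IndelEvent:
    """Left-shift an event to its canonical position on the full reference."""
    if event.ref_pos < 0 or event.ref_pos > len(ref_seq):
        raise ValueError(f"event position {event.ref_pos} outside reference")
    pos = event.ref_pos
    if event.kind == "del":
        length = event.length
        while pos > 0 and ref_seq[pos - 1] == ref_seq[pos + length - 1]:
            pos -= 1
        return event if pos == event.ref_pos else replace(event, ref_pos=pos)
    seq = event.inserted_seq
    while pos > 0 and seq[-1] == ref_seq[pos - 1]:
        seq = ref_seq[pos - 1] + seq[:-1]
        pos -= 1
    if pos == event.ref_pos:
        return event
    return replace(event, ref_pos=pos, inserted_seq=seq)


@dataclass(frozen=True)
class PairCall:
    """Reconciled per-pair verdict."""

    pair_id: str
    status: str
    events: frozenset[IndelEvent] = frozenset()
    net_indel: int = 0
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.status == STATUS_WT and self.events:
            raise ValueError("wild-type calls carry no events")
        if self.status == STATUS_MUTANT and not self.events:
            raise ValueError("mutant calls require at least one event")


def extract_events(aln: ReadAlignment, ref_seq: str) -> frozenset[IndelEvent]:
    """One canonical event per I/D op; mismatches are not events."""
    events: list[IndelEvent] = []
    j = aln.ref_start
    for op in aln.ops:
        kind = op[0]
        if kind == "M":
            j += op[1]
        elif kind == "D":
            events.append(normalize_event(IndelEvent(j, "del", op[1]), ref_seq))
            j += op[1]
        else:  # I
            events.append(normalize_event(IndelEvent(j, "ins", op[1], op[2]), ref_seq))
    return frozenset(events)


def reconcile_pair(
    aln1: ReadAlignment,
    aln2: ReadAlignment,
    events1: frozenset[IndelEvent],
    events2: frozenset[IndelEvent],
    pair_id: str | None = None,
) -> PairCall:
    """Cross-check mates: an event whose position both mates cover must be
    reported identically by both, else the pair is discordant; events covered
    by a single mate are accepted from that mate alone."""
    if pair_id is None:
        pair_id = aln1.read_id
    span1 = (aln1.ref_start, aln1.ref_end)
    span2 = (aln2.ref_start, aln2.ref_end)

    def covered(span: tuple[int, int], event: IndelEvent) -> bool:
        return span[0] <= event.ref_pos < span[1]

    accepted: set[IndelEvent] = set()
    for event in events1 | events2:
        in1 = covered(span1, event)
        in2 = covered(span2, event)
        if in1 and in2:
            if event in events1 and event in events2:
                accepted.add(event)
            else:
                return PairCall(pair_id, STATUS_DISCORDANT)
        elif event in events1 or event in events2:
            accepted.add(event)
    if not accepted:
        return PairCall(pair_id, STATUS_WT)
    net = sum(e.net for e in accepted)
    return PairCall(pair_id, STATUS_MUTANT, frozenset(accepted), net)


def apply_window(
    call: PairCall,
    aln1: ReadAlignment,
    aln2: ReadAlignment,
    window: WindowSpec,
) -> PairCall:
    """Restrict a reconciled call to the sgRNA+PAM window.

    The pair is counted only if some mate's reference span (deletions count
    as covered reference) overlaps the window by >= min_overlap. Events not
    overlapping the window are dropped; a pair left with no window events is
    wild-type for window summarization.
    """
    best_overlap = max(
        window.overlap(aln1.ref_start, aln1.ref_end),
        window.overlap(aln2.ref_start, aln2.ref_end),
    )
    if best_overlap < window.min_overlap:
        return PairCall(call.pair_id, STATUS_OFF_WINDOW)
    if call.status == STATUS_DISCORDANT:
        return call
    w0, w1 = window.interval
    kept = frozenset(e for e in call.events if _event_in_window(e, w0, w1))
    if not kept:
        return PairCall(call.pair_id, STATUS_WT)
    net = sum(e.net for e in kept)
    return PairCall(call.pair_id, STATUS_MUTANT, kept, net)


def _event_in_window(event: IndelEvent, w0: int, w1: int) -> bool:
    if event.kind == "del":
        a, b = event.ref_interval
        return min(b, w1) - max(a, w0) > 0
    # Insertions at either window edge are junction events and count as in.
    return w0 <= event.ref_pos <= w1


def classify_frame(call: PairCall) -> str:
    """FS iff the net indel length is not a multiple of 3."""
    if call.status != STATUS_MUTANT:
        raise ValueError(f"classify_frame called on status {call.status!r}")
    return FRAME_NFS if call.net_indel % 3 == 0 else FRAME_FS


@dataclass(frozen=True)
class GenomicEvent:
    contig: str
    pos: int  # 1-based genomic coordinate
    kind: str
    length: int
    inserted_seq: str = ""


def to_genomic(event: IndelEvent, reference: AmpliconReference) -> GenomicEvent:
    """Translate a local event to 1-based genomic coordinates."""
    if not 0 <= event.ref_pos <= len(reference.sequence):
        raise ValueError(f"event position {event.ref_pos} outside reference")
    return GenomicEvent(
        contig=reference.genomic_contig,
        pos=reference.genomic_offset + event.ref_pos,
        kind=event.kind,
        length=event.length,
        inserted_seq=event.inserted_seq,
    )


@dataclass(frozen=True)
class AlleleRecord:
    """One distinct window-restricted event set with its pair support."""

    events: tuple[IndelEvent, ...]
    n_pairs: int
    frame_class: str
    genomic: tuple[GenomicEvent, ...]

    @property
    def key(self) -> str:
        return ";".join(e.key() for e in self.events)


@dataclass
class SampleSummary:
    sample_id: str
    n_pairs_input: int = 0
    n_pass_qc: int = 0
    n_aligned_proper: int = 0
    n_window: int = 0
    n_wt: int = 0
    n_mutant: int = 0
    n_fs: int = 0
    n_nfs: int = 0
    n_discordant: int = 0
    allele_table: list[AlleleRecord] = field(default_factory=list)

    def check_invariants(self) -> None:
        if self.n_wt + self.n_mutant + self.n_discordant != self.n_window:
            raise ConservationError(
                f"{self.sample_id}: wt {self.n_wt} + mutant {self.n_mutant} + "
                f"discordant {self.n_discordant} != window {self.n_window}"
            )
        if self.n_fs + self.n_nfs != self.n_mutant:
            raise ConservationError(
                f"{self.sample_id}: FS {self.n_fs} + NFS {self.n_nfs} != mutant {self.n_mutant}"
            )
        for name in ("n_pairs_input", "n_pass_qc", "n_aligned_proper", "n_window",
                     "n_wt", "n_mutant", "n_fs", "n_nfs", "n_discordant"):
            if getattr(self, name) < 0:
                raise ConservationError(f"{self.sample_id}: negative tally {name}")

    @property
    def nfs_fraction(self) -> float | None:
        """NFS fraction among mutant pairs; None if no mutants."""
        if self.n_mutant == 0:
            return None
        return self.n_nfs / self.n_mutant


def summarize_sample(
    calls: Iterable[PairCall],
    reference: AmpliconReference,
    sample_id: str = "sample",
    n_pairs_input: int | None = None,
) -> SampleSummary:
    """Tally window-qualified calls and build the per-allele table.

    ``calls`` is the full per-pair outcome stream for one sample, including
    unaligned/off-window statuses. ``n_pairs_input`` defaults to the number
    of calls (i.e. no QC drops upstream).
    """
    summary = SampleSummary(sample_id=sample_id)
    allele_counts: Counter[tuple[IndelEvent, ...]] = Counter()
    allele_frame: dict[tuple[IndelEvent, ...], str] = {}
    for call in calls:
        summary.n_pass_qc += 1
        if call.status == STATUS_UNALIGNED:
            continue
        summary.n_aligned_proper += 1
        if call.status == STATUS_OFF_WINDOW:
            continue
        summary.n_window += 1
        if call.status == STATUS_WT:
            summary.n_wt += 1
        elif call.status == STATUS_DISCORDANT:
            summary.n_discordant += 1
        else:
            summary.n_mutant += 1
            frame = classify_frame(call)
            if frame == FRAME_FS:
                summary.n_fs += 1
            else:
                summary.n_nfs += 1
            key = tuple(sorted(call.events))
            allele_counts[key] += 1
            allele_frame[key] = frame
    summary.n_pairs_input = summary.n_pass_qc if n_pairs_input is None else n_pairs_input
    for key, count in sorted(allele_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        summary.allele_table.append(AlleleRecord(
            events=key,
            n_pairs=count,
            frame_class=allele_frame[key],
            genomic=tuple(to_genomic(e, reference) for e in key),
        ))
    summary.check_invariants()
    return summary
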