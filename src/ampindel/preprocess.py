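"""FASTQ ingestion and pair-level quality control.

The QC chain is fixed-order: 3' trim -> adapter clip -> pair filter. Reads
are handled pair-wise throughout; a pair is dropped if either mate fails a
filter. Dropped/kept counts satisfy a conservation identity asserted on
every run.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigurationError, ParseError

READ_ALPHABET = frozenset("ACGTN")

#: Nextera read-through adapter (mosaic end), identical for both mates.
NEXTERA_ADAPTERS: tuple[str, ...] = ("CTGTCTCTTATACACATCT",)

DROP_SHORT = "short"
DROP_LOW_QUALITY = "low_quality"


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with Sanger-scale per-base Phred qualities."""

    read_id: str
    mate: int
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ConfigurationError(f"mate must be 1 or 2, got {self.mate}")
        if len(self.sequence) != len(self.qualities):
            raise ParseError(
                f"read {self.read_id}/{self.mate}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if not set(self.sequence) <= READ_ALPHABET:
            bad = sorted(set(self.sequence) - READ_ALPHABET)
            raise ParseError(f"read {self.read_id}/{self.mate}: non-DNA characters {bad}")
        if any(q < 0 for q in self.qualities):
            raise ParseError(f"read {self.read_id}/{self.mate}: negative quality score")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    r1: ReadRecord
    r2: ReadRecord

    def __post_init__(self) -> None:
        if self.r1.read_id != self.r2.read_id:
            raise ParseError(
                f"mate id mismatch: {self.r1.read_id!r} vs {self.r2.read_id!r}"
            )
        if (self.r1.mate, self.r2.mate) != (1, 2):
            raise ParseError(f"pair {self.r1.read_id}: mates must be (1, 2)")

    @property
    def pair_id(self) -> str:
        return self.r1.read_id


@dataclass(frozen=True)
class QCParams:
    """Pair-level QC parameters. Defaults follow the pipeline's published
    settings: trim to 120 bp, retain only reads strictly longer than 15 bp,
    drop pairs where either mate has >= 50% of bases below Q30."""

    trim_to: int = 120
    adapters: tuple[str, ...] = NEXTERA_ADAPTERS
    min_len_exclusive: int = 15
    q_threshold: int = 30
    max_lowq_fraction: float = 0.5
    adapter_min_overlap: int = 5

    def __post_init__(self) -> None:
        if self.trim_to <= self.min_len_exclusive:
            raise ConfigurationError("trim_to must exceed min_len_exclusive")
        if not 0.0 <= self.max_lowq_fraction <= 1.0:
            raise ConfigurationError("max_lowq_fraction must lie in [0, 1]")
        if not self.adapters:
            raise ConfigurationError("adapter set must be non-empty")
        if self.adapter_min_overlap < 1:
            raise ConfigurationError("adapter_min_overlap must be >= 1")


def trim_3prime(read: ReadRecord, trim_to: int) -> ReadRecord:
    """Truncate to at most ``trim_to`` bases, keeping the 5' end."""
    if trim_to < 1:
        raise ConfigurationError("trim_to must be >= 1")
    if len(read) <= trim_to:
        return read
    return ReadRecord(read.read_id, read.mate,
                      read.sequence[:trim_to], read.qualities[:trim_to])


def clip_adapters(read: ReadRecord, adapters: Iterable[str],
                  min_overlap: int = 5) -> ReadRecord:
    """Remove the longest read suffix matching a prefix of any adapter.

    Overlaps of at least ``min_overlap`` bases qualify, tolerating one
    mismatch per 10 bases of overlap (floor). Qualities are clipped with the
    bases; 5' content is untouched.
    """
    best = 0
    seq = read.sequence
    for adapter in adapters:
        adapter = adapter.upper()
        top = min(len(seq), len(adapter))
        for length in range(top, min_overlap - 1, -1):
            if length <= best:
                break
            suffix = seq[-length:]
            prefix = adapter[:length]
            allowed = length // 10
            mismatches = sum(a != b for a, b in zip(suffix, prefix))
            if mismatches <= allowed:
                best = length
                break
    if best == 0:
        return read
    keep = len(seq) - best
    return ReadRecord(read.read_id, read.mate,
                      seq[:keep], read.qualities[:keep])


def _lowq_fraction(read: ReadRecord, q_threshold: int) -> float:
    if len(read) == 0:
        return 1.0
    # N carries no base call and counts as below-threshold regardless of its
    # reported quality.
    n_low = sum(1 for base, q in zip(read.sequence, read.qualities)
                if q < q_threshold or base == "N")
    return n_low / len(read)


def filter_pair(pair: ReadPair, params: QCParams) -> str | None:
    """Return a drop reason (``"short"`` / ``"low_quality"``) or None to keep.

    Length uses a strict inequality (a 15 bp read fails, 16 bp passes); the
    low-quality rule drops when the below-threshold fraction is >= the cap.
    """
    for read in (pair.r1, pair.r2):
        if len(read) <= params.min_len_exclusive:
            return DROP_SHORT
    for read in (pair.r1, pair.r2):
        if _lowq_fraction(read, params.q_threshold) >= params.max_lowq_fraction:
            return DROP_LOW_QUALITY
    return None


@dataclass
class QCReport:
    total: int = 0
    kept: int = 0
    dropped: dict[str, int] = field(default_factory=lambda: {DROP_SHORT: 0, DROP_LOW_QUALITY: 0})

    def check_conservation(self) -> None:
        from .errors import ConservationError
        if self.kept + sum(self.dropped.values()) != self.total:
            raise ConservationError(
                f"QC conservation violated: kept {self.kept} + dropped "
                f"{self.dropped} != total {self.total}"
            )


def preprocess_pair(pair: ReadPair, params: QCParams) -> tuple[ReadPair, str | None]:
    """Apply trim -> clip -> filter to one pair; returns (pair, drop_reason)."""
    reads = []
    for read in (pair.r1, pair.r2):
        read = trim_3prime(read, params.trim_to)
        read = clip_adapters(read, params.adapters, params.adapter_min_overlap)
        reads.append(read)
    cleaned = ReadPair(reads[0], reads[1])
    return cleaned, filter_pair(cleaned, params)


def run_qc(pairs: Iterable[ReadPair], params: QCParams,
           report: QCReport | None = None) -> Iterator[ReadPair]:
    """Generator applying the QC chain; tallies into ``report`` and asserts
    conservation when the input is exhausted."""
    if report is None:
        report = QCReport()
    for pair in pairs:
        report.total += 1
        cleaned, reason = preprocess_pair(pair, params)
        if reason is None:
            report.kept += 1
            yield cleaned
        else:
            report.dropped[reason] = report.dropped.get(reason, 0) + 1
    report.check_conservation()


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33 only; plain or gzip by file extension)
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _strip_mate_suffix(title: str) -> str:
    name = title.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    return name


def read_fastq(path: str | Path, mate: int) -> Iterator[ReadRecord]:
    """Iterate ReadRecords from one FASTQ file (Phred+33)."""
    with _open_text(path) as handle:
        iterator = FastqGeneralIterator(handle)
        n = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(f"{path}: malformed FASTQ at record {n + 1}: {exc}") from exc
            n += 1
            quals = tuple(q - 33 for q in qual.encode("ascii"))
            yield ReadRecord(_strip_mate_suffix(title), mate, seq.upper(), quals)


def iter_read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Pair mates by record order across two files; ids must agree."""
    from itertools import zip_longest

    it1 = read_fastq(r1_path, 1)
    it2 = read_fastq(r2_path, 2)
    for n, (r1, r2) in enumerate(zip_longest(it1, it2), start=1):
        if r1 is None or r2 is None:
            raise ParseError(f"{r1_path} and {r2_path} have different record counts")
        if r1.read_id != r2.read_id:
            raise ParseError(
                f"record {n}: mate id mismatch {r1.read_id!r} vs {r2.read_id!r}"
            )
        yield ReadPair(r1, r2)


def iter_interleaved(path: str | Path) -> Iterator[ReadPair]:
    """Pair mates from one interleaved FASTQ (r1, r2, r1, r2, ...)."""
    records = read_fastq(path, 1)
    for n, r1 in enumerate(records, start=1):
        r2 = next(records, None)
        if r2 is None:
            raise ParseError(f"{path}: odd record count; record {2 * n - 1} has no mate")
        r2 = ReadRecord(r2.read_id, 2, r2.sequence, r2.qualities)
        if r1.read_id != r2.read_id:
            raise ParseError(f"{path}: interleaved mate id mismatch at pair {n}")
        yield ReadPair(r1, r2)


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            qual = "".join(chr(q + 33) for q in rec.qualities)
            handle.write(f"@{rec.read_id}/{rec.mate}\n{rec.sequence}\n+\n{qual}\n")
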