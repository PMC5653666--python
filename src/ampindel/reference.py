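"""Amplicon reference model: flanked target locus, guide+PAM window, and the
exact-match suffix-array index used to anchor read termini.

The reference is a short PCR amplicon (target locus plus genomic flanks).
Coordinates are 0-based half-open internally; reports convert to 1-based
genomic coordinates via ``genomic_offset``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO

from .errors import ConfigurationError, ParseError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC wildcard handling is restricted to N (used for NGG-style PAM specs).
_N_MATCHES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconReference:
    """A flanked amplicon reference with its sgRNA/PAM annotation.

    ``guide_interval`` and ``pam_interval`` are 0-based half-open intervals on
    ``sequence``; ``genomic_offset`` is the 1-based genomic coordinate of the
    first base of ``sequence``. ``frame_offset`` is the codon phase of the
    first guide base and is carried for reporting only.
    """

    locus_id: str
    sequence: str
    genomic_contig: str
    genomic_offset: int
    guide_interval: tuple[int, int]
    pam_interval: tuple[int, int]
    guide_strand: str = "+"
    frame_offset: int = 0
    flank_len: int = 10

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ConfigurationError("reference sequence is empty")
        if not set(seq) <= DNA_ALPHABET:
            bad = sorted(set(seq) - DNA_ALPHABET)
            raise ConfigurationError(f"reference contains non-DNA characters: {bad}")
        if self.guide_strand not in {"+", "-"}:
            raise ConfigurationError(f"guide_strand must be '+' or '-', got {self.guide_strand!r}")
        if self.frame_offset not in {0, 1, 2}:
            raise ConfigurationError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")
        if len(seq) <= 2 * self.flank_len:
            raise ConfigurationError(
                f"sequence length {len(seq)} must exceed twice the flank length {self.flank_len}"
            )
        for name, (a, b) in (("guide_interval", self.guide_interval),
                             ("pam_interval", self.pam_interval)):
            if not (0 <= a < b <= len(seq)):
                raise ConfigurationError(f"{name} {a, b} out of bounds for length {len(seq)}")
        g0, g1 = self.guide_interval
        p0, p1 = self.pam_interval
        if max(g0, p0) < min(g1, p1):
            raise ConfigurationError("guide and PAM intervals overlap")
        # PAM sits 3' of the guide on '+', mirrored (5' in reference coords) on '-'.
        if self.guide_strand == "+" and p0 != g1:
            raise ConfigurationError("PAM must be immediately 3' of the guide on '+'")
        if self.guide_strand == "-" and p1 != g0:
            raise ConfigurationError("PAM must be immediately adjacent (reference-left) of the guide on '-'")

    @property
    def guide_seq(self) -> str:
        g0, g1 = self.guide_interval
        s = self.sequence[g0:g1]
        return s if self.guide_strand == "+" else revcomp(s)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class WindowSpec:
    """The sgRNA+PAM summarization window: a contiguous 0-based half-open
    interval plus the minimum alignment overlap required for a read pair to
    be counted at the locus."""

    interval: tuple[int, int]
    min_overlap: int = 20

    def __post_init__(self) -> None:
        a, b = self.interval
        if not a < b:
            raise ConfigurationError(f"window interval {self.interval} is empty")
        if self.min_overlap < 1:
            raise ConfigurationError("min_overlap must be >= 1")

    def overlap(self, start: int, end: int) -> int:
        """Length of the overlap between [start, end) and the window."""
        a, b = self.interval
        return max(0, min(end, b) - max(start, a))


def window_of(reference: AmpliconReference, min_overlap: int = 20) -> WindowSpec:
    """Union span of the guide and PAM intervals.

    Adjacency is guaranteed by the reference invariants, so the union is
    contiguous; a gap between the two intervals is a configuration error.
    """
    g0, g1 = reference.guide_interval
    p0, p1 = reference.pam_interval
    if g1 != p0 and p1 != g0:
        raise ConfigurationError("guide and PAM intervals are not adjacent")
    return WindowSpec(interval=(min(g0, p0), max(g1, p1)), min_overlap=min_overlap)


@dataclass(frozen=True)
class SuffixArrayIndex:
    """Suffix order of the reference plus binary-search exact lookup.

    The contract is the exact-match result set: ``locate`` returns exactly the
    start positions a naive scan would, in sorted order. Auxiliary tables of
    an enhanced suffix array are an optional accelerator, not part of the
    contract; plain binary search on the order is sufficient at amplicon
    scale.
    """

    text: str
    order: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.text)

    def locate(self, query: str) -> list[int]:
        return locate_exact(self, query)


def build_index(reference: AmpliconReference | str) -> SuffixArrayIndex:
    """Build the suffix-array index of a reference (or bare sequence)."""
    text = reference.sequence if isinstance(reference, AmpliconReference) else str(reference).upper()
    if not text:
        raise ConfigurationError("cannot index an empty sequence")
    order = tuple(sorted(range(len(text)), key=lambda i: text[i:]))
    return SuffixArrayIndex(text=text, order=order)


def locate_exact(index: SuffixArrayIndex, query: str) -> list[int]:
    """All start positions where ``query`` occurs verbatim, sorted ascending.

    N never matches (queries containing N return no hits); an empty result is
    not an error.
    """
    if not query:
        raise ValueError("query must be non-empty")
    query = query.upper()
    if "N" in query:
        return []
    text, order = index.text, index.order
    m = len(query)

    def prefix(i: int) -> str:
        p = text[order[i]: order[i] + m]
        return p

    # Lower bound: first suffix whose m-prefix >= query.
    lo, hi = 0, len(order)
    while lo < hi:
        mid = (lo + hi) // 2
        if prefix(mid) < query:
            lo = mid + 1
        else:
            hi = mid
    start = lo
    # Upper bound: first suffix whose m-prefix > query.
    hi = len(order)
    while lo < hi:
        mid = (lo + hi) // 2
        if prefix(mid) <= query:
            lo = mid + 1
        else:
            hi = mid
    # N in the reference compares as a literal and the query is N-free, so
    # every suffix in [start, lo) is a verbatim occurrence.
    return sorted(order[i] for i in range(start, lo))


def _match_with_n(pattern: str, observed: str) -> bool:
    """Pattern match where N in *pattern* matches any of ACGT."""
    if len(pattern) != len(observed):
        return False
    return all(p == o or (p == "N" and o in _N_MATCHES) for p, o in zip(pattern, observed))


def _find_all(text: str, query: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = text.find(query, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def load_reference(fasta_path: str | Path, config_path: str | Path) -> AmpliconReference:
    """Load a single-record FASTA plus its structured config.

    Config keys: locus_id, genomic_contig, genomic_offset, flank_len,
    guide_seq, pam_seq, guide_strand, frame_offset. The guide is located in
    the reference by exact match (must be unique); the PAM interval is placed
    adjacent to it and validated against ``pam_seq`` (N = wildcard).
    """
    try:
        record = SeqIO.read(str(fasta_path), "fasta")
    except ValueError as exc:
        raise ParseError(f"reference FASTA {fasta_path}: {exc}") from exc
    sequence = str(record.seq).upper()

    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"reference config {config_path} is not a mapping")
    required = {"locus_id", "genomic_contig", "genomic_offset", "guide_seq", "pam_seq", "guide_strand"}
    missing = required - cfg.keys()
    if missing:
        raise ConfigurationError(f"reference config missing keys: {sorted(missing)}")

    strand = str(cfg["guide_strand"])
    guide_seq = str(cfg["guide_seq"]).upper()
    pam_seq = str(cfg["pam_seq"]).upper()
    if strand not in {"+", "-"}:
        raise ConfigurationError(f"guide_strand must be '+' or '-', got {strand!r}")

    target = guide_seq if strand == "+" else revcomp(guide_seq)
    hits = _find_all(sequence, target)
    if len(hits) != 1:
        raise ConfigurationError(
            f"guide sequence must occur exactly once in the reference; found {len(hits)} occurrences"
        )
    g0 = hits[0]
    g1 = g0 + len(guide_seq)
    plen = len(pam_seq)
    if strand == "+":
        pam_interval = (g1, g1 + plen)
        expected = pam_seq
    else:
        pam_interval = (g0 - plen, g0)
        expected = revcomp(pam_seq)
    if pam_interval[0] < 0 or pam_interval[1] > len(sequence):
        raise ConfigurationError("PAM interval falls outside the reference")
    observed = sequence[pam_interval[0]: pam_interval[1]]
    if not _match_with_n(expected, observed):
        raise ConfigurationError(
            f"PAM mismatch: expected {expected} (from {pam_seq}) but reference has {observed}"
        )

    return AmpliconReference(
        locus_id=str(cfg["locus_id"]),
        sequence=sequence,
        genomic_contig=str(cfg["genomic_contig"]),
        genomic_offset=int(cfg["genomic_offset"]),
        guide_interval=(g0, g1),
        pam_interval=pam_interval,
        guide_strand=strand,
        frame_offset=int(cfg.get("frame_offset", 0)),
        flank_len=int(cfg.get("flank_len", 10)),
    )
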