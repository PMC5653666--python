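"""Paired-end amplicon read simulator with a known allele spectrum.

Fragments are drawn from indel haplotypes of a toy amplicon and read inward
as 150 bp mates, with substitution errors and a plateau-then-decay quality
profile. A truth table records each pair's source allele, so every pipeline
stage can be tested against ground truth without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError
from .events import IndelEvent
from .preprocess import ReadPair, ReadRecord, write_fastq
from .reference import AmpliconReference, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Deterministic 240 bp toy amplicon (all 10-mers unique; guide at [110,130),
#: NGG PAM at [130,133)). Stands in for a short PCR amplicon around a CRISPR
#: cut site, 10 bp genomic flanks included.
DEMO_SEQUENCE = (
    "GCGCCGTCTCGTTAAATGCAGCTCTGAACACCGCTCGCTCTCGCTAAGTTTAGGATCGTCGTTCAGTTGG"
    "TACGATCGTTTCATTGGTACCTGAGTAGGATCATCCCGCCCACGTGCCAAACAGAATGCCTGGAAGACCC"
    "GTCGCACTACGGCACAGTGGATCGACATCACCAGCGGCATTCTCGATGCCCTGTTGCCGTGACTGCCTAT"
    "ATGCGCTACCAATTGCATCATGGGATCCAC"
)


def demo_reference() -> AmpliconReference:
    """The canonical synthetic amplicon used by fixtures and examples."""
    return AmpliconReference(
        locus_id="toy_kras_ex3",
        sequence=DEMO_SEQUENCE,
        genomic_contig="chr6",
        genomic_offset=145_246_771,
        guide_interval=(110, 130),
        pam_interval=(130, 133),
        guide_strand="+",
        frame_offset=0,
        flank_len=10,
    )


# Canonical demo alleles at the cut site (3 bp upstream of the PAM). All
# positions are already left-aligned on DEMO_SEQUENCE.
def demo_allele(label: str, fraction: float) -> "AlleleSpec":
    events = {
        "wt": (),
        "del1": (IndelEvent(127, "del", 1),),          # frameshift
        "del3": (IndelEvent(125, "del", 3),),          # non-frameshift
        "del95": (IndelEvent(70, "del", 95),),         # long frameshift
        "ins2": (IndelEvent(127, "ins", 2, "TC"),),    # frameshift
    }[label]
    return AlleleSpec(label=label, events=events, fraction=fraction)


@dataclass(frozen=True)
class AlleleSpec:
    label: str
    events: tuple[IndelEvent, ...]
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError(f"allele {self.label}: fraction must lie in [0, 1]")

    @property
    def net(self) -> int:
        return sum(e.net for e in self.events)


def validate_spectrum(spectrum: Sequence[AlleleSpec]) -> None:
    total = sum(a.fraction for a in spectrum)
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"allele fractions sum to {total}, expected 1")
    labels = [a.label for a in spectrum]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("allele labels must be unique")


@dataclass(frozen=True)
class SimParams:
    n_pairs: int = 1000
    read_len: int = 150
    fragment_len_mean: float = 160.0
    fragment_len_sd: float = 15.0
    min_fragment_len: int = 40
    substitution_rate: float = 0.001
    q_plateau: int = 37
    q_floor: int = 20
    decay_cycles: int = 30
    quality_jitter: int = 2
    adapter_readthrough: bool = False
    adapter: str = "CTGTCTCTTATACACATCT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigurationError("n_pairs must be >= 1")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ConfigurationError("substitution_rate must lie in [0, 1]")
        if self.read_len < 1 or self.min_fragment_len < 1:
            raise ConfigurationError("read_len/min_fragment_len must be >= 1")


def make_haplotype(reference: AmpliconReference, allele: AlleleSpec) -> str:
    """Apply the allele's events right-to-left so positions stay valid."""
    seq = reference.sequence
    ordered = sorted(allele.events, key=lambda e: e.ref_pos, reverse=True)
    occupied: list[tuple[int, int]] = []
    for event in allele.events:
        a, b = event.ref_pos, event.ref_pos + (event.length if event.kind == "del" else 0)
        for oa, ob in occupied:
            if max(a, oa) < min(b, ob) or (a == oa and event.kind == "ins"):
                raise ConfigurationError(f"allele {allele.label}: overlapping events")
        occupied.append((a, b))
        if b > len(seq):
            raise ConfigurationError(f"allele {allele.label}: event extends past reference")
    for event in ordered:
        if event.kind == "del":
            seq = seq[:event.ref_pos] + seq[event.ref_pos + event.length:]
        else:
            seq = seq[:event.ref_pos] + event.inserted_seq + seq[event.ref_pos:]
    return seq


@dataclass(frozen=True)
class TruthRecord:
    pair_id: str
    allele: str
    fragment_start: int
    fragment_len: int


def _quality_profile(params: SimParams) -> np.ndarray:
    """High plateau with linear 3' decay over the final cycles."""
    L = params.read_len
    prof = np.full(L, params.q_plateau, dtype=np.int64)
    d = min(params.decay_cycles, L)
    if d > 0:
        ramp = np.linspace(params.q_plateau, params.q_floor, d + 1)[1:]
        prof[L - d:] = np.round(ramp).astype(np.int64)
    return prof


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_read_pairs(
    reference: AmpliconReference,
    spectrum: Sequence[AlleleSpec],
    params: SimParams,
    id_prefix: str = "sim",
) -> tuple[list[ReadPair], list[TruthRecord]]:
    """Draw read pairs from the allele spectrum; deterministic per seed."""
    validate_spectrum(spectrum)
    rng = np.random.default_rng(params.seed)
    haplotypes = [make_haplotype(reference, a) for a in spectrum]
    for allele, hap in zip(spectrum, haplotypes):
        if params.min_fragment_len > len(hap):
            raise ConfigurationError(
                f"allele {allele.label}: minimum fragment length {params.min_fragment_len} "
                f"exceeds haplotype length {len(hap)}"
            )
    fractions = np.array([a.fraction for a in spectrum])
    profile = _quality_profile(params)
    pairs: list[ReadPair] = []
    truth: list[TruthRecord] = []
    for i in range(params.n_pairs):
        ai = int(rng.choice(len(spectrum), p=fractions))
        hap = haplotypes[ai]
        frag_len = int(np.clip(round(rng.normal(params.fragment_len_mean, params.fragment_len_sd)),
                               params.min_fragment_len, len(hap)))
        start = int(rng.integers(0, len(hap) - frag_len + 1))
        fragment = hap[start: start + frag_len]
        pair_id = f"{id_prefix}_{i:06d}"
        mates = []
        for mate, template in ((1, fragment), (2, revcomp(fragment))):
            seq = template[: params.read_len]
            if params.adapter_readthrough and len(seq) < params.read_len:
                seq = (seq + params.adapter)[: params.read_len]
            seq = _mutate(seq, rng, params.substitution_rate)
            quals = profile[: len(seq)].copy()
            if params.quality_jitter:
                quals = quals + rng.integers(-params.quality_jitter,
                                             params.quality_jitter + 1, size=len(seq))
            quals = np.clip(quals, 2, 41)
            mates.append(ReadRecord(pair_id, mate, seq, tuple(int(q) for q in quals)))
        pairs.append(ReadPair(mates[0], mates[1]))
        truth.append(TruthRecord(pair_id, spectrum[ai].label, start, frag_len))
    return pairs, truth


def write_truth_table(truth: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tallele\tfragment_start\tfragment_len\n")
        for rec in truth:
            fh.write(f"{rec.pair_id}\t{rec.allele}\t{rec.fragment_start}\t{rec.fragment_len}\n")


def simulate_to_files(
    reference: AmpliconReference,
    spectrum: Sequence[AlleleSpec],
    params: SimParams,
    r1_path: str | Path,
    r2_path: str | Path,
    truth_path: str | Path | None = None,
    id_prefix: str = "sim",
) -> list[TruthRecord]:
    pairs, truth = simulate_read_pairs(reference, spectrum, params, id_prefix=id_prefix)
    write_fastq((p.r1 for p in pairs), r1_path)
    write_fastq((p.r2 for p in pairs), r2_path)
    if truth_path is not None:
        write_truth_table(truth, truth_path)
    return truth


def write_reference_files(reference: AmpliconReference, fasta_path: str | Path,
                          config_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{reference.locus_id}\n")
        seq = reference.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    g0, g1 = reference.guide_interval
    p0, p1 = reference.pam_interval
    guide = reference.sequence[g0:g1] if reference.guide_strand == "+" else revcomp(reference.sequence[g0:g1])
    pam = reference.sequence[p0:p1] if reference.guide_strand == "+" else revcomp(reference.sequence[p0:p1])
    cfg = {
        "locus_id": reference.locus_id,
        "genomic_contig": reference.genomic_contig,
        "genomic_offset": reference.genomic_offset,
        "flank_len": reference.flank_len,
        "guide_seq": guide,
        "pam_seq": pam,
        "guide_strand": reference.guide_strand,
        "frame_offset": reference.frame_offset,
    }
    import yaml
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


#: Spectra used by the canonical fixture bundle. Group A has an NFS fraction
#: of 0.5 among mutant pairs, group B 0.1 (enrichment power); the wt and
#: mixed samples exercise the caller itself.
FIXTURE_SPECTRA = {
    "wt": [("wt", 1.0)],
    "mixed": [("wt", 0.6), ("del1", 0.3), ("del3", 0.1)],
    "group_a": [("wt", 0.2), ("del1", 0.4), ("del3", 0.4)],
    "group_b": [("wt", 0.2), ("del1", 0.72), ("del3", 0.08)],
}


def _spectrum(name: str) -> list[AlleleSpec]:
    return [demo_allele(label, frac) for label, frac in FIXTURE_SPECTRA[name]]


def write_fixture_set(out_dir: str | Path, seed: int = 0,
                      n_pairs: int = 300) -> dict:
    """Emit the canonical test bundle: toy reference + 14 simulated samples
    (clean WT, mixed spectrum, and two 6-sample enrichment groups), each with
    a truth table; returns (and writes) a manifest of seeds and spectra."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = demo_reference()
    write_reference_files(reference, out / "reference.fasta", out / "reference.yaml")

    samples: list[tuple[str, str, SimParams]] = []
    samples.append(("wt", "wt",
                    SimParams(n_pairs=n_pairs, substitution_rate=0.0, seed=seed)))
    samples.append(("mixed", "mixed",
                    SimParams(n_pairs=n_pairs, seed=seed + 1)))
    for i in range(6):
        samples.append((f"a{i + 1}", "group_a", SimParams(n_pairs=n_pairs, seed=seed + 10 + i)))
        samples.append((f"b{i + 1}", "group_b", SimParams(n_pairs=n_pairs, seed=seed + 20 + i)))

    manifest: dict = {"seed": seed, "n_pairs": n_pairs, "samples": {}, "groups": {}}
    for sample_id, spectrum_name, params in samples:
        r1 = out / f"{sample_id}.r1.fastq.gz"
        r2 = out / f"{sample_id}.r2.fastq.gz"
        truth = out / f"{sample_id}.truth.tsv"
        simulate_to_files(reference, _spectrum(spectrum_name), params, r1, r2, truth,
                          id_prefix=sample_id)
        manifest["samples"][sample_id] = {
            "spectrum": spectrum_name,
            "seed": params.seed,
            "r1": r1.name, "r2": r2.name, "truth": truth.name,
        }
    manifest["groups"] = {
        "A": [f"a{i + 1}" for i in range(6)],
        "B": [f"b{i + 1}" for i in range(6)],
    }
    with open(out / "groups.tsv", "w") as fh:
        fh.write("sample_id\tgroup\n")
        for group, ids in manifest["groups"].items():
            for sid in ids:
                fh.write(f"{sid}\t{group}\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
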