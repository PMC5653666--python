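# ampindel

Anchored amplicon indel calling and frameshift-enrichment analysis for
CRISPR editing outcomes.

`ampindel` re-implements, as a tested and reusable pipeline, a bespoke
amplicon deep-sequencing analysis for quantifying CRISPR-induced indels at a
targeted locus and for comparing editing-outcome spectra between treatment
groups:

1. **QC** — paired-end FASTQ (Phred+33) reads are trimmed to 120 bp,
   Nextera adapter traces are clipped, pairs with a mate ≤ 15 bp or with
   ≥ 50% of bases below Q30 are dropped.
2. **Anchored alignment** — the amplicon reference (target locus + 10 bp
   genomic flanks) is indexed with a suffix array; read termini are anchored
   by exact 10-mer lookup with a unit-step sliding window and a 10 bp
   soft-clip limit on both strands; an optimal affine-gap Smith–Waterman
   alignment is run between the maximally distanced anchors; alignments with
   more than 4 mismatches are rejected.
3. **Event calling** — properly oriented pairs are reconciled (mates that
   both cover an event location must both support it), indels are
   left-aligned to canonical form, and pairs are summarized within the
   sgRNA+PAM window (≥ 20 bp alignment overlap required). Mutant pairs are
   classified frameshift (FS) vs non-frameshift (NFS) by the net indel
   length mod 3.
4. **Enrichment** — per-sample NFS/FS counts are compared across all
   pairwise combinations of two groups with a Pearson χ²-test of
   proportions (no continuity correction by default; significance = p < α
   and NFS enriched in group A).
5. **Simulation** — a deterministic read simulator generates paired-end
   reads from known allele spectra (including a canonical 95 bp deletion
   allele) with substitution errors, 3′ quality decay and truth tables, so
   the whole pipeline is testable without any external data.

## CLI

```sh
# validate a reference and report the guide+PAM window
ampindel index ref.fasta ref.yaml

# write the canonical synthetic fixture bundle (reference + 14 samples)
ampindel simulate out_dir --seed 1 --n-pairs 300

# call indel events for one sample
ampindel call sample.r1.fastq.gz sample.r2.fastq.gz \
    --ref-fasta out_dir/reference.fasta --ref-config out_dir/reference.yaml \
    --out-dir calls --sample-id sample1

# pairwise NFS-enrichment comparison between two groups
ampindel compare --groups out_dir/groups.tsv --summaries calls --out-dir cmp
```

`call` writes a per-sample summary TSV, an allele table TSV, minimal
VCF-style calls and a JSON run report with all conservation tallies (the
identity *input pairs = QC-dropped + unaligned/improper + off-window + wt +
mutant + discordant* is enforced on every run). `compare` writes the full
comparison grid and a verdict (`n_significant / n_comparisons`).

The reference config is YAML with keys `locus_id`, `genomic_contig`,
`genomic_offset` (1-based coordinate of the first reference base),
`flank_len`, `guide_seq`, `pam_seq` (N = wildcard, e.g. `NGG`),
`guide_strand` and `frame_offset`; the guide is located in the FASTA by
exact match at load time.

All QC/alignment/window/test parameters default to the published pipeline
settings and can be overridden by CLI flags.

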