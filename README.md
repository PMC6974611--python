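# eqascore

A proficiency-testing (EQA) engine for clinical NGS variant calling. Given
many laboratories' VCF+BED submissions, it:

- **normalizes** every call (multi-allelic decomposition, MNP→SNP
  splitting, minimal representation, reference-guided left alignment) so
  equivalent calls compare equal;
- **derives a participant-consensus truth set** by voting: a call enters
  the consensus iff its site lies in ≥7 labs' declared ROI and ≥75% of
  those labs made the identical call (both thresholds configurable;
  fractions compared with exact rational arithmetic);
- **builds assessable regions** under four scheme policies (exons ±2 bp;
  consensus-variant-containing exons ±2 bp; exact somatic variant spans;
  ROI pruned to ±1000 bp of reported variants);
- **scores concordance** per lab (agree/disagree/extra/missing →
  TP/FP/FN → sensitivity, precision, F-score), with genotype matching for
  germline and alternate-allele matching for somatic schemes, restricted
  to SNPs and indels <50 bp inside assessable ∩ declared ROI;
- **computes QC metrics** (FASTQ Q20/Q30, coverage thresholds,
  on/off-target, error rate, insert size, Ti/Tv, Het:Hom, call quality)
  and benchmarks each lab against the cohort;
- **simulates cohorts**: reproducible reference genomes with repeat
  tracts, planted truth variants, and labs with configurable
  false-negative/false-positive rates and representation quirks (merged
  MNPs, right-shifted indels, decoy multi-allelic records), so the whole
  pipeline is testable offline.

## CLI

```sh
# validate a submission
eqa validate sub.vcf --bed sub.bed

# ingest and normalize one lab
eqa ingest --vcf sub.vcf --bed sub.bed --scheme germline --reference ref.fasta

# generate a synthetic cohort
eqa simulate --labs 10 --scheme germline --seed 7 --out cohort/

# full run from a YAML config (see tests/test_cli.py for the shape)
eqa run --config run.yaml

# QC metrics
eqa metrics --fastq R1.fastq --vcf sub.vcf --aln sub.aln --roi sub.bed
```

Exit codes: 0 ok, 1 fatal diagnostics, 2 configuration error.

A `run.yaml` names the scheme (`germline`/`somatic`), the assessable
policy (`germline_exon2bp`, `germline_consensus_exon2bp`, `somatic_exact`,
`somatic_proximity`), the truth mode (`consensus` or `eqa_merge` with a
pre-established truth VCF), per-lab `vcf`/`bed` paths, and optionally a
reference FASTA and exon BED.

## Layout

| module | contents |
|---|---|
| `eqascore.variant_model` | normalization primitives and domain types |
| `eqascore.regions` | canonical interval sets (0-based half-open) |
| `eqascore.formats_io` | VCF/BED/FASTA validation, reading, writing |
| `eqascore.consensus_engine` | consensus voting, assessable policies, truth merge |
| `eqascore.concordance` | classification, scores, sequencing efficiency |
| `eqascore.qc_metrics` | FASTQ/alignment/VCF metrics, cohort benchmark |
| `eqascore.synthetic_cohort` | reference/truth/cohort simulator |
| `eqascore.cli` | orchestration (`run_eqa`), reports, `eqa` CLI |

Coordinates are 0-based half-open internally; VCF's 1-based POS and BED's
native convention are converted at the I/O boundary.
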