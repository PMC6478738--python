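# phasecall

SNV calling, read-backed phasing and filtering for noisy long reads, plus a
diploid read simulator and evaluation metrics. The toolkit implements:

- **`formats_io`** — SAM/VCF/FASTA/FASTQ/BED I/O (via pysam) and pileup
  construction with per-strand ref/alt/other/deletion tallies.
- **`sew_phase`** — single-sample, reference-panel-free phasing: reads are
  assigned to two haplotypes by EM over per-site, per-haplotype alternate-base
  emission probabilities θ, with base-call noise entering through
  phred-derived probabilities. Derived QC metrics: per-site phase entropy
  `PE = -log10(θ₁θ₂(1−θ₁)(1−θ₂))` and per-haplotype forward-strand counts
  SB1/SB2.
- **`snv_caller`** — per-site frequency-based diploid caller with
  contamination-adjusted expected allele fractions (binomial genotype
  likelihoods; default c_het = 0.7, c_hom = 0.1, minimum 5 alternate
  observations per site).
- **`annotate_filter`** — annotation battery (homopolymer ≥ 5 bp including
  flanks, coverage < 40×, ≥ 40% in-read deletions, exact-binomial strand
  imbalance, low QUAL, low PE) and the two filter policies
  `qual-contamination` and `phasing-heuristics`.
- **`diploid_simulator`** — synthetic diploid reference with phased truth
  SNVs and error-bearing reads (truncated-normal per-read accuracy,
  configurable substitution:insertion:deletion ratio, e.g. 60:35:5 or
  30:30:40), emitting FASTQ plus exact truth alignments as SAM — no aligner
  needed.
- **`eval_metrics`** — alignment error rates (e_sub, e_del, e_ins, p_id),
  TP/FP/FN classification with genotype-mismatch double counting,
  FDR/FNR/F1, switch error rate (all pairs or read-spanned), proportions.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a
0.5 Mb / 80× simulation that takes a couple of minutes.

## CLI

```sh
phasecall simulate --length 100000 --depth-per-haplotype 40 --seed 1 --out run/
phasecall call     --sam run/reads.sam --ref run/reference.fasta --out run/
phasecall phase    --sam run/reads.sam --vcf run/calls.vcf --ref run/reference.fasta --out run/
phasecall filter   --vcf run/phased.vcf --sam run/reads.sam --ref run/reference.fasta \
                   --policy phasing-heuristics --out run/
phasecall evaluate --calls run/filtered.vcf --truth run/truth.vcf --sam run/reads.sam --out run/
phasecall end-to-end --length 100000 --seed 1 --out run/
```

Every subcommand writes a `*.summary.json`; `end-to-end` chains
simulate → call → phase → filter → evaluate into one consolidated report.
All randomness derives from `--seed`.

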