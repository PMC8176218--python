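# hibernaseq

A toolkit for analysing transcription and steady-state RNA dynamics across
the torpor–arousal cycle of a hibernator, exercised end-to-end on synthetic
data with a written truth table. It implements:

- **`hibernaseq.simulate`** — synthetic genomes, gene models, strand-specific
  nascent coverage with state-dependent 3′ readthrough tails, negative-binomial
  count matrices following reference pattern templates (with a sex covariate),
  allele-count tables containing both true A-to-G editing and genomic
  polymorphisms visible in two assays, and junction-count tables with
  cold-shifted PSI. Every simulated quantity is recorded in a truth table; in
  `deterministic` mode downstream estimators must recover it exactly.
- **`hibernaseq.segmentation`** — transcribed-segment calling from pooled
  per-state coverage, via a two-state Poisson-emission HMM (EM + Viterbi) or
  a deterministic smoothed-threshold rule, plus strand-aware cross-state
  merging into maximal transcript regions.
- **`hibernaseq.readthrough`** — per-gene 3′ extension beyond the annotated
  TTS, TTS-offset distributions, the mean between-state extension difference
  with bootstrap SE, the implied elongation rate (kb/min), a revised gene
  annotation (3′ substitution → merge with `:`-joined names → 500-nt TSS
  trim), coverage-sum quantification, TPM, and per-state metagene profiles.
- **`hibernaseq.expression`** — median-of-ratios normalization, a
  pseudocounted log-level expression filter, gene-wise negative-binomial
  likelihood-ratio tests of state (controlling for sex), BH adjustment,
  Pearson-correlation assignment of DE genes to reference pattern templates
  (r ≥ 0.8), pairwise log2 fold changes, and GC-content comparisons.
- **`hibernaseq.concordance`** — DE-set intersection between the steady-state
  and nascent assays (LT ≡ Ar), fold-change correlations, sign-quadrant
  classification (including the stable-RNA and deferred-expression
  quadrants), and 3′-region k-mer enrichment with binomial tests.
- **`hibernaseq.editing`** — coverage filtering of allele-count tables,
  G-tests of state variability and pairwise differential editing,
  strand-resolved substitution spectra, the cross-assay polymorphism filter,
  genomic-region classification, and hypergeometric overlap tests.
- **`hibernaseq.splicing`** — PSI per junction, summer-dominant junction
  identification, Dirichlet-posterior dPSI significance (default criterion:
  99.9% probability of |dPSI| ≥ 0.2, with a closed-form check for 2-junction
  cases), and pattern classification of significant events.

All coordinates are 0-based, half-open; the TTS of a minus-strand gene is
its interval start. All file formats are plain text: FASTA, BED6/BED12,
per-strand bedGraph, TSV, YAML, JSON.

## CLI

```sh
hibernaseq simulate --config sim.yaml --out data/ --seed 7
hibernaseq segment --data data/ --out segs/ --method hmm
hibernaseq readthrough --data data/ --segments segs/ --out rt/
hibernaseq metagene --data data/ --out meta/ --anchor TTS
hibernaseq express --data data/ --out de/ --de-q 0.001
hibernaseq concord --rna-de de_rna.tsv --nascent-de de_gro.tsv --out conc/
hibernaseq edit --data data/ --out edit/
hibernaseq splice --data data/ --out splice/ --state-a SA --state-b LT
```

`sim.yaml` keys mirror `hibernaseq.simulate.SimConfig` fields (states,
replicates, extension truth per state, pattern mix, editing/splicing knobs).

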