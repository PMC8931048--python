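# epistate

Integrative epigenomic analysis of a two-genotype cohort, built as a
tested, reusable pipeline over interval-level multi-omics data:

- **Consensus peak calling** across replicates with a weak/stringent
  double p-value threshold and Fisher evidence combination.
- **Chromatin-state segmentation**: Poisson binarization of count tracks,
  a product-Bernoulli hidden Markov model (Baum-Welch, Viterbi/posterior
  decoding), semantic state labelling, promoter occupancy, and a
  genotype state contrast.
- **State–expression association**: Mann-Whitney presence tests and
  Cuzick's trend test across occupancy-dosage buckets, implemented from
  the rank formulas with exact/permutation branches.
- **Gene-body (hydroxy)methylation**: coverage fractions, a
  dosage-vs-threshold expression model, and an isolated gene-body
  hypermethylation filter over DMR tables.
- **Genotype-specific distal enhancer discovery**: ATAC ∧ H3K27ac
  co-marking unique to the mutant genotype, catalog annotation, PWM
  scanning, and Fisher interval enrichment.
- **Target assignment**: basal-plus-extension regulatory domains with a
  TAD-boundary constraint, distance structure, and enhancer–expression
  association.
- **Integration**: OLS of log(count + 1) on epigenetic covariates with
  e^β − 1 effects, LMG relative-importance decomposition of R², and
  leverage/Cook's-distance exclusion with a single refit.
- **Single-cell heterogeneity**: per-cell diversity and specialization
  entropies, genotype comparison by two-sample KS, and TF-motif
  accessibility ranking.
- **Synthetic data**: a seeded generator producing a complete toy study
  (peaks, tracks, expression, DMRs, cell matrices) with planted ground
  truth, so the whole pipeline is testable end to end offline.

## CLI

```sh
# generate a synthetic study with planted ground truth
epistate simulate --seed 1 --out runs/study

# run every stage (consensus → states → methylation → cre → targets →
# integrate → scatac); each stage writes outputs plus a checksummed manifest
epistate all --study runs/study --run runs/out --seed 1

# or run stages individually, e.g.
epistate consensus --study runs/study --run runs/out
epistate cre --study runs/study --run runs/out
```

Exit codes: 0 success, 2 validation error, 3 parse error, 4 numeric
failure. Identical study + seed reproduce identical output checksums.

## Layout

```
src/epistate/
  core.py         coordinate types, interval algebra, BED/GFF3 I/O
  simulate.py     seeded synthetic study generator (planted ground truth)
  studyio.py      plain-text study serialization (BED/GFF3/TSV/MTX/JSON)
  consensus.py    multi-replicate consensus peak calling
  hmm.py          product-Bernoulli HMM (EM, Viterbi, brute-force oracle)
  states.py       binarization, labels, occupancy, genotype contrast
  ranktests.py    Mann-Whitney and Cuzick trend tests
  methylation.py  gene-body methylation model and DMR filter
  cre.py          genotype-specific CREs, PWM scan, enrichment
  targets.py      regulatory domains, TAD-filtered target assignment
  integration.py  multivariable model, LMG shares, diagnostics
  entropy.py      single-cell diversity/specialization, KS, motif ranking
  pipeline.py     in-memory orchestration of all stages
  cli.py          click-based command line
tests/            unit + property tests; test_acceptance.py holds the
                  acceptance criteria at their stated tolerances
scripts/acceptance.py   acceptance report generator
```
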