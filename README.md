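# toxtemp-gxe

Factorial toxicant-by-temperature transcriptomics pipeline for two-color
dye-swap microarray experiments, with a fully synthetic data generator so
every stage is testable offline.

The pipeline models a design in which nematode extracts from two
organophosphorus pesticide treatments (CPF, DZN) and their combination are
each hybridized against control extracts, at two rearing temperatures,
with six biological replicates per treatment in a dye-swap layout. It
provides:

- **`synthetic_data`** — simulator for raw two-channel spot intensities
  with planted per-gene effect structure (additive log2 coefficients over
  the CPF/DZN/Temp indicators and all interaction products),
  intensity-dependent dye bias, array-scale shifts, Gaussian spot noise,
  gross outliers and gene→GO / gene→domain annotation maps with planted
  detox-domain enrichment. Ground truth is returned for
  parameter-recovery testing.
- **`preprocess`** — MA decomposition, within-array loess normalization
  of M on A (local polynomial, tricube weights, robustifying
  iterations), between-array A-quantile normalization, channel
  reconstruction (A ± M/2), and recursive removal of observations whose
  externally studentized residual falls outside a two-sided 99.5%
  confidence interval (at most 6 removals per gene).
- **`diffexpr`** — per-gene OLS models (single-toxicant and the full
  factorial `CPF * DZN * Temp` with all interactions), coefficient
  t-tests, aliasing detection on rank-deficient designs, a
  transcript-permutation null distribution (each permutation shuffles one
  distinct transcript's values across observations), and a plug-in FDR
  estimate at the common −log10 p > 2 threshold.
- **`annotation_enrichment`** — upper-tail hypergeometric
  over-representation of GO terms and protein domains, with terms of
  fewer than 4 genes discarded and the universe restricted to annotated
  tested genes.
- **`detox_catalog`** — classification of genes into six detoxification
  families (CYP, SDR, UGT, GST, ABC via shipped domain-id vocabularies;
  NR from a curated gene list), with per-set counts and enrichment flags.
- **`pipeline_report`** — Venn partitions, overlap matrices, one-decimal
  percentage reporting (half-away-from-zero), and the end-to-end
  orchestrator producing a deterministic TSV/JSON report bundle.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(percentage reporting, exhaustive hypergeometric oracle, null
calibration, parameter recovery, outlier removal, aliasing,
normalization, end-to-end determinism). The statistical tests run at a
reduced scale (2,000 genes, 2,000 permutations) to stay within a few
minutes on one CPU.

## CLI

```sh
# full synthetic pipeline at a reduced scale
toxtemp-gxe all --config run.yaml --seed 17 --out results/run
```

where `run.yaml` can override any run setting, e.g.

```yaml
simulation:
  n_genes: 2000
  sigma_spot: 0.25
  dye_bias: [0.02, -0.3, 1.0]
  array_shift_sd: 0.2
n_perm: 2000
threshold: 2.0
```

Individual stages operate on the TSV intermediates:
`simulate`, `preprocess`, `scan`, `permute`, `enrich`, `detox`,
`report` (see `toxtemp-gxe <cmd> --help`). Every run writes a resolved
`run_config.yaml` and a `manifest.json` with SHA-256 digests of all
outputs; reruns with the same seed are byte-identical.

## Notes on the modeling choices

- The experimental design has no toxicant-free array, so an 8-term
  factorial on within-array log-ratios is rank-deficient (6 distinct
  cells). The pipeline therefore models per-channel normalized log2
  intensities, letting reference channels supply the toxicant-free cells
  at both temperatures; all 7 effect terms are then estimable. On
  ratio-level designs the aliased terms (`CPF:DZN`, `CPF:DZN:Temp`) are
  flagged per gene and never reported as numbers.
- The permutation FDR is the plug-in estimator
  `FDR(term) = [G · #(null p ≤ 10^−t) / n_perm] / R(term)` with `G`
  genes tested and `R` observed rejections.
- Significance uses the strict inequality −log10 p > threshold.
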