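# centipet

Centiloid-scale amyloid PET analysis toolkit: quantification primitives,
level-2 calibration to Centiloid (CL) units, amyloid-positivity threshold
estimators, and cross-sectional/longitudinal cohort statistics — all
exercisable end-to-end on synthetic cohorts with known ground truth.

## What it does

- **`centipet.synthetic`** — generators for every input the pipeline needs:
  paired calibration cohorts (young-control + AD groups with a linear
  method-to-standard relation), two-visit longitudinal cohorts with a
  configurable baseline-dependent accumulation-rate function,
  reference-tissue-model time–activity curves with known binding potential,
  and regional-mixing phantoms.
- **`centipet.quantify`** — duration-weighted window means, target/reference
  SUVr, reference-tissue Logan graphical binding potential, mixing-matrix
  (GTM-style) partial-volume correction, mean cortical index, and an
  optional NIfTI region-mean entry point.
- **`centipet.calibrate`** — the anchor map (group means pinned to CL 0 and
  CL 100) and level-2 affine calibration of any method to the CL scale with
  fit diagnostics and a JSON serialization.
- **`centipet.thresholds`** — three positivity-threshold estimators:
  conversion of a legacy native-unit threshold, the 95th-percentile
  specificity threshold over young controls, and a modified
  reliable-worsening threshold from a LOESS-smoothed annualized-rate curve
  with bootstrap confidence bands (integer CL grid).
- **`centipet.stats`** — positivity classification, stable-negative vs
  accumulator grouping, variance F tests (with Pitman–Morgan for paired
  data), paired t tests, two-tier significance (0.05 / 0.0005), intra-
  individual variability, effect size, and trial sample-size estimation.
- **`centipet.pipeline` / `centipet.cli`** — deterministic end-to-end runs
  over multiple method variants with delimited + JSON reports and a
  checksummed file manifest.

## CLI

```sh
centipet demo --seed 1 --outdir out/            # full pipeline, shipped config
centipet simulate --kind longitudinal --seed 1 --n 243 --out cohort.csv
centipet calibrate --cohort cal.csv --label myMethod --out eq.json
centipet thresholds --cohort cohort.csv --equation eq.json --yc cal.csv \
    --nboot 1000 --seed 1 --out thresholds.json
centipet stats --cohort cohort.csv --threshold 10.7 --out stats.json
centipet quantify --tacs tacs.csv --reference cerebellum --metric SUVr --out suvr.csv
centipet report --config run.yaml --outdir out/  # YAML/JSON run config
```

Reports comprise `report.json` (the complete results bundle),
`calibration_table.csv` and `longitudinal_table.csv` (method-by-quantity
summaries), per-method equation/threshold JSON, rate-curve tables for
plotting, and `manifest.json` with SHA-256 checksums.

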