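# reinstate

Analysis toolkit for multivoxel-pattern memory consolidation studies:

* **`reinstate.sim`** — a synthetic cohort generator that emulates a
  three-day object–scene learning design (stimulus catalog of themed
  scene/object pairs in 7 categories, adaptive learning-to-criterion,
  scanner retrieval sessions of 3 runs × [10 recent + 10 remote] trials)
  and produces trial-wise beta patterns with planted, parameterized effect
  structure (item-specific reinstatement loadings, category "gist"
  loadings, pure-noise control ROIs). Patterns round-trip through a plain
  TSV/JSON archive so any real single-event beta estimates exported to the
  same layout can be analyzed identically.
* **`reinstate.rsa`** — representational-similarity indices: corrected
  scene-specific reinstatement (within-trial fixation–scene similarity
  minus the set-based between-trial baseline, Fisher-z per pair, averaged
  within run then across runs), the object-period control, and the
  gist index (within-category minus between-category fixation similarity
  pooled from Z-standardized within-run and cross-run pair blocks), plus
  session aggregation for the recent condition.
* **`reinstate.stats`** — sign-flip one-sample permutation tests
  (exhaustive when feasible), Benjamini–Hochberg FDR, Šidák adjustment,
  ω² effect sizes, IQR outlier screening, and random-intercept mixed
  models with Satterthwaite degrees of freedom and Šidák post hocs
  (`reinstate.lmm` implements the single-grouping closed forms,
  cross-checked against statsmodels MixedLM).
* **`reinstate.plsc`** — partial least squares correlation between
  per-subject ROI metric profiles and behavior: SVD of the behavior × ROI
  correlation matrix, permutation test of the singular value, bootstrap
  ratios for salience stability, brain scores, and Welch group comparison.
* **`reinstate.cli`** — a reproducible pipeline
  (`simulate → rsa → stats → plsc → report`) with YAML configuration,
  per-stage seeding from a master seed, and checksum-guarded stage inputs.

## Run the test suite

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py` with the calibration and
parameter-recovery checks (500 null cohorts for the permutation tests,
100 cohorts at n = 40/group for index recovery); the full run takes a few
minutes on one CPU.

## Command-line usage

```bash
# print all configuration defaults
reinstate config --dump-config

# full pipeline into ./results with a fixed master seed
reinstate all --out results --seed 7

# or stage by stage, optionally with a custom config
reinstate simulate --config my.yaml --out results
reinstate rsa      --config my.yaml --out results
reinstate stats    --config my.yaml --out results
reinstate plsc     --config my.yaml --out results
reinstate report   --config my.yaml --out results
```

Outputs (all plain text): a per-subject pattern archive under
`results/archive/`, `indices.tsv` (one row per subject × ROI × condition ×
index type), `stats.tsv`/`stats.json` (mixed-model effects, post hocs,
gist permutation tests with FDR), `plsc.json`/`brain_scores.tsv`,
`report.txt`/`report.json`, and `manifest.json` (seeds, timings, file
checksums). Re-running with the same config and seed reproduces every
result file byte-identically.

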