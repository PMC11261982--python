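# adtnorm

Landmark-based normalization and integration of CITE-seq surface-protein
(ADT) counts across batches, with stain-quality scoring and valley-threshold
auto-gating as first-class by-products.

## How it works

For each protein marker, independently:

1. **Transform** — raw counts are arcsinh-transformed (`asinh(x / cofactor)`,
   default cofactor 5).
2. **Landmark detection** — a Gaussian-kernel density is estimated per batch
   on a shared grid, walking a decreasing bandwidth ladder until enough peaks
   resolve. Local maxima become peaks, minima between adjacent peaks become
   valleys (slope-derived for unimodal batches). Cleanup rules merge
   discreteness artifacts near zero, drop spurious empty-droplet peaks, flag
   outlier positive peaks by scaled MAD, and impute outlier valleys from the
   most similar batches (1-D earth mover's distance).
3. **Alignment** — landmarks are harmonized into canonical slots
   (`neg_peak, valley_1, pos_peak_1, …`); per-slot targets default to the
   cross-batch mean (or user-fixed locations for incremental integration).
   Each batch gets a strictly monotone warp with fixed endpoints pinned at
   its landmarks; cells move through the inverse warp, so distributions align
   while within-batch rank order is preserved exactly.
4. **By-products** — stain index and a three-case stain-quality score per
   (marker, batch); automated cell-type annotation from valley thresholds;
   percent-positivity summaries.

Markers profiled in only some batches are supported: absent (marker, batch)
pairs are skipped and written as NA.

## CLI

```bash
# generate a synthetic dataset with known ground truth
adtnorm simulate --seed 0 --n-cells 2000 --out sim/

# normalize across batches
adtnorm normalize --counts sim/counts.csv --meta sim/metadata.csv \
    --batch-key batch --config sim/config.json --out norm/

# stain-quality report (score < 5 flagged by default)
adtnorm quality --counts sim/counts.csv --meta sim/metadata.csv \
    --batch-key batch --out quality/

# valley-threshold auto-gating (+ optional accuracy vs reference labels)
adtnorm gate --counts sim/counts.csv --meta sim/metadata.csv \
    --batch-key batch --rules rules.tsv --labels ref.csv --out gated/
```

Counts are accepted as a dense CSV/TSV (header = marker names, first column
= cell id) or a Matrix Market triplet (`counts.mtx` + `features.tsv` +
`barcodes.tsv`, features × barcodes orientation). Every subcommand writes a
`run_manifest.json` with its parameters. `normalize` also emits pre- and
post-alignment landmark tables, the target-landmark table and the per-batch
warp knots; the landmark TSV can be hand-edited and fed back with
`--landmark-override`, and `--target-landmarks` pins targets for integrating
new data without reprocessing old runs. An example PBMC gating rule set
ships in `src/adtnorm/data/pbmc_rules.tsv`.

## Python API

```python
import adtnorm as an

ds = an.read_counts("counts.csv")
ds = an.attach_batches(ds, "metadata.csv", batch_key="batch")
res = an.run_normalization(ds, an.RunConfig())
res.normalized              # cells × markers DataFrame, aligned arcsinh scale
res.landmarks_pre           # detected/cleaned landmarks per marker × batch
res.markers["CD3"].warps    # per-batch monotone warp functions

gates = an.auto_gate(res.normalized, res, an.read_rules("rules.tsv"))
```

## Layout

```
src/adtnorm/
  core_data.py           data model, I/O, run configuration
  landmark_detection.py  KDE, peaks/valleys, cleanup, MAD/EMD
  registration.py        slot harmonization, targets, warps, pipeline
  stain_quality.py       stain index + stain-quality scores
  gating.py              rule engine, accuracy, percent positivity
  synthetic_data.py      generators with exact landmark ground truth
  cli.py                 click command group
```
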