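# sepkit

Seafood elemental profiling (SEP) via portable XRF, as a tested, reusable
analysis pipeline. A handheld XRF instrument reports per-element
concentrations and instrument errors (ppm) for soft-tissue samples; this
package implements everything downstream of the instrument:

- **simulate** — synthetic profile tables (8 provenance groups × 5 samples,
  14-element roster, counting-statistics errors, zero-inflated As), paired
  reference/instrument calibration sets, replicate exposures, exposure-time
  error curves, and paired drying-treatment tables. All effect sizes are
  illustrative; directions (e.g. cooked samples higher in Cl/Zn/Th/Cu/Mn,
  raw higher in Zr) are configurable multiplicative shifts.
- **calibration** — per-element correction factors as the slope of the
  least-squares line of reference on instrument readings; N/A factors pass
  through flagged; negative factors warn and floor at zero.
- **qc** — the detection rule (error < concentration/3, strict; element kept
  if a majority of nonzero readings pass), the exposure-time optimizer
  (consecutive-slope improvement rate, stop when it falls below 33%), and the
  repeatability delta (mean instrument error − standard error of replicates).
- **moisture** — two-sided paired Wilcoxon signed-rank tests per element,
  stratified raw/cooked; exact enumeration for n ≤ 25 (midranks for ties),
  normal approximation with continuity correction above; all-zero strata
  flagged `*`.
- **preprocess** — remove elements with > 80% zeros, keep one element per
  |Pearson r| ≥ 0.8 cluster, then z-scale (invertible).
- **models** — per-group 80/20 stratified split, grid-tuned random forest
  (mtry × ntree, 5-fold CV, Gini + permutation importances), LDA
  (resubstitution accuracy), PCA, non-metric MDS (Kruskal stress-1), and
  canonical discriminant analysis with structure coefficients.

## CLI

```sh
sepkit run-all --outdir runs/demo --seed 1        # full pipeline
sepkit simulate --seed 1 --out profile.csv        # just the generator
sepkit preprocess --profile profile.csv --out scaled.csv --report report.csv
sepkit classify --profile scaled.csv --seed 1 --outdir model/
sepkit run-all --outdir runs/nomodel --seed 1 --skip model --skip preprocess
```

`run-all` executes simulate → calibrate → qc → moisture → preprocess →
model, writing every intermediate table as CSV plus a `manifest.json` with
the stage order, seed, and SHA-256 checksums (bit-identical across runs with
the same seed), and the resolved YAML config next to the outputs. A YAML
config can override thresholds and the RF grid (`--config cfg.yaml`).

## Conventions

Profile tables are CSVs with columns `sample_id, site, production,
preparation`, then `<El>_ppm` and `<El>_err` per element; missing values are
the literal `NA`. All randomness flows from one integer seed through
independent named streams, so every output is reproducible bit-for-bit.
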