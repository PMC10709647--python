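# eegfc

Spectral-power and phase-coupling analysis of two-group multichannel EEG
cohorts, with a synthetic-cohort simulator providing ground truth for
every stage. The pipeline mirrors a clinical resting-state workflow:

1. **simulate** — two groups of subjects with per-channel band-limited
   oscillations (theta 4–7, alpha 8–12, low beta 13–20, high beta
   21–30 Hz) over 1/f noise, configurable pairwise phase coupling
   (lag + von Mises jitter of concentration κ, so a coupled pair's
   expected PLV is the analytic I₁(κ)/I₀(κ)), and an instantaneous
   mixing matrix emulating volume conduction. Cohorts are written as
   EDF files plus sidecar CSV tables.
2. **preprocess** — 1–45 Hz zero-phase Hamming FIR filtering (heuristic
   order: transition bandwidth = 25% of the lower edge, min 2 Hz),
   re-referencing to Fz (19 → 18 channels), eyes-closed extraction,
   and non-overlapping 2-s epoching.
3. **features** — per-epoch Welch band powers min–max rescaled across
   electrodes and epoch-averaged (72 features), and Hilbert-phase
   PLV / corrected-imaginary-PLV for all 153 electrode pairs × 4 bands
   (612 features per measure; band FIR orders 24/24/24/50).
4. **stats** — Friedman tests (channel and matched-group effects),
   mass-univariate two-tailed Wilcoxon rank-sum tests (exact for small
   pooled samples), and Benjamini–Hochberg FDR control at q = 0.05.
5. **classify** — L2-regularized logistic regression with nested
   stratified cross-validation (6 outer × 5 inner splits, accuracy grid
   search over 13 log-spaced regularization strengths), leave-one-out
   per-subject probabilities, and conditional SHAP feature importance
   (Gaussian/linear closed form with Ledoit–Wolf covariance shrinkage,
   so correlated features share credit).

## Command line

```sh
# simulate a default 18+18 cohort (EDF + sidecars)
eegfc simulate -n 18 --duration 60 --seed 0 --outdir runs/edf

# feature tables from a cohort of EDFs
eegfc features --edf-dir runs/edf --outdir runs/feat --feature-sets spectral,plv,ciplv

# statistics / classification on a feature table
eegfc stats --features runs/feat/features_spectral.csv --q 0.05 --out runs/stats.tsv
eegfc classify --features runs/feat/features_spectral.csv --outdir runs/cls --seed 0

# everything in one go, from a YAML config
eegfc run-all --config config.yaml --outdir runs/full --seed 0
```

Example `config.yaml`:

```yaml
simulation: {preset: default, n_per_group: 18, duration_s: 60.0, seed: 0}
feature_sets: [spectral, plv, ciplv]
q: 0.05
outer_splits: 6
inner_splits: 5
seed: 0
```

`run-all` writes feature CSVs, stats TSVs (plus per-band signed
significance maps for connectivity), CV/LOO JSON reports, SHAP feature
importance TSVs, and a `manifest.json` with SHA-256 hashes of every
output (fixed config + seed ⇒ identical hashes).

## Package layout

| module | contents |
|---|---|
| `eegfc.simulate` | `SimulationConfig`, `CouplingSpec`, `generate_cohort`, cohort EDF I/O |
| `eegfc.edf` | minimal EDF reader/writer |
| `eegfc.preprocessing` | FIR design/application, Fz re-referencing, epoching |
| `eegfc.spectral` | Welch PSD, band power, per-segment rescaling, 72-dim features |
| `eegfc.connectivity` | instantaneous phase, PLV, ciPLV, 612-dim features |
| `eegfc.stats` | Wilcoxon rank-sum, Benjamini–Hochberg, Friedman, mass-univariate |
| `eegfc.classify` | L2 logistic regression, nested CV, conditional SHAP, LOO |
| `eegfc.pipeline` / `eegfc.cli` | orchestration, manifests, `eegfc` CLI |
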