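# attenuskin

Dual-modal analysis pipeline for discriminating benign nevi (BN) from
malignant melanoma (MM) on synthetic or measured data:

- **OCT branch** — per-A-scan tissue-surface detection, two-way
  Lambert–Beer exponential-decay fitting (`I(z) = a·e^(−2bz)`, `b` the
  effective attenuation coefficient), fit-quality metrics (R², RMSE, peak
  intensity), attenuation heatmaps, 5-A-scan feature binning into
  8-feature instances, and linear-SVM 10-fold cross-validation with
  interpolated mean ROC, per-sample correct-proportion reporting, and the
  SVM weight vector.
- **Raman branch** — cosmic-ray removal (modified z-score of second
  differences), Savitzky–Golay smoothing, area normalization over the
  800–1800 cm⁻¹ fingerprint region, autofluorescence baseline removal by
  asymmetrically reweighted penalized least squares (arPLS), and group
  mean / 95%-CI / Welch difference spectra.
- **Synthetic data** — seeded simulators for both modalities with ground
  truth emitted alongside every dataset, so all stages are testable
  without clinical data.

## CLI

Every stage is a subcommand of the umbrella `attenuskin` command (each is
also installed standalone):

```sh
attenuskin simulate-oct --class bn --n-ascans 1000 --seed 1 --out bscan.csv --truth truth.csv
attenuskin fit-oct --in bscan.csv --roi 0:1000 --fit-depth 150 --out fits.csv --map map.csv
attenuskin features --fits fits.csv --bin 5 --label bn --sample-id 01_Nevus --out features.csv
attenuskin classify --features features.csv --folds 10 --subset all --seed 7 --report report.json
attenuskin simulate-raman --group mm --seed 1 --out spectrum.tsv --truth baseline.tsv
attenuskin raman-process --in spectra/ --groups groups.csv --out processed/ --report raman.json
attenuskin run --config run.yaml          # full seeded pipeline + manifest
```

B-scans are delimited text with one `# key=value` header line
(`pixel_spacing`, `label`, …) and a depth × A-scan matrix; spectra are
two-column text (wavenumber cm⁻¹, intensity). Exit codes: 2 config
error, 3 parse error, 4 numeric failure.

A `run.yaml` may set any field of `attenuskin.pipeline.RunConfig`
(`seed`, `n_ascans`, `bin_size`, `n_folds`, `arpls_lambda`, …). A single
global seed deterministically derives per-stage seeds, so reruns are
bit-identical.

## Package layout

| Module | Contents |
| --- | --- |
| `attenuskin.synthetic` | seeded OCT / Raman simulators + default class configs |
| `attenuskin.attenuation` | surface detection, exponential fitting, heatmaps |
| `attenuskin.binning` | 5-A-scan binning into 8-feature instances |
| `attenuskin.classify` | linear-SVM CV, ROC interpolation, weights, per-sample report |
| `attenuskin.raman` | despike, smooth, normalize, arPLS, group statistics |
| `attenuskin.io` / `attenuskin.pipeline` / `attenuskin.cli` | file formats, orchestration, CLI |
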