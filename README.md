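# dssa — stationary subspace analysis for single-trial EEG prediction

Multichannel EEG is routinely modelled as a nonstationary multivariate time
series: task-related cortical activity rides on top of artifacts — blinks,
muscle bursts, drifting mental state — whose statistics change within a
trial.  This package treats that nonstationarity as noise and removes it by
**stationary subspace analysis (SSA)**: the observed p-channel series is
assumed to be a linear mixture

    X_t = A [Y_t^s ; Y_t^n]

of d stationary sources Y^s (signal) and p − d nonstationary sources Y^n
(noise), and a d × p orthonormal projection B₁ is estimated so that B₁X_t
recovers the stationary part.  Two estimators are provided:

* **DSSA** (frequency domain): the discrete Fourier transform of a
  second-order stationary series is asymptotically uncorrelated across
  Fourier frequencies, so the lag-r autocovariances of the DFT,
  Γ̂_r = (1/T) Σ_k J(ω_k) J(ω_{k+r})*, vanish for stationary series.  B₁
  minimises D(B₁) = Σ_{r≤m} ‖Γ̂_r^{B₁X}‖²_F over orthonormal frames.
* **ISSA** (epoch domain): the series is split into N epochs, a Gaussian is
  fitted to each, and B₁ minimises the summed (reduced-form) KL divergences
  Σ_i (−log det Σ̂ᵢˢ + ‖μ̂ᵢˢ − μ̄ˢ‖²) between epoch fits and their average.

On top of the subspace machinery sits a single-trial **choice-prediction
pipeline** (filter → prewhiten → SSA → spectral features → logistic model →
10-fold cross-validation) with three models: M1 (prefrontal average), M2
(Daniell-smoothed spectral-matrix distances of the observed series) and M3
(the same distances on the extracted stationary subspace series).
Performance is reported as A1 (accuracy), A2 (mean of sensitivity and
specificity) and A3 (cross-validated AUC), with a shuffled-label baseline
for calibration.  A synthetic-data module generates labeled datasets with
known mixing, subspace dimension, and class effect, so every stage is
testable end to end.

Intended users: researchers in biomedical signal processing, neuroeconomics
and applied time-series statistics who want a tested, reproducible SSA
implementation or a template for single-trial classification studies.

## Worked example

`examples/04_predict_choices.py` generates a 60-subject dataset whose
class effect (an AR-coefficient shift, 0.3 vs 0.5) lives entirely in the
d = 3 stationary sources while 3 of 6 channels carry subject-variable
artifact sources, then cross-validates M2 and M3:

```
60 subjects, p = 6, true d = 3, T = 2000, AR effect = 0.2
M2 (observed spectra):  A1 =  68.3%  A2 =  46.6%  A3 =  59.2%
M3 (subspace spectra):  A1 =  90.0%  A2 =  85.2%  A3 =  90.6%
AUC gain from noise reduction: +31.4 points
```

M2's features are diluted by between-subject variability of the artifact
spectra; projecting each trial onto its estimated stationary subspace (M3)
recovers the class effect.  The other examples demonstrate dataset
simulation, subspace recovery with a stationarity test before/after noise
reduction (`02`), sequential estimation of d (`03`) and the shuffled-label
chance baseline (`05`), each printing a few annotated numbers.

A thin CLI mirrors the pipeline: `dssa simulate`, `dssa fit`,
`dssa baseline`, `dssa compare`, `dssa ssa` (see `dssa --help`).

## Layout

```
src/dssa/
  synthetic.py   mixing model, source families, choice-dataset generator
  preprocess.py  zero-phase band-pass filter, prewhitening
  ssa.py         DFT autocovariances, DSSA/ISSA objectives + optimisers,
                 stationarity test, sequential dimension estimation
  spectral.py    Daniell-smoothed spectral matrices, class-mean distances
  evaluate.py    logistic models, A1/A2/A3, cross-validation, baselines
  pipeline.py    end-to-end orchestration, artifacts, model comparison
  scenarios.py   canonical seeded simulation scenarios
  cli.py         thin command-line interface
docs/methods.md  model, estimators, defaults and design choices
examples/        one narrative script per capability
```
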