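# Methods

## Model

The observed p-channel trial X (p × T) is a time-invariant linear mixture
X_t = A [Y_t^s; Y_t^n] of d second-order stationary sources and p − d
nonstationary sources, with A invertible.  Only the column span of the
stationary block is identifiable (any rotation of the sources can be
absorbed into A), so estimation targets a d-dimensional subspace and
accuracy is measured by principal angles.  Identifiability additionally
requires that no linear combination of the nonstationary sources is itself
stationary — e.g. two variance profiles whose positive mixture is constant
in time violate it, and no method can separate such a pair.

All subspace estimation operates on prewhitened data (see below), which
makes the stationary and nonstationary mixing columns approximately
orthogonal and lets orthonormal demixing frames represent the solution.

## Estimators

**Frequency-domain objective (DSSA).**  With the DFT
J_Z(ω_k) = (2πT)^{−1/2} Σ_{t=1..T} Z_t e^{−itω_k}, ω_k = 2πk/T, the lag-r
DFT autocovariance Γ̂_r = (1/T) Σ_k J(ω_k) J(ω_{k+r})* (frequency index
modulo T) is O(1/√T) for stationary series and O(1) under time-varying
dynamics.  The objective D(B₁) = Σ_{r=1..m} ‖Γ̂_r^{B₁X}‖²_F is minimised
over d × p orthonormal frames.  Because Γ̂_r^{B₁X} = B₁ Γ̂_r^X B₁ᵀ, the p × p
autocovariances are computed once per series and every objective/gradient
evaluation is O(m d p²).

**Epoch objective (ISSA).**  The series is split into N contiguous blocks
(remainder samples joining the last block); with per-epoch moments
(μ̂ᵢ, Σ̂ᵢ) the objective is L(B₁) = Σᵢ (−log det B₁Σ̂ᵢB₁ᵀ + ‖B₁(μ̂ᵢ − μ̄)‖²).
This is the Gaussian KL divergence to the grand-average fit with its trace
term omitted; the reduced form is principled only when the grand covariance
is ≈ identity, which prewhitening guarantees — hence the optimisers warn on
input that does not look prewhitened.

**Optimisation.**  Steepest descent on the frame manifold {B₁ : B₁B₁ᵀ = I}:
tangent-space-projected gradients, QR retraction, Armijo backtracking
(factor 0.5, slope 1e−4, step doubling between iterations), convergence at
relative objective change < 1e−8 or 500 iterations, best of `n_restarts`
Haar-random starts (QR of Gaussian matrices), fully deterministic given a
seed.  Accepted iterates are monotone, which the suite asserts.  At d = p
both objectives are frame-invariant, so the identity frame is returned
directly.

**Stationarity test.**  The test statistic is the same DFT-autocovariance
sum computed on *standardised* coefficients J̃(ω_k) = f̂(ω_k)^{−1/2} J(ω_k),
where f̂ is the Daniell-smoothed spectral matrix (window 25).  The
standardisation — in the spirit of the spectral-standardised DFT-covariance
tests this statistic descends from — equalises magnitudes across
frequencies so the statistic responds to cross-frequency phase coherence
(the signature of time-varying dynamics) rather than raw power; without it,
processes whose energy concentrates on a few low frequencies (integrated
noise) dominate observed and null statistics alike and the test has no
power against exactly the nonstationarity it should flag.  The null is
resampled by Fourier phase surrogates: random conjugate-symmetric phases
applied to J̃, preserving every amplitude (hence f̂) while destroying phase
coherence; the p-value uses the add-one permutation convention, so it is
bounded below by 1/(1 + n_null_draws) and n_null_draws < 19 is rejected.
Measured calibration (the acceptance suite recomputes both): empirical size
0.02–0.05 at α = 0.05 on iid and stationary-AR data; power 1.0 against a
mid-series variance doubling (T = 1024) and ≈ 0.9 against random walks
(T = 2048).

**Dimension estimation.**  Top-down sequential testing: accept d = p if the
full series passes the test at level α; otherwise fit frames for
d = p−1 … 1 and return the largest d whose extracted series passes, else 0.
Searching from above resolves ties toward retaining more signal.  With
independent random walks as sources, the optimiser can occasionally
assemble a spuriously stationary-looking one-dimensional combination (the
classic spurious-regression phenomenon), so single-replicate estimates at
d = 0 are less reliable than the modal estimate across replicates, which is
what the validation suite asserts.

## Pipeline defaults

| parameter | default | rationale |
|---|---|---|
| band-pass | 0.5–45 Hz, 4th-order Butterworth, forward–backward | standard EEG practice; zero phase; ≥ 20 dB at 60 Hz |
| prewhitening | per trial, symmetric inverse square root of the (centered) sample covariance | features are per subject-trial; output covariance = I to 1e−8 |
| m (autocovariance lags) | 10 | small relative to T = 640; sensitivity checked at m ∈ {3, 10, 20} |
| N (ISSA epochs) | 8 | 80-sample blocks at T = 640 support the projected moments |
| restarts | 10 (standalone), 5 (per-trial in pipeline) | diminishing returns beyond a handful on these objectives |
| Daniell window | 25 | ≈ √640, the usual bandwidth heuristic |
| smoothing, lag wraparound | circular in the frequency index | matches the k = 1..T indexing of the DFT grid |
| logistic models | no intercept | as the prediction models are written; at zero features the predicted probability is exactly 0.5; an `intercept` flag exists |
| CV | 10 folds, threshold 0.5, class means from training folds, leave-one-out self-exclusion for training features | see design choices |
| A3 | mean of per-fold AUCs | see design choices |

## Design choices on genuinely open points

**Cross-validated AUC.**  A3 is the average of per-fold AUCs (the cvAUC
estimator).  Pooling out-of-fold scores into one ROC is available
(`pool_auc=True`) but is biased below 50% under the shuffled-label null
with unstratified folds: a test fold rich in class-1 subjects leaves a
class-1-poor training set, shifting that fold's scores down and
anti-correlating pooled scores with labels (measured ≈ 45% under the null
here).  Per-fold AUCs are invariant to between-fold score offsets.

**Leave-one-out class means.**  Spectral-distance features measure each
trial's distance to the two class-mean spectra.  Class means are computed
from training-fold subjects only and, when featurising a *training*
subject, that subject is excluded from its own class mean.  Self-inclusion
leaks the label into the feature (a subject is always slightly closer to a
mean it participates in); under shuffled labels that leakage makes the
no-intercept model chase noise instead of collapsing to the majority class
(measured A1 61.5% instead of the ≈ 70% majority anchor).  The literal
all-subjects averaging remains available (`leave_test_out=False`).

**Per-trial, unsupervised SSA.**  For M3 each trial gets its own projection
fitted without labels, so the subspace step cannot leak fold information.
Because all stationary sources share one spectrum by design, the projected
d × d spectral matrix is approximately rotation-invariant
(f(ω)·I), making spectra comparable across subjects despite each trial's
arbitrary basis.  With `d="auto"` the dimension is estimated per trial and
the modal value is refitted for all trials so feature dimensions agree.

**Estimated vs. oracle subspace.**  Per-trial recovery at realistic trial
lengths is imperfect (principal angles of 15–40° at T = 640–2000); the
prediction gain survives because the leaked noise fraction scales as the
4th power of the angle's sine in the objective and the retained stationary
spectra still carry the class contrast.

## Synthetic data: what it emulates and what it does not

`generate_choice_dataset` emulates a single-trial neuroeconomics design:
181 subjects (default), one 9-channel, 640-sample trial each at 256 Hz,
binary labels at prevalence 0.70.  The class effect is an AR(1)-coefficient
shift (0.3 vs 0.3 + effect_size, default 0.4) applied to all d stationary
sources; nonstationary sources are identically distributed across classes,
so by construction all predictive signal lives in the stationary subspace.

The default noise menu alternates two artifact families with
subject-randomised parameters, as artifact profiles differ across
participants: (a) an envelope-modulated narrowband oscillation (resonance
drawn from 6–16 Hz, burst timing random — intermittent alpha/EMG), realised
as a time-varying vector moving average whose coefficients are a damped
cosine impulse response; (b) a variance-burst Gaussian (variance 0.05 → 12
inside a short window at a random time — a blink-like transient).  Both are
strongly nonstationary at the single-trial scale and lie inside the 0.5–45
Hz analysis band.  Unit-root drift is a supported source family and is used
in the stationarity-power and dimension-estimation scenarios, but it is not
in the default choice-data menu: the pipeline's own 0.5 Hz high-pass
removes drift almost entirely, and what survives is near-stationary — the
filter, not the subspace step, is the drift remover.

Deliberately not emulated: electrode geometry and volume conduction,
realistic artifact waveforms, multi-trial designs, and any physiological
link between choices and spectra — the class effect is a stylised
spectral-shape shift.  Passing tests therefore demonstrate that the
pipeline recovers the kind of subspace-confined spectral signal the model
assumes, not that real EEG contains one.

Numerical conventions worth knowing: AR sources discard a 500-sample
burn-in; the mixing matrix is Haar-orthogonal times uniform scales in
[0.5, 2] (condition number ≤ 4); `noise_scale` multiplies nonstationary
source amplitudes before mixing (largely neutralised by prewhitening, which
is the point of that preprocessing); datasets are byte-reproducible from
their seed.

## Validation scale

The statistical suite uses desk-scale problem sizes chosen to keep each
property measurable with comfortable margins: 50 seeded replicates for
subspace recovery (p = 5, d = 3, T = 2000) and dimension estimation, 200
replicates for test size/power and the 181-subject shuffled-label baseline
(200 shuffles), and 20 replicate datasets (n = 60, T = 2000) for the
M2-vs-M3 contrast.  The Gram-matrix identity for distance features (class
means are linear in member spectra, so every fold/permutation feature is a
quadratic form in one precomputed Gram matrix) makes the repeated
cross-validations exact and cheap rather than approximated.

## Known limitations

* The epoch objective's reduced KL form assumes prewhitened input; on raw
  data it is not a divergence and the optimiser only warns.
* The stationarity test is a surrogate-based calibration of a statistic,
  not the asymptotic test it descends from; its size was verified
  empirically, not derived.
* Dimension estimation against pure unit-root panels is reliable modally,
  not per replicate (spurious near-stationary combinations).
* Subspace estimates at T ≈ 640 carry 20–40° angular error; downstream
  claims are about prediction gain, not per-trial recovery.
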