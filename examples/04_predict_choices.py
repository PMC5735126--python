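"""Predict binary choices from single trials, with and without noise reduction.

Compares the spectral-distance logistic model on the observed series (M2)
against the same model on the per-trial stationary subspace series
(M3, DSSA) under strong subject-variable nonstationary noise, using 10-fold
cross-validation.  A1 = overall accuracy, A2 = mean of sensitivity and
specificity, A3 = cross-validated AUC (all %).
"""

import warnings

from dssa import cross_validate, generate_choice_dataset
from dssa.pipeline import preprocess_trials
from dssa.scenarios import contrast_dataset_spec

spec = contrast_dataset_spec(seed=101)
trials, truth = generate_choice_dataset(spec)
processed = preprocess_trials(trials)  # band-pass filter + prewhiten

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    m2 = cross_validate(processed, "M2", {"d": spec.d}, seed=5)
    m3 = cross_validate(processed, "M3-dssa", {"d": spec.d, "restarts": 3}, seed=5)

print(f"{spec.n_subjects} subjects, p = {spec.p}, true d = {spec.d}, "
      f"T = {spec.T}, AR effect = {spec.effect_size}")
print(f"M2 (observed spectra):  A1 = {m2.a1:5.1f}%  A2 = {m2.a2:5.1f}%  A3 = {m2.a3:5.1f}%")
print(f"M3 (subspace spectra):  A1 = {m3.a1:5.1f}%  A2 = {m3.a2:5.1f}%  A3 = {m3.a3:5.1f}%")
print(f"AUC gain from noise reduction: {m3.a3 - m2.a3:+.1f} points")
# The class effect lives in the stationary sources; projecting out the
# subject-variable artifacts (M3) recovers it, while M2's features are
# diluted by between-subject noise variability.
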