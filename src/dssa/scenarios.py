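"""Canonical simulation scenarios used by the validation suite and examples.

Each function pins the study conditions (sample sizes, source families,
effect sizes) for one headline property of the method, so the same
conditions are exercised by the test suite, the acceptance script and the
example scripts.
"""

from __future__ import annotations

import numpy as np

from dssa.synthetic import (
    ChoiceDatasetSpec,
    MixingGroundTruth,
    SourceSpec,
    TrialSeries,
    generate_sources,
    mix,
)

__all__ = [
    "baseline_dataset_spec",
    "contrast_dataset_spec",
    "recovery_instance",
    "mean_shift_instance",
    "dimension_instance",
    "principal_angle_deg",
]

#: Strong bursty variance profiles used in subspace-recovery scenarios.
_BURST_A = {"type": "bump", "low": 0.05, "high": 18.0, "center": 0.2, "width": 0.08}
_BURST_B = {"type": "bump", "low": 0.05, "high": 18.0, "center": 0.65, "width": 0.08}


def baseline_dataset_spec(seed: int = 7) -> ChoiceDatasetSpec:
    """The 181-subject, 9-channel, 640-sample choice dataset.

    Mirrors the design the prediction pipeline targets: one 2.5 s trial per
    subject at 256 Hz, prevalence 0.70, class effect in the stationary
    sources.
    """
    return ChoiceDatasetSpec(
        n_subjects=181, p=9, d=6, T=640, prevalence=0.70, effect_size=0.4, seed=seed
    )


def contrast_dataset_spec(seed: int) -> ChoiceDatasetSpec:
    """Strong-noise conditions for the M2-vs-M3 noise-reduction contrast.

    A subtler class effect (AR shift 0.2) and longer trials (T = 2000) with
    half the channels carrying subject-variable nonstationary artifacts:
    the observed-series model M2 is degraded by between-subject noise
    variability while the subspace model M3 can strip it.
    """
    return ChoiceDatasetSpec(
        n_subjects=60, p=6, d=3, T=2000, prevalence=0.70, effect_size=0.2, seed=seed
    )


def recovery_instance(rep: int, T: int = 2000):
    """One p=5, d=3 mixture of stationary AR and variance-burst sources.

    Returns (X, A, d): the mixed series, the mixing matrix and the true
    stationary dimension.  Seeded by ``rep``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rep, 0x5EC0]).generate_state(1)[0])
    specs = [
        SourceSpec("var_stationary", 1, {"coeffs": [0.5]}) for _ in range(3)
    ] + [
        SourceSpec("gaussian_tv_variance", 0, {"variance_profile": _BURST_A}),
        SourceSpec("gaussian_tv_variance", 0, {"variance_profile": _BURST_B}),
    ]
    A = rng.standard_normal((5, 5))
    truth = MixingGroundTruth(A=A, d=3, source_specs=tuple(specs))
    X = mix(truth, generate_sources(specs, T, rng))
    return X, A, 3


def mean_shift_instance(rep: int, T: int = 1500):
    """One p=3, d=2 mixture with a piecewise-mean-shifting third source.

    The epoch-based (ISSA) objective targets exactly this first-moment
    nonstationarity.  Returns (X, A, d).
    """
    rng = np.random.default_rng(np.random.SeedSequence([rep, 0x15A]).generate_state(1)[0])
    stationary = rng.standard_normal((2, T))
    u = np.arange(1, T + 1) / T
    levels = np.floor(u * 6).astype(int).clip(0, 5)
    mean_profile = np.array([0.0, 1.5, -1.0, 2.0, 0.5, -1.5])[levels]
    shifting = rng.standard_normal(T) * 0.7 + mean_profile
    S = np.vstack([stationary, shifting[None, :]])
    A = rng.standard_normal((3, 3))
    return A @ S, A, 2


def dimension_instance(kind: str, rep: int):
    """One instance for sequential dimension estimation.

    ``kind``: 'stationary' (p = 4, all stable AR, true d = 4), 'mixture'
    (p = 5, true d = 3, T = 2000) or 'unit_root' (p = 4 random walks,
    true d = 0, T = 2048).  Returns (X, true_d).
    """
    rng = np.random.default_rng(np.random.SeedSequence([rep, 0xD13]).generate_state(1)[0])
    if kind == "stationary":
        specs = [SourceSpec("var_stationary", 1, {"coeffs": [c]}) for c in (0.3, 0.5, -0.4, 0.6)]
        S = generate_sources(specs, 1024, rng)
        return rng.standard_normal((4, 4)) @ S, 4
    if kind == "mixture":
        X, _, d = recovery_instance(rep)
        return X, d
    if kind == "unit_root":
        S = np.cumsum(rng.standard_normal((4, 2048)), axis=1)
        return rng.standard_normal((4, 4)) @ S, 0
    raise ValueError(f"unknown scenario kind {kind!r}")


def principal_angle_deg(B1: np.ndarray, basis: np.ndarray) -> float:
    """Largest principal angle (degrees) between row-span(B1) and col-span(basis)."""
    q1, _ = np.linalg.qr(B1.T)
    q2, _ = np.linalg.qr(basis)
    s = np.clip(np.linalg.svd(q1.T @ q2, compute_uv=False), -1.0, 1.0)
    return float(np.degrees(np.arccos(s.min())))
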