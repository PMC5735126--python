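"""Trial preprocessing: zero-phase band-pass filtering and prewhitening.

These are the first two steps of the prediction pipeline.  Filtering keeps
the 0.5-45 Hz band conventionally retained in scalp EEG work; prewhitening
multiplies each trial by the inverse symmetric square root of its sample
covariance so the channels are cross-sectionally uncorrelated with unit
variance, the normalisation the subspace objectives assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from dssa.synthetic import TrialSeries

__all__ = ["FilterSpec", "WhiteningTransform", "bandpass_filter", "prewhiten"]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter design.

    Defaults: 0.5 Hz high-pass, 45 Hz low-pass, 4th-order Butterworth
    applied forward-backward (zero phase).  A zero-phase FIR design
    (Hamming-window, ``order`` taps) is available via ``design``.
    """

    highpass_hz: float = 0.5
    lowpass_hz: float = 45.0
    design: str = "butterworth_zerophase"
    order: int = 4

    def __post_init__(self):
        if not 0.0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass_hz < lowpass_hz")
        if self.design not in ("butterworth_zerophase", "fir_zerophase"):
            raise ValueError(f"unknown filter design {self.design!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class WhiteningTransform:
    """Sample covariance S and its inverse symmetric square root W.

    Satisfies ``W @ S @ W ~ I`` and ``W = W.T`` by construction.
    """

    S: np.ndarray
    W: np.ndarray

    def __post_init__(self):
        dev = np.max(np.abs(self.W @ self.S @ self.W - np.eye(self.S.shape[0])))
        if dev > 1e-8:
            raise ValueError(f"W S W deviates from identity by {dev:.2e}")
        if np.max(np.abs(self.W - self.W.T)) > 1e-10:
            raise ValueError("W must be symmetric")


def bandpass_filter(trial: TrialSeries, spec: FilterSpec | None = None) -> TrialSeries:
    """Zero-phase band-pass filter applied independently to every channel."""
    spec = spec or FilterSpec()
    nyquist = trial.sampling_rate_hz / 2.0
    if spec.lowpass_hz >= nyquist:
        raise ValueError(
            f"low-pass edge {spec.lowpass_hz} Hz at or above Nyquist {nyquist} Hz"
        )
    if spec.design == "butterworth_zerophase":
        sos = signal.butter(
            spec.order,
            [spec.highpass_hz, spec.lowpass_hz],
            btype="bandpass",
            fs=trial.sampling_rate_hz,
            output="sos",
        )
        filtered = signal.sosfiltfilt(sos, trial.data, axis=1)
    else:
        taps = signal.firwin(
            spec.order + 1,
            [spec.highpass_hz, spec.lowpass_hz],
            pass_zero=False,
            fs=trial.sampling_rate_hz,
        )
        filtered = signal.filtfilt(taps, [1.0], trial.data, axis=1)
    return trial.with_data(filtered)


def prewhiten(trial: TrialSeries) -> tuple[TrialSeries, WhiteningTransform]:
    """Standardise a trial to identity sample covariance.

    Channel means are subtracted, the sample covariance ``S`` (normalised by
    T) is eigendecomposed, and the trial is multiplied by ``W = S^{-1/2}``
    (symmetric inverse square root).  The output's sample covariance is the
    identity to numerical precision.
    """
    X = trial.data
    centered = X - X.mean(axis=1, keepdims=True)
    S = centered @ centered.T / X.shape[1]
    eigval, eigvec = np.linalg.eigh(S)
    if eigval[0] <= 1e-10 * eigval[-1]:
        raise ValueError(
            f"sample covariance numerically singular: min eigenvalue "
            f"{eigval[0]:.3e} vs max {eigval[-1]:.3e}"
        )
    W = (eigvec / np.sqrt(eigval)) @ eigvec.T
    W = 0.5 * (W + W.T)  # enforce exact symmetry against rounding
    return trial.with_data(W @ centered), WhiteningTransform(S=S, W=W)
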