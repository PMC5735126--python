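"""Spectral-matrix features for single-trial choice prediction.

Three feature families feed the logistic prediction models:

* the prefrontal average (model M1): the scalar mean of the three
  prefrontal channels over the whole trial;
* Daniell-smoothed spectral matrices (models M2/M3): the cross-periodogram
  of the (centered) series at every Fourier frequency, smoothed by a
  uniform moving average across frequencies, summarising each trial's
  second-order structure;
* class-mean distances: for each trial, the mean squared Frobenius distance
  of its spectral matrices to the two class-average spectral-matrix curves,
  a 2-vector that locates the trial relative to the class centres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from dssa.ssa import compute_dft
from dssa.synthetic import TrialSeries

__all__ = [
    "SpectralSet",
    "ClassMeanSpectra",
    "PREFRONTAL_CHANNELS",
    "prefrontal_average",
    "spectral_matrix",
    "class_mean_spectra",
    "distance_features",
    "spectral_gram",
    "distances_from_gram",
]

#: Prefrontal electrode labels of the default 9-channel montage.
PREFRONTAL_CHANNELS = ("F3", "F4", "FZ")


@dataclass(frozen=True)
class SpectralSet:
    """Hermitian spectral matrices of one trial, indexed by Fourier frequency.

    ``matrices[k - 1]`` is the q x q estimate at ``omega_k = 2 pi k / T``,
    k = 1..T.  ``smoothing_window`` is the (odd) Daniell window length.
    """

    matrices: np.ndarray  # (T, q, q) complex
    subject_id: str | None = None
    smoothing_window: int = 1

    def __post_init__(self):
        M = np.asarray(self.matrices)
        if M.ndim != 3 or M.shape[1] != M.shape[2]:
            raise ValueError("matrices must be a (T, q, q) stack")
        dev = np.max(np.abs(M - M.conj().transpose(0, 2, 1)))
        if dev > 1e-10:
            raise ValueError(f"spectral matrices deviate from Hermitian by {dev:.2e}")

    @property
    def n_freq(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]


@dataclass(frozen=True)
class ClassMeanSpectra:
    """Frequency-wise average spectral matrices of the two classes."""

    mean_0: SpectralSet
    mean_1: SpectralSet
    n_0: int
    n_1: int


def prefrontal_average(
    trial: TrialSeries, channels: Sequence[str] = PREFRONTAL_CHANNELS
) -> float:
    """Mean of the named channels over channels and all time points."""
    names = list(trial.channel_names)
    try:
        rows = [names.index(c) for c in channels]
    except ValueError as exc:
        raise ValueError(f"channel not present in trial: {exc}") from exc
    return float(trial.data[rows].mean())


def spectral_matrix(Y: np.ndarray, window: int = 25, subject_id: str | None = None) -> SpectralSet:
    """Daniell-smoothed spectral-matrix estimate of a q x T series.

    The series is mean-centered per channel, its cross-periodogram
    ``I(omega_k) = J(omega_k) J(omega_k)^*`` is formed at every Fourier
    frequency, and a circular uniform moving average of length ``window``
    (odd) is applied across the frequency index.  Under the DFT
    normalisation used here, a unit-variance white series has expected
    diagonal ``1 / (2 pi)``.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("Daniell window length must be a positive odd integer")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if window >= Y.shape[1]:
        raise ValueError("window must be smaller than the series length")
    centered = Y - Y.mean(axis=1, keepdims=True)
    J = compute_dft(centered).coefficients  # (q, T)
    perio = np.einsum("ik,jk->kij", J, J.conj())  # (T, q, q)
    if window > 1:
        smoothed = uniform_filter1d(perio.real, size=window, axis=0, mode="wrap") + 1j * (
            uniform_filter1d(perio.imag, size=window, axis=0, mode="wrap")
        )
    else:
        smoothed = perio
    # re-symmetrise against floating-point drift in the smoother
    smoothed = 0.5 * (smoothed + smoothed.conj().transpose(0, 2, 1))
    return SpectralSet(matrices=smoothed, subject_id=subject_id, smoothing_window=window)


def class_mean_spectra(
    spectra: Sequence[SpectralSet],
    labels: Sequence[int],
    subset: Sequence[int] | None = None,
) -> ClassMeanSpectra:
    """Frequency-wise arithmetic mean of the spectral sets within each class.

    ``subset`` restricts the averaging to the given trial indices (the
    training fold, in cross-validation) while leaving the full list
    addressable; both classes must be represented.
    """
    labels = np.asarray(labels)
    idx = np.arange(len(spectra)) if subset is None else np.asarray(subset)
    out = {}
    for cls in (0, 1):
        members = idx[labels[idx] == cls]
        if members.size == 0:
            raise ValueError(f"class {cls} has no members to average")
        stack = np.stack([spectra[i].matrices for i in members])
        out[cls] = SpectralSet(
            matrices=stack.mean(axis=0),
            smoothing_window=spectra[members[0]].smoothing_window,
        )
    return ClassMeanSpectra(
        mean_0=out[0],
        mean_1=out[1],
        n_0=int(np.sum(labels[idx] == 0)),
        n_1=int(np.sum(labels[idx] == 1)),
    )


def distance_features(subject: SpectralSet, means: ClassMeanSpectra) -> np.ndarray:
    """Mean squared Frobenius distance to each class-mean spectral curve.

    Component i is ``(1/T) sum_k ||g_j(omega_k) - gbar_i(omega_k)||_F^2``
    (sum of squared moduli of the complex difference), for i in {0, 1}.
    """
    out = np.empty(2)
    for i, mean in enumerate((means.mean_0, means.mean_1)):
        if mean.matrices.shape != subject.matrices.shape:
            raise ValueError("frequency grids / dimensions of subject and means differ")
        diff = subject.matrices - mean.matrices
        out[i] = np.sum(np.abs(diff) ** 2) / subject.n_freq
    return out


def spectral_gram(spectra: Sequence[SpectralSet]) -> np.ndarray:
    """Real Gram matrix ``R[j, l] = (1/T) Re sum_k <g_j(omega_k), g_l(omega_k)>``.

    The inner product is the entrywise (Frobenius) one.  Because class means
    are linear in the member spectra, every class-mean distance feature is a
    quadratic form in this Gram matrix (see :func:`distances_from_gram`),
    which makes repeated cross-validation over label permutations cheap: the
    Gram matrix is computed once per dataset.
    """
    T = spectra[0].n_freq
    V = np.stack([s.matrices.reshape(-1) for s in spectra])  # (n, T q^2)
    return (V @ V.conj().T).real / T


def distances_from_gram(
    R: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    eval_idx: np.ndarray,
    exclude_self: bool = False,
) -> np.ndarray:
    """Class-mean distance features evaluated through the Gram matrix.

    For evaluation trial j and class i with training members C_i:
    ``||g_j - mean(C_i)||^2 = R_jj - (2/n_i) sum_{l in C_i} R_jl
    + (1/n_i^2) sum_{l, l' in C_i} R_ll'``.  Identical (to rounding) to
    :func:`distance_features` with class means over ``train_idx``.

    With ``exclude_self`` an evaluation trial that is itself a training
    member of class i is removed from that class's mean before its distance
    is computed (leave-one-out hygiene: a trial's own spectrum inside the
    class centre would otherwise leak its label into the feature).
    """
    labels = np.asarray(labels)
    eval_idx = np.asarray(eval_idx)
    feats = np.empty((len(eval_idx), 2))
    diag = np.diag(R)
    for i, cls in enumerate((0, 1)):
        members = train_idx[labels[train_idx] == cls]
        if members.size == 0:
            raise ValueError(f"class {cls} has no training members")
        n_i = members.size
        cross = R[np.ix_(eval_idx, members)].sum(axis=1)
        within = R[np.ix_(members, members)].sum()
        feats[:, i] = diag[eval_idx] - 2.0 * cross / n_i + within / n_i**2
        if exclude_self:
            in_class = np.isin(eval_idx, members)
            if np.any(in_class) and n_i >= 2:
                j = eval_idx[in_class]
                nm = n_i - 1.0
                cross_j = cross[in_class]  # sum_l R_jl over members incl. self
                cross_excl = cross_j - diag[j]
                within_excl = within - 2.0 * cross_j + diag[j]
                feats[in_class, i] = (
                    diag[j] - 2.0 * cross_excl / nm + within_excl / nm**2
                )
    return feats
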