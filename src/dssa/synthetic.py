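"""Synthetic multichannel choice datasets with a known stationary subspace.

The generator realises the mixing model ``X_t = A [Y_t^s; Y_t^n]``: d
stationary autoregressive sources carry the (optional) class effect, the
remaining p - d sources are nonstationary "noise" drawn from three families
commonly used to stress stationarity methods — independent Gaussians with a
time-varying variance profile, unit-root (integrated) autoregressions, and
time-varying vector moving averages.  Every downstream stage of the pipeline
is testable against the ground truth returned alongside the trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SourceSpec",
    "MixingGroundTruth",
    "TrialSeries",
    "ChoiceDatasetSpec",
    "DEFAULT_MONTAGE_9",
    "evaluate_profile",
    "generate_sources",
    "mix",
    "generate_choice_dataset",
    "write_dataset",
    "read_dataset",
]

#: Electrode labels of the 9-channel prefrontal/central/parietal montage the
#: pipeline assumes by default (3 prefrontal, 3 central, 3 parietal sites).
DEFAULT_MONTAGE_9 = ("F3", "F4", "FZ", "C3", "C4", "CZ", "P3", "P4", "POZ")

SOURCE_KINDS = ("var_stationary", "gaussian_tv_variance", "unit_root_var", "tv_vma")

#: Samples discarded from the start of every simulated recursive process so
#: that the retained stretch is free of initialisation transients.
BURN_IN = 500


def evaluate_profile(profile: dict, u: np.ndarray) -> np.ndarray:
    """Evaluate a serialisable scalar profile on rescaled time ``u = t/T``.

    Supported profile dictionaries::

        {"type": "constant", "value": v}
        {"type": "linear", "start": a, "end": b}
        {"type": "sine", "base": b, "amplitude": a, "cycles": c}
        {"type": "step", "first": a, "second": b, "change_point": u0}
        {"type": "bump", "low": a, "high": b, "center": u0, "width": w}

    Profiles describe variances or moving-average scales as functions of the
    fraction of the trial elapsed, so they stay meaningful across trial
    lengths and serialise to JSON with the rest of the ground truth.
    """
    u = np.asarray(u, dtype=float)
    kind = profile.get("type")
    if kind == "constant":
        out = np.full_like(u, float(profile["value"]))
    elif kind == "linear":
        out = profile["start"] + (profile["end"] - profile["start"]) * u
    elif kind == "sine":
        out = profile["base"] + profile["amplitude"] * np.sin(
            2.0 * np.pi * profile.get("cycles", 1.0) * u
        )
    elif kind == "step":
        out = np.where(u < profile["change_point"], profile["first"], profile["second"])
        out = out.astype(float)
    elif kind == "bump":
        inside = np.abs(u - profile["center"]) <= profile["width"] / 2.0
        out = np.where(inside, profile["high"], profile["low"]).astype(float)
    else:
        raise ValueError(f"unknown profile type {kind!r}")
    return out


def _ar_spectral_radius(coeffs: Sequence[float]) -> float:
    """Spectral radius of the companion matrix of an AR(p) recursion."""
    coeffs = np.atleast_1d(np.asarray(coeffs, dtype=float))
    p = coeffs.size
    companion = np.zeros((p, p))
    companion[0] = coeffs
    if p > 1:
        companion[1:, :-1] = np.eye(p - 1)
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


@dataclass(frozen=True)
class SourceSpec:
    """Recipe for one scalar source process.

    Parameters
    ----------
    kind:
        One of ``var_stationary`` (stable AR), ``gaussian_tv_variance``
        (independent Gaussians with a variance profile),
        ``unit_root_var`` (integrated AR, e.g. a random walk) or
        ``tv_vma`` (moving average whose coefficients are rescaled over time).
    order:
        Number of lags in the recursion (0 for pure time-varying variance).
    params:
        Kind-specific parameters: ``coeffs`` (AR or MA lag coefficients),
        ``sigma`` (innovation standard deviation, default 1), and for the
        time-varying kinds a profile dict under ``variance_profile`` /
        ``scale_profile`` (see :func:`evaluate_profile`).
    """

    kind: str
    order: int = 1
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.order < 0:
            raise ValueError("order must be nonnegative")
        coeffs = self.params.get("coeffs")
        if self.kind == "var_stationary":
            if coeffs is None:
                raise ValueError("var_stationary requires 'coeffs'")
            rho = _ar_spectral_radius(coeffs)
            if rho >= 1.0:
                raise ValueError(
                    "var_stationary coefficients are not stable: companion "
                    f"spectral radius {rho:.4f} >= 1 (nonstationary recursion)"
                )
        if self.kind == "gaussian_tv_variance":
            prof = self.params.get("variance_profile", {"type": "constant", "value": 1.0})
            vals = evaluate_profile(prof, np.linspace(0.0, 1.0, 101))
            if np.any(vals <= 0):
                raise ValueError("variance profile must be strictly positive")

    @property
    def is_stationary(self) -> bool:
        return self.kind == "var_stationary"

    def to_dict(self) -> dict:
        return {"kind": self.kind, "order": self.order, "params": self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "SourceSpec":
        return cls(kind=d["kind"], order=int(d["order"]), params=dict(d["params"]))


def _simulate_source(spec: SourceSpec, T: int, rng: np.random.Generator) -> np.ndarray:
    sigma = float(spec.params.get("sigma", 1.0))
    if spec.kind == "var_stationary":
        coeffs = np.atleast_1d(np.asarray(spec.params["coeffs"], dtype=float))
        eps = rng.standard_normal(T + BURN_IN) * sigma
        # AR recursion x_t = sum_i coeffs[i] x_{t-i} + eps_t as an IIR filter
        x = signal.lfilter([1.0], np.concatenate(([1.0], -coeffs)), eps)
        return x[BURN_IN:]
    if spec.kind == "gaussian_tv_variance":
        prof = spec.params.get("variance_profile", {"type": "constant", "value": 1.0})
        var = evaluate_profile(prof, np.arange(1, T + 1) / T)
        return np.sqrt(var) * rng.standard_normal(T) * sigma
    if spec.kind == "unit_root_var":
        coeffs = spec.params.get("coeffs")
        eps = rng.standard_normal(T + BURN_IN) * sigma
        if coeffs is not None:
            coeffs = np.atleast_1d(np.asarray(coeffs, dtype=float))
            eps = signal.lfilter([1.0], np.concatenate(([1.0], -coeffs)), eps)
        # integrate a stationary increment process: x_t = x_{t-1} + eps_t
        x = np.cumsum(eps)
        return x[BURN_IN:] - x[BURN_IN]
    if spec.kind == "tv_vma":
        coeffs = np.atleast_1d(np.asarray(spec.params.get("coeffs", [0.8]), dtype=float))
        prof = spec.params.get("scale_profile", {"type": "linear", "start": 0.0, "end": 2.0})
        scale = evaluate_profile(prof, np.arange(1, T + 1) / T)
        q = coeffs.size
        eps = rng.standard_normal(T + q) * sigma
        x = eps[q:].copy()
        for i, c in enumerate(coeffs, start=1):
            x += scale * c * eps[q - i : q - i + T]
        return x
    raise AssertionError("unreachable")


def generate_sources(
    specs: Sequence[SourceSpec],
    T: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one row per spec; rows are mutually independent.

    Stationary AR rows are simulated with a burn-in of ``BURN_IN`` samples
    that is discarded, so the retained stretch is (approximately) a draw from
    the stationary distribution.
    """
    if not specs:
        raise ValueError("at least one SourceSpec required")
    max_order = max(s.order for s in specs)
    if T < 10 * max(1, max_order):
        raise ValueError(f"T={T} too short for max source order {max_order}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return np.vstack([_simulate_source(s, T, rng) for s in specs])


@dataclass(frozen=True)
class MixingGroundTruth:
    """The true mixing matrix and source layout behind a synthetic dataset.

    ``A`` maps the stacked sources (first ``d`` stationary) to observations.
    ``stationary_subspace`` returns the column span of the stationary block,
    the target of subspace recovery.
    """

    A: np.ndarray
    d: int
    source_specs: tuple[SourceSpec, ...]

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "source_specs", tuple(self.source_specs))
        p = A.shape[0]
        if A.shape != (p, p):
            raise ValueError("A must be square")
        if not (0 <= self.d <= p):
            raise ValueError("d must satisfy 0 <= d <= p")
        if len(self.source_specs) != p:
            raise ValueError("need one SourceSpec per source")
        n_stat = sum(s.is_stationary for s in self.source_specs)
        if n_stat != self.d:
            raise ValueError(f"{n_stat} stationary specs but d={self.d}")
        if any(s.is_stationary for s in self.source_specs[self.d :]):
            raise ValueError("stationary specs must come first")
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                f"mixing matrix A is singular or near-singular (cond {cond:.2e})"
            )

    @property
    def p(self) -> int:
        return self.A.shape[0]

    def stationary_subspace(self) -> np.ndarray:
        """Orthonormal basis (p x d) of the column span of A's stationary block."""
        if self.d == 0:
            return np.zeros((self.p, 0))
        q, _ = np.linalg.qr(self.A[:, : self.d])
        return q

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "d": self.d,
            "source_specs": [s.to_dict() for s in self.source_specs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixingGroundTruth":
        return cls(
            A=np.asarray(d["A"], dtype=float),
            d=int(d["d"]),
            source_specs=tuple(SourceSpec.from_dict(s) for s in d["source_specs"]),
        )


@dataclass
class TrialSeries:
    """One subject-trial: a channels x time matrix with label and metadata."""

    subject_id: str
    trial_id: str
    data: np.ndarray
    sampling_rate_hz: float = 256.0
    label: int | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x time matrix")
        p, T = self.data.shape
        if p < 2:
            raise ValueError("need at least 2 channels")
        if T < 2 * p:
            raise ValueError(f"need T >= 2p samples, got T={T}, p={p}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be binary (0/1) or None")
        if self.channel_names is None and p == len(DEFAULT_MONTAGE_9):
            self.channel_names = DEFAULT_MONTAGE_9
        elif self.channel_names is None:
            self.channel_names = tuple(f"ch{i + 1}" for i in range(p))
        else:
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != p:
                raise ValueError("one channel name per row required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        """Trial duration in seconds (n_samples / sampling rate)."""
        return self.n_samples / self.sampling_rate_hz

    def with_data(self, data: np.ndarray) -> "TrialSeries":
        return TrialSeries(
            subject_id=self.subject_id,
            trial_id=self.trial_id,
            data=data,
            sampling_rate_hz=self.sampling_rate_hz,
            label=self.label,
            channel_names=self.channel_names if data.shape[0] == self.n_channels else None,
        )


@dataclass(frozen=True)
class ChoiceDatasetSpec:
    """Design of a synthetic binary-choice dataset.

    One trial per subject.  Class 1 and class 0 differ only in the lag-1
    coefficient of the stationary sources (``ar_base`` vs ``ar_base +
    effect_size``); the nonstationary sources are identically distributed in
    the two classes, so any predictive signal lives in the stationary
    subspace.  ``noise_scale`` multiplies the amplitude of the nonstationary
    sources before mixing.
    """

    n_subjects: int = 181
    p: int = 9
    d: int = 6
    T: int = 640
    prevalence: float = 0.70
    effect_size: float = 0.4
    noise_scale: float = 3.0
    ar_base: float = 0.3
    sampling_rate_hz: float = 256.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.p, self.T) <= 0 or not (0 <= self.d <= self.p):
            raise ValueError("sizes must be positive and 0 <= d <= p")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in the open unit interval")
        if self.noise_scale <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("scales must be positive")
        if abs(self.ar_base + self.effect_size) >= 1.0 or abs(self.ar_base) >= 1.0:
            raise ValueError(
                "effect_size pushes the stationary AR coefficient to "
                f"|{self.ar_base + self.effect_size:.3f}| >= 1"
            )


def _random_mixing_matrix(p: int, rng: np.random.Generator) -> np.ndarray:
    """Random orthogonal matrix times a diagonal of mild scales.

    The orthogonal factor is Haar-distributed (QR of a Gaussian matrix with
    the conventional sign fix); the diagonal scales in [0.5, 2] keep the
    condition number at most 4, so the mixing is always well identifiable.
    """
    g = rng.standard_normal((p, p))
    q, r = np.linalg.qr(g)
    q = q * np.sign(np.diag(r))
    scales = rng.uniform(0.5, 2.0, size=p)
    return q @ np.diag(scales)


def resonant_vma_spec(
    f0_hz: float,
    envelope: dict,
    sampling_rate_hz: float = 256.0,
    rho: float = 0.92,
    order: int = 16,
) -> SourceSpec:
    """Narrowband oscillation with a time-varying envelope, as a tv-VMA.

    The MA coefficients are the impulse response of a damped cosine resonant
    at ``f0_hz`` (decay ``rho`` per sample), and the whole MA part is scaled
    by the envelope profile — an amplitude-bursting rhythm like intermittent
    alpha or muscle activity.
    """
    theta = 2.0 * np.pi * f0_hz / sampling_rate_hz
    coeffs = [rho**i * np.cos(theta * i) for i in range(1, order + 1)]
    return SourceSpec(
        kind="tv_vma", order=order, params={"coeffs": coeffs, "scale_profile": envelope}
    )


def _nonstationary_specs(
    n: int, rng: np.random.Generator | None = None, sampling_rate_hz: float = 256.0
) -> list[SourceSpec]:
    """Alternate between two nonstationary artifact families.

    * an envelope-modulated narrowband oscillation (subject-specific
      resonance frequency and burst timing — intermittent alpha / EMG);
    * a variance-burst Gaussian (brief high-amplitude artifact like a
      blink, subject-specific timing).

    Both are strongly nonstationary on the single-trial timescale and
    survive band-pass filtering, so they are exactly the noise the subspace
    step must remove.  Unit-root drift is deliberately not in this default
    menu: the pipeline's 0.5 Hz high-pass removes drift almost entirely,
    leaving a nearly stationary residual that is no longer "noise" in the
    subspace sense (it remains available as a :class:`SourceSpec` kind).

    With an ``rng`` the subject-varying parameters (resonance frequency,
    burst centers) are drawn at random, as they differ across participants
    in real recordings; without one, fixed mid-range template values are
    used.
    """
    draw = (
        (lambda lo, hi, mid: rng.uniform(lo, hi)) if rng is not None else (lambda lo, hi, mid: mid)
    )
    specs = []
    for i in range(n):
        if i % 2 == 0:
            specs.append(
                resonant_vma_spec(
                    f0_hz=draw(6.0, 16.0, 10.0),
                    envelope={
                        "type": "bump",
                        "low": 0.15,
                        "high": 4.0,
                        "center": draw(0.2, 0.8, 0.6),
                        "width": 0.25,
                    },
                    sampling_rate_hz=sampling_rate_hz,
                )
            )
        else:
            specs.append(
                SourceSpec(
                    kind="gaussian_tv_variance",
                    order=0,
                    params={
                        "variance_profile": {
                            "type": "bump",
                            "low": 0.05,
                            "high": 12.0,
                            "center": draw(0.2, 0.8, 0.3),
                            "width": 0.12,
                        }
                    },
                )
            )
    return specs


def mix(truth: MixingGroundTruth, sources: np.ndarray) -> np.ndarray:
    """Observed data = A @ sources (the linear mixing model), exactly."""
    sources = np.asarray(sources, dtype=float)
    if sources.ndim != 2 or sources.shape[0] != truth.p:
        raise ValueError(
            f"sources must be {truth.p} x T to match the mixing matrix, "
            f"got shape {sources.shape}"
        )
    return truth.A @ sources


def generate_choice_dataset(
    spec: ChoiceDatasetSpec,
) -> tuple[list[TrialSeries], MixingGroundTruth]:
    """Generate one labeled trial per subject under a shared mixing matrix.

    Labels are Bernoulli(``prevalence``); class 1 subjects' stationary
    sources use AR coefficient ``ar_base + effect_size``, class 0 subjects
    use ``ar_base``.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    A = _random_mixing_matrix(spec.p, rng)
    base_stationary = [
        SourceSpec(kind="var_stationary", order=1, params={"coeffs": [spec.ar_base]})
        for _ in range(spec.d)
    ]
    template_nonstat = _nonstationary_specs(spec.p - spec.d, None, spec.sampling_rate_hz)
    truth = MixingGroundTruth(
        A=A, d=spec.d, source_specs=tuple(base_stationary + template_nonstat)
    )

    labels = (rng.random(spec.n_subjects) < spec.prevalence).astype(int)
    trials = []
    for j in range(spec.n_subjects):
        phi = spec.ar_base + (spec.effect_size if labels[j] == 1 else 0.0)
        stat_specs = [
            SourceSpec(kind="var_stationary", order=1, params={"coeffs": [phi]})
            for _ in range(spec.d)
        ]
        # subject-specific noise parameters (burst timing, resonance freq)
        nonstat = _nonstationary_specs(spec.p - spec.d, rng, spec.sampling_rate_hz)
        sources = generate_sources(stat_specs + nonstat, spec.T, rng)
        sources[spec.d :] *= spec.noise_scale
        trials.append(
            TrialSeries(
                subject_id=f"s{j + 1:03d}",
                trial_id="t01",
                data=mix(truth, sources),
                sampling_rate_hz=spec.sampling_rate_hz,
                label=int(labels[j]),
            )
        )
    return trials, truth


def write_dataset(
    trials: Sequence[TrialSeries],
    directory: str | Path,
    truth: MixingGroundTruth | None = None,
) -> Path:
    """Write trials as headerless channels x time CSVs plus a CSV manifest.

    Ground truth, when given, is serialised to ``ground_truth.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trials:
        fname = f"{tr.subject_id}_{tr.trial_id}.csv"
        np.savetxt(directory / fname, tr.data, delimiter=",")
        rows.append(
            {
                "subject_id": tr.subject_id,
                "trial_id": tr.trial_id,
                "label": tr.label if tr.label is not None else "",
                "sampling_rate": tr.sampling_rate_hz,
                "path": fname,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    if truth is not None:
        (directory / "ground_truth.json").write_text(json.dumps(truth.to_dict()))
    return directory


def read_dataset(
    directory: str | Path,
) -> tuple[list[TrialSeries], MixingGroundTruth | None]:
    """Read a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    trials = []
    for _, row in manifest.iterrows():
        data = np.loadtxt(directory / row["path"], delimiter=",")
        label = row["label"]
        label = None if pd.isna(label) or label == "" else int(label)
        trials.append(
            TrialSeries(
                subject_id=str(row["subject_id"]),
                trial_id=str(row["trial_id"]),
                data=data,
                sampling_rate_hz=float(row["sampling_rate"]),
                label=label,
            )
        )
    truth = None
    gt_path = directory / "ground_truth.json"
    if gt_path.exists():
        truth = MixingGroundTruth.from_dict(json.loads(gt_path.read_text()))
    return trials, truth
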