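"""Prediction models and cross-validated performance evaluation.

Three no-intercept logistic models predict the binary choice label from:

* M1 — the scalar prefrontal average;
* M2 — the 2-vector of class-mean spectral distances of the prewhitened
  observed series;
* M3 — the same distances computed on the stationary subspace series
  extracted per trial by DSSA or ISSA.

Performance is summarised by A1 (overall accuracy), A2 (mean of sensitivity
and specificity) and A3 (area under the ROC curve), all in percent, under
10-fold cross-validation, with a shuffled-label repetition scheme providing
the empirical chance baseline for each measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from dssa.spectral import (
    PREFRONTAL_CHANNELS,
    distances_from_gram,
    prefrontal_average,
    spectral_gram,
    spectral_matrix,
)
from dssa.ssa import estimate_dimension, optimize_dssa, optimize_issa
from dssa.synthetic import TrialSeries

__all__ = [
    "LogisticModel",
    "ConfusionMatrix",
    "CVReport",
    "FeatureContext",
    "DEFAULT_EVAL_CONFIG",
    "fit_logistic",
    "performance_measures",
    "auc",
    "prepare_features",
    "cross_validate",
    "shuffled_label_baseline",
]

MODEL_IDS = ("M1", "M2", "M3-dssa", "M3-issa")

#: Evaluation settings and their defaults; unknown keys are rejected.
DEFAULT_EVAL_CONFIG = {
    "folds": 10,
    "window": 25,  # Daniell smoothing window (odd)
    "d": 6,  # stationary-subspace dimension for M3, or "auto"
    "m": 10,  # number of DFT-autocovariance lags
    "epochs": 8,  # ISSA epoch count
    "restarts": 5,  # optimiser restarts per trial (M3)
    "alpha": 0.05,  # level for auto dimension estimation
    "ssa_seed": 0,
    "prefrontal_channels": PREFRONTAL_CHANNELS,
    "leave_test_out": True,  # class means from training fold only
    "pool_auc": False,  # A3 = mean of per-fold AUCs (cvAUC); True pools one ROC
    "intercept": False,
    "threshold": 0.5,
}


def _resolve_config(config: dict | None) -> dict:
    cfg = dict(DEFAULT_EVAL_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown evaluation config keys: {sorted(unknown)}")
        cfg.update(config)
    return cfg


@dataclass
class LogisticModel:
    """Fitted logistic regression; intercept optional and absent by default."""

    coefficients: np.ndarray
    intercept: float | None = None
    separated: bool = False
    converged: bool = True

    def __post_init__(self):
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficients")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(label = 1 | features), strictly inside (0, 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = X @ self.coefficients
        if self.intercept is not None:
            eta = eta + self.intercept
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-eta))
        return np.clip(p, 1e-12, 1.0 - 1e-12)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for the binary choice task (class 1 = product A).

    ``c_a``/``c_b`` are correct predictions of A/B, ``i_a``/``i_b`` the
    incorrect ones: ``i_b`` counts actual-A trials predicted B and ``i_a``
    actual-B trials predicted A.
    """

    c_a: int
    i_b: int
    i_a: int
    c_b: int

    def __post_init__(self):
        if min(self.c_a, self.i_b, self.i_a, self.c_b) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def t_a(self) -> int:
        return self.c_a + self.i_b

    @property
    def t_b(self) -> int:
        return self.i_a + self.c_b

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.c_a + other.c_a,
            self.i_b + other.i_b,
            self.i_a + other.i_a,
            self.c_b + other.c_b,
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            c_a=int(np.sum((y_true == 1) & (y_pred == 1))),
            i_b=int(np.sum((y_true == 1) & (y_pred == 0))),
            i_a=int(np.sum((y_true == 0) & (y_pred == 1))),
            c_b=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold confusion matrices and A1/A2/A3."""

    model_id: str
    fold_matrices: list
    pooled: ConfusionMatrix
    a1: float
    a2: float
    a3: float
    seed: int
    n_subjects: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "a1": self.a1,
            "a2": self.a2,
            "a3": self.a3,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "pooled": {
                "c_a": self.pooled.c_a,
                "i_b": self.pooled.i_b,
                "i_a": self.pooled.i_a,
                "c_b": self.pooled.c_b,
            },
            "folds": [
                {"c_a": cm.c_a, "i_b": cm.i_b, "i_a": cm.i_a, "c_b": cm.c_b}
                for cm in self.fold_matrices
            ],
            "diagnostics": {
                k: v
                for k, v in self.diagnostics.items()
                if isinstance(v, (bool, int, float, str))
                or (isinstance(v, list) and all(isinstance(x, (bool, int, float, str)) for x in v))
            },
        }


# ---------------------------------------------------------------------------
# Model fitting and measures
# ---------------------------------------------------------------------------


def fit_logistic(
    X: np.ndarray, y: np.ndarray, include_intercept: bool = False
) -> LogisticModel:
    """Maximum-likelihood logistic fit (IRLS/Newton, BFGS fallback).

    Perfect or quasi separation is detected, reported via the model's
    ``separated`` flag and a warning, and the iteration-capped coefficients
    are returned rather than raising.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(float)
    if X.shape[0] != y.size:  # accept a 1-D feature vector
        X = X.T
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
    design = sm.add_constant(X) if include_intercept else X
    separated = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separated = True
            res = sm.Logit(y, design).fit(disp=0, method="bfgs", maxiter=200)
            converged = False
    params = np.asarray(res.params, dtype=float)
    fitted = 1.0 / (1.0 + np.exp(-np.clip(design @ params, -700, 700)))
    if not separated and (np.all(np.abs(fitted - y) < 1e-8) or np.max(np.abs(params)) > 1e8):
        separated = True
    if separated:
        warnings.warn("(quasi-)separation detected in logistic fit", stacklevel=2)
    if include_intercept:
        return LogisticModel(
            coefficients=params[1:], intercept=float(params[0]),
            separated=separated, converged=converged,
        )
    return LogisticModel(coefficients=params, separated=separated, converged=converged)


def performance_measures(cm: ConfusionMatrix) -> tuple[float, float]:
    """Overall accuracy A1 and mean of sensitivity/specificity A2, in percent."""
    total = cm.t_a + cm.t_b
    if total == 0:
        raise ValueError("empty confusion matrix")
    a1 = 100.0 * (cm.c_a + cm.c_b) / total
    if cm.t_a == 0 or cm.t_b == 0:
        raise ValueError("A2 undefined: one class has no members")
    a2 = 100.0 * 0.5 * (cm.c_a / cm.t_a + cm.c_b / cm.t_b)
    return a1, a2


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, in percent (Mann-Whitney; ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    u = np.sum(ranks[labels == 1]) - n1 * (n1 + 1) / 2.0
    return float(100.0 * u / (n1 * n0))


# ---------------------------------------------------------------------------
# Feature preparation
# ---------------------------------------------------------------------------


@dataclass
class FeatureContext:
    """Label-independent feature state reusable across folds and permutations.

    For M1 the features are fixed scalars.  For M2/M3 the per-trial spectral
    matrices are summarised by their Gram matrix, from which any training
    fold's class-mean distance features follow in closed form — so repeated
    cross-validation (in particular the shuffled-label baseline) never
    recomputes spectra.
    """

    model_id: str
    labels: np.ndarray
    subject_ids: list
    scalar: np.ndarray | None = None  # M1
    gram: np.ndarray | None = None  # M2 / M3
    diagnostics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.labels)


def _fit_trial_subspace(data, method, d, cfg, seed):
    if method == "dssa":
        return optimize_dssa(data, d, m=cfg["m"], n_restarts=cfg["restarts"], seed=seed)
    return optimize_issa(data, d, N=cfg["epochs"], n_restarts=cfg["restarts"], seed=seed)


def prepare_features(
    trials: Sequence[TrialSeries], model_id: str, config: dict | None = None
) -> FeatureContext:
    """Build the label-independent feature state for one model.

    Trials are expected band-pass filtered and prewhitened.  For M3 the
    stationary subspace is fitted per trial (unsupervised, so no fold
    leakage); with ``d="auto"`` the dimension is estimated per trial and the
    modal estimate is used for every trial so the spectral matrices share a
    common size.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; choose from {MODEL_IDS}")
    cfg = _resolve_config(config)
    labels = np.asarray([t.label for t in trials])
    if any(l is None for l in labels):
        raise ValueError("all trials need labels")
    subject_ids = [t.subject_id for t in trials]
    diagnostics: dict = {}

    if model_id == "M1":
        x = np.asarray(
            [prefrontal_average(t, cfg["prefrontal_channels"]) for t in trials]
        )
        return FeatureContext(model_id, labels.astype(int), subject_ids, scalar=x)

    if model_id == "M2":
        spectra = [
            spectral_matrix(t.data, window=cfg["window"], subject_id=t.subject_id)
            for t in trials
        ]
    else:
        method = model_id.split("-")[1]
        seeds = np.random.SeedSequence(cfg["ssa_seed"]).generate_state(2 * len(trials))
        d_cfg = cfg["d"]
        if d_cfg == "auto":
            d_hats = [
                estimate_dimension(
                    t.data,
                    alpha=cfg["alpha"],
                    m=cfg["m"],
                    seed=int(seeds[2 * i + 1]),
                    n_restarts=cfg["restarts"],
                )
                for i, t in enumerate(trials)
            ]
            vals, cnt = np.unique(d_hats, return_counts=True)
            # modal estimate; ties resolve toward the larger dimension
            d_use = int(vals[cnt == cnt.max()].max())
            d_use = max(d_use, 1)
            diagnostics["d_estimates"] = [int(v) for v in d_hats]
            diagnostics["d_modal"] = d_use
        else:
            d_use = int(d_cfg)
        fits = [
            _fit_trial_subspace(t.data, method, d_use, cfg, int(seeds[2 * i]))
            for i, t in enumerate(trials)
        ]
        diagnostics["demixing"] = fits
        diagnostics["d_used"] = d_use
        spectra = [
            spectral_matrix(
                fit.B1 @ t.data, window=cfg["window"], subject_id=t.subject_id
            )
            for fit, t in zip(fits, trials)
        ]
    return FeatureContext(
        model_id,
        labels.astype(int),
        subject_ids,
        gram=spectral_gram(spectra),
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Cross-validation and the shuffled-label baseline
# ---------------------------------------------------------------------------


def _make_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, n_folds)]


def _fold_features(ctx: FeatureContext, labels, train_idx, eval_idx, cfg, training: bool):
    if ctx.model_id == "M1":
        return ctx.scalar[eval_idx][:, None]
    mean_idx = train_idx if cfg["leave_test_out"] else np.arange(ctx.n)
    # training trials leave themselves out of their own class mean
    return distances_from_gram(ctx.gram, labels, mean_idx, eval_idx, exclude_self=training)


def _cross_validate_context(
    ctx: FeatureContext, labels: np.ndarray, cfg: dict, seed: int
) -> CVReport:
    n = ctx.n
    labels = np.asarray(labels).astype(int)
    folds = _make_folds(n, cfg["folds"], np.random.default_rng(seed))
    for attempt in range(2):
        ok = all(len(np.unique(labels[np.setdiff1d(np.arange(n), f)])) == 2 for f in folds)
        if ok:
            break
        if attempt == 0:
            folds = _make_folds(n, cfg["folds"], np.random.default_rng(seed + 1))
        else:
            raise ValueError("a training fold contains a single class after re-randomisation")
    fold_matrices = []
    scores = np.empty(n)
    fold_aucs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            X_train = _fold_features(ctx, labels, train_idx, train_idx, cfg, training=True)
            X_test = _fold_features(ctx, labels, train_idx, test_idx, cfg, training=False)
            model = fit_logistic(X_train, labels[train_idx], cfg["intercept"])
            p = model.predict_proba(X_test)
            scores[test_idx] = p
            fold_matrices.append(
                ConfusionMatrix.from_predictions(labels[test_idx], p >= cfg["threshold"])
            )
            if len(np.unique(labels[test_idx])) == 2:
                fold_aucs.append(auc(p, labels[test_idx]))
    pooled = fold_matrices[0]
    for cm in fold_matrices[1:]:
        pooled = pooled + cm
    a1, a2 = performance_measures(pooled)
    if cfg["pool_auc"] or not fold_aucs:
        a3 = auc(scores, labels)
    else:
        a3 = float(np.mean(fold_aucs))
    return CVReport(
        model_id=ctx.model_id,
        fold_matrices=fold_matrices,
        pooled=pooled,
        a1=a1,
        a2=a2,
        a3=a3,
        seed=seed,
        n_subjects=n,
        diagnostics=dict(ctx.diagnostics),
    )


def cross_validate(
    trials: Sequence[TrialSeries],
    model_id: str,
    config: dict | None = None,
    seed: int = 0,
    context: FeatureContext | None = None,
) -> CVReport:
    """K-fold cross-validation of one prediction model.

    Subjects are shuffled by ``seed`` into nearly equal folds; per fold the
    class-mean spectra (for M2/M3) and the logistic model are built from
    training subjects only, and test-fold predictions at the configured
    threshold populate the confusion matrices.  A1/A2 come from the pooled
    confusion matrix; A3 defaults to the cross-validated AUC (mean of
    per-fold AUCs), with a pooled-ROC variant behind ``pool_auc``.

    A precomputed ``context`` (see :func:`prepare_features`) can be supplied
    to skip the spectral stage.
    """
    cfg = _resolve_config(config)
    ctx = context or prepare_features(trials, model_id, config)
    if ctx.n < 2 * cfg["folds"]:
        raise ValueError(f"need at least {2 * cfg['folds']} subjects for {cfg['folds']} folds")
    return _cross_validate_context(ctx, ctx.labels, cfg, seed)


def shuffled_label_baseline(
    trials: Sequence[TrialSeries],
    model_id: str,
    reps: int = 500,
    seed: int = 0,
    config: dict | None = None,
    context: FeatureContext | None = None,
) -> dict:
    """Chance baseline by refitting under uniform label permutations.

    Labels are permuted uniformly per repetition (preserving prevalence), a
    full cross-validation is run, and the three measures are averaged over
    repetitions.  Uses a seed stream independent of any single CV's fold
    seed.  Returns mean A1/A2/A3 plus the per-repetition arrays.
    """
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    cfg = _resolve_config(config)
    ctx = context or prepare_features(trials, model_id, config)
    ss = np.random.SeedSequence([seed, 0xBA5E])
    states = ss.generate_state(2 * reps)
    a1s, a2s, a3s = np.empty(reps), np.empty(reps), np.empty(reps)
    for i in range(reps):
        rng = np.random.default_rng(states[2 * i])
        shuffled = rng.permutation(ctx.labels)
        report = _cross_validate_context(ctx, shuffled, cfg, int(states[2 * i + 1]) % 2**31)
        a1s[i], a2s[i], a3s[i] = report.a1, report.a2, report.a3
    return {
        "a1": float(a1s.mean()),
        "a2": float(a2s.mean()),
        "a3": float(a3s.mean()),
        "reps": reps,
        "per_rep": {"a1": a1s, "a2": a2s, "a3": a3s},
    }
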