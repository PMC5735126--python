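"""Stationary subspace estimation.

Two objectives are provided, both minimised over d x p orthonormal frames
``B1`` (rows span the candidate stationary subspace of a prewhitened
p-channel series X):

* the frequency-domain (DSSA) objective: for a second-order stationary
  series the discrete Fourier transform is asymptotically uncorrelated
  across distinct Fourier frequencies, so the lag-r autocovariances of the
  DFT of ``Y = B1 X`` — summed over r = 1..m in squared Frobenius norm —
  measure departure from stationarity;
* the epoch-based (ISSA) objective: split the series into N contiguous
  epochs, fit a Gaussian to each, and sum the (reduced-form)
  Kullback-Leibler divergences between the per-epoch fits and their grand
  average.

The same DFT-autocovariance statistic, with a Fourier phase-surrogate null,
yields a formal stationarity test, and a top-down sequential procedure
estimates the unknown subspace dimension d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DFTSet",
    "DemixingResult",
    "EpochStats",
    "StationarityTestResult",
    "compute_dft",
    "dft_autocovariance",
    "dssa_objective",
    "optimize_dssa",
    "epoch_statistics",
    "issa_objective",
    "optimize_issa",
    "stationarity_test",
    "estimate_dimension",
]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class DFTSet:
    """DFT coefficients ``J(omega_k)`` of a d-variate series.

    Column ``k - 1`` holds the coefficient at the Fourier frequency
    ``omega_k = 2 pi k / T`` for k = 1..T (so the last column, k = T, is the
    DC-equivalent frequency ``2 pi``).  Normalisation is
    ``J(omega_k) = (2 pi T)^{-1/2} sum_{t=1}^{T} Z_t exp(-i t omega_k)``,
    under which the total squared coefficient mass equals the series'
    squared norm divided by ``2 pi`` (Parseval).
    """

    coefficients: np.ndarray

    @property
    def n_series(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_freq(self) -> int:
        return self.coefficients.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        T = self.n_freq
        return 2.0 * np.pi * np.arange(1, T + 1) / T


@dataclass
class DemixingResult:
    """Estimated stationary-subspace projection and optimiser diagnostics."""

    B1: np.ndarray
    objective: float
    d: int
    method: str
    n_restarts: int
    best_restart_seed: int
    converged: bool
    iterations: int
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.B1 = np.asarray(self.B1, dtype=float)
        dev = np.max(np.abs(self.B1 @ self.B1.T - np.eye(self.d)))
        if dev > 1e-8:
            raise ValueError(f"B1 rows deviate from orthonormality by {dev:.2e}")

    def to_dict(self) -> dict:
        return {
            "B1": self.B1.tolist(),
            "objective": float(self.objective),
            "d": int(self.d),
            "method": self.method,
            "n_restarts": int(self.n_restarts),
            "best_restart_seed": int(self.best_restart_seed),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
        }


@dataclass(frozen=True)
class EpochStats:
    """Per-epoch Gaussian moments and their grand averages."""

    means: np.ndarray  # (N, d)
    covariances: np.ndarray  # (N, d, d)
    grand_mean: np.ndarray  # (d,)
    grand_covariance: np.ndarray  # (d, d)

    @property
    def n_epochs(self) -> int:
        return self.means.shape[0]


@dataclass(frozen=True)
class StationarityTestResult:
    """DFT-autocovariance stationarity test outcome."""

    statistic: float
    p_value: float
    n_null_draws: int
    m: int

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.statistic < 0:
            raise ValueError("statistic must be nonnegative")


# ---------------------------------------------------------------------------
# DFT machinery
# ---------------------------------------------------------------------------


def compute_dft(Z: np.ndarray) -> DFTSet:
    """DFT of a d x T series at the Fourier frequencies ``2 pi k / T``, k=1..T.

    The sum runs over t = 1..T (not 0..T-1), which multiplies the standard
    FFT output by a per-frequency phase ``exp(-i omega_k)``; the overall
    scale is ``(2 pi T)^{-1/2}``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not np.all(np.isfinite(Z)):
        raise ValueError("input contains non-finite values")
    T = Z.shape[1]
    if T < 2:
        raise ValueError("need at least 2 samples")
    F = np.fft.fft(Z, axis=1)
    k = np.arange(1, T + 1)
    phase = np.exp(-2j * np.pi * k / T)
    coeff = F[:, k % T] * phase / np.sqrt(2.0 * np.pi * T)
    return DFTSet(coefficients=coeff)


def dft_autocovariance(dfts: DFTSet, r: int) -> np.ndarray:
    """Lag-r autocovariance of the DFT viewed as a sequence in k.

    ``Gamma_r = (1/T) sum_k J(omega_k) J(omega_{k+r})^*`` with ``*`` the
    conjugate transpose; the frequency index wraps modulo T.
    """
    T = dfts.n_freq
    if not 1 <= r < T:
        raise ValueError(f"lag r must satisfy 1 <= r < T, got r={r}")
    J = dfts.coefficients
    J_shift = np.roll(J, -r, axis=1)
    return J @ J_shift.conj().T / T


def _autocov_stack(Z: np.ndarray, m: int) -> np.ndarray:
    """Stack of the first m DFT autocovariance matrices of Z (m, d, d)."""
    dfts = compute_dft(Z)
    return np.stack([dft_autocovariance(dfts, r) for r in range(1, m + 1)])


def _nonstationarity_statistic(Z: np.ndarray, m: int) -> float:
    """``sum_{r=1..m} ||Gamma_r||_F^2`` — the departure-from-stationarity score."""
    G = _autocov_stack(Z, m)
    return float(np.sum(np.abs(G) ** 2))


def _check_frame(B1: np.ndarray, p: int | None = None) -> np.ndarray:
    B1 = np.atleast_2d(np.asarray(B1, dtype=float))
    if p is not None and B1.shape[1] != p:
        raise ValueError(f"frame has {B1.shape[1]} columns, expected {p}")
    dev = np.max(np.abs(B1 @ B1.T - np.eye(B1.shape[0])))
    if dev > _ORTHO_TOL:
        raise ValueError(f"B1 rows are not orthonormal (deviation {dev:.2e})")
    return B1


def dssa_objective(B1: np.ndarray, X: np.ndarray, m: int = 10) -> float:
    """Departure-from-stationarity of the projected series ``Y = B1 X``.

    Sums the squared Frobenius norms of the first m DFT autocovariances of
    Y.  Zero for exactly "frequency-uncorrelated" series; invariant under
    rotation of the frame's rows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B1 = _check_frame(B1, X.shape[0])
    if m < 1:
        raise ValueError("m must be >= 1")
    return _nonstationarity_statistic(B1 @ X, m)


# ---------------------------------------------------------------------------
# Optimisation over orthonormal frames
# ---------------------------------------------------------------------------


def _retract(B: np.ndarray) -> np.ndarray:
    """Map a full-rank d x p matrix to the nearest-ish orthonormal frame (QR)."""
    q, r = np.linalg.qr(B.T)
    return (q * np.sign(np.diag(r))).T


def _tangent_project(grad: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Project a Euclidean gradient onto the tangent space of the frame manifold."""
    GB = grad @ B.T
    return grad - 0.5 * (GB + GB.T) @ B


def _minimize_on_frames(fun, grad, B0, max_iter=500, tol=1e-8):
    """Steepest descent with QR retraction and Armijo backtracking.

    Accepted iterates are monotonically non-increasing in the objective.
    Returns (B, f, history, converged, iterations).
    """
    B = B0
    f = fun(B)
    history = [f]
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = _tangent_project(grad(B), B)
        gnorm2 = float(np.sum(g * g))
        if gnorm2 < 1e-30:
            converged = True
            break
        step = min(step * 2.0, 1e6)
        accepted = False
        for _ in range(40):
            B_new = _retract(B - step * g)
            f_new = fun(B_new)
            if f_new <= f - 1e-4 * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no descent direction at line-search resolution
            break
        rel_change = abs(f - f_new) / max(1.0, abs(f))
        B, f = B_new, f_new
        history.append(f)
        if rel_change < tol:
            converged = True
            break
    return B, f, np.asarray(history), converged, it


def _warn_if_not_prewhitened(X: np.ndarray) -> None:
    centered = X - X.mean(axis=1, keepdims=True)
    S = centered @ centered.T / X.shape[1]
    if np.max(np.abs(S - np.eye(X.shape[0]))) > 0.1:
        warnings.warn(
            "input does not look prewhitened (sample covariance far from "
            "identity); subspace objectives assume prewhitened data",
            stacklevel=3,
        )


def _best_of_restarts(fun, grad, p, d, n_restarts, seed, max_iter, tol, method):
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best = None
    for s in seeds:
        rng = np.random.default_rng(s)
        B0 = _retract(rng.standard_normal((d, p)))
        B, f, hist, conv, it = _minimize_on_frames(fun, grad, B0, max_iter, tol)
        if best is None or f < best[1]:
            best = (B, f, hist, conv, it, int(s))
    B, f, hist, conv, it, s = best
    return DemixingResult(
        B1=B,
        objective=f,
        d=d,
        method=method,
        n_restarts=n_restarts,
        best_restart_seed=s,
        converged=conv,
        iterations=it,
        objective_history=hist,
    )


def optimize_dssa(
    X: np.ndarray,
    d: int,
    m: int = 10,
    n_restarts: int = 10,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> DemixingResult:
    """Best-of-restarts minimiser of the frequency-domain objective.

    Restart frames are Haar-distributed (QR of Gaussian matrices) drawn from
    ``seed``; the result is deterministic given the seed.  At ``d == p``
    the objective is invariant over frames (any full frame is a rotation),
    so the identity frame is returned directly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[0]
    if not 1 <= d <= p:
        raise ValueError(f"need 1 <= d <= p, got d={d}, p={p}")
    _warn_if_not_prewhitened(X)
    G = _autocov_stack(X, m)  # (m, p, p) complex
    if d == p:
        B = np.eye(p)
        return DemixingResult(
            B1=B,
            objective=float(np.sum(np.abs(G) ** 2)),
            d=d,
            method="dssa",
            n_restarts=0,
            best_restart_seed=-1,
            converged=True,
            iterations=0,
            objective_history=np.asarray([float(np.sum(np.abs(G) ** 2))]),
        )

    def fun(B):
        M = B @ G @ B.T  # (m, d, d)
        return float(np.sum(np.abs(M) ** 2))

    def grad(B):
        M = B @ G @ B.T
        # d/dB sum_r ||B G_r B^T||_F^2 for complex G_r
        term = np.conj(M) @ B @ G.transpose(0, 2, 1) + np.conj(M).transpose(0, 2, 1) @ B @ G
        return 2.0 * np.real(term.sum(axis=0))

    return _best_of_restarts(fun, grad, p, d, n_restarts, seed, max_iter, tol, "dssa")


# ---------------------------------------------------------------------------
# Epoch (ISSA) machinery
# ---------------------------------------------------------------------------


def epoch_statistics(Y: np.ndarray, N: int) -> EpochStats:
    """Sample mean and covariance of N contiguous equal blocks.

    Remainder samples are appended to the last block.  Grand statistics are
    the arithmetic means of the per-epoch ones.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    d, T = Y.shape
    if N < 1:
        raise ValueError("N must be >= 1")
    if T < N * (d + 1):
        raise ValueError(f"series too short: need T >= N (d+1) = {N * (d + 1)}, got {T}")
    base = T // N
    means = np.empty((N, d))
    covs = np.empty((N, d, d))
    for i in range(N):
        start = i * base
        stop = (i + 1) * base if i < N - 1 else T
        block = Y[:, start:stop]
        mu = block.mean(axis=1)
        centered = block - mu[:, None]
        means[i] = mu
        covs[i] = centered @ centered.T / block.shape[1]
    return EpochStats(
        means=means,
        covariances=covs,
        grand_mean=means.mean(axis=0),
        grand_covariance=covs.mean(axis=0),
    )


def issa_objective(B1: np.ndarray, X: np.ndarray, N: int = 8) -> float:
    """Reduced epoch-KL objective of the projected series.

    ``L = sum_i ( -log det Sigma_i^s + ||mu_i^s - mu_bar^s||^2 )`` where the
    per-epoch moments are those of ``Y = B1 X``.  The reduced form drops the
    trace term of the Gaussian KL divergence, which is principled when the
    input is prewhitened (grand covariance ~ identity).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B1 = _check_frame(B1, X.shape[0])
    stats = epoch_statistics(X, N)
    mu_s = stats.means @ B1.T  # (N, d)
    mu_bar = mu_s.mean(axis=0)
    L = 0.0
    for i in range(N):
        sigma_s = B1 @ stats.covariances[i] @ B1.T
        sign, logdet = np.linalg.slogdet(sigma_s)
        if sign <= 0:
            raise ValueError(f"projected covariance of epoch {i} is not positive definite")
        diff = mu_s[i] - mu_bar
        L += -logdet + float(diff @ diff)
    return float(L)


def optimize_issa(
    X: np.ndarray,
    d: int,
    N: int = 8,
    n_restarts: int = 10,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> DemixingResult:
    """Best-of-restarts minimiser of the epoch-KL objective."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[0]
    if not 1 <= d <= p:
        raise ValueError(f"need 1 <= d <= p, got d={d}, p={p}")
    _warn_if_not_prewhitened(X)
    stats = epoch_statistics(X, N)
    mu_dev = stats.means - stats.grand_mean  # (N, p)
    covs = stats.covariances  # (N, p, p)

    def fun(B):
        total = 0.0
        for i in range(len(covs)):
            sigma = B @ covs[i] @ B.T
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return np.inf
            v = B @ mu_dev[i]
            total += -logdet + float(v @ v)
        return total

    def grad(B):
        g = np.zeros_like(B)
        for i in range(len(covs)):
            BS = B @ covs[i]
            sigma = BS @ B.T
            g += -2.0 * np.linalg.solve(sigma, BS)
            v = B @ mu_dev[i]
            g += 2.0 * np.outer(v, mu_dev[i])
        return g

    if d == p:
        B = np.eye(p)
        f = fun(B)
        return DemixingResult(
            B1=B,
            objective=f,
            d=d,
            method="issa",
            n_restarts=0,
            best_restart_seed=-1,
            converged=True,
            iterations=0,
            objective_history=np.asarray([f]),
        )
    return _best_of_restarts(fun, grad, p, d, n_restarts, seed, max_iter, tol, "issa")


# ---------------------------------------------------------------------------
# Stationarity testing and dimension estimation
# ---------------------------------------------------------------------------


def _standardized_dft(Y: np.ndarray, window: int) -> np.ndarray:
    """DFT coefficients whitened by the Daniell-smoothed spectral matrix.

    ``J~(omega_k) = f^(omega_k)^{-1/2} J(omega_k)`` with ``f^`` the circular
    moving-average (length ``window``) of the cross-periodogram.  The
    standardisation equalises magnitudes across frequencies, so the
    DFT-autocovariance statistic of the standardised coefficients responds
    to phase coherence between nearby frequencies (the signature of
    nonstationarity) rather than to raw spectral power — without it,
    processes whose energy concentrates on a few frequencies (integrated
    noise, say) would dominate observed and surrogate statistics alike.
    """
    from scipy.ndimage import uniform_filter1d

    d, T = Y.shape
    J = compute_dft(Y).coefficients  # (d, T)
    perio = np.einsum("ik,jk->kij", J, J.conj())  # (T, d, d)
    fhat = uniform_filter1d(perio.real, size=window, axis=0, mode="wrap") + 1j * (
        uniform_filter1d(perio.imag, size=window, axis=0, mode="wrap")
    )
    fhat = 0.5 * (fhat + fhat.conj().transpose(0, 2, 1))
    eigval, eigvec = np.linalg.eigh(fhat)  # (T, d), (T, d, d)
    floor = 1e-12 * eigval[:, -1:].max()
    inv_sqrt = eigvec @ (eigvec.conj().transpose(0, 2, 1) / np.sqrt(np.maximum(eigval, floor))[:, :, None])
    return np.einsum("kij,jk->ik", inv_sqrt, J)


def _surrogate_phases(T: int, rng: np.random.Generator) -> np.ndarray:
    """Random conjugate-symmetric phase vector over the k = 1..T grid."""
    phi = np.zeros(T)
    half = (T - 1) // 2  # frequencies k = 1..half have mirrors T-k
    phi[:half] = 2.0 * np.pi * rng.random(half)  # k = 1..half at index k-1
    for k in range(1, half + 1):
        phi[T - k - 1] = -phi[k - 1]
    phases = np.exp(1j * phi)
    if T % 2 == 0:
        phases[T // 2 - 1] = rng.choice([-1.0, 1.0])  # Nyquist k = T/2
    phases[T - 1] = 1.0  # DC-equivalent k = T
    return phases


def stationarity_test(
    Y: np.ndarray,
    m: int = 10,
    n_null_draws: int = 199,
    seed: int | None = 0,
    window: int = 25,
) -> StationarityTestResult:
    """Test second-order stationarity via standardised DFT autocovariances.

    The statistic is ``sum_{r=1..m} ||Gamma_r||_F^2`` computed on DFT
    coefficients standardised by the Daniell-smoothed spectral matrix
    (length ``window``); for a stationary series the standardised
    coefficients are asymptotically uncorrelated across frequencies, so the
    statistic is small.  The null distribution is approximated by Fourier
    phase surrogates — random conjugate-symmetric phases applied to the
    standardised coefficients, which preserve every amplitude (hence the
    spectral estimate) while destroying the cross-frequency phase coherence
    that time-varying dynamics induce.  The p-value uses the add-one
    permutation convention ``(1 + #{null >= observed}) / (1 + n_null_draws)``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    T = Y.shape[1]
    if T < 64:
        raise ValueError("need T >= 64 for a meaningful stationarity test")
    if n_null_draws < 19:
        raise ValueError("n_null_draws must be >= 19 for usable p-value resolution")
    if window % 2 == 0 or window >= T:
        raise ValueError("window must be odd and smaller than T")
    rng = np.random.default_rng(seed)

    def statistic(J: np.ndarray) -> float:
        total = 0.0
        for r in range(1, m + 1):
            J_shift = np.roll(J, -r, axis=1)
            total += float(np.sum(np.abs(J @ J_shift.conj().T / T) ** 2))
        return total

    J_std = _standardized_dft(Y, window)
    observed = statistic(J_std)
    exceed = 0
    for _ in range(n_null_draws):
        if statistic(J_std * _surrogate_phases(T, rng)) >= observed:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_null_draws)
    return StationarityTestResult(
        statistic=observed, p_value=p_value, n_null_draws=n_null_draws, m=m
    )


def estimate_dimension(
    X: np.ndarray,
    alpha: float = 0.05,
    m: int = 10,
    seed: int | None = 0,
    n_restarts: int = 5,
    n_null_draws: int = 99,
    max_iter: int = 500,
) -> int:
    """Sequential top-down estimate of the stationary-subspace dimension.

    The full p-dimensional series is tested first; if it passes, ``d = p``.
    Otherwise candidate frames are fitted for d = p-1 down to 1 and the
    largest d whose projected series passes the stationarity test at level
    ``alpha`` is returned; 0 if none does.  Ties therefore resolve toward
    retaining more signal.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[0]
    child = np.random.SeedSequence(seed).generate_state(2 * p)
    res = stationarity_test(X, m=m, n_null_draws=n_null_draws, seed=int(child[0]))
    if res.p_value > alpha:
        return p
    for d in range(p - 1, 0, -1):
        fit = optimize_dssa(
            X, d, m=m, n_restarts=n_restarts, seed=int(child[2 * d]), max_iter=max_iter
        )
        res = stationarity_test(
            fit.B1 @ X, m=m, n_null_draws=n_null_draws, seed=int(child[2 * d + 1])
        )
        if res.p_value > alpha:
            return d
    return 0
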