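"""Gaussian-emission hidden Markov models with diagonal covariance.

This module implements the probabilistic engine behind every panel
classifier in the package: EM fitting (Baum-Welch for ordered sequences,
Gaussian-mixture EM for cross-sectional data), scaled forward-backward
posterior inference, and BIC-based selection of the number of hidden
states.

Two sequence modes are supported.  In ``per_sample`` mode every sample is
a length-1 sequence: with no transitions to estimate the model is a
principled Gaussian mixture, the initial distribution coincides with the
mixing weights, and the transition matrix is unidentifiable and frozen
uniform.  In ``concatenated`` mode the rows of the observation matrix are
treated as one ordered sequence and the full Baum-Welch recursion is run.
Cross-sectional patient cohorts have no natural ordering, so
``per_sample`` is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GaussianHMMSpec",
    "GaussianHMMFit",
    "DegenerateDataError",
    "fit_em",
    "forward_backward",
    "bic",
    "select_states",
]

_VAR_FLOOR = 1e-6
_LOG2PI = math.log(2.0 * math.pi)


class DegenerateDataError(ValueError):
    """Raised when the observations cannot support a Gaussian fit."""


@dataclass(frozen=True)
class GaussianHMMSpec:
    """Structural description of a Gaussian HMM.

    Parameters
    ----------
    n_states : int
        Number of hidden states K (>= 1).
    n_features : int
        Emission dimension D (panel size).
    sequence_mode : {"per_sample", "concatenated"}
        Whether rows of the observation matrix are independent length-1
        sequences or a single ordered sequence.
    """

    n_states: int
    n_features: int
    covariance_structure: str = "diagonal"
    sequence_mode: str = "per_sample"

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.covariance_structure != "diagonal":
            raise ValueError("only diagonal covariance is supported")
        if self.sequence_mode not in ("per_sample", "concatenated"):
            raise ValueError(f"unknown sequence_mode {self.sequence_mode!r}")

    @property
    def n_free_parameters(self) -> int:
        """Free parameters: initial distribution, transitions (ordered mode
        only), and per-state diagonal means/variances."""
        k, d = self.n_states, self.n_features
        p = (k - 1) + 2 * k * d
        if self.sequence_mode == "concatenated":
            p += k * (k - 1)
        return p


@dataclass
class GaussianHMMFit:
    """A fitted Gaussian HMM.

    ``startprob`` sums to 1 and each row of ``transmat`` sums to 1 (both
    within 1e-10); variances are floored at 1e-6.  ``bic`` equals
    ``-2*log_likelihood + p_free*ln(n_obs)``.
    """

    spec: GaussianHMMSpec
    startprob: np.ndarray  # (K,)
    transmat: np.ndarray  # (K, K)
    means: np.ndarray  # (K, D)
    variances: np.ndarray  # (K, D)
    log_likelihood: float
    bic: float
    n_obs: int
    converged: bool
    n_iter: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_states": self.spec.n_states,
            "n_features": self.spec.n_features,
            "sequence_mode": self.spec.sequence_mode,
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }


def _as_matrix(observations: np.ndarray) -> np.ndarray:
    x = np.asarray(observations, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("observations must be an (N, D) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("observations contain non-finite values")
    return x


def _log_gauss(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Log density of each row of x under each state's diagonal Gaussian.

    Returns an (N, K) matrix.
    """
    # (N, 1, D) - (K, D) -> (N, K, D)
    diff = x[:, None, :] - means[None, :, :]
    return -0.5 * np.sum(
        diff * diff / variances[None, :, :] + np.log(variances)[None, :, :] + _LOG2PI,
        axis=2,
    )


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    amax = np.max(a, axis=axis, keepdims=True)
    out = amax + np.log(np.sum(np.exp(a - amax), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


def _init_params(
    x: np.ndarray, k: int, rng: np.random.Generator, jitter_scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-sliced means along the first principal direction, plus jitter.

    Returns (means, variances).  The first restart uses jitter_scale 0 so a
    clean deterministic initialisation is always among the candidates.
    """
    n, d = x.shape
    centered = x - x.mean(axis=0)
    if k == 1:
        means = x.mean(axis=0)[None, :].copy()
    else:
        # first right singular vector = first principal direction
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        order = np.argsort(proj, kind="stable")
        slices = np.array_split(order, k)
        means = np.vstack([x[idx].mean(axis=0) for idx in slices])
    col_sd = x.std(axis=0)
    if jitter_scale > 0:
        means = means + rng.normal(0.0, 1.0, size=(k, d)) * jitter_scale * (col_sd + 1e-12)
    variances = np.maximum(np.tile(x.var(axis=0), (k, 1)), _VAR_FLOOR)
    return means, variances


def _em_mixture(
    x: np.ndarray,
    startprob: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    """EM for the per_sample (Gaussian mixture) case."""
    n = x.shape[0]
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logb = _log_gauss(x, means, variances)
        logw = logb + np.log(startprob)[None, :]
        norm = _logsumexp(logw, axis=1)
        ll = float(np.sum(norm))
        gamma = np.exp(logw - norm[:, None])
        if ll + 1e-8 * (1.0 + abs(ll)) < ll_prev:
            raise RuntimeError(
                f"EM log-likelihood decreased ({ll_prev:.10g} -> {ll:.10g})"
            )
        if abs(ll - ll_prev) <= tol * (1.0 + abs(ll)):
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
        nk = gamma.sum(axis=0) + 1e-300
        startprob = nk / n
        means = (gamma.T @ x) / nk[:, None]
        diff = x[:, None, :] - means[None, :, :]
        variances = np.maximum(
            np.einsum("nk,nkd->kd", gamma, diff * diff) / nk[:, None], _VAR_FLOOR
        )
    return startprob, means, variances, ll_prev, converged, it


def _forward_backward_scaled(
    startprob: np.ndarray, transmat: np.ndarray, logb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Scaled forward-backward on one sequence.

    logb is the (T, K) emission log-density matrix.  Returns
    (gamma, xi_sum, log_likelihood, alpha_hat, scale).
    """
    t_len, k = logb.shape
    # scale emission densities per time step to avoid underflow
    bmax = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - bmax)
    alpha = np.empty((t_len, k))
    scale = np.empty(t_len)
    alpha[0] = startprob * b[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, t_len):
        alpha[t] = (alpha[t - 1] @ transmat) * b[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta = np.empty((t_len, k))
    beta[-1] = 1.0
    for t in range(t_len - 2, -1, -1):
        beta[t] = (transmat @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((k, k))
    for t in range(t_len - 1):
        xi = (
            alpha[t][:, None]
            * transmat
            * (b[t + 1] * beta[t + 1])[None, :]
            / scale[t + 1]
        )
        xi_sum += xi
    ll = float(np.sum(np.log(scale)) + np.sum(bmax))
    return gamma, xi_sum, ll, alpha, scale


def _em_baum_welch(
    x: np.ndarray,
    startprob: np.ndarray,
    transmat: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logb = _log_gauss(x, means, variances)
        gamma, xi_sum, ll, _, _ = _forward_backward_scaled(startprob, transmat, logb)
        if ll + 1e-8 * (1.0 + abs(ll)) < ll_prev:
            raise RuntimeError(
                f"EM log-likelihood decreased ({ll_prev:.10g} -> {ll:.10g})"
            )
        if abs(ll - ll_prev) <= tol * (1.0 + abs(ll)):
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
        startprob = gamma[0] / gamma[0].sum()
        denom = xi_sum.sum(axis=1, keepdims=True)
        transmat = np.where(denom > 0, xi_sum / np.maximum(denom, 1e-300), transmat)
        transmat /= transmat.sum(axis=1, keepdims=True)
        nk = gamma.sum(axis=0) + 1e-300
        means = (gamma.T @ x) / nk[:, None]
        diff = x[:, None, :] - means[None, :, :]
        variances = np.maximum(
            np.einsum("nk,nkd->kd", gamma, diff * diff) / nk[:, None], _VAR_FLOOR
        )
    return startprob, transmat, means, variances, ll_prev, converged, it


def fit_em(
    observations: np.ndarray,
    spec: GaussianHMMSpec,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> GaussianHMMFit:
    """Fit a Gaussian HMM by expectation-maximisation.

    Runs ``n_restarts`` EM runs from quantile-sliced/jittered initial
    means (restart 0 is jitter-free) and keeps the run with the highest
    final log-likelihood; ties resolve to the earliest restart, so the
    result is bit-reproducible for a given seed.

    Raises
    ------
    ValueError
        If there are fewer observations than states.
    DegenerateDataError
        If every observation row is identical.
    """
    x = _as_matrix(observations)
    n, d = x.shape
    if d != spec.n_features:
        raise ValueError(f"observations have D={d}, spec expects D={spec.n_features}")
    if n < spec.n_states:
        raise ValueError(f"need at least K={spec.n_states} observations, got {n}")
    if np.all(x == x[0]):
        raise DegenerateDataError("all observations identical; Gaussian fit degenerate")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    k = spec.n_states
    best: tuple | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng([seed % (2**31), r])
        jitter = 0.0 if r == 0 else 0.25
        means0, var0 = _init_params(x, k, rng, jitter)
        pi0 = np.full(k, 1.0 / k)
        if spec.sequence_mode == "per_sample":
            pi, mu, var, ll, conv, it = _em_mixture(x, pi0, means0, var0, max_iter, tol)
            a = np.full((k, k), 1.0 / k)
        else:
            a0 = np.full((k, k), 0.2 / max(k - 1, 1))
            np.fill_diagonal(a0, 0.8 if k > 1 else 1.0)
            a0 /= a0.sum(axis=1, keepdims=True)
            pi, a, mu, var, ll, conv, it = _em_baum_welch(
                x, pi0, a0, means0, var0, max_iter, tol
            )
        if best is None or ll > best[0]:
            best = (ll, pi, a, mu, var, conv, it, r)

    ll, pi, a, mu, var, conv, it, _ = best
    fit = GaussianHMMFit(
        spec=spec,
        startprob=pi,
        transmat=a,
        means=mu,
        variances=var,
        log_likelihood=ll,
        bic=0.0,
        n_obs=n,
        converged=conv,
        n_iter=it,
        seed=seed,
    )
    fit.bic = bic(fit)
    return fit


def forward_backward(
    fit: GaussianHMMFit, observations: np.ndarray
) -> tuple[np.ndarray, float]:
    """Posterior state probabilities and log-likelihood for new data.

    In ``per_sample`` mode each row is scored independently:
    ``gamma[i, k] = pi_k N(x_i; mu_k, var_k) / sum_j pi_j N(x_i; mu_j, var_j)``.
    In ``concatenated`` mode the scaled forward-backward recursion is run
    over the rows as one sequence.

    Returns
    -------
    gamma : (N, K) array whose rows sum to 1.
    log_likelihood : float
    """
    x = _as_matrix(observations)
    if x.shape[1] != fit.spec.n_features:
        raise ValueError(
            f"observations have D={x.shape[1]}, fit expects D={fit.spec.n_features}"
        )
    logb = _log_gauss(x, fit.means, fit.variances)
    if fit.spec.sequence_mode == "per_sample":
        logw = logb + np.log(fit.startprob)[None, :]
        norm = _logsumexp(logw, axis=1)
        return np.exp(logw - norm[:, None]), float(np.sum(norm))
    gamma, _, ll, _, _ = _forward_backward_scaled(fit.startprob, fit.transmat, logb)
    return gamma, ll


def bic(fit: GaussianHMMFit) -> float:
    """Bayesian Information Criterion: ``-2 logL + p_free ln(n_obs)``.

    ``per_sample`` mode counts samples as observations and excludes the
    (unidentifiable) transition matrix from the parameter count.
    """
    p_free = fit.spec.n_free_parameters
    return -2.0 * fit.log_likelihood + p_free * math.log(fit.n_obs)


def select_states(
    observations: np.ndarray,
    k_range: range | list[int] | tuple[int, ...],
    spec: GaussianHMMSpec,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> GaussianHMMFit:
    """Fit one model per candidate K and return the minimum-BIC fit.

    Ties (within nothing — comparison is strict) resolve to the smaller K
    because candidates are visited in ascending order.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    if ks[0] < 1 or ks[-1] > 5:
        raise ValueError("k_range must lie within [1, 5]")
    best: GaussianHMMFit | None = None
    for k in ks:
        cand = fit_em(
            observations,
            replace(spec, n_states=k),
            n_restarts=n_restarts,
            max_iter=max_iter,
            tol=tol,
            seed=seed,
        )
        if best is None or cand.bic < best.bic:
            best = cand
    return best
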