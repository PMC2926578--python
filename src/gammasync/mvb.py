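"""The multivariate beta (MVB) distribution on the open unit hypercube.

A J-vector U follows MVB(theta_1, ..., theta_{J+1}) when V with
v_j = u_j / (1 - u_j) is inverted-Dirichlet; equivalently
u_j = G_j / (G_j + G_{J+1}) for independent unit-scale gamma variates
G_j ~ Gamma(theta_j). The log-density is

    log f(u) = log G(sum theta) - sum_j log G(theta_j)
             + sum_{j<=J} [ (theta_j - 1) log u_j - (theta_j + 1) log(1 - u_j) ]
             - (sum theta) * log(1 + sum_{j<=J} u_j / (1 - u_j)),

which for J = 1 reduces exactly to Beta(theta_1, theta_2). All
evaluation is done in the log domain: shape parameters of the size seen
in practice (up to ~40-50) would overflow the gamma function otherwise.

Maximum likelihood, optionally with nonnegative observation weights
(as required by the M-step of an EM fit), is solved over eta = log theta
with an analytic gradient; the weighted log-likelihood depends on the
data only through fixed sufficient statistics, so each solve is cheap
regardless of sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, psi

from .errors import OptimizationFailureError

__all__ = ["MVBParams", "mvb_logdensity", "mvb_loglik", "mvb_mle", "mvb_sample"]

_THETA_FLOOR = 1e-6


@dataclass(frozen=True)
class MVBParams:
    """Parameter vector theta = (theta_1, ..., theta_{J+1}), all positive."""

    theta: np.ndarray

    def __post_init__(self):
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if theta.ndim != 1 or theta.size < 2:
            raise ValueError("theta must be a vector of length J + 1 >= 2")
        if not np.all(np.isfinite(theta)) or np.any(theta <= 0):
            raise ValueError("all theta_j must be positive and finite")
        object.__setattr__(self, "theta", theta)

    @property
    def J(self) -> int:
        return self.theta.size - 1

    def to_dict(self) -> dict:
        return {"theta": self.theta.tolist(), "J": self.J}

    @classmethod
    def from_dict(cls, d: dict) -> "MVBParams":
        p = cls(theta=np.asarray(d["theta"], dtype=float))
        if "J" in d and d["J"] != p.J:
            raise ValueError("stored J inconsistent with theta length")
        return p


def mvb_logdensity(u: np.ndarray, params: MVBParams) -> float | np.ndarray:
    """Log-density of the MVB distribution at ``u``.

    ``u`` may be a single J-vector or an (N, J) matrix; the return is a
    scalar or length-N vector accordingly.
    """
    theta = params.theta
    J = params.J
    U = np.asarray(u, dtype=float)
    squeeze = U.ndim == 1
    U = np.atleast_2d(U)
    if U.shape[1] != J:
        raise ValueError(f"u must have {J} components, got {U.shape[1]}")
    if np.any(U <= 0.0) or np.any(U >= 1.0):
        raise ValueError("all u_j must lie strictly inside (0, 1)")
    s = theta.sum()
    const = gammaln(s) - gammaln(theta).sum()
    logu = np.log(U)
    log1mu = np.log1p(-U)
    core = logu @ (theta[:J] - 1.0) - log1mu @ (theta[:J] + 1.0)
    tail = s * np.log1p(np.exp(logu - log1mu).sum(axis=1))
    out = const + core - tail
    return float(out[0]) if squeeze else out


def mvb_loglik(
    U: np.ndarray, params: MVBParams, weights: np.ndarray | None = None
) -> float:
    """(Weighted) log-likelihood: sum_i w_i * log f(U_i)."""
    ld = mvb_logdensity(np.atleast_2d(np.asarray(U, float)), params)
    if weights is None:
        return float(np.sum(ld))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (np.atleast_2d(U).shape[0],):
        raise ValueError("weights must have one entry per observation")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    return float(weights @ ld)


def _suff_stats(U: np.ndarray, weights: np.ndarray | None):
    U = np.atleast_2d(np.asarray(U, dtype=float))
    n, J = U.shape
    if np.any(U <= 0.0) or np.any(U >= 1.0):
        raise ValueError("all entries of U must lie strictly inside (0, 1)")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must have one entry per observation")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    logu = np.log(U)
    log1mu = np.log1p(-U)
    A = w @ logu  # (J,) sum w_i log u_ij
    B = w @ log1mu  # (J,)
    TS = float(w @ np.log1p(np.exp(logu - log1mu).sum(axis=1)))
    W = float(w.sum())
    return A, B, TS, W, J


def _loglik_from_stats(theta, A, B, TS, W, J):
    s = theta.sum()
    return (
        W * (gammaln(s) - gammaln(theta).sum())
        + (theta[:J] - 1.0) @ A
        - (theta[:J] + 1.0) @ B
        - s * TS
    )


def _grad_from_stats(theta, A, B, TS, W, J):
    s = theta.sum()
    g = W * (psi(s) - psi(theta)) - TS
    g[:J] += A - B
    return g


def mvb_mle(
    U: np.ndarray,
    weights: np.ndarray | None = None,
    init: MVBParams | None = None,
) -> MVBParams:
    """Maximum-likelihood fit of the MVB parameter vector.

    Optimizes over eta = log theta (unconstrained) with L-BFGS-B and an
    analytic gradient, starting from ``init`` (all-ones by default).
    The returned fit never has a lower likelihood than the start.

    Raises
    ------
    OptimizationFailureError
        If the optimizer stops abnormally; carries the best-so-far
        parameters in ``best_params``.
    """
    A, B, TS, W, J = _suff_stats(U, weights)
    if W <= 0:
        raise ValueError("total weight must be positive")
    theta0 = np.ones(J + 1) if init is None else init.theta.copy()
    if theta0.size != J + 1:
        raise ValueError("init has the wrong dimension")
    ll0 = _loglik_from_stats(theta0, A, B, TS, W, J)

    def negloglik(eta):
        theta = np.exp(eta)
        f = -_loglik_from_stats(theta, A, B, TS, W, J)
        g = -_grad_from_stats(theta, A, B, TS, W, J) * theta
        return f, g

    res = minimize(
        negloglik,
        np.log(theta0),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    theta_hat = np.maximum(np.exp(res.x), _THETA_FLOOR)
    ll_hat = _loglik_from_stats(theta_hat, A, B, TS, W, J)
    if not np.isfinite(ll_hat) or ll_hat < ll0:
        # ascent contract: never leave the caller worse than its start
        theta_hat, ll_hat = theta0, ll0
    if not res.success and res.status not in (0, 2):
        raise OptimizationFailureError(
            f"MVB likelihood maximization did not converge: {res.message}",
            best_params=MVBParams(theta=theta_hat),
        )
    return MVBParams(theta=theta_hat)


def mvb_sample(
    params: MVBParams, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw n MVB variates via the gamma-ratio construction.

    u_j = G_j / (G_j + G_{J+1}) with independent unit-scale gamma
    variates G_j of shape theta_j. Reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = params.theta
    J = params.J
    G = rng.gamma(shape=theta, size=(n, J + 1))
    return G[:, :J] / (G[:, :J] + G[:, [J]])
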