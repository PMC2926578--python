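"""Finite mixtures of multivariate beta distributions, fitted by EM.

Each row U_i of an IC series is assumed to arise from one of p latent
coupling states, state k carrying its own MVB parameter vector theta_k
and prior probability pi_k. The E-step computes responsibilities

    r_{k,i} = pi_k P_{theta_k}(u_i) / sum_l pi_l P_{theta_l}(u_i)

in the log domain with max-subtraction (shape parameters near 40 make
raw densities overflow-prone); the M-step sets pi_k to the mean
responsibility and theta_k to the responsibility-weighted MVB MLE.
The number of states is chosen by minimizing

    BIC_p = -2 * l_mix + [p (J + 2) - 1] log N',

where l_mix is the mixture log-likelihood and p (J + 2) - 1 counts the
independent parameters (p theta-vectors of length J + 1 plus p - 1 free
mixing probabilities).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist
from sklearn.cluster import KMeans

from .errors import NumericDegeneracyError, StarvedComponentError
from .ic import ICSeries
from .mvb import MVBParams, mvb_logdensity, mvb_mle

__all__ = [
    "MixtureFit",
    "StateSequence",
    "e_step",
    "m_step",
    "run_em",
    "kmeans_beta_init",
    "bic",
    "select_p",
    "assign_states",
    "state_means",
]

logger = logging.getLogger(__name__)


def _as_matrix(U) -> np.ndarray:
    """Accept an ICSeries or a bare (N, J) matrix of clipped IC values."""
    M = U.U if isinstance(U, ICSeries) else np.asarray(U, dtype=float)
    M = np.atleast_2d(M)
    if np.any(M <= 0.0) or np.any(M >= 1.0):
        raise ValueError("IC values must be clipped strictly inside (0, 1) before fitting")
    return M


@dataclass
class MixtureFit:
    """A fitted p-state MVB mixture."""

    p: int
    pis: np.ndarray
    thetas: list[MVBParams]
    resp: np.ndarray  # (p, N')
    loglik: float
    bic: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "pi": self.pis.tolist(),
            "theta": [t.theta.tolist() for t in self.thetas],
            "loglik": self.loglik,
            "bic": self.bic,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


@dataclass
class StateSequence:
    """Hard state labels (1..p) per IC window."""

    states: np.ndarray
    windows: np.ndarray | None = None  # (N', 2) start/end samples, if known

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)


def _log_component_matrix(M: np.ndarray, pis, thetas) -> np.ndarray:
    """(p, N) matrix of log pi_k + log P_{theta_k}(u_i)."""
    pis = np.asarray(pis, dtype=float)
    return np.vstack(
        [np.log(pis[k]) + mvb_logdensity(M, thetas[k]) for k in range(len(thetas))]
    )


def e_step(U, pis, thetas) -> np.ndarray:
    """Responsibility matrix r_{k,i}; columns sum to one.

    Raises
    ------
    NumericDegeneracyError
        If every component's density underflows for some observation.
    """
    M = _as_matrix(U)
    a = _log_component_matrix(M, pis, thetas)
    bad = np.flatnonzero(~np.isfinite(a).any(axis=0))
    if bad.size:
        raise NumericDegeneracyError(
            f"all component densities degenerate at row {bad[0]}", row=int(bad[0])
        )
    a = a - a.max(axis=0, keepdims=True)
    r = np.exp(a)
    return r / r.sum(axis=0, keepdims=True)


def m_step(U, resp, init_thetas: list[MVBParams] | None = None):
    """Update (pis, thetas) from responsibilities.

    ``init_thetas`` warm-starts the per-component weighted MLE solves.

    Raises
    ------
    StarvedComponentError
        If a component's effective weight falls below J + 1.
    """
    M = _as_matrix(U)
    resp = np.asarray(resp, dtype=float)
    p, n = resp.shape
    if n != M.shape[0]:
        raise ValueError("responsibility matrix does not match the data")
    J = M.shape[1]
    eff = resp.sum(axis=1)
    starving = np.flatnonzero(eff < J + 1)
    if starving.size:
        raise StarvedComponentError(
            f"component {starving[0] + 1} has effective weight {eff[starving[0]]:.3g} < {J + 1}"
        )
    pis = eff / n
    thetas = []
    for k in range(p):
        init = None if init_thetas is None else init_thetas[k]
        thetas.append(mvb_mle(M, weights=resp[k], init=init))
    return pis, thetas


def mixture_loglik(U, pis, thetas) -> float:
    """Mixture log-likelihood l_mix at the given parameters."""
    M = _as_matrix(U)
    return float(logsumexp(_log_component_matrix(M, pis, thetas), axis=0).sum())


def bic(loglik: float, p: int, J: int, n_obs: int) -> float:
    """-2 l_mix + [p (J + 2) - 1] log(n_obs)."""
    if n_obs < 2:
        raise ValueError("n_obs must be at least 2")
    return -2.0 * loglik + (p * (J + 2) - 1) * math.log(n_obs)


def kmeans_beta_init(U, p: int, seed: int = 0, n_restarts: int = 25):
    """Cluster-then-beta initialization for the EM fit.

    k-means (Euclidean, ``n_restarts`` restarts, best within-cluster sum
    of squares kept) partitions the IC vectors; per cluster, each
    dimension gets a univariate Beta(alpha_j, beta_j) MLE, the combined
    start is (alpha_1, ..., alpha_J, mean_j beta_j), and one MVB MLE on
    the cluster refines it. Mixing probabilities start at the cluster
    proportions.
    """
    M = _as_matrix(U)
    n, J = M.shape
    if n < p:
        raise ValueError("need at least p observations")
    if p == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=p, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(M)
    pis = np.empty(p)
    thetas = []
    for k in range(p):
        rows = M[labels == k]
        pis[k] = rows.shape[0] / n
        ab = np.array(
            [beta_dist.fit(rows[:, j], floc=0, fscale=1)[:2] for j in range(J)]
        )
        theta0 = MVBParams(theta=np.append(ab[:, 0], ab[:, 1].mean()))
        thetas.append(mvb_mle(rows, init=theta0))
    return pis, thetas


def run_em(
    U,
    p: int,
    init=None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_retries: int = 3,
) -> MixtureFit:
    """Fit a p-state MVB mixture by EM.

    Iterates E- and M-steps from ``init`` (a (pis, thetas) pair; the
    k-means/beta initializer by default) until the relative change of
    the mixture log-likelihood drops below ``tol`` or ``max_iter`` is
    reached. A starved component triggers a fresh initialization, up to
    ``n_retries`` times.
    """
    M = _as_matrix(U)
    n, J = M.shape
    last_err: Exception | None = None
    for attempt in range(n_retries + 1):
        if init is not None and attempt == 0:
            pis, thetas = init
            pis = np.asarray(pis, dtype=float)
        else:
            pis, thetas = kmeans_beta_init(M, p, seed=seed + attempt)
        try:
            return _em_loop(M, p, pis, list(thetas), J, n, tol, max_iter)
        except StarvedComponentError as err:
            last_err = err
            logger.warning("EM restart %d for p=%d: %s", attempt + 1, p, err)
    raise last_err  # type: ignore[misc]


def _em_loop(M, p, pis, thetas, J, n, tol, max_iter) -> MixtureFit:
    trace = [mixture_loglik(M, pis, thetas)]
    converged = False
    it = 0
    resp = e_step(M, pis, thetas)
    for it in range(1, max_iter + 1):
        pis, thetas = m_step(M, resp, init_thetas=thetas)
        ll = mixture_loglik(M, pis, thetas)
        trace.append(ll)
        if abs(ll - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
        resp = e_step(M, pis, thetas)
        if converged:
            break
    ll = trace[-1]
    return MixtureFit(
        p=p,
        pis=np.asarray(pis),
        thetas=list(thetas),
        resp=resp,
        loglik=ll,
        bic=bic(ll, p, J, n),
        n_iter=it,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )


def select_p(
    U,
    p_range=range(2, 9),
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """Fit every p in ``p_range`` and keep the BIC-minimizing model.

    Ties within 1e-6 go to the smallest p (the simplest model). Fits
    that fail are excluded from the argmin and logged. Returns the best
    MixtureFit and a dict {p: bic} over the successful fits.
    """
    p_list = sorted(set(int(p) for p in p_range))
    if not p_list:
        raise ValueError("p_range must be nonempty")
    fits: dict[int, MixtureFit] = {}
    for p in p_list:
        try:
            fits[p] = run_em(U, p, seed=seed, tol=tol, max_iter=max_iter)
        except Exception as err:  # noqa: BLE001 - per-p failures are non-fatal
            logger.warning("EM failed for p=%d: %s", p, err)
    if not fits:
        raise RuntimeError("every candidate p failed to fit")
    bics = {p: f.bic for p, f in fits.items()}
    best_bic = min(bics.values())
    best_p = next(p for p in sorted(bics) if bics[p] <= best_bic + 1e-6)
    return fits[best_p], bics


def assign_states(fit: MixtureFit, U=None) -> StateSequence:
    """Hard state labels: state_i = argmax_k r_{k,i}, ties to smallest k."""
    states = fit.resp.argmax(axis=0) + 1
    windows = U.windows if isinstance(U, ICSeries) else None
    return StateSequence(states=states, windows=windows)


def state_means(U, seq: StateSequence):
    """Per-state mean and SD (ddof=1) of the IC values, channel by channel.

    Returns (means, sds), each (p, J) with NaN rows for empty states.
    """
    M = _as_matrix(U)
    p = int(seq.states.max())
    J = M.shape[1]
    means = np.full((p, J), np.nan)
    sds = np.full((p, J), np.nan)
    for k in range(1, p + 1):
        rows = M[seq.states == k]
        if rows.shape[0] == 0:
            continue
        means[k - 1] = rows.mean(axis=0)
        sds[k - 1] = rows.std(axis=0, ddof=1) if rows.shape[0] > 1 else np.nan
    return means, sds
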