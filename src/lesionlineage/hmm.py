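"""Scaled forward-backward and Viterbi primitives.

Both HMMs in this package (the 3-state depth model and the joint
genotype-by-subclone model) use a distance-independent transition matrix with
a single self-transition probability ``rho`` and the remaining mass spread
uniformly over the other states.  Chromosomes are independent chains; callers
run these routines per chromosome and concatenate.

Underflow is prevented by per-step scaling of the forward/backward variables
plus a per-locus shift of the emission row maxima (restored in the returned
log-likelihood), so arbitrarily sharp emissions (e.g. sigma -> 0 tests) stay
finite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def structured_transition(n_states: int, rho: float) -> np.ndarray:
    """Self-transition ``rho``; uniform ``(1-rho)/(K-1)`` elsewhere."""
    if not 0.0 < rho < 1.0:
        raise ValueError(f"self-transition must be in (0, 1), got {rho}")
    if n_states == 1:
        return np.ones((1, 1))
    trans = np.full((n_states, n_states), (1.0 - rho) / (n_states - 1))
    np.fill_diagonal(trans, rho)
    return trans


@njit(cache=True)
def _fb_kernel(emit, trans, init):  # pragma: no cover - exercised via wrapper
    T, K = emit.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    scale = np.empty(T)

    a = init * emit[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        pred = alpha[t - 1] @ trans
        a = pred * emit[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]

    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (trans @ (emit[t + 1] * beta[t + 1])) / scale[t + 1]

    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    return gamma, np.log(scale).sum()


@njit(cache=True)
def _viterbi_kernel(logemit, logtrans, loginit, pref):  # pragma: no cover
    T, K = logemit.shape
    delta = loginit + logemit[0]
    psi = np.zeros((T, K), dtype=np.int32)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                sc = delta[i] + logtrans[i, j]
                if sc > best or (sc == best and pref[i] < pref[arg]):
                    best = sc
                    arg = i
            new[j] = best + logemit[t, j]
            psi[t, j] = arg
        delta = new
    best = -np.inf
    arg = 0
    for k in range(K):
        if delta[k] > best or (delta[k] == best and pref[k] < pref[arg]):
            best = delta[k]
            arg = k
    path = np.empty(T, dtype=np.int32)
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


def forward_backward(
    log_emit: np.ndarray, trans: np.ndarray, init: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Posterior state marginals and log-likelihood of one chain.

    Parameters
    ----------
    log_emit:
        ``(T, K)`` per-locus log emission likelihoods.
    trans:
        ``(K, K)`` transition matrix (probabilities).
    init:
        Initial distribution; uniform if omitted.

    Returns
    -------
    gamma, log_likelihood
        ``gamma[t]`` sums to 1 for every locus.
    """
    log_emit = np.asarray(log_emit, dtype=np.float64)
    T, K = log_emit.shape
    if T == 0:
        return np.zeros((0, K)), 0.0
    if init is None:
        init = np.full(K, 1.0 / K)
    shift = log_emit.max(axis=1)
    emit = np.exp(log_emit - shift[:, None])
    gamma, log_scale = _fb_kernel(emit, np.asarray(trans, float), np.asarray(init, float))
    return gamma, float(log_scale + shift.sum())


def viterbi(
    log_emit: np.ndarray,
    trans: np.ndarray,
    init: np.ndarray | None = None,
    pref: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Most likely state path; exact score ties broken toward lower ``pref``."""
    log_emit = np.asarray(log_emit, dtype=np.float64)
    T, K = log_emit.shape
    if T == 0:
        return np.zeros(0, dtype=np.int32), 0.0
    if init is None:
        init = np.full(K, 1.0 / K)
    if pref is None:
        pref = np.arange(K)
    with np.errstate(divide="ignore"):
        logtrans = np.log(np.asarray(trans, float))
        loginit = np.log(np.asarray(init, float))
    path, score = _viterbi_kernel(log_emit, logtrans, loginit, np.asarray(pref, np.int64))
    return path, float(score)
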