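"""Independent brute-force HMM oracle: exhaustive enumeration over all state
paths.  Used only to check forward-backward posteriors and Viterbi paths on
short chains; deliberately shares no code with the package's recursions."""

import itertools

import numpy as np
from scipy.special import logsumexp


def enumerate_paths(log_emit, trans, init=None):
    """Exact posteriors, log-likelihood and best path by summing every path.

    Returns (gamma, loglik, viterbi_path).
    """
    log_emit = np.asarray(log_emit, float)
    T, K = log_emit.shape
    with np.errstate(divide="ignore"):
        logtrans = np.log(np.asarray(trans, float))
        loginit = np.log(np.full(K, 1.0 / K) if init is None else np.asarray(init))
    paths = np.array(list(itertools.product(range(K), repeat=T)), dtype=np.int64)
    logp = loginit[paths[:, 0]].copy()
    for t in range(T):
        logp += log_emit[t, paths[:, t]]
        if t > 0:
            logp += logtrans[paths[:, t - 1], paths[:, t]]
    loglik = float(logsumexp(logp))
    gamma = np.empty((T, K))
    for t in range(T):
        for k in range(K):
            sel = logp[paths[:, t] == k]
            gamma[t, k] = np.exp(logsumexp(sel) - loglik) if len(sel) else 0.0
    best = paths[int(np.argmax(logp))]
    return gamma, loglik, best
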