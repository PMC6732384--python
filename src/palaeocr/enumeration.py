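"""Brute-force reference likelihoods by latent-interval enumeration.

Each genus's latent state is its true extancy interval [b, d] (entry bin,
exit bin).  These functions sum the probability of a capture history over
every admissible interval with plain Python loops and explicit products --
no recursions, no vectorization -- and exist solely as an independent
cross-check of the fast implementations in :mod:`palaeocr.cr`.  They are
exponential in nothing but still O(K^2) per history and far slower than
the production code; use them only on small matrices.
"""

from __future__ import annotations

import math

import numpy as np

from .cr import POPANParams, PradelParams

__all__ = ["popan_loglik_enum", "pradel_loglik_enum"]


def _interval_prob(b: int, d: int, history, beta, phi, p, k: int) -> float:
    """P(extant exactly [b, d] and detected exactly as in history)."""
    f_ok = all(history[i] == 0 for i in range(0, b)) and \
        all(history[i] == 0 for i in range(d + 1, k))
    if not f_ok:
        return 0.0
    prob = beta[b]
    for j in range(b, d):
        prob *= phi[j]
    if d < k - 1:
        prob *= 1.0 - phi[d]
    for i in range(b, d + 1):
        prob *= p[i] if history[i] else 1.0 - p[i]
    return prob


def _history_prob(history, beta, phi, p, k: int) -> float:
    det = [i for i in range(k) if history[i]]
    first, last = det[0], det[-1]
    total = 0.0
    for b in range(0, first + 1):
        for d in range(last, k):
            total += _interval_prob(b, d, history, beta, phi, p, k)
    return total


def _never_detected_prob(beta, phi, p, k: int) -> float:
    total = 0.0
    zero = [0] * k
    for b in range(k):
        for d in range(b, k):
            total += _interval_prob(b, d, zero, beta, phi, p, k)
    return total


def popan_loglik_enum(params: POPANParams, cells: np.ndarray) -> float:
    """Full POPAN log-likelihood by enumeration over entry/exit bins."""
    cells = np.asarray(cells)
    n_obs, k = cells.shape
    beta, phi, p = params.entry_probs, params.survival, params.detection
    n = float(params.n_super)
    if n < n_obs:
        return -math.inf
    ll = 0.0
    for row in cells:
        ll += math.log(_history_prob(row, beta, phi, p, k))
    p0 = _never_detected_prob(beta, phi, p, k)
    ll += math.lgamma(n + 1) - math.lgamma(n - n_obs + 1) - math.lgamma(n_obs + 1)
    if n - n_obs > 1e-12:
        ll += (n - n_obs) * math.log(p0)
    return ll


def pradel_loglik_enum(params: PradelParams, cells: np.ndarray) -> float:
    """Pradel log-likelihood by enumeration.

    The seniority chain pins the relative cohort sizes
    (``N_{i+1}/N_i = phi_i/gamma_{i+1}``) and in-flows
    (``B_i = N_i (1 - gamma_i)``); normalizing the in-flows yields the
    entry distribution over which extancy intervals are enumerated, and
    the result is conditioned on detection at least once.
    """
    cells = np.asarray(cells)
    n_obs, k = cells.shape
    phi, gamma, p = params.survival, params.seniority, params.detection
    rel_n = [1.0]
    for i in range(k - 1):
        rel_n.append(rel_n[i] * phi[i] / gamma[i])
    rel_b = [rel_n[0]] + [rel_n[i + 1] * (1.0 - gamma[i]) for i in range(k - 1)]
    total_b = sum(rel_b)
    beta = np.array([x / total_b for x in rel_b])
    p0 = _never_detected_prob(beta, phi, p, k)
    ll = 0.0
    for row in cells:
        ll += math.log(_history_prob(row, beta, phi, p, k)) \
            - math.log(1.0 - p0)
    return ll
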