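"""Internal vectorized marginal-likelihood machinery shared by the estimators.

Conventions: responses are an ``(n_persons, n_items)`` integer array with
``-1`` marking a missing entry; quadrature is a fixed grid of trait points
with prior mass per point.  Analytic gradients of the marginal
log-likelihood use Fisher's identity: the marginal score equals the
posterior-expected complete-data score, so the same expected-count arrays
drive both the EM M-step and direct quasi-Newton fitting.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logsumexp

MISSING = -1
_TINY = 1e-300
_PFLOOR = 1e-12


def prob_table(alpha: float, b: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Category probabilities at every grid point, shape (Q, m + 1)."""
    pstar = expit(alpha * (points[:, None] - b[None, :]))
    padded = np.concatenate(
        [np.ones((points.size, 1)), pstar, np.zeros((points.size, 1))], axis=1
    )
    return np.clip(padded[:, :-1] - padded[:, 1:], 0.0, 1.0)


def log_prob_table(alpha: float, b: np.ndarray, points: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(prob_table(alpha, b, points), _TINY))


def pattern_log_lik(codes: np.ndarray, log_tables: list) -> np.ndarray:
    """log P(responses_s | theta_q) for every person and grid point, shape (S, Q)."""
    n, _ = codes.shape
    out = np.zeros((n, log_tables[0].shape[0]))
    for i, lt in enumerate(log_tables):
        col = codes[:, i]
        obs = col != MISSING
        if obs.any():
            out[obs] += lt[:, col[obs]].T
    return out


def posterior_weights(codes, log_tables, log_prior):
    """Posterior over grid points per person.

    Returns ``(post, loglik_total, loglik_per_person)`` where ``post[s, q]``
    is the normalized posterior mass and the log-likelihood marginalizes the
    trait over the grid.
    """
    logjoint = pattern_log_lik(codes, log_tables) + log_prior[None, :]
    ll_person = logsumexp(logjoint, axis=1)
    post = np.exp(logjoint - ll_person[:, None])
    return post, float(ll_person.sum()), ll_person


def expected_counts(post: np.ndarray, code_col: np.ndarray, n_cats: int) -> np.ndarray:
    """r[q, j] = expected number of responses in category j at grid point q."""
    q = post.shape[1]
    r = np.zeros((q, n_cats))
    for j in range(n_cats):
        mask = code_col == j
        if mask.any():
            r[:, j] = post[mask].sum(axis=0)
    return r


def item_natural_grad(r: np.ndarray, alpha: float, b: np.ndarray, points: np.ndarray):
    """Gradient of sum_{q,j} r[q,j] log P_j(theta_q) w.r.t. (alpha, b).

    By Fisher's identity this is also the marginal-likelihood score for the
    item when ``r`` holds posterior expected counts.
    """
    pstar = expit(alpha * (points[:, None] - b[None, :]))  # (Q, m)
    padded = np.concatenate(
        [np.ones((points.size, 1)), pstar, np.zeros((points.size, 1))], axis=1
    )
    probs = np.maximum(padded[:, :-1] - padded[:, 1:], _PFLOOR)
    ratio = r / probs  # (Q, m+1)
    s = ratio[:, 1:] - ratio[:, :-1]  # S_k = R_k - R_{k-1}, k = 1..m
    w = pstar * (1.0 - pstar)
    galpha = float(((points[:, None] - b[None, :]) * w * s).sum())
    gb = -alpha * (w * s).sum(axis=0)
    return galpha, gb


def item_expected_loglik(r: np.ndarray, alpha: float, b: np.ndarray, points: np.ndarray) -> float:
    probs = np.maximum(prob_table(alpha, b, points), _TINY)
    return float((r * np.log(probs)).sum())


# --- parameter transforms: (alpha, b) <-> unconstrained raw vector ------------
#
# raw = [log alpha, b_1, log(b_2 - b_1), ..., log(b_m - b_{m-1})]
# keeps the slope positive and thresholds ordered in every iterate.

_MIN_GAP = 1e-8


def to_raw(alpha: float, b: np.ndarray) -> np.ndarray:
    diffs = np.maximum(np.diff(b), _MIN_GAP)
    return np.concatenate([[np.log(alpha), b[0]], np.log(diffs)])


def from_raw(raw: np.ndarray) -> tuple:
    alpha = float(np.exp(np.clip(raw[0], -30, 10)))
    b = raw[1] + np.concatenate([[0.0], np.cumsum(np.exp(np.clip(raw[2:], -500, 10)))])
    return alpha, b


def chain_to_raw(raw: np.ndarray, galpha: float, gb: np.ndarray) -> np.ndarray:
    """Map a natural-parameter gradient to the raw parameterization."""
    alpha = np.exp(np.clip(raw[0], -30, 10))
    tail = np.cumsum(gb[::-1])[::-1]  # tail[k] = sum_{j >= k} gb_j
    g = np.empty(raw.size)
    g[0] = alpha * galpha
    g[1] = tail[0]
    if raw.size > 2:
        g[2:] = np.exp(np.clip(raw[2:], -500, 10)) * tail[1:]
    return g
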