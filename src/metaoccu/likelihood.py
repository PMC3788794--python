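"""Marginal likelihood of a detection history under the dynamic occupancy model.

Each patch follows a two-state hidden Markov chain over seasons: latent
occupancy starts at Pr(occupied) = psi1, transitions with per-interval
colonisation gamma_t and extinction epsilon_t, and emits the season's
detections — Bernoulli(p_{t,j}) per survey when occupied, all-zero with
probability one when unoccupied.  The latent states are marginalised by a
forward recursion in log space; :func:`brute_force_log_likelihood` computes
the same quantity by explicit enumeration of all 2^T latent sequences and
serves as an independent oracle in tests.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _expand_p(p: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Broadcast per-season or per-survey detection probabilities to (n, T, J)."""
    p = np.asarray(p, dtype=float)
    n, T, J = shape
    if p.ndim == 2:  # (n, T): constant across surveys within a season
        p = p[:, :, None]
    return np.broadcast_to(p, shape)


def _season_emission_logs(y: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log emission probability of each patch-season under occupied/unoccupied.

    Missing surveys (NaN) contribute nothing; an unoccupied patch emits a
    detection with probability 0, giving a -inf log term.
    """
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
        log_q = np.log1p(-p)
    term = np.where(y == 1.0, log_p, log_q)
    term = np.where(np.isnan(y), 0.0, term)
    log_occ = term.sum(axis=2)
    detected = np.nansum(y, axis=2) > 0
    log_unocc = np.where(detected, -np.inf, 0.0)
    return log_occ, log_unocc


def forward_log_likelihood(
    y: np.ndarray,
    psi1: np.ndarray,
    gamma: np.ndarray,
    epsilon: np.ndarray,
    p: np.ndarray,
) -> np.ndarray:
    """Per-patch log-likelihood by the forward recursion.

    Parameters
    ----------
    y
        Detections, shape ``(n, T, J)``, values in {0, 1, NaN}.
    psi1
        First-season occupancy probability, shape ``(n,)``.
    gamma, epsilon
        Per-interval colonisation/extinction probabilities, shape ``(n, T-1)``.
    p
        Detection probabilities, shape ``(n, T)`` or ``(n, T, J)``.

    Returns
    -------
    ndarray of shape ``(n,)``; ``-inf`` where a degenerate parameter
    conflicts with the data, never an exception.
    """
    y = np.asarray(y, dtype=float)
    n, T, J = y.shape
    psi1 = np.asarray(psi1, dtype=float)
    gamma = np.asarray(gamma, dtype=float).reshape(n, T - 1) if T > 1 else np.empty((n, 0))
    epsilon = np.asarray(epsilon, dtype=float).reshape(n, T - 1) if T > 1 else np.empty((n, 0))
    p = _expand_p(p, (n, T, J))

    em_occ, em_unocc = _season_emission_logs(y, p)
    with np.errstate(divide="ignore"):
        la_occ = np.log(psi1) + em_occ[:, 0]
        la_unocc = np.log1p(-psi1) + em_unocc[:, 0]
        for t in range(1, T):
            g, e = gamma[:, t - 1], epsilon[:, t - 1]
            log_stay = np.log1p(-e)
            log_ext = np.log(e)
            log_col = np.log(g)
            log_rem = np.log1p(-g)
            new_occ = np.logaddexp(la_occ + log_stay, la_unocc + log_col) + em_occ[:, t]
            new_unocc = np.logaddexp(la_occ + log_ext, la_unocc + log_rem) + em_unocc[:, t]
            la_occ, la_unocc = new_occ, new_unocc
    return np.logaddexp(la_occ, la_unocc)


def _as_single_patch(detections, psi1, gamma, epsilon, p):
    y = np.atleast_2d(np.asarray(detections, dtype=float))[None, :, :]
    _, T, J = y.shape
    psi1 = np.array([float(psi1)])
    gamma = np.asarray(gamma, dtype=float).ravel()
    epsilon = np.asarray(epsilon, dtype=float).ravel()
    if T > 1 and (gamma.size != T - 1 or epsilon.size != T - 1):
        raise ValueError(f"need {T - 1} gamma and epsilon values for {T} seasons")
    p = np.asarray(p, dtype=float)
    if p.ndim == 0:
        p = np.full((T, J), float(p))
    elif p.ndim == 1:
        p = np.broadcast_to(p[:, None], (T, J))
    return y, psi1, gamma[None, :], epsilon[None, :], p[None, :, :]


def patch_log_likelihood(detections, psi1, gamma, epsilon, p) -> float:
    """Log-likelihood of one patch's history (forward recursion).

    ``detections`` is (T, J) with values in {0, 1, NaN}; ``gamma`` and
    ``epsilon`` have length T-1; ``p`` is scalar, per-season (T,) or
    per-survey (T, J).  Returns ``-inf`` when a boundary probability (0 or 1)
    conflicts with the data.
    """
    y, psi1, gamma, epsilon, p = _as_single_patch(detections, psi1, gamma, epsilon, p)
    _check_probs(psi1, gamma, epsilon, p)
    return float(forward_log_likelihood(y, psi1, gamma, epsilon, p)[0])


def _check_probs(*arrays) -> None:
    for a in arrays:
        a = np.asarray(a, dtype=float)
        if a.size and (np.isnan(a).any() or (a < 0).any() or (a > 1).any()):
            raise ValueError("probabilities must lie in [0, 1]")


MAX_BRUTE_FORCE_SEASONS = 12


def brute_force_log_likelihood(detections, psi1, gamma, epsilon, p) -> float:
    """Same contract as :func:`patch_log_likelihood`, by explicit enumeration
    of all 2^T latent occupancy sequences.  Intended as a testing oracle;
    refuses T > 12."""
    y, psi1v, gamma, epsilon, p = _as_single_patch(detections, psi1, gamma, epsilon, p)
    _check_probs(psi1v, gamma, epsilon, p)
    _, T, J = y.shape
    if T > MAX_BRUTE_FORCE_SEASONS:
        raise ValueError(f"enumeration limited to {MAX_BRUTE_FORCE_SEASONS} seasons")
    y2, p2 = y[0], p[0]
    g, e = gamma[0], epsilon[0]
    psi = float(psi1v[0])
    total = 0.0
    for z in itertools.product((0, 1), repeat=T):
        prob = psi if z[0] else 1.0 - psi
        for t in range(1, T):
            if z[t - 1]:
                prob *= (1.0 - e[t - 1]) if z[t] else e[t - 1]
            else:
                prob *= g[t - 1] if z[t] else (1.0 - g[t - 1])
        for t in range(T):
            for j in range(J):
                obs = y2[t, j]
                if math.isnan(obs):
                    continue
                if z[t]:
                    prob *= p2[t, j] if obs == 1.0 else (1.0 - p2[t, j])
                elif obs == 1.0:
                    prob = 0.0
        total += prob
    return math.log(total) if total > 0 else -math.inf
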