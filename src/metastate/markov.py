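"""Small shared utilities for finite Markov chains (row-stochastic matrices)."""
from __future__ import annotations

import numpy as np


def check_stochastic(T: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < -tol):
        raise ValueError("transition matrix has negative entries")
    if not np.allclose(T.sum(axis=1), 1.0, atol=max(tol, 1e-8)):
        raise ValueError("transition matrix rows must sum to 1")
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix.

    Solved as the null space of ``(T^T - I)`` with the normalization
    constraint, which is robust for nearly-uncoupled chains.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    A = np.vstack([T.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def detailed_balance_residual(T: np.ndarray, pi: np.ndarray | None = None) -> float:
    """Max |pi_i T_ij - pi_j T_ji| over all pairs."""
    T = np.asarray(T, dtype=float)
    if pi is None:
        pi = stationary_distribution(T)
    F = pi[:, None] * T
    return float(np.max(np.abs(F - F.T)))


def mean_first_passage_time(T: np.ndarray, A, B, step_time: float = 1.0) -> float:
    """Mean first-passage time from set ``A`` into set ``B``.

    Solves the linear first-passage system ``h_i = step + sum_{j not in B}
    T_ij h_j`` on the complement of ``B`` and returns the stationary-weighted
    average of ``h`` over ``A`` (the convention used by MSM packages).
    Result is in units of ``step_time``. Returns ``inf`` when B is
    unreachable from A.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    A = np.atleast_1d(np.asarray(A, dtype=int))
    B = np.atleast_1d(np.asarray(B, dtype=int))
    if len(A) == 0 or len(B) == 0:
        raise ValueError("A and B must be nonempty")
    if np.intersect1d(A, B).size:
        # overlapping states have zero passage time; classic convention is 0
        # only when A is fully inside B
        if np.all(np.isin(A, B)):
            return 0.0
        raise ValueError("A and B must be disjoint (or A a subset of B)")
    notB = np.setdiff1d(np.arange(n), B)
    M = np.eye(len(notB)) - T[np.ix_(notB, notB)]
    try:
        h = np.linalg.solve(M, np.ones(len(notB)))
    except np.linalg.LinAlgError:
        return float("inf")
    if np.any(h < -1e-8) or not np.all(np.isfinite(h)):
        return float("inf")
    full = np.zeros(n)
    full[notB] = h
    pi = stationary_distribution(T)
    w = pi[A]
    return float(np.dot(w, full[A]) / w.sum() * step_time)


def sorted_eigenvalues(T: np.ndarray) -> np.ndarray:
    """Eigenvalues of T sorted by decreasing real part (largest first)."""
    ev = np.linalg.eigvals(np.asarray(T, dtype=float))
    order = np.argsort(-ev.real)
    return ev[order]


def relaxation_timescales(T: np.ndarray, lag_time: float, n: int | None = None) -> np.ndarray:
    """Implied relaxation timescales ``-lag / ln(lambda_i)`` for i >= 2.

    Only real eigenvalues in (0, 1) yield finite timescales; others are
    reported as NaN (flagged, not silently dropped).
    """
    ev = sorted_eigenvalues(T)[1:]
    if n is not None:
        ev = ev[:n]
    out = np.full(len(ev), np.nan)
    for k, lam in enumerate(ev):
        if abs(lam.imag) < 1e-12 and 0.0 < lam.real < 1.0:
            out[k] = -lag_time / np.log(lam.real)
    return out
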