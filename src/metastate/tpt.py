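"""Transition path theory: committors, reactive fluxes, pathway decomposition.

Given a (macro)state transition matrix with stationary distribution and two
disjoint state sets A (source) and B (sink), computes forward/backward
committors, gross and net reactive fluxes, the total A->B flux, and a ranked
decomposition of the net-flux network into bottleneck pathways.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markov


@dataclass
class FluxNetwork:
    """Committors and reactive fluxes between a source set A and sink set B.

    ``gross_flux[i, j] = pi_i q-_i T_ij q+_j`` (i != j); ``net_flux`` is the
    positive part of its antisymmetrization. ``total_flux`` is per model step;
    ``total_flux_per_ns`` converts via the lag.
    """

    A: np.ndarray
    B: np.ndarray
    q_plus: np.ndarray
    q_minus: np.ndarray
    gross_flux: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    lag_ns: float = 1.0
    pi: np.ndarray | None = None

    @property
    def total_flux_per_ns(self) -> float:
        return self.total_flux / self.lag_ns

    @property
    def rate_per_ns(self) -> float:
        """A->B transition rate: flux divided by the reactant population."""
        pi_reactant = np.sum(self.pi * self.q_minus)
        return self.total_flux_per_ns / pi_reactant if pi_reactant > 0 else np.nan


def _committor(T: np.ndarray, A, B) -> np.ndarray:
    """Forward committor: probability of hitting B before A."""
    n = T.shape[0]
    q = np.zeros(n)
    q[B] = 1.0
    C = np.setdiff1d(np.arange(n), np.union1d(A, B))
    if len(C) > 0:
        M = np.eye(len(C)) - T[np.ix_(C, C)]
        rhs = T[np.ix_(C, B)].sum(axis=1)
        try:
            q[C] = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular committor system: sink unreachable from intermediates") from exc
    return np.clip(q, 0.0, 1.0)


def committors_and_flux(model, A, B) -> FluxNetwork:
    """Compute committors and reactive fluxes of a Markov or macrostate model.

    ``model`` may be anything exposing a transition matrix (``T`` or
    ``T_macro``), a stationary distribution (``pi``/``pi_macro``), and
    ``lag_ns``. A and B must be disjoint, nonempty state sets.
    """
    T = getattr(model, "T_macro", None)
    pi = getattr(model, "pi_macro", None)
    if T is None:
        T, pi = model.T, model.pi
    lag_ns = getattr(model, "lag_ns", 1.0)
    A = np.atleast_1d(np.asarray(A, dtype=int))
    B = np.atleast_1d(np.asarray(B, dtype=int))
    if len(A) == 0 or len(B) == 0:
        raise ValueError("A and B must be nonempty")
    if np.intersect1d(A, B).size:
        raise ValueError("A and B must be disjoint")
    markov.check_stochastic(T)
    q_plus = _committor(T, A, B)
    # backward committor via the time-reversed chain T~_ij = pi_j T_ji / pi_i
    T_rev = (pi[:, None] * T).T / pi[:, None]
    q_minus = _committor(T_rev, B, A)  # probability of hitting A before B under reversal
    n = T.shape[0]
    gross = pi[:, None] * q_minus[:, None] * T * q_plus[None, :]
    gross[np.diag_indices(n)] = 0.0
    net = np.maximum(gross - gross.T, 0.0)
    total = float(net[A, :].sum() - net[:, A].sum())
    return FluxNetwork(A=A, B=B, q_plus=q_plus, q_minus=q_minus, gross_flux=gross,
                       net_flux=net, total_flux=total, lag_ns=lag_ns, pi=pi)


# ---- pathway decomposition ------------------------------------------------

@dataclass
class PathwayDecomposition:
    """Ranked bottleneck pathways with flux shares (% of total flux)."""

    paths: list          # state index tuples, each starting in A and ending in B
    shares: np.ndarray   # percentages
    fluxes: np.ndarray   # absolute bottleneck fluxes
    total_flux: float

    @property
    def cumulative_share(self) -> float:
        return float(np.sum(self.shares))

    def to_dataframe(self, names=None) -> pd.DataFrame:
        def fmt(p):
            return " -> ".join(str(s) if names is None else names[s] for s in p)
        return pd.DataFrame({"path": [fmt(p) for p in self.paths],
                             "percentage": np.round(self.shares, 2),
                             "flux": self.fluxes})


def _best_bottleneck_path(F: np.ndarray, A, B, tol: float):
    """Path A->B maximizing the minimum edge flux.

    Exhaustive over simple paths (state counts here are small); ties broken
    by shorter path, then lexicographic state order.
    """
    n = F.shape[0]
    inter = [s for s in range(n) if s not in set(A) | set(B)]
    best = None
    for a in sorted(A):
        for b in sorted(B):
            for k in range(len(inter) + 1):
                for mid in itertools.permutations(inter, k):
                    path = (a, *mid, b)
                    w = min(F[path[i], path[i + 1]] for i in range(len(path) - 1))
                    if w <= tol:
                        continue
                    key = (-w, len(path), path)
                    if best is None or key < best[0]:
                        best = (key, path, w)
    if best is None:
        return None, 0.0
    return best[1], best[2]


def decompose_pathways(net: FluxNetwork, coverage_stop: float = 90.0,
                       max_paths: int = 1000) -> PathwayDecomposition:
    """Iterative bottleneck decomposition of the net flux network.

    Repeatedly extracts the A->B path whose minimum-edge (bottleneck) net
    flux is maximal, subtracts that flux along the path, and records the
    share ``bottleneck / total_flux * 100``; stops when the cumulative share
    reaches ``coverage_stop`` percent or no positive-flux path remains.
    """
    F = net.net_flux.copy()
    total = net.total_flux
    paths, fluxes = [], []
    if total <= 0:
        return PathwayDecomposition([], np.array([]), np.array([]), total)
    tol = total * 1e-12
    covered = 0.0
    while covered < coverage_stop and len(paths) < max_paths:
        path, w = _best_bottleneck_path(F, net.A, net.B, tol)
        if path is None:
            break
        for i in range(len(path) - 1):
            F[path[i], path[i + 1]] -= w
        paths.append(path)
        fluxes.append(w)
        covered += w / total * 100.0
    fluxes = np.asarray(fluxes)
    return PathwayDecomposition(paths=paths, shares=fluxes / total * 100.0,
                                fluxes=fluxes, total_flux=total)


def network_table(net: FluxNetwork, model=None, names=None) -> pd.DataFrame:
    """Edge table of the net flux network (for plotting / export).

    One row per directed edge with positive net flux; when ``model`` is
    given, per-edge MFPTs (ns) between the single states are included.
    """
    rows = []
    n = net.net_flux.shape[0]
    for i in range(n):
        for j in range(n):
            if net.net_flux[i, j] > 0:
                row = {"from": i if names is None else names[i],
                       "to": j if names is None else names[j],
                       "net_flux": net.net_flux[i, j],
                       "gross_flux": net.gross_flux[i, j]}
                if model is not None:
                    row["mfpt_ns"] = model.mfpt_ns([i], [j])
                rows.append(row)
    return pd.DataFrame(rows)
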