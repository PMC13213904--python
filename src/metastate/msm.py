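"""Microstate and macrostate Markov model estimation with Bayesian uncertainty.

The workflow mirrors established MSM practice: k-means discretization of
(optionally TICA-projected) features, sliding-window transition counting on
the largest strongly connected state set, reversible maximum-likelihood
estimation by the standard fixed-point iteration, MCMC sampling of reversible
transition matrices for uncertainty, spectral (PCCA-style) coarse-graining
refined by a discrete-emission hidden Markov model, Chapman-Kolmogorov
validation, and kinetic summaries (implied timescales, lifetimes, MFPTs) with
Gaussian-mixture posterior summaries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph

from . import markov
from .features import FeatureMatrix


class EstimationError(RuntimeError):
    pass


def _as_arrays(X):
    if isinstance(X, FeatureMatrix):
        return [X.values], X.frame_interval_ns
    if isinstance(X, np.ndarray):
        return [X] if X.ndim == 2 else [X[:, None]], 1.0
    mats = list(X)
    if isinstance(mats[0], FeatureMatrix):
        return [m.values for m in mats], mats[0].frame_interval_ns
    return [np.asarray(m) for m in mats], 1.0


# ---- discretization -------------------------------------------------------

@dataclass
class Discretization:
    centers: np.ndarray
    dtrajs: list
    seed: int
    inertia: float


def cluster_kmeans(X, k: int, seed: int = 0, max_fit_points: int = 500_000) -> Discretization:
    """k-means discretization with seeded, deterministic initialization.

    For large inputs the centers are fitted on an evenly strided subset of at
    most ``max_fit_points`` frames (mini-batch k-means); every frame is then
    assigned to its nearest center in chunks. Inertia is the total squared
    distance of all frames to their assigned centers.
    """
    from sklearn.cluster import KMeans, MiniBatchKMeans

    mats, _ = _as_arrays(X)
    n_total = sum(len(m) for m in mats)
    if k > n_total:
        raise ValueError(f"k={k} exceeds number of frames {n_total}")
    if n_total <= 10_000:
        distinct = len(np.unique(np.vstack(mats), axis=0))
        if k > distinct:
            raise ValueError(f"k={k} exceeds number of distinct frames {distinct}")
    stride = max(1, int(np.ceil(n_total / max_fit_points)))
    fit_data = np.vstack([m[::stride] for m in mats]).astype(np.float64, copy=False)
    if len(fit_data) > 100_000:
        km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3,
                             batch_size=4096, max_iter=200).fit(fit_data)
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=5).fit(fit_data)
    centers = km.cluster_centers_
    sq = np.einsum("ij,ij->i", centers, centers)
    dtrajs, inertia = [], 0.0
    for m in mats:
        lab = np.empty(len(m), dtype=np.int32)
        for lo in range(0, len(m), 200_000):
            chunk = np.asarray(m[lo:lo + 200_000], dtype=np.float64)
            d2 = sq[None, :] - 2.0 * chunk @ centers.T
            idx = np.argmin(d2, axis=1)
            lab[lo:lo + 200_000] = idx
            inertia += float(np.sum(d2[np.arange(len(chunk)), idx]
                                    + np.einsum("ij,ij->i", chunk, chunk)))
        dtrajs.append(lab)
    return Discretization(centers=centers, dtrajs=dtrajs, seed=seed, inertia=inertia)


def assign_to_centers(X: np.ndarray, centers: np.ndarray,
                      chunk: int = 200_000) -> np.ndarray:
    """Assign frames to their nearest cluster center (chunked, memory-bounded)."""
    centers = np.asarray(centers, dtype=np.float64)
    sq = np.einsum("ij,ij->i", centers, centers)
    out = np.empty(len(X), dtype=np.int32)
    for lo in range(0, len(X), chunk):
        part = np.asarray(X[lo:lo + chunk], dtype=np.float64)
        d2 = sq[None, :] - 2.0 * part @ centers.T
        out[lo:lo + chunk] = np.argmin(d2, axis=1)
    return out


# ---- counting -------------------------------------------------------------

@dataclass
class CountMatrix:
    """Transition counts at a lag, with the largest strongly connected subset."""

    C: np.ndarray             # (k, k) full count matrix
    lag_frames: int
    frame_interval_ns: float
    mode: str
    active_set: np.ndarray    # state indices of the largest connected component

    @property
    def lag_ns(self) -> float:
        return self.lag_frames * self.frame_interval_ns

    @property
    def C_active(self) -> np.ndarray:
        return self.C[np.ix_(self.active_set, self.active_set)]


def count_transitions(dtrajs, lag_frames: int, mode: str = "sliding", trim: bool = True,
                      n_states: int | None = None, frame_interval_ns: float = 1.0) -> CountMatrix:
    """Count transitions at a lag over one or more discrete trajectories.

    ``sliding`` counts every (t, t+lag) pair; ``strided`` counts only pairs
    starting at multiples of the lag. With ``trim`` the active set is the
    largest strongly connected component of the count graph, otherwise all
    states with any counts.
    """
    if mode not in ("sliding", "strided"):
        raise ValueError(f"unknown counting mode {mode!r}")
    dtrajs = [np.asarray(d, dtype=np.int64) for d in
              (dtrajs if isinstance(dtrajs, (list, tuple)) else [dtrajs])]
    shortest = min(len(d) for d in dtrajs)
    if lag_frames < 1 or lag_frames >= shortest:
        raise ValueError(f"lag_frames={lag_frames} must be in [1, shortest trajectory)")
    k = n_states if n_states is not None else max(int(d.max()) for d in dtrajs) + 1
    C = np.zeros((k, k), dtype=np.int64)
    for d in dtrajs:
        if np.any(d < 0) or np.any(d >= k):
            raise ValueError("state labels out of range")
        a = d[:-lag_frames]
        b = d[lag_frames:]
        if mode == "strided":
            a = d[:-lag_frames:lag_frames]
            b = d[lag_frames::lag_frames]
        np.add.at(C, (a, b), 1)
    if trim:
        graph = scipy.sparse.csr_matrix(C)
        n_comp, labels = scipy.sparse.csgraph.connected_components(
            graph, directed=True, connection="strong")
        sizes = np.array([C[labels == c].sum() for c in range(n_comp)])
        best = int(np.argmax(sizes))
        active = np.flatnonzero(labels == best)
        # a strongly connected singleton with no self-transitions carries no
        # kinetic information
        if sizes[best] == 0:
            raise EstimationError("no connected transition counts")
    else:
        active = np.flatnonzero(C.sum(axis=0) + C.sum(axis=1) > 0)
    return CountMatrix(C=C, lag_frames=lag_frames, frame_interval_ns=frame_interval_ns,
                       mode=mode, active_set=active)


# ---- reversible maximum likelihood ---------------------------------------

@dataclass
class MarkovModel:
    """Row-stochastic transition matrix on the active set, with stationary law."""

    T: np.ndarray
    pi: np.ndarray
    lag_ns: float
    active_set: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def eigenvalues(self) -> np.ndarray:
        return markov.sorted_eigenvalues(self.T)

    def timescales_ns(self, n: int | None = None) -> np.ndarray:
        return markov.relaxation_timescales(self.T, self.lag_ns, n)

    def mfpt_ns(self, A, B) -> float:
        return markov.mean_first_passage_time(self.T, A, B, step_time=self.lag_ns)


def reversible_mle(C: np.ndarray, tol: float = 1e-10, max_iter: int = 100_000):
    """Reversible maximum-likelihood transition matrix by fixed-point iteration.

    Iterates ``x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)`` on the
    symmetric auxiliary matrix until the max change of T drops below ``tol``.
    Returns ``(T, pi)``.
    """
    C = np.asarray(C, dtype=float)
    c_row = C.sum(axis=1)
    if np.any(c_row == 0):
        raise EstimationError("count matrix has an empty row on the active set")
    Csym = C + C.T
    x = Csym.copy()
    T_old = x / x.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        x_row = x.sum(axis=1)
        denom = c_row[:, None] / x_row[:, None] + c_row[None, :] / x_row[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(Csym > 0, Csym / denom, 0.0)
        x_row_new = x_new.sum(axis=1)
        T = x_new / x_row_new[:, None]
        delta = np.max(np.abs(T - T_old))
        x, T_old = x_new, T
        if delta < tol:
            pi = x.sum(axis=1) / x.sum()
            return T_old, pi
    raise EstimationError(
        f"reversible MLE did not converge in {max_iter} iterations (last delta {delta:.2e})")


def estimate_reversible(counts: CountMatrix, tol: float = 1e-10,
                        max_iter: int = 100_000) -> MarkovModel:
    """Reversible MLE Markov model on the active set of a count matrix."""
    T, pi = reversible_mle(counts.C_active, tol=tol, max_iter=max_iter)
    return MarkovModel(T=T, pi=pi, lag_ns=counts.lag_ns, active_set=counts.active_set)


# ---- implied timescales ---------------------------------------------------

def implied_timescales(models, n: int = 5) -> pd.DataFrame:
    """Implied timescale table for models at several lags.

    One row per model; columns ``t1..tn`` (ns), NaN where the eigenvalue is
    non-positive or complex (flagged, not reported), plus per-process
    ``below_lag`` flags for converged-but-fast processes.
    """
    rows = []
    for m in models:
        ts = m.timescales_ns(n)
        row = {"lag_ns": m.lag_ns}
        for i in range(n):
            t = ts[i] if i < len(ts) else np.nan
            row[f"t{i + 1}_ns"] = t
            row[f"t{i + 1}_below_lag"] = bool(np.isfinite(t) and t < m.lag_ns)
        rows.append(row)
    return pd.DataFrame(rows)


# ---- Bayesian posterior ---------------------------------------------------

@dataclass
class PosteriorEnsemble:
    models: list
    seed: int

    def collect(self, fn) -> np.ndarray:
        """Evaluate a scalar/array statistic on every sampled model."""
        return np.array([fn(m) for m in self.models])


def sample_posterior(counts: CountMatrix, n_samples: int = 100, seed: int = 0,
                     n_thin: int = 5, step: float = 0.25) -> PosteriorEnsemble:
    """MCMC samples of reversible transition matrices given the counts.

    Random-walk Metropolis in the log of the symmetric auxiliary matrix
    ``x`` (the unnormalized reversible parameterization), so every sample is
    row-stochastic and in detailed balance by construction. ``n_thin`` full
    sweeps separate consecutive stored samples.
    """
    rng = np.random.default_rng(seed)
    C = np.asarray(counts.C_active, dtype=float)
    k = C.shape[0]
    c_row = C.sum(axis=1)
    Csym = C + C.T
    pairs = [(i, j) for i in range(k) for j in range(i, k) if Csym[i, j] > 0]
    x = Csym / Csym.sum()
    x_row = x.sum(axis=1)
    models = []
    for _ in range(n_samples):
        for _ in range(n_thin):
            zs = rng.standard_normal(len(pairs)) * step
            us = rng.random(len(pairs))
            for (i, j), z, u in zip(pairs, zs, us):
                old = x[i, j]
                new = old * np.exp(z)
                d = new - old
                if i == j:
                    new_ri = x_row[i] + d
                    dlog = C[i, i] * (np.log(new) - np.log(old)) \
                        - c_row[i] * (np.log(new_ri) - np.log(x_row[i]))
                    if np.log(u) < dlog:
                        x[i, i] = new
                        x_row[i] = new_ri
                else:
                    new_ri = x_row[i] + d
                    new_rj = x_row[j] + d
                    dlog = (C[i, j] + C[j, i]) * (np.log(new) - np.log(old)) \
                        - c_row[i] * (np.log(new_ri) - np.log(x_row[i])) \
                        - c_row[j] * (np.log(new_rj) - np.log(x_row[j]))
                    if np.log(u) < dlog:
                        x[i, j] = x[j, i] = new
                        x_row[i] = new_ri
                        x_row[j] = new_rj
            # guard against slow numeric drift of the cached row sums
            x_row = x.sum(axis=1)
        T = x / x_row[:, None]
        models.append(MarkovModel(T=T, pi=x_row / x_row.sum(), lag_ns=counts.lag_ns,
                                  active_set=counts.active_set))
    return PosteriorEnsemble(models=models, seed=seed)


# ---- coarse graining ------------------------------------------------------

@dataclass
class MacrostateModel:
    """Hidden/macrostate model: macro transition matrix plus fuzzy memberships."""

    n_macro: int
    T_macro: np.ndarray
    pi_macro: np.ndarray
    memberships: np.ndarray    # (n_micro_active, n_macro), rows sum to 1
    emission: np.ndarray       # (n_macro, n_micro_active), rows sum to 1
    lag_ns: float
    active_set: np.ndarray
    em_converged: bool = True

    def eigenvalues(self) -> np.ndarray:
        return markov.sorted_eigenvalues(self.T_macro)

    def timescales_ns(self, n: int | None = None) -> np.ndarray:
        return markov.relaxation_timescales(self.T_macro, self.lag_ns, n)

    def mfpt_ns(self, A, B) -> float:
        return markov.mean_first_passage_time(self.T_macro, A, B, step_time=self.lag_ns)

    def lifetimes_ns(self) -> np.ndarray:
        return self.lag_ns / (1.0 - np.diag(self.T_macro))

    def micro_to_macro(self) -> np.ndarray:
        """Crisp microstate -> macrostate map (argmax membership, ties -> lower)."""
        return np.argmax(self.memberships, axis=1)


def pcca_memberships(T: np.ndarray, pi: np.ndarray, n_macro: int) -> np.ndarray:
    """Spectral metastability (PCCA+-style) membership matrix.

    Uses the inner-simplex construction on the top right eigenvectors of the
    reversible transition matrix: representative microstates spanning the
    eigenvector simplex are located, and memberships follow from expressing
    each state in their barycentric basis (clipped and renormalized).
    """
    n = T.shape[0]
    if not 2 <= n_macro <= n:
        raise ValueError("n_macro must be between 2 and the number of microstates")
    if n_macro == n:
        return np.eye(n)
    # symmetrized eigenproblem for numerically real spectra
    sqrt_pi = np.sqrt(pi)
    S = T * sqrt_pi[:, None] / sqrt_pi[None, :]
    S = (S + S.T) / 2
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1][:n_macro]
    psi = evecs[:, order] / sqrt_pi[:, None]       # right eigenvectors of T
    psi = psi / np.abs(psi[:, 0:1])                # first column == 1
    # inner simplex: greedily pick spanning vertices
    verts = [int(np.argmax(np.linalg.norm(psi - psi.mean(axis=0), axis=1)))]
    basis = psi - psi[verts[0]]
    for _ in range(1, n_macro):
        q, _ = np.linalg.qr(basis[verts[1:]].T) if len(verts) > 1 else (np.zeros((n_macro, 0)), None)
        resid = basis - basis @ q @ q.T
        verts.append(int(np.argmax(np.linalg.norm(resid, axis=1))))
    A = psi[verts]                                  # (n_macro, n_macro)
    chi = psi @ np.linalg.inv(A)
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    return chi


def _coarse_grain_T(T, pi, chi):
    """Project a micro transition matrix onto macrostates (pi-weighted)."""
    D = pi[:, None] * chi
    M = chi.T @ D                                  # (n_macro, n_macro) overlap
    Tm = np.linalg.solve(M, chi.T @ (pi[:, None] * (T @ chi)))
    Tm = np.clip(Tm, 0.0, None)
    return Tm / Tm.sum(axis=1, keepdims=True)


def coarse_grain(dtrajs, micro_model: MarkovModel, n_macro: int,
                 lag_frames: int | None = None, max_em_iter: int = 500,
                 em_tol: float = 1e-6, n_offsets: int = 1) -> MacrostateModel:
    """Coarse-grain a microstate model into a discrete-emission hidden Markov model.

    The spectral (PCCA-style) metastability decomposition of the microstate
    model initializes macrostate transition, stationary, and emission
    matrices; expectation-maximization on the lag-strided discrete
    trajectories then refines them at the model lag. ``n_offsets`` strided
    phases are used as independent sequences (1 uses frames 0, lag, 2*lag...).
    """
    if n_macro == micro_model.n_states:
        chi = np.eye(n_macro)
        return MacrostateModel(n_macro=n_macro, T_macro=micro_model.T.copy(),
                               pi_macro=micro_model.pi.copy(), memberships=chi,
                               emission=chi * 1.0, lag_ns=micro_model.lag_ns,
                               active_set=micro_model.active_set)
    chi = pcca_memberships(micro_model.T, micro_model.pi, n_macro)
    T_init = _coarse_grain_T(micro_model.T, micro_model.pi, chi)
    pi_init = markov.stationary_distribution(T_init)
    n_micro = micro_model.n_states
    # emission: P(micro i | macro m) via Bayes from memberships
    B = (chi * micro_model.pi[:, None]).T
    B = np.maximum(B, 1e-12)
    B /= B.sum(axis=1, keepdims=True)

    if lag_frames is None:
        lag_frames = 1
    seqs = _strided_active_sequences(dtrajs, micro_model.active_set, lag_frames, n_offsets)
    if not seqs:
        raise EstimationError("no usable sequences at this lag on the active set")
    from hmmlearn.hmm import CategoricalHMM

    hmm = CategoricalHMM(n_components=n_macro, n_features=n_micro,
                         init_params="", params="ste", n_iter=max_em_iter,
                         tol=em_tol, random_state=0)
    hmm.startprob_ = pi_init
    hmm.transmat_ = T_init
    hmm.emissionprob_ = B
    concat = np.concatenate(seqs)[:, None]
    lengths = [len(s) for s in seqs]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hmm.fit(concat, lengths)
    converged = bool(hmm.monitor_.converged)
    if not converged:
        warnings.warn("macrostate EM did not converge; returning best iterate")
    T_macro = hmm.transmat_
    pi_macro = markov.stationary_distribution(T_macro)
    B_fit = hmm.emissionprob_
    # memberships P(macro m | micro i)
    post = (pi_macro[:, None] * B_fit).T
    post /= np.maximum(post.sum(axis=1, keepdims=True), 1e-300)
    return MacrostateModel(n_macro=n_macro, T_macro=T_macro, pi_macro=pi_macro,
                           memberships=post, emission=B_fit, lag_ns=micro_model.lag_ns,
                           active_set=micro_model.active_set, em_converged=converged)


def _strided_active_sequences(dtrajs, active_set, lag_frames: int, n_offsets: int):
    """Map dtrajs onto active-set indices, split at excluded frames, stride by lag."""
    dtrajs = dtrajs if isinstance(dtrajs, (list, tuple)) else [dtrajs]
    n_full = max(int(np.max(d)) for d in dtrajs) + 1
    to_active = np.full(max(n_full, int(active_set.max()) + 1), -1, dtype=np.int64)
    to_active[active_set] = np.arange(len(active_set))
    seqs = []
    offsets = range(min(n_offsets, lag_frames))
    for d in dtrajs:
        mapped = to_active[np.asarray(d, dtype=np.int64)]
        # split into maximal runs of active frames
        bad = np.flatnonzero(mapped < 0)
        bounds = np.concatenate([[-1], bad, [len(mapped)]])
        for lo, hi in zip(bounds[:-1] + 1, bounds[1:]):
            if hi - lo < 2 * lag_frames:
                continue
            for off in offsets:
                s = mapped[lo + off:hi:lag_frames]
                if len(s) >= 2:
                    seqs.append(s)
    return seqs


def scan_macrostates(dtrajs, micro_model: MarkovModel, lag_frames: int,
                     n_range=range(4, 9), multiples=(2, 3, 4, 5),
                     min_population: float = 0.01, seed: int = 0,
                     n_offsets: int = 1, max_em_iter: int = 500,
                     em_tol: float = 1e-6):
    """Macrostate-count scan with CK and resolved-timescale validation.

    For each candidate count ``n`` a macrostate model is built and judged on
    three criteria: (i) the Chapman-Kolmogorov test passes, (ii) all ``n - 1``
    macro relaxation timescales are real and exceed the model lag (a model
    that splits a metastable set introduces an unresolved fast process), and
    (iii) no macrostate has stationary population below ``min_population``
    (spurious resolution). The selected count is the largest candidate
    meeting all three; returns ``(selected_n, table, models)``.
    """
    rows, models = [], {}
    for n in n_range:
        mac = coarse_grain(dtrajs, micro_model, n_macro=n, lag_frames=lag_frames,
                           n_offsets=n_offsets, max_em_iter=max_em_iter, em_tol=em_tol)
        models[n] = mac
        ck = ck_test(mac, dtrajs, lag_frames, multiples=multiples, seed=seed)
        ts = mac.timescales_ns(n - 1)
        resolved = bool(np.all(np.isfinite(ts)) and np.all(ts > mac.lag_ns))
        pop_ok = bool(mac.pi_macro.min() >= min_population)
        rows.append({"n_macro": n, "ck_passed": bool(ck.passed),
                     "timescales_resolved": resolved, "min_population": mac.pi_macro.min(),
                     "population_ok": pop_ok,
                     "accepted": bool(ck.passed and resolved and pop_ok)})
    table = pd.DataFrame(rows)
    accepted = table.loc[table["accepted"], "n_macro"]
    selected = int(accepted.max()) if len(accepted) else None
    return selected, table, models


# ---- Chapman-Kolmogorov test ---------------------------------------------

@dataclass
class CKResult:
    table: pd.DataFrame
    passed: bool


def ck_test(model: MacrostateModel, dtrajs, lag_frames: int, multiples=(2, 3, 4, 5),
            n_boot: int = 200, seed: int = 0, frame_interval_ns: float | None = None) -> CKResult:
    """Chapman-Kolmogorov test of the macrostate model.

    Compares model-predicted residence probabilities ``(T^k)_mm`` against
    residence probabilities re-estimated from the data at lag ``k * tau``,
    with 95% intervals from Dirichlet posterior sampling of the respective
    count matrices. The test passes when the intervals overlap for every
    state and multiple.
    """
    rng = np.random.default_rng(seed)
    macro_dtrajs = assign_macro_dtrajs(model, dtrajs)
    rows = []
    passed = True
    base = _macro_counts(macro_dtrajs, lag_frames, model.n_macro)
    base_samples = _dirichlet_T_samples(base, n_boot, rng)
    for k in multiples:
        try:
            est = _macro_counts(macro_dtrajs, k * lag_frames, model.n_macro)
        except ValueError:
            for m in range(model.n_macro):
                rows.append({"state": m, "multiple": k, "status": "indeterminate"})
            continue
        est_samples = _dirichlet_T_samples(est, n_boot, rng)
        pred_diag = np.array([np.linalg.matrix_power(model.T_macro, k).diagonal()])
        pred_samples = np.array([np.linalg.matrix_power(S, k).diagonal()
                                 for S in base_samples])
        for m in range(model.n_macro):
            if est[m].sum() == 0:
                rows.append({"state": m, "multiple": k, "status": "indeterminate"})
                continue
            plo, phi = np.percentile(pred_samples[:, m], [2.5, 97.5])
            elo, ehi = np.percentile(est_samples[:, m, m], [2.5, 97.5])
            est_diag = est[m, m] / est[m].sum()
            ok = (plo <= ehi) and (elo <= phi)
            passed &= ok
            rows.append({"state": m, "multiple": k, "predicted": float(pred_diag[0, m]),
                         "pred_lo": plo, "pred_hi": phi, "estimated": float(est_diag),
                         "est_lo": elo, "est_hi": ehi,
                         "status": "pass" if ok else "fail"})
    return CKResult(table=pd.DataFrame(rows), passed=passed)


def assign_macro_dtrajs(model: MacrostateModel, dtrajs) -> list:
    """Crisp macrostate label sequences (-1 for frames outside the active set)."""
    dtrajs = dtrajs if isinstance(dtrajs, (list, tuple)) else [dtrajs]
    n_full = max(int(np.max(d)) for d in dtrajs) + 1
    lut = np.full(max(n_full, int(model.active_set.max()) + 1), -1, dtype=np.int64)
    lut[model.active_set] = model.micro_to_macro()
    return [lut[np.asarray(d, dtype=np.int64)] for d in dtrajs]


def _macro_counts(macro_dtrajs, lag_frames: int, n_macro: int) -> np.ndarray:
    """Non-overlapping (strided) macro transition counts.

    Strided counting keeps the counts approximately independent, so the
    Dirichlet posterior intervals used by the CK test have honest coverage
    (sliding counts at lag L are ~L-fold autocorrelated).
    """
    shortest = min(len(d) for d in macro_dtrajs)
    if lag_frames >= shortest:
        raise ValueError("lag exceeds trajectory length")
    C = np.zeros((n_macro, n_macro), dtype=np.int64)
    for d in macro_dtrajs:
        a, b = d[:-lag_frames:lag_frames], d[lag_frames::lag_frames]
        ok = (a >= 0) & (b >= 0)
        np.add.at(C, (a[ok], b[ok]), 1)
    return C


def _dirichlet_T_samples(C: np.ndarray, n: int, rng) -> np.ndarray:
    out = np.empty((n, *C.shape))
    for i in range(C.shape[0]):
        out[:, i, :] = rng.dirichlet(C[i] + 0.5, size=n)
    return out


# ---- kinetic summaries ----------------------------------------------------

def mfpt(model, A, B) -> float:
    """Mean first-passage time (in the model's time unit, ns) from set A to set B."""
    return model.mfpt_ns(A, B)


@dataclass
class GMMSummary:
    mean: float
    sd: float
    n_components: int
    component_means: np.ndarray
    component_weights: np.ndarray


def gmm_summary(samples: np.ndarray, max_components: int = 3, seed: int = 0) -> GMMSummary:
    """Summarize a posterior scalar sample with a 1-3 component GMM (BIC-selected)."""
    from sklearn.mixture import GaussianMixture

    x = np.asarray(samples, dtype=float).reshape(-1, 1)
    x = x[np.isfinite(x[:, 0])]
    if len(x) == 0:
        return GMMSummary(np.nan, np.nan, 0, np.array([]), np.array([]))
    if len(x) < 3 or np.std(x) < 1e-12:
        return GMMSummary(float(np.mean(x)), float(np.std(x)), 1,
                          np.array([float(np.mean(x))]), np.array([1.0]))
    best, best_bic = None, np.inf
    for nc in range(1, max_components + 1):
        gm = GaussianMixture(n_components=nc, random_state=seed, n_init=2).fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best, best_bic = gm, bic
    return GMMSummary(mean=float(np.mean(x)), sd=float(np.std(x)),
                      n_components=best.n_components,
                      component_means=best.means_.ravel(),
                      component_weights=best.weights_.ravel())


@dataclass
class KineticSummary:
    lifetimes: pd.DataFrame
    timescales: pd.DataFrame


def summarize_kinetics(ensemble: PosteriorEnsemble | None, model: MacrostateModel,
                       seed: int = 0) -> KineticSummary:
    """Lifetimes and relaxation timescales with posterior GMM summaries.

    Lifetime of state i is ``tau / (1 - T_ii)`` (geometric dwell); relaxation
    timescales come from the macro eigenvalues. When a posterior ensemble of
    macro-level models is supplied, each scalar gets a 1-3 component GMM
    summary (mean, sd, BIC-selected component count).
    """
    n = model.n_macro
    life_rows = []
    ts_point = model.timescales_ns()
    life_point = model.lifetimes_ns()
    life_samples = ts_samples = None
    if ensemble is not None and ensemble.models:
        life_samples = ensemble.collect(
            lambda m: m.lag_ns / (1.0 - np.diag(_macro_T_of(m))))
        ts_samples = ensemble.collect(
            lambda m: markov.relaxation_timescales(_macro_T_of(m), m.lag_ns, n - 1))
    for i in range(n):
        row = {"state": i, "lifetime_ns": float(life_point[i])}
        if life_samples is not None:
            g = gmm_summary(life_samples[:, i], seed=seed)
            row.update(posterior_mean=g.mean, posterior_sd=g.sd,
                       gmm_components=g.n_components)
        life_rows.append(row)
    ts_rows = []
    for i in range(n - 1):
        row = {"process": i + 1, "timescale_ns": float(ts_point[i])}
        if ts_samples is not None:
            g = gmm_summary(ts_samples[:, i], seed=seed)
            row.update(posterior_mean=g.mean, posterior_sd=g.sd,
                       gmm_components=g.n_components)
        ts_rows.append(row)
    return KineticSummary(lifetimes=pd.DataFrame(life_rows),
                          timescales=pd.DataFrame(ts_rows))


def _macro_T_of(m) -> np.ndarray:
    return m.T_macro if isinstance(m, MacrostateModel) else m.T
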