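"""Slow-mode estimation and feature selection.

Implements reversible (symmetrized) time-lagged independent component
analysis, feature/IC Pearson correlation ranking with the 0.45 (candidate)
and 0.70 (strong) thresholds, redundancy/locality pruning of residue-pair
candidates, and VAMP-2 scoring of feature representations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .features import FeatureMatrix

CANDIDATE_THRESHOLD = 0.45
STRONG_THRESHOLD = 0.70


def _as_matrix_list(X) -> tuple:
    """Normalize input to (list of 2-D arrays, frame_interval_ns)."""
    if isinstance(X, FeatureMatrix):
        return [X.values], X.frame_interval_ns
    if isinstance(X, np.ndarray):
        return [np.asarray(X, dtype=float)], 1.0
    mats = list(X)
    if not mats:
        raise ValueError("need at least one trajectory")
    if isinstance(mats[0], FeatureMatrix):
        return [m.values for m in mats], mats[0].frame_interval_ns
    return [np.asarray(m, dtype=float) for m in mats], 1.0


def _lag_frames(lag_ns: float, frame_interval_ns: float) -> int:
    ratio = lag_ns / frame_interval_ns
    lf = int(round(ratio))
    if lf < 1 or abs(ratio - lf) > 1e-6:
        raise ValueError(f"lag {lag_ns} ns must be a positive multiple of the "
                         f"frame interval {frame_interval_ns} ns")
    return lf


def _lagged_covariances(mats, lag_frames: int, ridge: float):
    """Mean-free symmetrized instantaneous and time-lagged covariances.

    Returns ``(C0, Ct, mean, n_pairs, keep)`` where ``keep`` marks columns
    with nonzero variance (zero-variance columns are dropped with a warning).
    """
    usable = [m for m in mats if m.shape[0] > lag_frames]
    if not usable:
        raise ValueError("lag exceeds every trajectory length")
    n_pairs = sum(m.shape[0] - lag_frames for m in usable)
    d = usable[0].shape[1]
    s = np.zeros(d)
    for m in usable:
        s += m[:-lag_frames].sum(axis=0) + m[lag_frames:].sum(axis=0)
    mean = s / (2 * n_pairs)
    C0 = np.zeros((d, d))
    Ct = np.zeros((d, d))
    for m in usable:
        a = m[:-lag_frames] - mean
        b = m[lag_frames:] - mean
        C0 += a.T @ a + b.T @ b
        Ct += a.T @ b
    C0 /= 2 * n_pairs
    Ct = (Ct + Ct.T) / (2 * n_pairs)
    keep = np.diag(C0) > 1e-15
    if not np.all(keep):
        warnings.warn(f"dropping {np.sum(~keep)} zero-variance feature column(s)")
        C0 = C0[np.ix_(keep, keep)]
        Ct = Ct[np.ix_(keep, keep)]
    C0 = C0 + ridge * np.eye(C0.shape[0])
    return C0, Ct, mean, n_pairs, keep


@dataclass
class TICAModel:
    """Reversible TICA solution.

    ``components`` has one loading vector per column (ordered by decreasing
    eigenvalue); ``eigenvalues`` are the symmetrized autocovariance
    eigenvalues clipped to [-1, 1]; ``means`` are the centering offsets.
    ``kept_columns`` marks input features that survived the zero-variance
    filter.
    """

    lag_ns: float
    components: np.ndarray     # (n_kept_features, n_components)
    eigenvalues: np.ndarray
    means: np.ndarray          # in the original feature space
    kept_columns: np.ndarray
    feature_labels: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def timescales_ns(self) -> np.ndarray:
        """Implied timescale per component, -lag / ln(lambda); NaN outside (0,1)."""
        out = np.full(self.n_components, np.nan)
        ok = (self.eigenvalues > 0) & (self.eigenvalues < 1)
        out[ok] = -self.lag_ns / np.log(self.eigenvalues[ok])
        return out

    def transform(self, X) -> np.ndarray:
        """Project frames onto the independent components."""
        vals = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        return (vals[:, self.kept_columns] - self.means[self.kept_columns]) @ self.components


def estimate_tica(X, lag_ns: float, dim: int | None = None, ridge: float = 1e-6) -> TICAModel:
    """Estimate reversible TICA at the given lag.

    Covariances are symmetrized (``C(tau) <- (C + C^T)/2`` over forward and
    reversed time pairs) after mean-centering, a small ridge ``ridge`` is
    added to the instantaneous covariance, and the generalized symmetric
    eigenproblem ``Ct v = lambda C0 v`` is solved. Components are ordered by
    decreasing eigenvalue and sign-fixed so each component's largest-|loading|
    feature has positive loading.
    """
    mats, dt = _as_matrix_list(X)
    labels: list = []
    if isinstance(X, FeatureMatrix):
        labels = X.labels
    elif isinstance(X, (list, tuple)) and X and isinstance(X[0], FeatureMatrix):
        labels = X[0].labels
    lf = _lag_frames(lag_ns, dt)
    C0, Ct, mean, n_pairs, keep = _lagged_covariances(mats, lf, ridge)
    if n_pairs < 2:
        raise ValueError("need at least 2 time pairs at this lag")
    try:
        evals, evecs = scipy.linalg.eigh(Ct, C0)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "instantaneous covariance not positive definite after regularization") from exc
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], -1.0, 1.0)
    evecs = evecs[:, order]
    # deterministic sign convention
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    if dim is not None:
        evals = evals[:dim]
        evecs = evecs[:, :dim]
    return TICAModel(lag_ns=lag_ns, components=evecs, eigenvalues=evals,
                     means=mean, kept_columns=keep,
                     feature_labels=list(labels) if labels else [])


# ---- correlation ranking --------------------------------------------------

@dataclass
class CorrelationTable:
    """Pearson correlations of raw features with IC projections.

    ``corr`` is (n_features, n_ics); the candidate / strong flags are per
    feature, set when |corr| with any considered IC exceeds the threshold.
    """

    corr: np.ndarray
    feature_labels: list
    candidate_threshold: float = CANDIDATE_THRESHOLD
    strong_threshold: float = STRONG_THRESHOLD

    @property
    def max_abs(self) -> np.ndarray:
        return np.max(np.abs(self.corr), axis=1)

    @property
    def candidate(self) -> np.ndarray:
        return self.max_abs >= self.candidate_threshold

    @property
    def strong(self) -> np.ndarray:
        return self.max_abs >= self.strong_threshold

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.corr,
                          columns=[f"IC{k + 1}" for k in range(self.corr.shape[1])])
        df.insert(0, "feature", self.feature_labels or np.arange(len(self.corr)))
        df["max_abs_corr"] = self.max_abs
        df["candidate"] = self.candidate
        df["strong"] = self.strong
        return df


def feature_ic_correlation(model: TICAModel, X, n_ics: int = 6,
                           ics: list | None = None) -> CorrelationTable:
    """Correlate every raw feature with the IC projections.

    ``ics`` optionally restricts to specific 1-based IC indices (e.g.
    ``[1, 2, 5, 6]`` to prioritize concerted over terminal motions); otherwise
    the first ``n_ics`` components are used. Constant features get
    correlation 0 with a warning.
    """
    if ics is None:
        ics = list(range(1, n_ics + 1))
    if max(ics) > model.n_components:
        raise ValueError(f"requested IC {max(ics)} but model has {model.n_components}")
    mats, _ = _as_matrix_list(X)
    vals = np.vstack(mats)
    proj = np.vstack([model.transform(m) for m in mats])[:, [i - 1 for i in ics]]
    fstd = vals.std(axis=0)
    pstd = proj.std(axis=0)
    # relative threshold: .std() of a constant column only reaches ~1e-13
    const = fstd <= 1e-10 * np.maximum(1.0, np.abs(vals.mean(axis=0)))
    if np.any(const):
        warnings.warn(f"{np.sum(const)} constant feature(s): correlation set to 0")
    fc = vals - vals.mean(axis=0)
    pc = proj - proj.mean(axis=0)
    cov = fc.T @ pc / len(vals)
    denom = np.outer(np.where(const, 1.0, fstd), np.where(pstd <= 1e-15, 1.0, pstd))
    corr = np.clip(cov / denom, -1.0, 1.0)
    corr[const] = 0.0
    labels = X.labels if isinstance(X, FeatureMatrix) else list(model.feature_labels)
    return CorrelationTable(corr=corr, feature_labels=labels)


# ---- redundancy / locality pruning ---------------------------------------

@dataclass
class FeatureRegistrySelection:
    """Retained residue pairs with provenance plus a pruning log."""

    retained: dict            # (i, j) -> score
    provenance: dict          # (i, j) -> arbitrary metadata (e.g. best IC)
    pruning_log: list         # (pair, reason) tuples in decision order


def prune_redundancy_locality(candidates: dict, neighborhood: int = 3,
                              terminal_margin: int = 3, near_window: int = 4,
                              residue_range: tuple | None = None,
                              provenance: dict | None = None) -> FeatureRegistrySelection:
    """Prune candidate residue pairs by locality and index-space redundancy.

    ``candidates`` maps unordered residue-index pairs to |correlation| scores.
    Pairs with either residue within ``terminal_margin`` of the chain ends,
    or with ``|i - j| <= near_window``, are removed first. The survivors are
    processed in descending score (ties: lexicographically smaller pair
    first); a pair is retained only if no already-retained pair lies within
    the ``neighborhood x neighborhood`` window of (i, j) index space
    (Chebyshev distance <= (neighborhood - 1) // 2).
    """
    if neighborhood % 2 != 1 or neighborhood < 1:
        raise ValueError("neighborhood must be a positive odd integer")
    radius = (neighborhood - 1) // 2
    norm = {}
    for (i, j), s in candidates.items():
        a, b = (int(i), int(j)) if i <= j else (int(j), int(i))
        norm[(a, b)] = float(s)
    if not norm:
        return FeatureRegistrySelection({}, {}, [])
    if residue_range is None:
        all_res = [r for p in norm for r in p]
        residue_range = (min(all_res), max(all_res))
    lo, hi = residue_range
    log = []
    local = {}
    for pair, s in norm.items():
        a, b = pair
        if a < lo + terminal_margin or b > hi - terminal_margin:
            log.append((pair, "terminal"))
        elif b - a <= near_window:
            log.append((pair, "near-neighbor"))
        else:
            local[pair] = s
    retained = {}
    for pair in sorted(local, key=lambda p: (-local[p], p)):
        a, b = pair
        clash = any(abs(a - ra) <= radius and abs(b - rb) <= radius
                    for ra, rb in retained)
        if clash:
            log.append((pair, "redundant-neighborhood"))
        else:
            retained[pair] = local[pair]
    prov = {p: (provenance or {}).get(p) for p in retained}
    return FeatureRegistrySelection(retained=retained, provenance=prov, pruning_log=log)


# ---- VAMP-2 ---------------------------------------------------------------

def vamp2_score(X, lag_ns: float, dim: int, ridge: float = 1e-6) -> float:
    """VAMP-2 score of a feature representation at a lag.

    Sum of squared singular values of the half-weighted time-lagged
    correlation operator ``C00^{-1/2} C0t Ctt^{-1/2}``, truncated at ``dim``
    singular functions including the constant one (so white noise scores 1
    and the score is bounded by ``dim``).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    mats, dt = _as_matrix_list(X)
    lf = _lag_frames(lag_ns, dt)
    usable = [m for m in mats if m.shape[0] > lf]
    if not usable:
        raise ValueError("lag exceeds every trajectory length")
    n_pairs = sum(m.shape[0] - lf for m in usable)
    d = usable[0].shape[1]
    mu0 = np.zeros(d)
    mut = np.zeros(d)
    for m in usable:
        mu0 += m[:-lf].sum(axis=0)
        mut += m[lf:].sum(axis=0)
    mu0 /= n_pairs
    mut /= n_pairs
    C00 = np.zeros((d, d))
    Ctt = np.zeros((d, d))
    C0t = np.zeros((d, d))
    for m in usable:
        a = m[:-lf] - mu0
        b = m[lf:] - mut
        C00 += a.T @ a
        Ctt += b.T @ b
        C0t += a.T @ b
    C00 = C00 / n_pairs + ridge * np.eye(d)
    Ctt = Ctt / n_pairs + ridge * np.eye(d)
    C0t /= n_pairs
    K = _inv_sqrt(C00) @ C0t @ _inv_sqrt(Ctt)
    sv = np.linalg.svd(K, compute_uv=False)
    sv = np.clip(sv, 0.0, 1.0)
    return float(1.0 + np.sum(sv[:dim - 1] ** 2))


def _inv_sqrt(C: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    evals, evecs = np.linalg.eigh(C)
    evals = np.clip(evals, eps, None)
    return evecs @ np.diag(evals ** -0.5) @ evecs.T
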