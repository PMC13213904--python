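"""Shared geometric primitives: torsions, superposition, plane fits, circumspheres.

All coordinates are in nanometres unless a function says otherwise.
"""
from __future__ import annotations

import numpy as np


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed torsion angle (degrees, in (-180, 180]) for four points.

    Accepts single points of shape (3,) or stacks of shape (..., 3); the
    computation is fully vectorized over leading axes.
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    # normal vectors of the two planes
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # fold -180 onto +180 so the range is (-180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def kabsch(mobile: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None):
    """Optimal least-squares rotation/translation of ``mobile`` onto ``target``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimizes the weighted RMSD.
    Both inputs are (n, 3). Reflections are excluded (proper rotation only).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if weights is None:
        weights = np.ones(len(mobile))
    w = np.asarray(weights, dtype=float)[:, None] / np.sum(weights)
    mu_m = np.sum(mobile * w, axis=0)
    mu_t = np.sum(target * w, axis=0)
    A = (target - mu_t).T @ ((mobile - mu_m) * w)
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = mu_t - R @ mu_m
    return R, t


def superpose(mobile: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Return ``mobile`` superposed onto ``target`` (shapes (n, 3))."""
    R, t = kabsch(mobile, target, weights)
    return mobile @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unweighted, unaligned) RMSD between two (n, 3) coordinate sets."""
    return float(np.sqrt(np.mean(np.sum((np.asarray(a) - np.asarray(b)) ** 2, axis=-1))))


def plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points`` (n >= 3, shape (n, 3)).

    The normal is the singular vector of the centered coordinates with the
    smallest singular value; its overall sign is arbitrary.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("plane fit requires at least 3 points")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]


def plane_angle(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Acute angle (degrees, in [0, 90]) between two least-squares planes."""
    na = plane_normal(points_a)
    nb = plane_normal(points_b)
    c = abs(float(np.dot(na, nb)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def circumsphere(tetra: np.ndarray):
    """Center and radius of the sphere through 4 points (shape (4, 3)).

    Solves the linear system from equating squared distances to the four
    vertices. Raises ``np.linalg.LinAlgError`` for degenerate (coplanar) input.
    """
    p = np.asarray(tetra, dtype=float)
    A = 2.0 * (p[1:] - p[0])
    b = np.sum(p[1:] ** 2, axis=1) - np.sum(p[0] ** 2)
    center = np.linalg.solve(A, b)
    radius = float(np.linalg.norm(p[0] - center))
    return center, radius


def angle_at(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle (degrees) at ``vertex`` spanned by points ``a`` and ``b``; vectorized."""
    u = np.asarray(a) - np.asarray(vertex)
    v = np.asarray(b) - np.asarray(vertex)
    un = np.linalg.norm(u, axis=-1)
    vn = np.linalg.norm(v, axis=-1)
    c = np.sum(u * v, axis=-1) / (un * vn)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
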