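"""Geometric featurization of coordinate ensembles.

Descriptors follow the conventions of MSM featurizers: side-chain
center-of-mass (COM) and Cα pair distances in nm, backbone φ/ψ torsions
encoded as (cos, sin) pairs, Cα four-residue dihedrals in degrees, and
aromatic ring-plane angles in degrees folded to [0°, 90°].
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .trajectory import (
    HYDROPHOBIC_RESIDUES,
    Trajectory,
    TrajectoryDataError,
)

#: ring heavy atoms used for the least-squares plane fit, per aromatic residue
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


@dataclass
class DescriptorRegistry:
    """Declarative list of geometric descriptors.

    ``com_pairs`` and ``ca_pairs`` hold residue-id pairs (distances, nm);
    ``dihedral_quads`` holds 4-residue Cα quadruples (degrees); ``ring_pairs``
    holds aromatic residue pairs (ring-plane angle, degrees).
    """

    com_pairs: list = field(default_factory=list)
    ca_pairs: list = field(default_factory=list)
    dihedral_quads: list = field(default_factory=list)
    ring_pairs: list = field(default_factory=list)

    def __post_init__(self):
        for pairs, label in ((self.com_pairs, "com_pairs"), (self.ca_pairs, "ca_pairs"),
                             (self.ring_pairs, "ring_pairs")):
            seen = set()
            for i, j in pairs:
                if i == j:
                    raise ValueError(f"{label}: pair ({i},{j}) has equal members")
                key = (min(i, j), max(i, j))
                if key in seen:
                    raise ValueError(f"{label}: pair {key} repeats")
                seen.add(key)

    @property
    def size(self) -> int:
        return (len(self.com_pairs) + len(self.ca_pairs)
                + len(self.dihedral_quads) + len(self.ring_pairs))

    def validate_against(self, traj: Trajectory) -> None:
        present = set(int(r) for r in traj.residue_ids)
        referenced = set()
        for i, j in itertools.chain(self.com_pairs, self.ca_pairs, self.ring_pairs):
            referenced.update((int(i), int(j)))
        for quad in self.dihedral_quads:
            referenced.update(int(r) for r in quad)
        missing = referenced - present
        if missing:
            raise TrajectoryDataError(f"registry references absent residues {sorted(missing)}")


@dataclass
class FeatureMatrix:
    """Frames × descriptors table with labels and per-column units."""

    values: np.ndarray
    labels: list
    units: list
    frame_interval_ns: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x descriptors)")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count must equal column count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if len(self.units) != len(self.labels):
            raise ValueError("units must align with labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.labels)

    def write_csv(self, path) -> None:
        """Write values as CSV with a JSON sidecar carrying labels/units/lag."""
        path = str(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {"labels": list(self.labels), "units": list(self.units),
                   "frame_interval_ns": self.frame_interval_ns}
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def read_csv(cls, path) -> "FeatureMatrix":
        path = str(path)
        df = pd.read_csv(path)
        with open(path + ".json") as fh:
            sidecar = json.load(fh)
        return cls(df.to_numpy(), sidecar["labels"], sidecar["units"],
                   sidecar["frame_interval_ns"])

    @staticmethod
    def concatenate(mats: list) -> "FeatureMatrix":
        first = mats[0]
        for m in mats[1:]:
            if m.labels != first.labels:
                raise ValueError("cannot concatenate feature matrices with different labels")
        return FeatureMatrix(np.vstack([m.values for m in mats]), first.labels,
                             first.units, first.frame_interval_ns)


# ---- COM / Cα distances ---------------------------------------------------

def sidechain_com(traj: Trajectory, res_id: int) -> np.ndarray:
    """Mass-weighted side-chain heavy-atom COM per frame; glycine → Cα.

    "Side chain" means heavy atoms from Cβ outward (backbone N, CA, C, O and
    terminal oxygens excluded).
    """
    idx = traj.residue_atom_indices(res_id)
    names = traj.atom_names[idx]
    heavy = traj.heavy_atom_mask()[idx]
    backbone = np.isin(names, ("N", "CA", "C", "O", "OXT"))
    side = idx[heavy & ~backbone]
    if len(side) == 0:
        # glycine (or stripped residue): fall back to Cα
        try:
            ca = traj.atom_index(res_id, "CA")
        except TrajectoryDataError as exc:
            raise TrajectoryDataError(
                f"residue {res_id} has neither side-chain heavy atoms nor CA") from exc
        return traj.coords[:, ca, :]
    masses = traj.masses()[side]
    return np.einsum("fas,a->fs", traj.coords[:, side, :], masses) / masses.sum()


def _distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a - b, axis=-1)


def pair_distance_features(traj: Trajectory, pairs=None, mode: str = "sidechain-com",
                           selection=None) -> FeatureMatrix:
    """Residue-pair distance features (nm).

    Parameters
    ----------
    pairs
        Explicit residue-id pairs, or ``None`` for exhaustive enumeration of
        all unordered pairs of the (optionally filtered) residue set.
    mode
        ``'sidechain-com'`` (mass-weighted side-chain COM, glycine → Cα) or
        ``'calpha'``.
    selection
        Optional residue-class filter applied before exhaustive enumeration:
        either an iterable of residue names (e.g. a hydrophobic class) or the
        string ``'hydrophobic'`` for the default class.
    """
    if mode not in ("sidechain-com", "calpha"):
        raise ValueError(f"unknown distance mode {mode!r}")
    res_ids = [int(r) for r in traj.residue_ids]
    if selection is not None:
        if isinstance(selection, str):
            if selection != "hydrophobic":
                raise ValueError(f"unknown selection {selection!r}")
            cls = HYDROPHOBIC_RESIDUES
        else:
            cls = {str(s).upper() for s in selection}
        res_ids = [r for r in res_ids if traj.residue_name(r).upper() in cls]
    if pairs is None:
        pairs = list(itertools.combinations(res_ids, 2))
    pairs = [(int(i), int(j)) for i, j in pairs]
    DescriptorRegistry(com_pairs=pairs)  # reuse pair validity checks

    if mode == "sidechain-com":
        points = {r: sidechain_com(traj, r) for r in {r for p in pairs for r in p}}
        tag = "com"
    else:
        points = {r: traj.coords[:, traj.atom_index(r, "CA"), :]
                  for r in {r for p in pairs for r in p}}
        tag = "ca"
    values = np.column_stack([_distance(points[i], points[j]) for i, j in pairs]) \
        if pairs else np.empty((traj.n_frames, 0))
    labels = [f"{tag}_dist_{i}_{j}" for i, j in pairs]
    return FeatureMatrix(values, labels, ["nm"] * len(labels), traj.frame_interval_ns)


# ---- backbone torsions ----------------------------------------------------

def backbone_torsion_features(traj: Trajectory) -> FeatureMatrix:
    """φ/ψ backbone torsions as (cos, sin) column pairs.

    φ is defined for residues 2..n, ψ for residues 1..n-1, so a chain of n
    residues yields ``4 (n - 1)`` columns. Angles are computed from the
    N/CA/C backbone atoms; a missing backbone atom raises a data error naming
    the residue.
    """
    res = [int(r) for r in traj.residue_ids]
    n = len(res)
    if n < 2:
        raise TrajectoryDataError("torsions require at least 2 residues")
    atom = {}
    for r in res:
        for name in ("N", "CA", "C"):
            atom[(r, name)] = traj.atom_index(r, name)  # raises naming the residue
    X = traj.coords
    cols, labels = [], []
    for k in range(n):
        r = res[k]
        if k > 0:  # φ: C(k-1), N(k), CA(k), C(k)
            ang = geometry.dihedral(X[:, atom[(res[k - 1], "C")]], X[:, atom[(r, "N")]],
                                    X[:, atom[(r, "CA")]], X[:, atom[(r, "C")]])
            rad = np.radians(ang)
            cols += [np.cos(rad), np.sin(rad)]
            labels += [f"cos_phi_{r}", f"sin_phi_{r}"]
        if k < n - 1:  # ψ: N(k), CA(k), C(k), N(k+1)
            ang = geometry.dihedral(X[:, atom[(r, "N")]], X[:, atom[(r, "CA")]],
                                    X[:, atom[(r, "C")]], X[:, atom[(res[k + 1], "N")]])
            rad = np.radians(ang)
            cols += [np.cos(rad), np.sin(rad)]
            labels += [f"cos_psi_{r}", f"sin_psi_{r}"]
    return FeatureMatrix(np.column_stack(cols), labels,
                         ["dimensionless"] * len(labels), traj.frame_interval_ns)


# ---- angular descriptors --------------------------------------------------

def ring_plane_angle(traj: Trajectory, res_i: int, res_j: int) -> np.ndarray:
    """Per-frame acute angle between two aromatic ring planes (degrees)."""
    idx = []
    for r in (res_i, res_j):
        name = traj.residue_name(r).upper()
        if name not in RING_ATOMS:
            raise TrajectoryDataError(f"residue {r} ({name}) is not aromatic")
        try:
            idx.append([traj.atom_index(r, a) for a in RING_ATOMS[name]])
        except TrajectoryDataError as exc:
            raise TrajectoryDataError(f"residue {r} ({name}) has an incomplete ring") from exc
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = geometry.plane_angle(traj.coords[f, idx[0]], traj.coords[f, idx[1]])
    return out


def angular_descriptors(traj: Trajectory, quads=(), ring_pairs=()) -> FeatureMatrix:
    """Cα four-residue dihedrals (degrees, (-180, 180]) and ring-plane angles.

    ``quads`` are 4-tuples of residue ids (Cα dihedral, e.g. an inter-helix
    reorientation coordinate); ``ring_pairs`` are aromatic residue-id pairs
    (angle between least-squares ring planes, folded to [0°, 90°]).
    """
    cols, labels, units = [], [], []
    for quad in quads:
        ca = [traj.atom_index(int(r), "CA") for r in quad]
        ang = geometry.dihedral(traj.coords[:, ca[0]], traj.coords[:, ca[1]],
                                traj.coords[:, ca[2]], traj.coords[:, ca[3]])
        cols.append(np.atleast_1d(ang))
        labels.append("ca_dihedral_" + "_".join(str(int(r)) for r in quad))
        units.append("degrees")
    for i, j in ring_pairs:
        cols.append(ring_plane_angle(traj, int(i), int(j)))
        labels.append(f"ring_angle_{int(i)}_{int(j)}")
        units.append("degrees")
    values = np.column_stack(cols) if cols else np.empty((traj.n_frames, 0))
    return FeatureMatrix(values, labels, units, traj.frame_interval_ns)


def curated_rrm_registry() -> DescriptorRegistry:
    """The curated 18-descriptor registry for the TRMT2A-like RRM domain.

    Seven side-chain COM distances around the loop-5 hydrophobic cluster,
    nine Cα-Cα distances reporting on helix/sheet packing, the α1/α2
    inter-helix Cα dihedral (F86-F96-L129-A119), and the F92/W134 aromatic
    ring-plane angle.
    """
    return DescriptorRegistry(
        com_pairs=[(134, 92), (134, 133), (92, 133), (77, 92),
                   (77, 133), (77, 134), (77, 86)],
        ca_pairs=[(86, 104), (86, 79), (95, 130), (129, 132), (129, 134),
                  (133, 137), (132, 138), (86, 105), (86, 134)],
        dihedral_quads=[(86, 96, 129, 119)],
        ring_pairs=[(92, 134)],
    )


def compute_features(traj: Trajectory, registry: DescriptorRegistry) -> FeatureMatrix:
    """Evaluate a full DescriptorRegistry into one FeatureMatrix.

    Column order: COM distances, Cα distances, Cα dihedrals, ring angles.
    """
    registry.validate_against(traj)
    parts = []
    if registry.com_pairs:
        parts.append(pair_distance_features(traj, registry.com_pairs, mode="sidechain-com"))
    if registry.ca_pairs:
        parts.append(pair_distance_features(traj, registry.ca_pairs, mode="calpha"))
    if registry.dihedral_quads or registry.ring_pairs:
        parts.append(angular_descriptors(traj, registry.dihedral_quads, registry.ring_pairs))
    if not parts:
        return FeatureMatrix(np.empty((traj.n_frames, 0)), [], [], traj.frame_interval_ns)
    values = np.column_stack([p.values for p in parts])
    labels = sum((p.labels for p in parts), [])
    units = sum((p.units for p in parts), [])
    return FeatureMatrix(values, labels, units, traj.frame_interval_ns)
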