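"""Coordinate ensembles of a single protein chain.

A :class:`Trajectory` holds an ordered stack of frames (one conformation per
frame) together with per-atom metadata. Coordinates are stored in nanometres;
PDB files (Ångström) are converted on read. Multi-model PDB is the mandatory
interchange format; binary trajectory+topology pairs are supported behind the
same reader contract when :mod:`mdtraj` is importable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry

# standard atomic masses (u) for the elements that occur in protein heavy atoms
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}

#: default hydrophobic residue class used by the preset COM feature set
HYDROPHOBIC_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"})

BACKBONE_ATOMS = ("N", "CA", "C")


class TrajectoryFormatError(ValueError):
    """Raised when an input ensemble violates the format contract."""


class TrajectoryDataError(ValueError):
    """Raised when atoms required by an operation are missing."""


def infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name (best effort, protein atoms)."""
    name = atom_name.strip()
    if not name:
        raise TrajectoryDataError("empty atom name")
    if name[0].isdigit():  # e.g. 1HB2
        name = name.lstrip("0123456789")
    if name[:2].upper() in ("SE",) and len(name) >= 2:
        return "SE"
    return name[0].upper()


@dataclass
class Trajectory:
    """Ordered frames of one chain's atom coordinates plus atom metadata.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in nm.
    atom_names, elements, res_ids, res_names
        Per-atom records, each of length ``n_atoms``. ``res_ids`` must be
        non-decreasing along the chain.
    chain_id
        Single chain identifier.
    frame_interval_ns
        Time between stored frames; defaults to 1.0 when unknown.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_id: str = "A"
    frame_interval_ns: float = 1.0
    _res_atom_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryFormatError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryFormatError("coordinates must be finite")
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        n_atoms = self.coords.shape[1]
        for arr, label in ((self.atom_names, "atom_names"), (self.elements, "elements"),
                           (self.res_ids, "res_ids"), (self.res_names, "res_names")):
            if len(arr) != n_atoms:
                raise TrajectoryFormatError(f"{label} length {len(arr)} != atom count {n_atoms}")
        if np.any(np.diff(self.res_ids) < 0):
            raise TrajectoryFormatError("residue ids must be non-decreasing within the chain")

    # ---- basic accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue ids in chain order."""
        _, idx = np.unique(self.res_ids, return_index=True)
        return self.res_ids[np.sort(idx)]

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def residue_name(self, res_id: int) -> str:
        return str(self.res_names[self.res_ids == res_id][0])

    def atom_index(self, res_id: int, atom_name: str) -> int:
        """Index of a named atom in a residue; raises TrajectoryDataError if absent."""
        key = (int(res_id), atom_name)
        cache = self._res_atom_index
        if key not in cache:
            hits = np.flatnonzero((self.res_ids == res_id) & (self.atom_names == atom_name))
            if len(hits) == 0:
                raise TrajectoryDataError(
                    f"residue {res_id} ({self.residue_name(res_id) if np.any(self.res_ids == res_id) else '?'}) "
                    f"has no atom {atom_name!r}")
            cache[key] = int(hits[0])
        return cache[key]

    def has_atom(self, res_id: int, atom_name: str) -> bool:
        try:
            self.atom_index(res_id, atom_name)
            return True
        except TrajectoryDataError:
            return False

    def residue_atom_indices(self, res_id: int) -> np.ndarray:
        return np.flatnonzero(self.res_ids == res_id)

    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[str(e).upper()] for e in self.elements])
        except KeyError as exc:  # pragma: no cover - unusual elements
            raise TrajectoryDataError(f"no mass tabulated for element {exc}") from exc

    def heavy_atom_mask(self) -> np.ndarray:
        return np.array([str(e).upper() != "H" for e in self.elements])

    def slice_frames(self, frame_index) -> "Trajectory":
        idx = np.atleast_1d(np.asarray(frame_index, dtype=int))
        return Trajectory(self.coords[idx], self.atom_names, self.elements,
                          self.res_ids, self.res_names, self.chain_id, self.frame_interval_ns)


# ---- readers -------------------------------------------------------------

def read_structure_ensemble(path, format: str = "pdb-multimodel", topology=None,
                            frame_interval_ns: float = 1.0) -> Trajectory:
    """Read a coordinate ensemble into a :class:`Trajectory`.

    ``format='pdb-multimodel'`` reads a (possibly multi-model) PDB file; each
    MODEL becomes one frame and all models must share atom count and ordering.
    ``format='trajectory+topology'`` delegates to mdtraj (any trajectory format
    it supports, with ``topology`` a structure file) behind the same contract.
    """
    if format == "pdb-multimodel":
        return _read_pdb_multimodel(path, frame_interval_ns)
    if format == "trajectory+topology":
        return _read_mdtraj(path, topology, frame_interval_ns)
    raise ValueError(f"unknown ensemble format {format!r}")


def _read_pdb_multimodel(path, frame_interval_ns: float) -> Trajectory:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    model_count = pdb_file.get_model_count()
    if model_count == 0:
        raise TrajectoryFormatError(f"{path}: no models found (empty file?)")
    # biotite raises on heterogeneous models when stacking; translate the error
    try:
        stack = pdb_file.get_structure(model=None)  # AtomArrayStack
    except Exception as exc:
        # locate the offending model for a useful message
        counts = []
        for m in range(1, model_count + 1):
            counts.append(pdb_file.get_structure(model=m).array_length())
        bad = [m + 1 for m in range(len(counts)) if counts[m] != counts[0]]
        raise TrajectoryFormatError(
            f"{path}: inconsistent atom counts across models "
            f"(model(s) {bad} differ from model 1: {counts})") from exc
    elements = np.array([e if e else infer_element(n)
                         for e, n in zip(stack.element, stack.atom_name)], dtype=object)
    chain_ids = np.unique(stack.chain_id)
    return Trajectory(
        coords=np.asarray(stack.coord, dtype=float) / 10.0,  # Å -> nm
        atom_names=stack.atom_name.astype(object),
        elements=elements,
        res_ids=stack.res_id,
        res_names=stack.res_name.astype(object),
        chain_id=str(chain_ids[0]),
        frame_interval_ns=frame_interval_ns,
    )


def _read_mdtraj(path, topology, frame_interval_ns: float) -> Trajectory:
    try:
        import mdtraj
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading binary trajectories requires mdtraj") from exc
    traj = mdtraj.load(str(path), top=str(topology)) if topology else mdtraj.load(str(path))
    top = traj.topology
    return Trajectory(
        coords=np.asarray(traj.xyz, dtype=float),  # mdtraj is already nm
        atom_names=np.array([a.name for a in top.atoms], dtype=object),
        elements=np.array([a.element.symbol.upper() for a in top.atoms], dtype=object),
        res_ids=np.array([a.residue.resSeq for a in top.atoms]),
        res_names=np.array([a.residue.name for a in top.atoms], dtype=object),
        chain_id="A",
        frame_interval_ns=frame_interval_ns,
    )


def write_pdb(traj: Trajectory, path) -> None:
    """Write a Trajectory as a (multi-model) PDB file via biotite."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = traj.n_atoms
    arrays = []
    for f in range(traj.n_frames):
        arr = struc.AtomArray(n)
        arr.coord = traj.coords[f] * 10.0  # nm -> Å
        arr.atom_name = traj.atom_names.astype("U6")
        arr.element = traj.elements.astype("U2")
        arr.res_id = traj.res_ids
        arr.res_name = traj.res_names.astype("U5")
        arr.chain_id = np.full(n, traj.chain_id, dtype="U4")
        arrays.append(arr)
    stack = struc.stack(arrays)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# ---- superposition and fluctuations --------------------------------------

def superpose_and_rmsf(traj: Trajectory, reference: np.ndarray,
                       atom_selection: np.ndarray | None = None):
    """Superpose every frame onto a reference and report RMSD/RMSF (nm).

    Parameters
    ----------
    traj
        The ensemble to align.
    reference
        Reference coordinates, shape ``(n_atoms, 3)`` in nm.
    atom_selection
        Indices of the atoms used for the fit (typically the Cα set).
        Defaults to all atoms. At least 3 atoms are required.

    Returns
    -------
    aligned : (n_frames, n_atoms, 3) array
    rmsd_per_frame : (n_frames,) array — fit-atom RMSD to the reference
    rmsf_per_atom : (n_atoms,) array — fluctuation about the per-atom mean
        of the aligned frames
    """
    reference = np.asarray(reference, dtype=float)
    if atom_selection is None:
        atom_selection = np.arange(traj.n_atoms)
    sel = np.asarray(atom_selection, dtype=int)
    if len(sel) < 3:
        raise TrajectoryDataError("superposition requires at least 3 selected atoms")
    aligned = np.empty_like(traj.coords)
    rmsd_vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t = geometry.kabsch(traj.coords[f, sel], reference[sel])
        aligned[f] = traj.coords[f] @ R.T + t
        rmsd_vals[f] = geometry.rmsd(aligned[f, sel], reference[sel])
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    return aligned, rmsd_vals, rmsf


def calpha_indices(traj: Trajectory) -> np.ndarray:
    """Indices of the Cα atoms, in residue order."""
    return np.flatnonzero(traj.atom_names == "CA")
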