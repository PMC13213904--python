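"""Alpha-sphere cavity detection and scoring across conformational ensembles.

An alpha-sphere is the circumsphere of a Delaunay tetrahedron of heavy-atom
centers: it touches its four contact atoms and contains no atom center, so
spheres within a radius window probe void regions of the structure. Sphere
centers accumulated over an ensemble are binned on a cubic grid (2 Å cubes);
voxels holding at least ``isovalue`` centers per frame on average are kept
and clustered into cavities (26-connectivity). Cavities are scored by the
voxelized union volume of their spheres and by the mean local hydrophobic
density (total apolar-apolar sphere overlaps divided by the apolar-sphere
count).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
from scipy.spatial import Delaunay, cKDTree

from .trajectory import Trajectory, calpha_indices, superpose_and_rmsf

#: default alpha-sphere radius window (nm) = 3.0-6.0 Å
DEFAULT_R_MIN_NM = 0.30
DEFAULT_R_MAX_NM = 0.60
#: grid spacing (nm) = 2 Å, i.e. 8 A^3 cubes
DEFAULT_SPACING_NM = 0.20
DEFAULT_ISOVALUE = 2.0

APOLAR_ELEMENTS = ("C", "S")


@dataclass
class AlphaSpheres:
    """Alpha spheres of one frame (column arrays)."""

    centers: np.ndarray        # (n, 3) nm
    radii: np.ndarray          # (n,) nm
    contacts: np.ndarray       # (n, 4) atom indices
    apolar: np.ndarray         # (n,) bool

    def __len__(self) -> int:
        return len(self.radii)


def compute_alpha_spheres(coords: np.ndarray, elements,
                          r_min: float = DEFAULT_R_MIN_NM,
                          r_max: float = DEFAULT_R_MAX_NM) -> AlphaSpheres:
    """Alpha spheres of one frame from heavy-atom coordinates.

    ``coords`` is (n_atoms, 3) in nm and ``elements`` the matching element
    symbols; hydrogens are ignored. Spheres are circumspheres of the Delaunay
    tetrahedra, filtered to radii in [r_min, r_max]. A sphere is apolar when
    at least 3 of its 4 contact atoms are carbon or sulfur.
    """
    coords = np.asarray(coords, dtype=float)
    elements = np.asarray([str(e).upper() for e in elements], dtype=object)
    heavy = np.flatnonzero(elements != "H")
    if len(heavy) < 4:
        raise ValueError("need at least 4 heavy atoms")
    pts = coords[heavy]
    try:
        tri = Delaunay(pts)
    except Exception as exc:
        raise ValueError("degenerate (coplanar) atom arrangement") from exc
    simplices = tri.simplices
    tetra = pts[simplices]                         # (m, 4, 3)
    # batched circumsphere solve
    A = 2.0 * (tetra[:, 1:] - tetra[:, :1])
    b = np.sum(tetra[:, 1:] ** 2, axis=2) - np.sum(tetra[:, :1] ** 2, axis=2)
    det = np.abs(np.linalg.det(A))
    ok = det > 1e-12
    centers = np.full((len(tetra), 3), np.nan)
    if ok.any():
        centers[ok] = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
    radii = np.linalg.norm(tetra[:, 0] - centers, axis=1)
    keep = ok & (radii >= r_min) & (radii <= r_max)
    centers, radii = centers[keep], radii[keep]
    contacts_local = simplices[keep]
    contacts = heavy[contacts_local]
    apolar_atoms = np.isin(elements, APOLAR_ELEMENTS)
    apolar = apolar_atoms[contacts].sum(axis=1) >= 3
    return AlphaSpheres(centers=centers, radii=radii, contacts=contacts, apolar=apolar)


def ensemble_alpha_spheres(traj: Trajectory, reference: np.ndarray | None = None,
                           r_min: float = DEFAULT_R_MIN_NM,
                           r_max: float = DEFAULT_R_MAX_NM) -> list:
    """Alpha spheres per frame, after superposing frames to a reference.

    Superposition (on Cα when present, else all atoms) makes sphere centers
    comparable across frames, which the frequency grid requires.
    """
    if reference is not None:
        sel = calpha_indices(traj)
        if len(sel) < 3:
            sel = np.arange(traj.n_atoms)
        aligned, _, _ = superpose_and_rmsf(traj, np.asarray(reference), sel)
    else:
        aligned = traj.coords
    return [compute_alpha_spheres(aligned[f], traj.elements, r_min, r_max)
            for f in range(traj.n_frames)]


# ---- frequency grid -------------------------------------------------------

@dataclass
class CavityMap:
    """Alpha-sphere frequency grid with selected cavity voxels."""

    origin: np.ndarray
    spacing: float
    shape: tuple
    frequency: np.ndarray            # mean sphere centers per frame per voxel
    isovalue: float
    cavities: list                   # list of (n_i, 3) voxel index arrays
    frame_spheres: list = field(default_factory=list, repr=False)

    @property
    def n_cavities(self) -> int:
        return len(self.cavities)

    def cavity_voxel_sets(self) -> list:
        return [set(map(tuple, vox)) for vox in self.cavities]

    def write_opendx(self, path) -> None:
        """Write the frequency grid in OpenDX scalar-field format (Å units)."""
        nx, ny, nz = self.shape
        with open(str(path), "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            ox, oy, oz = self.origin * 10.0
            s = self.spacing * 10.0
            fh.write(f"origin {ox:.4f} {oy:.4f} {oz:.4f}\n")
            fh.write(f"delta {s:.4f} 0 0\ndelta 0 {s:.4f} 0\ndelta 0 0 {s:.4f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
            flat = self.frequency.ravel(order="C")
            for i in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.6f}" for v in flat[i:i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "density" class field\n')


def pocket_frequency_grid(frame_spheres: list, spacing: float = DEFAULT_SPACING_NM,
                          isovalue: float = DEFAULT_ISOVALUE,
                          bounds: tuple | None = None) -> CavityMap:
    """Build the per-voxel mean alpha-sphere-center count and select cavities.

    ``frame_spheres`` is one :class:`AlphaSpheres` per frame. Voxels whose
    mean center count per frame reaches ``isovalue`` are retained and grouped
    into cavities by 26-connectivity. ``bounds`` optionally fixes the grid
    box as ``(lo, hi)`` corner points (nm) so maps are comparable across
    ensembles.
    """
    if len(frame_spheres) == 0:
        raise ValueError("need at least one frame")
    all_centers = [s.centers for s in frame_spheres if len(s)]
    if not all_centers:
        empty = CavityMap(origin=np.zeros(3), spacing=spacing, shape=(0, 0, 0),
                          frequency=np.zeros((0, 0, 0)), isovalue=isovalue,
                          cavities=[], frame_spheres=list(frame_spheres))
        return empty
    stacked = np.vstack(all_centers)
    if bounds is None:
        lo = stacked.min(axis=0) - spacing
        hi = stacked.max(axis=0) + spacing
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    shape = tuple(np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1))
    counts = np.zeros(shape)
    for s in frame_spheres:
        if not len(s):
            continue
        idx = np.floor((s.centers - lo) / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        np.add.at(counts, tuple(idx[inside].T), 1)
    freq = counts / len(frame_spheres)
    mask = freq >= isovalue
    structure = np.ones((3, 3, 3), dtype=bool)   # 26-connectivity
    labeled, n_cav = scipy.ndimage.label(mask, structure=structure)
    cavities = [np.argwhere(labeled == c) for c in range(1, n_cav + 1)]
    # deterministic ordering: largest voxel count first, then lexicographic
    cavities.sort(key=lambda v: (-len(v), tuple(map(tuple, v[:1]))))
    return CavityMap(origin=lo, spacing=spacing, shape=shape, frequency=freq,
                     isovalue=isovalue, cavities=cavities,
                     frame_spheres=list(frame_spheres))


def _spheres_in_voxels(spheres: AlphaSpheres, cavity_voxels: np.ndarray,
                       origin: np.ndarray, spacing: float):
    if not len(spheres):
        return np.zeros(0, dtype=bool)
    idx = np.floor((spheres.centers - origin) / spacing).astype(int)
    vox = set(map(tuple, cavity_voxels))
    return np.array([tuple(i) in vox for i in idx])


def union_volume_A3(centers: np.ndarray, radii: np.ndarray,
                    sample_nm: float = 0.05) -> float:
    """Union volume of spheres (Å^3) by sub-voxel sampling (0.5 Å default)."""
    if len(radii) == 0:
        return 0.0
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    axes = [np.arange(lo[d] + sample_nm / 2, hi[d], sample_nm) for d in range(3)]
    if min(len(a) for a in axes) == 0:
        return 0.0
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(centers)
    inside = np.zeros(len(pts), dtype=bool)
    neighbors = tree.query_ball_point(pts, r=float(radii.max()))
    for k, nb in enumerate(neighbors):
        for j in nb:
            if np.sum((pts[k] - centers[j]) ** 2) <= radii[j] ** 2:
                inside[k] = True
                break
    return float(inside.sum()) * (sample_nm * 10.0) ** 3


def hydrophobic_density(spheres: AlphaSpheres, subset: np.ndarray | None = None) -> float:
    """Mean local hydrophobic density of a sphere set.

    Sum over apolar spheres of their overlapping apolar neighbors, divided by
    the number of apolar spheres (two spheres overlap when their center
    distance is below the sum of their radii). Zero apolar spheres -> 0.
    """
    if subset is not None:
        centers = spheres.centers[subset]
        radii = spheres.radii[subset]
        apolar = spheres.apolar[subset]
    else:
        centers, radii, apolar = spheres.centers, spheres.radii, spheres.apolar
    ap = np.flatnonzero(apolar)
    if len(ap) == 0:
        return 0.0
    c, r = centers[ap], radii[ap]
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
    overlap = d < (r[:, None] + r[None, :])
    np.fill_diagonal(overlap, False)
    return float(overlap.sum()) / len(ap)


def cavity_metrics(cmap: CavityMap, cavity_index: int,
                   sample_nm: float = 0.05) -> pd.Series:
    """Volume (Å^3, mean ± SE over frames) and hydrophobic density of a cavity."""
    vox = cmap.cavities[cavity_index]
    vols, dens = [], []
    for s in cmap.frame_spheres:
        member = _spheres_in_voxels(s, vox, cmap.origin, cmap.spacing)
        if not member.any():
            vols.append(0.0)
            dens.append(0.0)
            continue
        vols.append(union_volume_A3(s.centers[member], s.radii[member], sample_nm))
        dens.append(hydrophobic_density(s, subset=member))
    vols = np.asarray(vols)
    dens = np.asarray(dens)
    n = len(vols)
    return pd.Series({
        "cavity": cavity_index,
        "n_voxels": len(vox),
        "volume_A3_mean": float(vols.mean()),
        "volume_A3_se": float(vols.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "hydrophobic_density_mean": float(dens.mean()),
        "hydrophobic_density_se": float(dens.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
    })


def per_state_cavity_report(state_maps: dict, reference_state,
                            jaccard_min: float = 0.5,
                            sample_nm: float = 0.05) -> pd.DataFrame:
    """Relative cavity volume change and density per state, vs a reference state.

    Cavities are matched across states to the reference state's cavities by
    voxel-set Jaccard overlap (>= ``jaccard_min``); unmatched cavities are
    listed with ``matched=False`` rather than dropped. Relative change is
    ``(V_state - V_ref) / V_ref``. All maps must share grid origin/spacing
    (pass explicit ``bounds`` to :func:`pocket_frequency_grid`).
    """
    if reference_state not in state_maps:
        raise ValueError(f"reference state {reference_state!r} missing")
    ref_map = state_maps[reference_state]
    ref_sets = ref_map.cavity_voxel_sets()
    ref_metrics = [cavity_metrics(ref_map, k, sample_nm) for k in range(ref_map.n_cavities)]
    rows = []
    for state, cmap in state_maps.items():
        if not np.allclose(cmap.origin, ref_map.origin) or cmap.spacing != ref_map.spacing:
            raise ValueError("all maps must share grid origin and spacing")
        for k in range(cmap.n_cavities):
            vox = set(map(tuple, cmap.cavities[k]))
            best, best_j = None, 0.0
            for rk, rset in enumerate(ref_sets):
                j = len(vox & rset) / len(vox | rset)
                if j > best_j:
                    best, best_j = rk, j
            m = cavity_metrics(cmap, k, sample_nm)
            row = {"state": state, "cavity": k, "jaccard": best_j,
                   "volume_A3_mean": m["volume_A3_mean"], "volume_A3_se": m["volume_A3_se"],
                   "hydrophobic_density_mean": m["hydrophobic_density_mean"],
                   "hydrophobic_density_se": m["hydrophobic_density_se"]}
            if best is not None and best_j >= jaccard_min:
                v_ref = ref_metrics[best]["volume_A3_mean"]
                row.update(matched=True, reference_cavity=best,
                           relative_volume_change=(m["volume_A3_mean"] - v_ref) / v_ref
                           if v_ref > 0 else np.nan)
            else:
                row.update(matched=False, reference_cavity=-1,
                           relative_volume_change=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def write_spheres_pdb(spheres: AlphaSpheres, path) -> None:
    """Write alpha spheres as PDB pseudo-atoms with the radius (Å) as B-factor."""
    with open(str(path), "w") as fh:
        for k in range(len(spheres)):
            x, y, z = spheres.centers[k] * 10.0
            r = spheres.radii[k] * 10.0
            name = "APS" if spheres.apolar[k] else "POS"
            fh.write(f"ATOM  {k + 1:5d}  C   {name} A{k + 1:4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{r:6.2f}           C\n")
        fh.write("END\n")
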