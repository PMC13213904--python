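"""Per-macrostate structural characterization.

Frames are assigned to macrostates by argmax membership of their microstate;
per-state ensembles are then summarized: secondary-structure probabilities
from a reduced, H-bond-based assignment (geometric criteria: H...O distance
0.15-0.40 nm, N-H...O angle at the hydrogen 100-180 degrees), RMSF after
superposition to a reference, mass-weighted radius of gyration, normalized
descriptor histograms, and named pair-distance reports.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .features import DescriptorRegistry, compute_features
from .msm import MacrostateModel, assign_macro_dtrajs
from .trajectory import Trajectory, calpha_indices, superpose_and_rmsf


@dataclass
class HBondCriteria:
    """Geometric backbone H-bond definition (N-H...O=C).

    A bond requires the H...O distance inside ``d_ho_nm`` and the N-H...O
    angle, measured at the hydrogen, inside ``angle_nho_deg``.
    """

    d_ho_nm: tuple = (0.15, 0.40)
    angle_nho_deg: tuple = (100.0, 180.0)


def assign_macrostates(model: MacrostateModel, dtrajs):
    """Per-frame macrostate labels (argmax membership; -1 = unassigned).

    Frames whose microstate is outside the model's active set are labeled -1
    and the unassigned fraction is reported alongside the labels.
    """
    labels = assign_macro_dtrajs(model, dtrajs)
    total = sum(len(l) for l in labels)
    unassigned = sum(int(np.sum(l < 0)) for l in labels)
    return labels, unassigned / total if total else 0.0


# ---- hydrogen bonds -------------------------------------------------------

def _backbone_table(traj: Trajectory, frame: int):
    """Per-residue backbone coordinates (N, H, CA, C, O); H built if absent.

    Amide hydrogens are constructed at 0.101 nm along the direction opposed
    to the bisector of the N->C(prev) and N->CA bonds when missing; prolines
    and the N-terminal residue have no amide H (donor skipped).
    """
    res = [int(r) for r in traj.residue_ids]
    X = traj.coords[frame]
    rows = {}
    prev_c = None
    for k, r in enumerate(res):
        entry = {}
        for name in ("N", "CA", "C", "O"):
            if traj.has_atom(r, name):
                entry[name] = X[traj.atom_index(r, name)]
        if "N" not in entry or "O" not in entry:
            warnings.warn(f"residue {r}: missing backbone N or O, skipped")
            prev_c = entry.get("C")
            continue
        if traj.has_atom(r, "H"):
            entry["H"] = X[traj.atom_index(r, "H")]
        elif (traj.residue_name(r) != "PRO" and k > 0 and prev_c is not None
              and "CA" in entry):
            u1 = prev_c - entry["N"]
            u2 = entry["CA"] - entry["N"]
            d = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
            entry["H"] = entry["N"] + 0.101 * d / np.linalg.norm(d)
        rows[r] = entry
        prev_c = entry.get("C")
    return rows


def detect_hbonds(traj: Trajectory, frame: int = 0,
                  criteria: HBondCriteria = HBondCriteria()) -> pd.DataFrame:
    """Backbone N-H...O=C hydrogen bonds in one frame.

    Returns a table with donor residue, acceptor residue, d(H,O) in nm and
    the N-H...O angle in degrees. Sequence-adjacent pairs (|i - j| < 2) are
    excluded (their geometry is fixed by the peptide bond).
    """
    table = _backbone_table(traj, frame)
    donors = [(r, e) for r, e in table.items() if "H" in e]
    acceptors = [(r, e) for r, e in table.items() if "O" in e]
    if not donors or not acceptors:
        return pd.DataFrame(columns=["donor", "acceptor", "d_ho_nm", "angle_deg"])
    H = np.array([e["H"] for _, e in donors])
    N = np.array([e["N"] for _, e in donors])
    O = np.array([e["O"] for _, e in acceptors])
    don_ids = np.array([r for r, _ in donors])
    acc_ids = np.array([r for r, _ in acceptors])
    d = np.linalg.norm(H[:, None, :] - O[None, :, :], axis=2)
    lo, hi = criteria.d_ho_nm
    sep_ok = np.abs(don_ids[:, None] - acc_ids[None, :]) >= 2
    cand = (d >= lo) & (d <= hi) & sep_ok
    rows = []
    for i, j in zip(*np.nonzero(cand)):
        ang = float(geometry.angle_at(H[i], N[i], O[j]))
        alo, ahi = criteria.angle_nho_deg
        if alo <= ang <= ahi:
            rows.append({"donor": int(don_ids[i]), "acceptor": int(acc_ids[j]),
                         "d_ho_nm": float(d[i, j]), "angle_deg": ang})
    return pd.DataFrame(rows, columns=["donor", "acceptor", "d_ho_nm", "angle_deg"])


# ---- secondary structure --------------------------------------------------

def assign_secondary_structure(traj: Trajectory, frame: int = 0,
                               criteria: HBondCriteria = HBondCriteria()) -> dict:
    """Reduced three-state secondary structure per residue: H, E, or C.

    Helix (H): residues covered by runs of at least two consecutive
    i -> i+4 backbone H-bonds (acceptor i, donor i+4). Strand (E): residues
    participating in a ladder of at least two H-bonds between segments at
    least 3 residues apart in sequence (neighboring bonds within +-1 on both
    sides belong to the same ladder). Everything else is coil (C); helix
    takes precedence.
    """
    res = [int(r) for r in traj.residue_ids]
    labels = {r: "C" for r in res}
    hb = detect_hbonds(traj, frame, criteria)
    if len(hb) == 0:
        return labels
    bonds = set(zip(hb["donor"], hb["acceptor"]))
    # helix: acceptor i with donor i+4, two consecutive
    turn = {a for d, a in bonds if d - a == 4}
    for i in sorted(turn):
        if i + 1 in turn:
            for r in range(i + 1, i + 6):
                if r in labels:
                    labels[r] = "H"
    # strands: long-range bonds grouped into ladders
    long_pairs = sorted({(min(d, a), max(d, a)) for d, a in bonds if abs(d - a) >= 3})
    n = len(long_pairs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (a1, b1), (a2, b2) = long_pairs[i], long_pairs[j]
            if abs(a1 - a2) <= 1 and abs(b1 - b2) <= 1:
                parent[find(i)] = find(j)
    ladders = {}
    for i in range(n):
        ladders.setdefault(find(i), []).append(long_pairs[i])
    for members in ladders.values():
        if len(members) >= 2:
            for a, b in members:
                for r in (a, b):
                    if labels.get(r) == "C":
                        labels[r] = "E"
    return labels


# ---- per-state summaries --------------------------------------------------

@dataclass
class StateSummary:
    """Structural summary of one macrostate's frame ensemble."""

    state: int
    n_frames: int
    ss_probs: pd.DataFrame              # per residue: P_H, P_E, P_C
    rmsf_nm: np.ndarray                 # per atom
    rmsd_nm: np.ndarray                 # per frame, fit-atom RMSD to reference
    radius_of_gyration_nm: tuple        # (mean, sd)
    descriptor_histograms: dict = field(default_factory=dict)
    named_distances: pd.DataFrame | None = None


def radius_of_gyration(traj: Trajectory) -> np.ndarray:
    """Mass-weighted radius of gyration per frame (nm)."""
    m = traj.masses()
    com = np.einsum("fas,a->fs", traj.coords, m) / m.sum()
    d2 = np.sum((traj.coords - com[:, None, :]) ** 2, axis=2)
    return np.sqrt(np.einsum("fa,a->f", d2, m) / m.sum())


def per_state_summary(traj: Trajectory, frame_labels: np.ndarray, reference: np.ndarray,
                      registry: DescriptorRegistry | None = None,
                      named_ca_pairs: dict | None = None,
                      criteria: HBondCriteria = HBondCriteria(),
                      n_hist_bins: int = 50) -> dict:
    """Structural summaries per macrostate.

    Parameters
    ----------
    traj
        The full ensemble (frames of all states).
    frame_labels
        Per-frame macrostate label; negative labels are excluded.
    reference
        Reference coordinates (n_atoms, 3) for superposition.
    registry
        Optional descriptor registry; per-state normalized histograms of each
        descriptor are reported.
    named_ca_pairs
        Optional mapping name -> (res_i, res_j); per-state Cα distance mean,
        SD, and SE are reported (e.g. a reporter-residue pair distance).

    Returns ``{state: StateSummary}``; empty states are omitted with a warning.
    """
    frame_labels = np.asarray(frame_labels)
    if len(frame_labels) != traj.n_frames:
        raise ValueError("one label per frame required")
    ca = calpha_indices(traj)
    states = sorted(int(s) for s in np.unique(frame_labels) if s >= 0)
    out = {}
    res_ids = [int(r) for r in traj.residue_ids]
    for s in states:
        idx = np.flatnonzero(frame_labels == s)
        if len(idx) == 0:
            warnings.warn(f"state {s}: no frames, omitted")
            continue
        sub = traj.slice_frames(idx)
        _, rmsd_vals, rmsf = superpose_and_rmsf(sub, reference, ca)
        # secondary structure frequencies over frames
        counts = {r: {"H": 0, "E": 0, "C": 0} for r in res_ids}
        for f in range(sub.n_frames):
            lab = assign_secondary_structure(sub, f, criteria)
            for r, l in lab.items():
                counts[r][l] += 1
        ss = pd.DataFrame({
            "residue": res_ids,
            "P_H": [counts[r]["H"] / sub.n_frames for r in res_ids],
            "P_E": [counts[r]["E"] / sub.n_frames for r in res_ids],
            "P_C": [counts[r]["C"] / sub.n_frames for r in res_ids],
        })
        rg = radius_of_gyration(sub)
        hists = {}
        if registry is not None and registry.size > 0:
            fm = compute_features(sub, registry)
            for k, lab_name in enumerate(fm.labels):
                dens, edges = np.histogram(fm.values[:, k], bins=n_hist_bins, density=True)
                hists[lab_name] = (dens, edges)
        named = None
        if named_ca_pairs:
            rows = []
            for name, (ri, rj) in named_ca_pairs.items():
                d = np.linalg.norm(
                    sub.coords[:, traj.atom_index(ri, "CA")]
                    - sub.coords[:, traj.atom_index(rj, "CA")], axis=1)
                rows.append({"name": name, "mean_nm": float(d.mean()),
                             "sd_nm": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
                             "se_nm": float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0})
            named = pd.DataFrame(rows)
        out[s] = StateSummary(
            state=s, n_frames=len(idx), ss_probs=ss, rmsf_nm=rmsf, rmsd_nm=rmsd_vals,
            radius_of_gyration_nm=(float(rg.mean()),
                                   float(rg.std(ddof=1)) if len(rg) > 1 else 0.0),
            descriptor_histograms=hists, named_distances=named)
    return out


def medoid_frame(traj: Trajectory, frame_indices: np.ndarray,
                 registry: DescriptorRegistry) -> int:
    """Representative (medoid) frame of a state in descriptor space."""
    sub = traj.slice_frames(frame_indices)
    fm = compute_features(sub, registry)
    X = (fm.values - fm.values.mean(axis=0)) / np.maximum(fm.values.std(axis=0), 1e-12)
    d = np.linalg.norm(X - X.mean(axis=0), axis=1)
    return int(np.asarray(frame_indices)[np.argmin(d)])
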