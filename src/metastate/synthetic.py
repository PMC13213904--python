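"""Ground-truth synthetic data: hidden-chain feature trajectories and toy structures.

The generator emulates the situation the analysis pipeline is built for: a
single protein domain whose slow dynamics interconvert six metastable
conformations — a dominant closed pair, a short-lived hub intermediate, and
three sparsely populated open states reachable only through the hub. Feature
trajectories are emitted by a reversible hidden Markov chain with known
stationary distribution and known kinetics, so every downstream stage
(TICA, discretization, MSM/macrostate estimation, TPT, state assignment) can
be scored against exact ground truth. Toy 3-D structures (ideal helix,
antiparallel hairpin, extended chain, a 78-residue chain, a hollow cavity
shell) exercise the structure-facing stages.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import markov
from .features import FeatureMatrix
from .trajectory import HYDROPHOBIC_RESIDUES, Trajectory

#: canonical state ordering of the default six-state chain
STATE_NAMES = ("closed-major", "closed-minor", "hub",
               "open-terminal", "open-bridge", "open-leaf")

#: default stationary distribution: dominant closed pair 62% / 24%, hub 5%,
#: open states 4% / 3% / 2% (minor states inside the 2-5% band)
DEFAULT_PI = (0.62, 0.24, 0.05, 0.04, 0.03, 0.02)

#: hub-mediated exchange topology: closed pair <-> hub <-> three open states,
#: with the open states interconnecting through the bridge state. Values are
#: per-step exchange rate prefactors a_ij (symmetric flux S_ij = a_ij *
#: min(pi_i, pi_j)); they set the kinetic hierarchy: closed<->closed fast,
#: closed<->hub intermediate, hub<->open slow.
DEFAULT_EDGE_RATES = {
    (0, 1): 2e-3,
    (0, 2): 4e-4,
    (1, 2): 4e-4,
    (2, 3): 1e-4,
    (2, 4): 1e-4,
    (2, 5): 1e-4,
    (3, 4): 2e-4,
    (4, 5): 2e-4,
}

#: default per-step time unit (ns); 2e5 steps ~ 20 us per trajectory
DEFAULT_STEP_NS = 0.1


@dataclass
class GroundTruthChain:
    """Reversible hidden chain with analytically known stationary law and kinetics."""

    T: np.ndarray
    pi: np.ndarray
    step_ns: float
    state_names: tuple = STATE_NAMES

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def mfpt_steps(self, A, B) -> float:
        """Analytic mean first-passage time in steps (linear solve)."""
        return markov.mean_first_passage_time(self.T, A, B)

    def mfpt_ns(self, A, B) -> float:
        return self.mfpt_steps(A, B) * self.step_ns

    def lifetimes_ns(self) -> np.ndarray:
        """Geometric mean dwell time per state, in ns."""
        return self.step_ns / (1.0 - np.diag(self.T))

    def relaxation_timescales_ns(self) -> np.ndarray:
        return markov.relaxation_timescales(self.T, self.step_ns)


def build_ground_truth_chain(pi=DEFAULT_PI, topology=None, step_ns: float = DEFAULT_STEP_NS,
                             mfpt_calibration=None) -> GroundTruthChain:
    """Construct the reversible ground-truth chain.

    The transition matrix is built from symmetric exchange fluxes
    ``S_ij = a_ij * min(pi_i, pi_j)`` on the topology edges, which enforces
    detailed balance with respect to ``pi`` exactly; diagonals absorb the
    remainder.

    Parameters
    ----------
    pi
        Target stationary distribution (positive, sums to 1).
    topology
        Mapping ``(i, j) -> a_ij`` of edge rate prefactors; defaults to the
        hub-mediated six-state topology.
    step_ns
        Physical time per chain step (ns).
    mfpt_calibration
        Optional ``(source, sink, target_ns)``: after construction, ``step_ns``
        is rescaled so the analytic MFPT from source to sink equals
        ``target_ns`` exactly. Source/sink may be ints or state names.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError("pi must be positive and sum to 1")
    n = len(pi)
    if topology is None:
        if n != 6:
            raise ValueError("default topology is defined for 6 states")
        topology = DEFAULT_EDGE_RATES
    T = np.zeros((n, n))
    for (i, j), a in topology.items():
        if i == j:
            raise ValueError("topology edges must join distinct states")
        s = a * min(pi[i], pi[j])
        T[i, j] += s / pi[i]
        T[j, i] += s / pi[j]
    diag = 1.0 - T.sum(axis=1)
    if np.any(diag < 0):
        raise ValueError("edge rates too large: negative diagonal")
    T[np.diag_indices(n)] = diag
    # irreducibility check: every state reachable from state 0
    reach = np.linalg.matrix_power((T > 0).astype(float) + np.eye(n), n) > 0
    if not np.all(reach[0]):
        raise ValueError("topology does not connect all states")
    names = STATE_NAMES if n == len(STATE_NAMES) else tuple(f"state-{k}" for k in range(n))
    chain = GroundTruthChain(T=T, pi=pi, step_ns=float(step_ns), state_names=names)
    if mfpt_calibration is not None:
        src, sink, target_ns = mfpt_calibration
        src = _resolve_state(chain, src)
        sink = _resolve_state(chain, sink)
        steps = chain.mfpt_steps([src], [sink])
        if not np.isfinite(steps) or steps <= 0:
            raise ValueError("cannot calibrate: sink unreachable from source")
        chain.step_ns = float(target_ns) / steps
    return chain


def _resolve_state(chain: GroundTruthChain, state) -> int:
    if isinstance(state, str):
        return chain.state_names.index(state)
    return int(state)


# ---- emissions ------------------------------------------------------------

@dataclass
class EmissionModel:
    """Per-state diagonal Gaussian emissions in descriptor space."""

    means: np.ndarray   # (n_states, n_features)
    sds: np.ndarray     # (n_states, n_features), positive

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        if self.sds.shape != self.means.shape:
            raise ValueError("means and sds must have identical shape")
        if np.any(self.sds <= 0):
            raise ValueError("emission sds must be positive")
        if len(np.unique(self.means, axis=0)) != self.means.shape[0]:
            raise ValueError("state means must be distinct")

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def default_emission_model(n_states: int = 6, n_features: int = 18,
                           separation: float = 4.0, n_noise_features: int = 0) -> EmissionModel:
    """Deterministic default emissions: each state displaces a distinct block
    of descriptors by ``separation`` standard deviations; optional pure-noise
    columns carry no state information.

    The default separation keeps states cleanly resolvable by k-means
    discretization: overlapping emissions make cluster boundaries flicker
    between states, which injects spurious fast transitions and biases
    recovered kinetics toward shorter passage times. Lowering ``separation``
    is the intended way to study exactly that degradation.
    """
    total = n_features + n_noise_features
    means = np.zeros((n_states, total))
    block = max(1, n_features // n_states)
    for s in range(n_states):
        lo = (s * block) % n_features
        means[s, lo:min(lo + block, n_features)] = separation
        # a secondary signature keeps states distinct even if blocks collide
        means[s, s % n_features] += 0.5 * separation
    sds = np.ones((n_states, total))
    return EmissionModel(means=means, sds=sds)


# ---- sampling -------------------------------------------------------------

def sample_hidden_path(chain: GroundTruthChain, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a hidden state path of length ``n_steps``, started from pi.

    Uses geometric dwell-time sampling (exactly equivalent in law to per-step
    sampling, O(number of jumps) instead of O(n_steps))."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    T = chain.T
    n = chain.n_states
    labels = np.empty(n_steps, dtype=np.int64)
    state = int(rng.choice(n, p=chain.pi))
    t = 0
    while t < n_steps:
        p_leave = 1.0 - T[state, state]
        if p_leave <= 0:
            dwell = n_steps - t
        else:
            dwell = int(rng.geometric(p_leave))
        dwell = min(dwell, n_steps - t)
        labels[t:t + dwell] = state
        t += dwell
        if t < n_steps:
            jump_p = T[state].copy()
            jump_p[state] = 0.0
            jump_p /= jump_p.sum()
            state = int(rng.choice(n, p=jump_p))
    return labels


def sample_observations(chain: GroundTruthChain, emissions: EmissionModel, n_steps: int,
                        rng: np.random.Generator, dtype=np.float64):
    """One trajectory: (observations (n_steps, n_features), hidden labels)."""
    labels = sample_hidden_path(chain, n_steps, rng)
    X = rng.standard_normal((n_steps, emissions.n_features)).astype(dtype, copy=False)
    X *= emissions.sds[labels].astype(dtype, copy=False)
    X += emissions.means[labels].astype(dtype, copy=False)
    return X, labels


def trajectory_seeds(seed: int, n_traj: int) -> list:
    """Independent child seeds for each trajectory, derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_traj)]


def sample_feature_trajectories(chain: GroundTruthChain, emissions: EmissionModel,
                                n_traj: int, n_steps: int, seed: int):
    """Sample ``n_traj`` feature trajectories plus their hidden label paths.

    Returns ``(list of FeatureMatrix, list of int arrays)``; fully determined
    by ``seed``.
    """
    rngs = trajectory_seeds(seed, n_traj)
    mats, labels = [], []
    feat_labels = [f"synth_feat_{k}" for k in range(emissions.n_features)]
    units = ["dimensionless"] * emissions.n_features
    for rng in rngs:
        X, lab = sample_observations(chain, emissions, n_steps, rng)
        mats.append(FeatureMatrix(X, list(feat_labels), list(units), chain.step_ns))
        labels.append(lab)
    return mats, labels


# ---- structure fixtures ---------------------------------------------------

# idealized backbone internal coordinates (nm / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H, _B_CA_CB = 0.1458, 0.1525, 0.1329, 0.1231, 0.101, 0.153
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8

_HYDRO_CYCLE = ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO")
_POLAR_CYCLE = ("GLY", "SER", "ASP", "LYS", "ASN", "GLU", "THR", "ARG", "GLN", "HIS", "TYR")

# planar ring templates in local 2-D coordinates (nm); first atom sits at the
# attachment origin
_RING_TEMPLATES = {
    "PHE": [("CG", 0.0, 0.0), ("CD1", 0.0695, 0.1204), ("CD2", 0.0695, -0.1204),
            ("CE1", 0.2085, 0.1204), ("CE2", 0.2085, -0.1204), ("CZ", 0.278, 0.0)],
    "TYR": [("CG", 0.0, 0.0), ("CD1", 0.0695, 0.1204), ("CD2", 0.0695, -0.1204),
            ("CE1", 0.2085, 0.1204), ("CE2", 0.2085, -0.1204), ("CZ", 0.278, 0.0)],
    "HIS": [("CG", 0.0, 0.0), ("ND1", 0.035, 0.131), ("CD2", 0.109, -0.084),
            ("CE1", 0.171, 0.083), ("NE2", 0.218, -0.047)],
    "TRP": [("CG", 0.0, 0.0), ("CD1", 0.080, 0.110), ("NE1", 0.210, 0.090),
            ("CE2", 0.225, -0.045), ("CD2", 0.105, -0.110), ("CE3", 0.095, -0.250),
            ("CZ3", 0.210, -0.325), ("CH2", 0.330, -0.260), ("CZ2", 0.340, -0.120)],
}


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d), torsion(a,b,c,d)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d2 = np.array([-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor),
                   bond * np.sin(ang) * np.sin(tor)])
    M = np.column_stack([bc, m, n])
    return c + M @ d2


def _amide_h(c_prev, n_pos, ca_pos) -> np.ndarray:
    """Amide H on the bisector-opposed direction, 0.101 nm from N."""
    u1 = (c_prev - n_pos) / np.linalg.norm(c_prev - n_pos)
    u2 = (ca_pos - n_pos) / np.linalg.norm(ca_pos - n_pos)
    d = -(u1 + u2)
    d /= np.linalg.norm(d)
    return n_pos + _B_N_H * d


def _build_backbone(phi, psi, omega: float = 180.0):
    """Backbone N/CA/C positions for given per-residue phi/psi (degrees)."""
    n = len(phi)
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1]))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega))
        C.append(place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i]))
    return N, CA, C


def _assemble_chain(res_names, phi, psi, with_sidechains: bool = True,
                    start_id: int = 1) -> Trajectory:
    N, CA, C = _build_backbone(phi, psi)
    n = len(res_names)
    names, elements, rids, rnames, coords = [], [], [], [], []

    def add(rid, rname, aname, elem, pos):
        names.append(aname)
        elements.append(elem)
        rids.append(rid)
        rnames.append(rname)
        coords.append(pos)

    for i, rname in enumerate(res_names):
        rid = i + start_id
        add(rid, rname, "N", "N", N[i])
        if i > 0 and rname != "PRO":
            add(rid, rname, "H", "H", _amide_h(C[i - 1], N[i], CA[i]))
        add(rid, rname, "CA", "C", CA[i])
        add(rid, rname, "C", "C", C[i])
        psi_o = psi[i] if i < n - 1 else 180.0
        add(rid, rname, "O", "O", place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi_o + 180.0))
        if with_sidechains and rname != "GLY":
            cb = place_atom(C[i], N[i], CA[i], _B_CA_CB, 110.5, 122.5)
            add(rid, rname, "CB", "C", cb)
            if rname in _RING_TEMPLATES:
                cg = cb + 0.15 * _unit(cb - CA[i])
                e1 = _unit(cg - cb)
                e2 = _unit(np.cross(e1, _unit(CA[i] - N[i]) + np.array([0.11, 0.07, 0.31])))
                for aname, x, y in _RING_TEMPLATES[rname]:
                    elem = "N" if aname.startswith("N") else "C"
                    add(rid, rname, aname, elem, cg + x * e1 + y * e2)
    return Trajectory(np.asarray(coords)[None, :, :], names, elements, rids, rnames)


def _unit(v):
    return v / np.linalg.norm(v)


#: first residue id of the 78-residue fixture; the numbering covers the
#: residue ids referenced by the curated RRM descriptor registry (77-138)
CHAIN78_START_ID = 64


def _chain78_sequence() -> list:
    """78 residue names with exactly 43 hydrophobic-class members.

    Residues 92 (PHE) and 134 (TRP) are pinned so the fixture supports the
    curated registry's aromatic ring pair; the interleaving pattern is then
    rebalanced to keep the hydrophobic count at exactly 43.
    """
    seq, h, p = [], 0, 0
    for i in range(78):
        if (i * 43) // 78 != ((i + 1) * 43) // 78:
            seq.append(_HYDRO_CYCLE[h % len(_HYDRO_CYCLE)])
            h += 1
        else:
            seq.append(_POLAR_CYCLE[p % len(_POLAR_CYCLE)])
            p += 1
    pinned = {92 - CHAIN78_START_ID: "PHE", 134 - CHAIN78_START_ID: "TRP"}
    for idx, name in pinned.items():
        seq[idx] = name
    count = sum(r in HYDROPHOBIC_RESIDUES for r in seq)
    for idx in range(77, -1, -1):
        if count == 43:
            break
        if idx in pinned:
            continue
        if count > 43 and seq[idx] in HYDROPHOBIC_RESIDUES:
            seq[idx] = "SER"
            count -= 1
        elif count < 43 and seq[idx] not in HYDROPHOBIC_RESIDUES:
            seq[idx] = "ALA"
            count += 1
    assert sum(r in HYDROPHOBIC_RESIDUES for r in seq) == 43
    return seq


def _build_hairpin(n_per_strand: int = 6) -> Trajectory:
    """Synthetic antiparallel beta-hairpin with exact cross-strand H-bond geometry.

    Backbone atoms are placed directly (not from torsions) so that every
    strand residue forms the canonical N-H...O=C pair with its partner at
    d(H,O) = 0.20 nm and a straight N-H...O angle.
    """
    m = n_per_strand
    names, elements, rids, rnames, coords = [], [], [], [], []

    def add(rid, aname, elem, pos):
        names.append(aname)
        elements.append(elem)
        rids.append(rid)
        rnames.append("VAL" if aname != "X" else "GLY")
        coords.append(np.asarray(pos, dtype=float))

    spacing, y_b = 0.35, 0.424
    for i in range(m):  # strand A, residues 1..m, running +x
        rid, x = i + 1, i * spacing
        add(rid, "N", "N", (x, 0.0, 0.0))
        add(rid, "H", "H", (x, _B_N_H, 0.0))
        add(rid, "CA", "C", (x + 0.115, -0.09, 0.0))
        add(rid, "C", "C", (x + 0.23, 0.0, 0.0))
        add(rid, "O", "O", (x + 0.23, 0.123, 0.0))
    x_turn = (m - 1) * spacing + 0.55
    for k in range(2):  # turn residues m+1, m+2 (no H-bond partners)
        rid = m + 1 + k
        base = np.array([x_turn, 0.10 + 0.22 * k, 0.10 - 0.20 * k])
        add(rid, "N", "N", base)
        add(rid, "H", "H", base + (0.0, -0.101, 0.0))
        add(rid, "CA", "C", base + (0.05, 0.05, 0.0))
        add(rid, "C", "C", base + (0.10, 0.0, 0.0))
        add(rid, "O", "O", base + (0.10, 0.123, 0.0))
    for l in range(m):  # strand B, residues m+3..2m+2, running -x at y = y_b
        rid = m + 3 + l
        partner = m - 1 - l          # strand-A index paired with this residue
        x = partner * spacing + 0.23
        add(rid, "N", "N", (x, y_b, 0.0))
        add(rid, "H", "H", (x, y_b - _B_N_H, 0.0))
        add(rid, "CA", "C", (x - 0.115, y_b + 0.09, 0.0))
        add(rid, "C", "C", (x - 0.23, y_b, 0.0))
        add(rid, "O", "O", (x - 0.23, y_b - 0.123, 0.0))
    return Trajectory(np.asarray(coords)[None, :, :], names, elements, rids,
                      ["VAL"] * len(names))


def _build_cavity_shell(radius_nm: float = 0.8, spacing_nm: float = 0.22,
                        jitter_nm: float = 0.06, seed: int = 0) -> Trajectory:
    """Hollow shell of carbon atoms on a (jittered) sphere of the given radius."""
    n_pts = max(16, int(np.ceil(4.0 * np.pi * radius_nm ** 2 / spacing_nm ** 2)))
    k = np.arange(n_pts)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n_pts
    r_xy = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    theta = golden * k
    pts = np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
    rng = np.random.default_rng(seed)
    radii = radius_nm + rng.uniform(-jitter_nm, jitter_nm, n_pts)
    coords = pts * radii[:, None]
    return Trajectory(coords[None, :, :], ["C"] * n_pts, ["C"] * n_pts,
                      np.arange(1, n_pts + 1), ["SHL"] * n_pts)


def build_structure_fixtures(kind: str, **params) -> Trajectory:
    """Build a synthetic single-frame structure fixture.

    ``kind`` is one of:

    ``'helix'``
        Ideal alpha-helix (phi = -57, psi = -47), default 16 ALA residues.
    ``'hairpin'``
        Antiparallel beta-hairpin with exact cross-strand H-bond geometry.
    ``'extended'``
        Fully extended chain (phi = psi = 180), no internal H-bonds.
    ``'chain78'``
        78-residue chain with full backbone and side-chain placeholder atoms,
        containing exactly 43 hydrophobic-class residues (including aromatics
        with complete ring heavy atoms).
    ``'cavity_shell'``
        Hollow shell of carbon atoms on a sphere of radius ``radius_nm``.
    """
    if kind == "helix":
        n = int(params.get("n_residues", 16))
        return _assemble_chain(["ALA"] * n, [-57.0] * n, [-47.0] * n)
    if kind == "hairpin":
        return _build_hairpin(int(params.get("n_per_strand", 6)))
    if kind == "extended":
        n = int(params.get("n_residues", 12))
        return _assemble_chain(["ALA"] * n, [180.0] * n, [180.0] * n)
    if kind == "chain78":
        seq = _chain78_sequence()
        return _assemble_chain(seq, [-120.0] * 78, [140.0] * 78,
                               start_id=CHAIN78_START_ID)
    if kind == "cavity_shell":
        return _build_cavity_shell(
            float(params.get("radius_nm", 0.8)),
            float(params.get("spacing_nm", 0.22)),
            float(params.get("jitter_nm", 0.06)),
            int(params.get("seed", 0)))
    raise ValueError(f"unknown fixture kind {kind!r}")
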