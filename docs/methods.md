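# Methods

`metastate` turns coordinate ensembles of a single protein chain into a
validated kinetic model of its conformational landscape, and scores the
cryptic cavities that open in rarely visited states. This note documents the
models and procedures, the numerical choices behind them, what the synthetic
generator does and does not emulate, and the known limitations.

## Featurization

A `Trajectory` stores frames of atom coordinates in nanometres (PDB Ångström
input is converted on read) with per-atom metadata. Descriptors are declared
in a `DescriptorRegistry` and evaluated into a frames × descriptors
`FeatureMatrix`:

- **Side-chain COM distances** (nm). The center of mass uses heavy atoms
  from Cβ outward with standard atomic masses; glycine falls back to Cα.
  This convention makes exhaustive enumeration well defined for every
  residue: a 78-residue chain yields C(78,2) = 3003 pair distances, and a
  43-member hydrophobic subset (default class {ALA, VAL, LEU, ILE, MET, PHE,
  TRP, PRO}, configurable) yields C(43,2) = 903.
- **Cα–Cα distances** (nm).
- **Backbone φ/ψ torsions**, always encoded as (cos, sin) pairs so angular
  periodicity never enters downstream linear algebra: 4(n−1) columns for an
  n-residue chain (308 for n = 78).
- **Cα four-residue dihedrals** (degrees, (−180°, 180°]), e.g. an
  inter-helix reorientation coordinate, and **aromatic ring-plane angles**:
  the acute angle between least-squares planes fitted to all ring heavy
  atoms (6 for PHE/TYR, 5 for HIS, 9 for the TRP bicycle), folded to
  [0°, 90°]. The least-squares fit is orientation-stable and invariant to
  ring-atom ordering.

Superposition uses the Kabsch SVD solution (proper rotations only); RMSF is
computed about the per-atom mean of the aligned frames.

## Slow modes, feature ranking, and representation scoring

**TICA.** Reversible TICA solves the generalized eigenproblem
`C(τ) v = λ C(0) v` with mean-free data, symmetrized covariances
(`C ← (C + Cᵀ)/2` accumulated over forward and reversed time pairs) and a
ridge of 1e−6 on `C(0)`. Zero-variance columns are dropped with a warning.
Eigenvalues are clipped to [−1, 1]; implied timescales are `−τ/ln λ` for
λ ∈ (0, 1). Components are sign-fixed so the largest-|loading| feature of
each component is positive, making downstream correlation signs
reproducible.

**Feature ranking.** Features are ranked by |Pearson correlation| with the
IC projections (by default the first six; a subset such as {1, 2, 5, 6} can
be requested when some ICs are dominated by terminal fluctuations).
Candidate and strong flags are set at |r| ≥ 0.45 and |r| ≥ 0.70. Ranking by
absolute correlation is a deliberate choice; the sign carries no selection
information here.

**Pruning.** Residue-pair candidates are filtered in a fixed order: pairs
with either residue within 3 residues of the chain termini, then pairs with
|i−j| ≤ 4 (both windows configurable), and finally a greedy redundancy pass
in descending |r| (ties: lexicographically smaller pair) in which a pair is
kept only if no retained pair lies within its 3×3 index neighborhood.
Pruning is deterministic and idempotent.

**VAMP-2.** The score of a representation at lag τ is the sum of squared
singular values of `C00^{-1/2} C0τ Cττ^{-1/2}` truncated at `dim` singular
functions including the constant one, so white noise scores 1 and an exactly
Markovian two-state indicator representation scores `1 + λ₂²`.

## Markov model estimation

- **Discretization:** seeded k-means (mini-batch with strided fitting above
  ~5×10⁵ frames, exact assignment of every frame afterwards). Deterministic
  for a fixed seed.
- **Counting:** sliding-window counts at lag τ; the active set is the
  largest strongly connected component of the count graph.
- **Reversible MLE:** the standard fixed-point iteration on the symmetric
  auxiliary matrix, `x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j)`, converged
  to 1e−10 max change of T. Symmetric counts give row-normalized counts
  exactly; every estimate satisfies detailed balance to < 1e−8.
- **Bayesian uncertainty:** random-walk Metropolis in log x (symmetric
  proposals, step 0.25, 5 sweeps between stored samples), so every posterior
  sample is reversible by construction. The sampler is O(pairs) per sweep in
  Python; it is intended for macrostate-level matrices and modest microstate
  counts, not for thousands of states.
- **Coarse-graining:** a PCCA-style inner-simplex membership construction on
  the top right eigenvectors initializes a discrete-emission hidden Markov
  model (start, transition, and emission matrices); EM at the model lag
  (lag-strided sequences, hmmlearn backend, 500 iterations / 1e−6 tolerance
  by default) refines it. Non-convergence returns the best iterate with a
  warning flag. `n_macro` equal to the microstate count short-circuits to
  the identity coarse-graining.
- **Validation:** implied timescales (`−τ/ln λ`, non-positive or complex
  eigenvalues flagged rather than reported) and the Chapman–Kolmogorov test
  comparing `(T̃^k)_mm` against residence probabilities re-estimated at lag
  kτ. CK intervals come from Dirichlet posteriors over *non-overlapping*
  (strided) counts — sliding counts at lag L are ~L-fold autocorrelated and
  produce dishonestly narrow intervals. Pass = overlap of the 95% intervals
  for every state and multiple.
- **Macrostate-count scan:** candidates (default 4–8) are judged on CK
  passing, all n−1 macro relaxation timescales exceeding the lag (splitting
  a metastable set introduces an unresolved fast process), and no state
  below 1% population (spurious resolution); the largest candidate meeting
  all three is selected.
- **Kinetic summaries:** state lifetime `τ/(1 − T̃_ii)` (geometric dwell; at
  lag τ this targets `τ/(1 − (Tᵗʳᵘᵉ^τ)_ii)`, which exceeds the nominal dwell
  for lifetimes comparable to the lag — a known property of lag-based
  lifetimes, not an estimator defect), relaxation timescales from macro
  eigenvalues, MFPTs from the first-passage linear system with the
  stationary-weighted-source convention. Posterior scalars are summarized by
  a 1–3 component Gaussian mixture selected by BIC (mean ± SD reported
  alongside the component structure).

## Transition path theory

Forward committors solve the standard linear system on intermediate states;
backward committors use the time-reversed chain (for reversible models
q⁻ = 1 − q⁺ to numerical precision). Gross flux `f_ij = π_i q⁻_i T_ij q⁺_j`,
net flux its positive antisymmetric part; net flux out of the source set
equals net flux into the sink to < 1e−10. Pathways are extracted by
iterative bottleneck (widest-path) decomposition — remove the best path's
bottleneck flux, repeat — with deterministic tie-breaking (shorter path,
then lexicographic order), stopping at a cumulative coverage (default 90%
of total flux, reported as percentages of total flux). Path search is
exhaustive over simple paths, which is exact at macrostate counts.

## State characterization

Frames are assigned to macrostates by argmax membership of their microstate
(ties to the lower index; frames outside the active set are reported as
unassigned and excluded). Backbone H-bonds use the geometric windows
d(H···O) ∈ [0.15, 0.40] nm and N–H···O angle ∈ [100°, 180°] measured **at
the hydrogen** (the at-H convention is a documented choice); amide hydrogens
are built at 0.101 nm opposite the bisector of N→C(prev) and N→Cα when
absent, prolines and the N-terminus donate nothing, and sequence-adjacent
pairs (|i−j| < 2) are excluded. Secondary structure is a reduced,
self-consistent rule built on those same windows: helix for residues covered
by ≥2 consecutive i→i+4 bonds, strand for residues in ladders of ≥2
long-range (|i−j| ≥ 3) bonds whose pairs agree within ±1 on both sides,
coil otherwise, helix taking precedence. Per-state summaries report
per-residue P(H)/P(E)/P(C) (closing to 1 by construction), RMSF after
superposition to a reference, mass-weighted radius of gyration, normalized
descriptor histograms, and named pair distances with SD and SE.

## Cavity detection and scoring

Alpha spheres are circumspheres of Delaunay tetrahedra of heavy-atom
centers — tangent to four atoms, empty by the Delaunay property — filtered
to radii in [3.0, 6.0] Å by default (configurable; fpocket-like bounds). A
sphere is apolar when ≥3 of its 4 contact atoms are carbon or sulfur.
Frames are superposed to a reference before gridding (the frequency grid is
meaningless otherwise). Sphere centers are binned on a cubic grid of 2 Å
spacing (8 Å³ cubes); voxels whose mean center count per frame reaches the
isovalue (default 2) are retained and clustered into cavities by
26-connectivity. Per cavity: volume is the voxelized union volume of its
spheres at 0.5 Å sub-sampling (mean ± SE over frames); mean local
hydrophobic density is the total count of apolar–apolar sphere overlaps
(center distance below the radius sum) divided by the number of apolar
spheres, so n mutually overlapping apolar spheres score n−1 and a cavity
with no apolar spheres scores 0. Across states, cavities are matched to a
reference state by voxel-set Jaccard ≥ 0.5; unmatched cavities are listed,
never dropped. Grids export as OpenDX, spheres as PDB pseudo-atoms with the
radius in the B-factor column.

## The synthetic generator

The generator is the study's ground truth, not a convenience fixture. It
emulates a domain with six metastable conformations: a dominant closed pair
(62% and 24% occupancy, together 86%), a short-lived hub intermediate (5%),
and three open states (4%, 3%, 2% — all minor states inside a 2–5% band,
the specific split being a documented choice). The transition matrix is
built from symmetric exchange fluxes `S_ij = a_ij·min(π_i, π_j)` on a
hub-mediated topology (closed pair ↔ hub ↔ three open states, the open
states interconnecting through a bridge state), which enforces detailed
balance with the requested stationary law exactly. Edge prefactors set the
kinetic hierarchy — closed↔closed fast, closed↔hub intermediate, hub↔open
slow — giving relaxation timescales of roughly 0.03–1.1 μs at the default
0.1 ns per step, well above the 10 ns model lag and well below the 20 μs
trajectory length. When an MFPT calibration is requested, the per-step time
unit is rescaled so the analytic hub→open first-passage time equals the
target (17 μs in the packaged recovery experiments) exactly.

Observations are per-state diagonal Gaussians in an 18-descriptor space.
The default means displace distinct descriptor blocks by 4 standard
deviations. That separation is deliberate: with overlapping emissions,
k-means cluster boundaries flicker between states, injecting spurious fast
transitions that bias recovered passage times short (at 3 sd separation the
bias reaches ~15%; at 4 sd the discretized pipeline agrees with an estimate
from the true hidden labels to better than 0.5%). Lowering the separation
is the intended way to study exactly that failure mode, and the test suite
does so for the CK test. Hidden paths are sampled by geometric dwell times
(exactly equivalent in law to per-step sampling), started from the
stationary distribution so occupancy estimates are unbiased.

What the generator does **not** emulate: continuous intra-state dynamics
(emissions are i.i.d. given the state, so microstates inside a metastable
state carry no kinetics), non-Gaussian and multimodal descriptor
distributions, anisotropic correlated noise, and any coupling between the
feature trajectories and the toy 3-D structures. Passing recovery tests
therefore demonstrates correctness of the estimators under exactly
Markovian, well-separated conditions — not robustness to force-field error,
poor feature choice, or insufficient sampling in real MD data.

Structure fixtures: an ideal α-helix (φ = −57°, ψ = −47°, NeRF-built
backbone with standard internal coordinates), an antiparallel β-hairpin
with exact cross-strand H-bond geometry (synthetic, placed directly rather
than torsion-built), a fully extended chain, a 78-residue chain with full
backbone, Cβ placeholders, and complete aromatic rings containing exactly
43 hydrophobic-class residues, and a hollow jittered shell of carbon atoms
for cavity detection.

## Problem sizes and reproducibility

The packaged recovery experiments use 50 trajectories × 200 000 steps
(10⁷ steps total) for stationary populations — about 59 analytic
hub→open passage times of data — and 250 × 200 000 (5×10⁷) for the
calibrated MFPT, whose error budget is dominated by rare hub→open entries
(~10 per 10⁶ steps); bootstrap-over-trajectories 95% intervals accompany
both. All stochastic steps (sampling, k-means, MCMC, bootstrap) take
explicit seeds, with per-trajectory seeds spawned from one master seed.

## Known limitations

- The reversible-matrix MCMC is pure Python and intended for small state
  spaces; microstate-level posteriors at k ≳ 200 would need a compiled
  sampler.
- The HMM refinement uses one strided phase per trajectory by default;
  increasing `n_offsets` uses more data at proportional cost.
- MFPTs and lifetimes inherit the usual lag-time coarse-graining caveats;
  they are accurate when dwell and passage times are much longer than the
  lag, as in all packaged experiments.
- Pathway decomposition enumerates simple paths and is exact but
  combinatorial; it is meant for macrostate networks, not microstate graphs.
- The alpha-sphere step requires a few thousand heavy atoms at most per
  frame (scipy Delaunay); cavity volumes use dense sub-sampling and scale
  with cavity size.
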