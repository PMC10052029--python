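# Methods

This note documents the models and procedures implemented in kinetraj, the
defaults and units, what the synthetic systems do and do not emulate, and
the numerical choices made where the underlying conventions are genuinely
open.

Units throughout: Å for length, kcal/mol for energy, K for temperature, ps
for time, elementary charges for charge.  Boltzmann constant
k<sub>B</sub> = 0.0019872041 kcal/(mol·K); Coulomb prefactor
k<sub>e</sub> = 332.0636 kcal·Å/(mol·e²).  Default temperature 300 K.

## Trajectory model and IO

A `Topology` is an ordered atom list grouped into residues (residue ids keep
their PDB numbering; internal atom indices are 0-based and never surfaced in
reports).  A `Trajectory` is a (frames × atoms × 3) array of Cartesian
coordinates in Å over a topology.  Trajectories are exchanged as multi-model
PDB (MODEL/ENDMDL blocks, `%8.3f` coordinates, TER at chain ends, HETATM for
ligand atoms) or plain TSV coordinate tables; both are plain text and
round-trip losslessly at PDB precision (3 decimals).  Alternate locations:
altloc 'A' or blank is kept, others dropped; insertion codes are appended to
the residue-id string.  The selection grammar covers residue-id ranges,
chains, atom-name classes (`calpha`, `backbone`, `heavy`, `name X`), the
ligand flag, and `and`/`or`/`not` with parentheses.  Binary trajectory
formats are deliberately out of scope; any converter that can emit
multi-model PDB feeds the stack.

## Stability metrics

Superposition is weighted Kabsch via SVD with the determinant correction, so
the rotation is always proper; rank-deficient (collinear/planar) point sets
are resolved by the SVD's ordering of singular vectors.  `rmsd_series` fits
each frame on a *fit* selection and reports RMSD on a possibly different
*report* selection — fitting on the rigid scaffold while reporting on a
mobile loop separates internal motion from tumbling.  RMSF uses the iterated
mean structure: frames are superposed onto the current mean and the mean
recomputed until it moves < 1e-6 Å RMS; fluctuation of a residue is
√⟨‖r − ⟨r⟩‖²⟩ of its alpha carbon.  Equilibrated-window statistics (mean ±
sample sd) default to the second half of a series; both the window and the
replica pooling (concatenation) are parameters, since production protocols
rarely state theirs.

## Cross-correlation

DCCM entries are normalized displacement covariances of residue alpha
carbons after superposition onto the iterated mean (same convention as
RMSF).  Residues whose fluctuation is numerically zero (RMS < 1e-9 Å) get 0
off-diagonal and 1 on the diagonal, with a warning — a division guard, not a
statement about their coupling.  Display masking replaces |C| below a
threshold (default 0.3) with NaN, never 0, so downstream consumers can
distinguish "weak" from "absent".  Per-replica DCCMs are averaged
element-wise and re-clipped to [−1, 1].

Superposition and correlation interact: removing the best-fit rigid-body
motion projects out part of any collective displacement field.  The
synthetic generator therefore appends rigid anchor residues (zero planted
displacement) and the analysis fits on them, making the alignment an exact
identity; on real data the standard practice of fitting on a stable core has
the same role, and perfectly exact recovery is not available.

## Collective motions and free-energy landscapes

PCA RMS-fits every frame to a reference structure (frame 0 by default) on
the analysis selection, then takes the SVD of the centered flattened
coordinates; eigenvalues are sample variances (ddof 1) in Å².  Eigenvector
sign is fixed by making each mode's largest-magnitude component positive, so
porcupine plots are reproducible; arrows are eigenvector blocks scaled by
√eigenvalue.  Free-energy landscapes bin two per-frame scalars (principal
components, RMSD, distances) on a 100×100 grid over the padded (1%) bounding
box and apply G<sub>i</sub> = −k<sub>B</sub>T ln(N<sub>i</sub>/N<sub>m</sub>);
the most populated bin is pinned to exactly 0 and empty bins are NaN, not a
large number.  The loop–ligand distance defaults to
center-of-geometry-to-center-of-geometry, with minimum-distance behind a
flag, because published landscape axes rarely say which variant they used.

## Markov state models

Microstates come from K-means (k-means++ with a fixed seed, single
initialization, default 100 centers / 100 iterations) on the PCA
projections.  Transition counts use a sliding window at lag τ and never
cross replica boundaries.  The default estimator symmetrizes counts,
(C+Cᵀ)/2, before row-normalizing, which enforces detailed balance by
construction; the raw estimator is kept for oracle tests against planted
non-reversible chains.  States outside the largest connected set of the
count graph are ergodically trimmed and reported.

Implied timescales are t<sub>i</sub> = −τ/ln|λ<sub>i</sub>(τ)|; eigenvalues
≤ 0 are reported undefined and |λ| ≥ 1 as an infinite sentinel, flagged
either way.  The Chapman–Kolmogorov test compares metastate self-transition
probabilities predicted by T(τ)ⁿ with those estimated directly at lag nτ,
reporting the maximum absolute deviation and pass/fail at a stated tolerance
(default 0.05).  PCCA+ takes the m dominant right eigenvectors (computed via
the π-symmetrized matrix), finds the m most spread-out rows as simplex
vertices (orthogonal deflation), and expresses every microstate as a convex
combination; memberships are clipped to [0, 1] and row-renormalized, and the
crisp assignment is the argmax.  Mean first passage times solve
(I − T<sub>nn</sub>) m = 1 over non-sink states and average over the source
set weighted by the stationary distribution restricted to it; an unreachable
sink reports infinity with a flag.  Representative conformations are the
frames nearest each metastate's occupancy-weighted centroid in projection
space, ties broken to the lowest frame index — a concrete stand-in for the
under-specified "similarity score" conventions in the literature.

## Energetics

The binding-energy combination is pure bookkeeping over per-frame additive
components (E_internal, E_elec, E_vdw, G_pol, G_np) for complex, receptor,
and ligand: Δ per frame is complex − receptor − ligand, the total is the sum
of Δ-component means, and this additivity is asserted as the module's
conservation law.  The entropy term is omitted by design: normal-mode
estimates are noisy and cancel in comparisons of structurally similar
complexes.  In the single-trajectory convention all species share frames and
the internal terms cancel exactly.  No Generalized-Born solver is
implemented — polar solvation enters as data from files or the synthetic
generator; the per-residue decomposition consumes any per-frame
residue-ligand energy table and flags residues two-sided at |mean| ≥ 1
kcal/mol (unfavorable contributors are reported too).  The toy pairwise
evaluator (Coulomb with a dielectric, Lorentz–Berthelot Lennard-Jones, an
optional per-contact non-polar term) exists to produce such tables with
known answers.  Hydrogen-bond occupancy is geometric: donor–acceptor
distance ≤ 3.5 Å and, when hydrogens are present, donor–H–acceptor angle ≥
120°; distance-only otherwise.

## Community networks

Nodes are residues; an edge requires the minimum heavy-atom distance to stay
≤ 4.5 Å for ≥ 75 % of frames (≥ boundary semantics).  Although nodes are
conventionally drawn at alpha carbons, heavy-atom contacts define the edges
— a 4.5 Å cutoff is far below typical Cα–Cα contact distances; a
Cα-distance mode is available (on bead models the two coincide).
Sequence-adjacent pairs (|i−j| < 2) are excluded as trivially permanent.
Edge weights are d<sub>ij</sub> = −ln|C<sub>ij</sub>| with |C| clamped to
[1e-6, 1]; natural log (the base uniformly rescales weights and cannot change
shortest paths or communities).  Girvan–Newman removes the edge of highest
weighted betweenness (lexicographically smallest residue pair on ties, for
determinism), tracking the modularity of each intermediate component
partition and returning the maximizer.  Modularity is evaluated on the
*unweighted* graph: under distance weights, modularity would reward weakly
correlated edges, inverting the intended meaning.  Communities smaller than
3 residues are dropped and reported unassigned.  Intercommunity strength is
the summed weighted edge betweenness (computed on the full graph) of the
edges spanning a community pair.

## Synthetic systems

All generators are pure functions of (parameters, seed); randomness flows
through one explicit `numpy.random.Generator`.

* **Multi-well Brownian dynamics** — overdamped Langevin (Euler–Maruyama) on
  a sum of inverted Gaussians plus a weak harmonic confinement (default 0.02
  kcal/(mol·Å²)) that keeps long runs bounded, since the Gaussian part
  flattens far from the wells.  The exact stationary occupancy of each basin
  is available by quadrature of e^(−V/kT), giving an oracle for occupancy
  tests; a timestep above the stability bound 2γ/max-curvature raises.
  Euler–Maruyama's stationary-density bias grows with (dt·curvature/γ);
  validation runs keep that product ≲ 0.4.
* **Loop protein** — 50 alpha-carbon beads by default: two lattice-blob
  lobes (4 Å spacing), a three-bead hinge strand bridging the cleft, a
  ligand bead, and a loop (residues 10–17) protruding from the N-lobe; the
  closed frame moves each loop bead along its line of sight to the ligand,
  stopping 3.5 Å short, which also brings it within contact range of the
  first hinge bead.  A 1-D progress path in [0, 1] is mapped to frames by
  linear interpolation plus isotropic Gaussian jitter.
* **Planted covariances** — displacement fields drawn per Cartesian
  component from N(0, R) with a block-structured correlation matrix R
  (PSD-checked at construction), scaled by per-residue amplitudes, so
  ⟨Δr<sub>i</sub>·Δr<sub>j</sub>⟩ recovers R exactly in expectation; four
  rigid anchor residues are appended for alignment (see Cross-correlation).
* **Markov chains and energy tables** — direct sampling from a
  row-stochastic matrix (validated to 1e-10); independent Gaussian per-frame
  energy components with specified means and sds.

What the generators do *not* emulate: force-field energetics, solvent,
anisotropic or sequence-dependent fluctuations, correlated energy
components, and the slow non-Markovian memory of real collective variables.
Passing tests therefore demonstrate that the estimators recover planted
structure under their own assumptions — the correct behavior of the
analysis code — not that any particular biological system behaves this way.

## Problem sizes and reproducibility

Validation uses sizes chosen so every planted quantity is estimated well
inside its tolerance: 5 000 frames for DCCM recovery (sampling error ≈
1/√n ≈ 0.014 per entry), 10⁵ steps for chain estimation (entry error ≈
0.005), 10⁵ walkers for first-passage simulation (relative error ≈ 0.3 %),
2×10⁵ steps per Brownian occupancy run, 300 frames per pipeline system.
`scripts/acceptance.py` regenerates everything from a single `--seed` and
derives per-stage seeds from a `SeedSequence` stream, so runs are
reproducible and stages are independent of each other's consumption of
randomness.

## Known limitations

* The Girvan–Newman loop recomputes betweenness after every edge removal
  (O(E²V) with weights); it is meant for residue-scale graphs (hundreds of
  nodes), not large meshes.
* PCCA+ memberships can be noisy when the spectral gap after the requested
  number of metastates is small; the crisp assignment is stable in the
  block-structured regimes it is used for here.
* The PDB writer emits a minimal dialect (ATOM/HETATM, MODEL/ENDMDL, TER,
  END) — no CONECT, occupancy/B-factor semantics, or SEQRES.
* `contact_edges` is O(frames · residues² · atoms-per-residue²) in the
  general case; the one-bead-per-residue fast path is fully vectorized.
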