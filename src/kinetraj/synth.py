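"""Seedable synthetic systems with planted, recoverable ground truth.

Real multi-microsecond kinase trajectories are not shippable, so every
analysis stage here is exercised on generators whose answers are known in
advance:

* overdamped Brownian dynamics on a multi-well potential — a stand-in for a
  flexible loop hopping between open / intermediate / closed basins, with the
  exact stationary density available by quadrature;
* a two-lobe bead "protein" with a ligand bead in the cleft and a loop whose
  open→closed displacement is planted exactly;
* residue displacement fields drawn from a planted block covariance, so
  cross-correlation and PCA structure is recoverable;
* discrete Markov chains from a known transition matrix;
* additive per-frame energy tables with known component means.

All randomness flows through an explicit :class:`numpy.random.Generator` (or
an integer seed); identical calls produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .energetics import ENERGY_COMPONENTS, EnergyTable
from .traj import Topology, Trajectory, make_bead_topology

__all__ = [
    "WellSpec",
    "PlantedCovariance",
    "sample_overdamped_dynamics",
    "make_loop_protein",
    "interpolate_trajectory",
    "sample_markov_chain",
    "sample_correlated_displacements",
    "make_energy_tables",
    "stationary_well_occupancy",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# multi-well Brownian dynamics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WellSpec:
    """Sum-of-inverted-Gaussians potential for overdamped Langevin dynamics.

    V(x) = −Σ_k depth_k · exp(−‖x−c_k‖² / 2w_k²) + ½·confinement·‖x−x̄‖²

    ``depths`` are well depths in kcal/mol, ``widths`` in Å.  The weak
    harmonic confinement (about the well-center centroid) keeps long runs
    bounded, since the Gaussian part flattens to zero far from the wells; it
    is part of the potential and of the quadrature oracle alike.
    """

    centers: tuple  # K points, each d-dimensional
    depths: tuple  # kcal/mol, > 0
    widths: tuple  # Å, > 0
    temperature: float = 300.0  # K
    friction: float = 1.0  # kcal·ps/(mol·Å²)
    timestep: float = 0.01  # ps
    confinement: float = 0.02  # kcal/(mol·Å²)

    def __post_init__(self):
        if len(self.centers) < 2:
            raise ValueError("need at least 2 wells")
        if len(self.depths) != len(self.centers) or len(self.widths) != len(self.centers):
            raise ValueError("centers, depths, widths must have equal length")
        if any(d <= 0 for d in self.depths) or any(w <= 0 for w in self.widths):
            raise ValueError("depths and widths must be positive")

    @property
    def ndim(self) -> int:
        c0 = np.atleast_1d(np.asarray(self.centers[0], float))
        return c0.size

    def _centers_array(self) -> np.ndarray:
        return np.atleast_2d(np.asarray(self.centers, float).reshape(len(self.centers), -1))

    def potential(self, x: np.ndarray) -> np.ndarray:
        """V at points x of shape (..., d), in kcal/mol."""
        x = np.asarray(x, float)
        squeeze = x.ndim == 1 and self.ndim == 1 and x.shape[-1] != 1
        pts = x.reshape(-1, self.ndim)
        C = self._centers_array()
        d2 = ((pts[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        depths = np.asarray(self.depths, float)
        widths = np.asarray(self.widths, float)
        v = -(depths[None, :] * np.exp(-d2 / (2 * widths[None, :] ** 2))).sum(axis=1)
        center = C.mean(axis=0)
        v = v + 0.5 * self.confinement * ((pts - center) ** 2).sum(axis=1)
        return v.reshape(x.shape[:-1]) if not squeeze else v

    def force(self, x: np.ndarray) -> np.ndarray:
        """−∇V at points x of shape (..., d)."""
        x = np.asarray(x, float)
        pts = x.reshape(-1, self.ndim)
        C = self._centers_array()
        diff = pts[:, None, :] - C[None, :, :]  # (n, K, d)
        d2 = (diff**2).sum(axis=2)
        depths = np.asarray(self.depths, float)
        w2 = np.asarray(self.widths, float) ** 2
        g = depths[None, :] * np.exp(-d2 / (2 * w2[None, :])) / w2[None, :]
        f = -(g[:, :, None] * diff).sum(axis=1)
        center = C.mean(axis=0)
        f = f - self.confinement * (pts - center)
        return f.reshape(x.shape)

    def assign_well(self, x: np.ndarray) -> np.ndarray:
        """Index of the nearest well center for each point."""
        pts = np.asarray(x, float).reshape(-1, self.ndim)
        C = self._centers_array()
        d2 = ((pts[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def stability_limit(self) -> float:
        """Largest stable Euler–Maruyama timestep, ps (dt < 2γ/max curvature)."""
        # max curvature of an inverted Gaussian well is depth/width² at center
        curv = max(d / w**2 for d, w in zip(self.depths, self.widths))
        curv += self.confinement
        return 2.0 * self.friction / curv


def sample_overdamped_dynamics(
    wellspec: WellSpec, n_steps: int, seed, x0: np.ndarray | None = None
) -> np.ndarray:
    """Euler–Maruyama integration of overdamped Langevin dynamics.

    dx = (F/γ) dt + sqrt(2 kB T dt / γ) ξ.  Returns the (n_steps, d) path.
    Raises if the timestep exceeds the stability bound of the stiffest well.
    """
    dt = wellspec.timestep
    limit = wellspec.stability_limit()
    if dt >= limit:
        raise ValueError(
            f"timestep {dt} ps exceeds stability bound {limit:.4g} ps "
            "for the stiffest well"
        )
    rng = _rng(seed)
    d = wellspec.ndim
    if x0 is None:
        x = np.asarray(wellspec.centers[0], float).reshape(d).copy()
    else:
        x = np.asarray(x0, float).reshape(d).copy()
    gamma = wellspec.friction
    noise_scale = np.sqrt(2.0 * KB * wellspec.temperature * dt / gamma)
    path = np.empty((n_steps, d))
    xi = rng.standard_normal((n_steps, d))
    for t in range(n_steps):
        x = x + wellspec.force(x) / gamma * dt + noise_scale * xi[t]
        path[t] = x
    return path


def stationary_well_occupancy(
    wellspec: WellSpec, grid_points: int = 4001, span: float = 6.0
) -> np.ndarray:
    """Exact Boltzmann occupancy of each well basin, by quadrature (1-D only).

    Integrates exp(−V/kBT) on a fine grid and assigns each grid point to its
    nearest well center — the same basin rule used for empirical occupancies.
    """
    if wellspec.ndim != 1:
        raise ValueError("quadrature oracle implemented for 1-D potentials")
    C = wellspec._centers_array().ravel()
    w = max(wellspec.widths)
    lo, hi = C.min() - span * w, C.max() + span * w
    x = np.linspace(lo, hi, grid_points)
    rho = np.exp(-wellspec.potential(x[:, None]) / (KB * wellspec.temperature))
    labels = wellspec.assign_well(x[:, None])
    occ = np.array([rho[labels == k].sum() for k in range(len(C))])
    return occ / occ.sum()


# --------------------------------------------------------------------------
# two-lobe loop protein
# --------------------------------------------------------------------------


def _lattice_blob(n: int, center: np.ndarray, spacing: float) -> np.ndarray:
    """Compact cubic-lattice arrangement of n beads around a center."""
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                pts.append((i, j, k))
                if len(pts) == n:
                    break
            if len(pts) == n:
                break
        if len(pts) == n:
            break
    pts = np.asarray(pts, float) * spacing
    return pts - pts.mean(axis=0) + center


def make_loop_protein(
    n_residues: int,
    loop_span: tuple[int, int],
    seed,
    closed_standoff: float = 3.5,
    jitter: float = 0.3,
) -> tuple[Topology, np.ndarray, np.ndarray]:
    """Two-lobe alpha-carbon pseudo-protein with a mobile loop and a ligand bead.

    Residues 1..n/2 form the N-lobe (a compact lattice blob centred above the
    cleft), the rest the C-lobe below it; the first three C-lobe residues are
    repositioned as a "hinge" strand bridging from the cleft into the C-lobe.
    Residues in ``loop_span`` (inclusive residue ids) are pulled out of the
    N-lobe onto a protruding arc far from the cleft; the returned
    ``closed_frame`` differs from ``open_frame`` only by displacing those
    loop residues toward the ligand bead, stopping ``closed_standoff`` Å
    short of it — close enough to contact both the ligand and the first
    hinge residue, as a loop folding over a bound inhibitor does.

    Returns ``(topology, open_frame, closed_frame)``; the topology's final
    atom is the ligand bead.
    """
    lo, hi = loop_span
    if not (1 <= lo <= hi <= n_residues):
        raise ValueError(f"loop span {loop_span} outside residue range 1..{n_residues}")
    rng = _rng(seed)
    n_lobe1 = n_residues // 2
    spacing = 4.0
    lobe1 = _lattice_blob(n_lobe1, np.array([0.0, 0.0, 10.0]), spacing)
    lobe2 = _lattice_blob(n_residues - n_lobe1, np.array([0.0, 0.0, -10.0]), spacing)
    coords = np.vstack([lobe1, lobe2])
    coords += rng.normal(scale=jitter, size=coords.shape)

    ligand_pos = np.array([6.0, 0.0, 0.0])
    # hinge strand: first C-lobe residues bridging cleft -> C-lobe
    hinge_positions = np.array(
        [[5.0, 0.0, -1.0], [4.6, 0.0, -3.0], [4.2, 0.0, -5.0]]
    )
    hinge_idx = np.arange(n_lobe1, min(n_lobe1 + 3, n_residues))
    coords[hinge_idx] = hinge_positions[: len(hinge_idx)]

    # loop: protruding arc on the N-lobe side, far from the ligand when open
    loop_idx = np.arange(lo - 1, hi)
    n_loop = len(loop_idx)
    arc = np.linspace(-1.0, 1.0, n_loop)
    open_positions = np.stack(
        [
            -8.0 - 3.0 * (1 - arc**2),
            4.0 * arc,
            np.full(n_loop, 14.0),
        ],
        axis=1,
    )
    open_frame = coords.copy()
    open_frame[loop_idx] = open_positions

    # closed: each loop bead moves along its line of sight to the ligand,
    # stopping closed_standoff Å short
    closed_frame = open_frame.copy()
    to_lig = ligand_pos - open_positions
    dist = np.linalg.norm(to_lig, axis=1, keepdims=True)
    closed_frame[loop_idx] = ligand_pos - closed_standoff * to_lig / dist

    open_frame = np.vstack([open_frame, ligand_pos])
    closed_frame = np.vstack([closed_frame, ligand_pos])
    topology = make_bead_topology(n_residues, ligand=True)

    d_open = np.linalg.norm(open_frame[loop_idx] - ligand_pos, axis=1).min()
    d_closed = np.linalg.norm(closed_frame[loop_idx] - ligand_pos, axis=1).min()
    assert d_closed < d_open
    return topology, open_frame, closed_frame


def interpolate_trajectory(
    open_frame: np.ndarray,
    closed_frame: np.ndarray,
    state_path: np.ndarray,
    topology: Topology | None = None,
    jitter_sigma: float = 0.0,
    seed=0,
    frame_interval: float | None = None,
) -> Trajectory:
    """Map a 1-D progress path in [0, 1] onto 3-D frames between two endpoints.

    Frame t is ``open + s_t·(closed − open)`` plus isotropic Gaussian jitter
    of width ``jitter_sigma`` Å, so a metastable 1-D path (e.g. from
    :func:`sample_overdamped_dynamics`, rescaled) becomes a trajectory whose
    slow coordinate is the open→closed transition.
    """
    s = np.asarray(state_path, float).ravel()
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("state_path values must lie in [0, 1]")
    open_frame = np.asarray(open_frame, float)
    closed_frame = np.asarray(closed_frame, float)
    if open_frame.shape != closed_frame.shape:
        raise ValueError("open and closed frames must have the same shape")
    rng = _rng(seed)
    coords = open_frame[None, :, :] + s[:, None, None] * (closed_frame - open_frame)[None, :, :]
    if jitter_sigma > 0:
        coords = coords + rng.normal(scale=jitter_sigma, size=coords.shape)
    if topology is None:
        topology = make_bead_topology(open_frame.shape[0])
    return Trajectory(coords, topology, frame_interval=frame_interval)


# --------------------------------------------------------------------------
# Markov chains
# --------------------------------------------------------------------------


def sample_markov_chain(
    transition_matrix: np.ndarray, n_steps: int, seed, start_state: int = 0
) -> np.ndarray:
    """Sample a discrete chain from a row-stochastic transition matrix."""
    T = np.asarray(transition_matrix, float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < 0):
        raise ValueError("transition matrix has negative entries")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix rows must sum to 1 within 1e-10")
    rng = _rng(seed)
    k = T.shape[0]
    cum = np.cumsum(T, axis=1)
    states = np.empty(n_steps, dtype=int)
    s = start_state
    u = rng.random(n_steps)
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        s = min(s, k - 1)  # guard float round-off at the top edge
        states[t] = s
    return states


# --------------------------------------------------------------------------
# planted covariance displacements
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCovariance:
    """Block residue-residue correlation structure with per-residue amplitudes.

    ``blocks`` partitions residue indices (0-based) into groups; residues in
    the same group correlate at ``intra_correlation``, residues in different
    groups at ``inter_correlation`` (signed).  ``amplitudes`` are per-residue
    RMS displacement scales in Å (scalar broadcasts).  The implied correlation
    matrix must be positive semi-definite — checked at construction.
    """

    blocks: tuple  # tuple of tuples of residue indices
    intra_correlation: float = 0.9
    inter_correlation: float = 0.0
    amplitudes: float | tuple = 1.0

    def __post_init__(self):
        R = self.correlation_matrix()
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-8:
            raise ValueError(
                f"planted correlation matrix is not PSD (min eigenvalue {eig.min():.3g})"
            )

    @property
    def n_residues(self) -> int:
        return sum(len(b) for b in self.blocks)

    def correlation_matrix(self) -> np.ndarray:
        n = self.n_residues
        membership = np.empty(n, dtype=int)
        for b, grp in enumerate(self.blocks):
            for i in grp:
                membership[i] = b
        same = membership[:, None] == membership[None, :]
        R = np.where(same, self.intra_correlation, self.inter_correlation)
        np.fill_diagonal(R, 1.0)
        return R

    def amplitude_vector(self) -> np.ndarray:
        amps = np.asarray(self.amplitudes, float)
        if amps.ndim == 0:
            return np.full(self.n_residues, float(amps))
        if amps.shape != (self.n_residues,):
            raise ValueError("amplitudes must be scalar or one per residue")
        return amps


def sample_correlated_displacements(
    planted: PlantedCovariance,
    n_frames: int,
    seed,
    base_structure: np.ndarray | None = None,
    topology: Topology | None = None,
    n_anchor: int = 4,
) -> Trajectory:
    """Trajectory of residue beads whose displacement correlations equal the plant.

    Each Cartesian component of the per-frame displacement field is an
    independent draw from N(0, R) scaled by the per-residue amplitude, so the
    displacement-vector dot products satisfy ⟨Δr_i·Δr_j⟩ = a_i a_j R_ij and a
    cross-correlation estimate converges to the planted R.

    The last ``n_anchor`` residues are a rigid, non-collinear scaffold with
    zero displacement.  Superposing frames on the anchors (the cross-
    correlation stage's fit selection) is then an exact identity, so the
    alignment cannot leak the planted collective motion into — or out of —
    the correlations.  The planted residues occupy ids 1..n; the anchors
    follow.
    """
    rng = _rng(seed)
    n = planted.n_residues
    R = planted.correlation_matrix()
    amps = planted.amplitude_vector()
    # symmetric PSD factor (eigh tolerates the degenerate ±1 cases Cholesky rejects)
    evals, evecs = np.linalg.eigh(R)
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    if base_structure is None:
        # helix for the planted residues; spread anchors off-axis
        t = np.arange(n) * np.radians(100.0)
        helix = np.column_stack([8.0 * np.cos(t), 8.0 * np.sin(t), 1.5 * np.arange(n)])
        anchors = np.array(
            [
                [20.0, 0.0, 0.0],
                [0.0, 20.0, 0.0],
                [0.0, 0.0, -15.0],
                [15.0, 15.0, 10.0],
            ]
        )[: max(n_anchor, 0)]
        if n_anchor > 4:
            extra = rng.normal(scale=10.0, size=(n_anchor - 4, 3)) + 25.0
            anchors = np.vstack([anchors, extra])
        base_structure = np.vstack([helix, anchors]) if n_anchor else helix
    base_structure = np.asarray(base_structure, float)
    if base_structure.shape[0] != n + n_anchor:
        raise ValueError(
            f"base structure must cover {n} planted + {n_anchor} anchor residues"
        )
    z = rng.standard_normal((n_frames, 3, n))
    fields = z @ L.T  # (frames, 3, n) correlated across residues
    disp = np.transpose(fields, (0, 2, 1)) * (amps[None, :, None] / np.sqrt(3.0))
    coords = np.repeat(base_structure[None, :, :], n_frames, axis=0)
    coords[:, :n, :] += disp
    if topology is None:
        topology = make_bead_topology(n + n_anchor)
    return Trajectory(coords, topology)


# --------------------------------------------------------------------------
# energy tables
# --------------------------------------------------------------------------


def make_energy_tables(
    component_means: dict,
    component_sds: dict | float,
    n_frames: int,
    seed,
) -> tuple[EnergyTable, EnergyTable, EnergyTable]:
    """Gaussian per-frame energy tables for complex, receptor, and ligand.

    ``component_means`` maps species ('complex', 'receptor', 'ligand') to a
    mapping of component name → mean (kcal/mol); missing components default
    to 0.  ``component_sds`` follows the same structure, or is a single
    scalar applied everywhere.  Per-frame values are independent Gaussians,
    so the combination stage's Δ-component means converge to the planted
    differences at the usual sd/√n rate.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames (sample sd undefined otherwise)")
    rng = _rng(seed)
    tables = []
    for species in ("complex", "receptor", "ligand"):
        means = component_means.get(species, {})
        data = {}
        for comp in ENERGY_COMPONENTS:
            mu = float(means.get(comp, 0.0))
            if isinstance(component_sds, dict):
                sd = float(component_sds.get(species, {}).get(comp, 0.0))
            else:
                sd = float(component_sds)
            data[comp] = mu + sd * rng.standard_normal(n_frames)
        tables.append(EnergyTable(components=data, species=species))
    return tuple(tables)
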