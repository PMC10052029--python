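"""Principal-component analysis of coordinates and free-energy landscapes.

PCA diagonalizes the covariance of RMS-fitted Cartesian coordinates; the
first few eigenvectors are the dominant collective motions (lobe opening /
closing, loop relocation), and projecting each frame onto them gives
low-dimensional reaction coordinates.  Binning two such coordinates and
converting populations to free energies,

    G_i = −k_B T ln(N_i / N_m),

with N_m the most populated bin, yields the 2-D free-energy landscape whose
basins are the system's metastable conformations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB
from .stability import apply_superposition, kabsch_superpose
from .traj import Selection, Trajectory

__all__ = [
    "PCAModel",
    "FreeEnergyGrid",
    "fit_pca",
    "population_to_free_energy",
    "free_energy_landscape",
    "loop_distance_series",
    "porcupine_field",
]


@dataclass
class PCAModel:
    """Eigen-decomposition of the coordinate covariance over selected atoms.

    ``eigenvectors`` rows are unit-norm modes in the flattened (3n,)
    coordinate space, eigenvalues (Å²) descending; ``projections`` are the
    centered coordinates dotted with the modes, one row per frame.
    """

    mean_structure: np.ndarray  # (n_atoms, 3)
    eigenvectors: np.ndarray  # (modes, 3n)
    eigenvalues: np.ndarray  # (modes,), Å², descending
    projections: np.ndarray  # (frames, modes)
    atom_indices: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def fit_pca(
    trajectory: Trajectory,
    selection: Selection,
    fit_reference: int | np.ndarray = 0,
    n_modes: int | None = None,
) -> PCAModel:
    """PCA of RMS-fitted coordinates over the selected atoms.

    Every frame is least-squares fit (on the selection) to ``fit_reference``
    — a frame index or explicit coordinates — before covariance accumulation,
    so translation and overall rotation do not contaminate the modes.
    Eigenvector signs are fixed by making each mode's largest-magnitude
    component positive.
    """
    if len(selection) == 0:
        raise ValueError("selection must be non-empty")
    idx = selection.as_array()
    ref = (
        trajectory.coordinates[fit_reference]
        if isinstance(fit_reference, (int, np.integer))
        else np.asarray(fit_reference, float)
    )
    F = trajectory.n_frames
    fitted = np.empty((F, len(idx), 3))
    for f in range(F):
        frame = trajectory.coordinates[f]
        sup = kabsch_superpose(ref[idx], frame[idx])
        fitted[f] = apply_superposition(frame[idx], sup)
    flat = fitted.reshape(F, -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    max_modes = min(F - 1, flat.shape[1])
    if n_modes is None:
        n_modes = max_modes
    if n_modes > max_modes or F <= n_modes:
        raise ValueError(
            f"cannot extract {n_modes} modes from {F} frames of {flat.shape[1]} coordinates"
        )
    # SVD of the centered data matrix; eigenvalues of the sample covariance
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (F - 1)
    eigenvectors = Vt
    # deterministic sign: largest-|component| positive
    for m in range(eigenvectors.shape[0]):
        peak = np.argmax(np.abs(eigenvectors[m]))
        if eigenvectors[m, peak] < 0:
            eigenvectors[m] = -eigenvectors[m]
    projections = centered @ eigenvectors.T
    return PCAModel(
        mean_structure=mean.reshape(-1, 3),
        eigenvectors=eigenvectors[:n_modes],
        eigenvalues=eigenvalues[:n_modes],
        projections=projections[:, :n_modes],
        atom_indices=idx,
    )


@dataclass
class FreeEnergyGrid:
    """2-D free-energy surface from binned populations.

    ``values`` holds G in kcal/mol on occupied bins and NaN on empty bins;
    the most populated bin is exactly 0.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray  # (nx, ny), kcal/mol, NaN = unvisited
    temperature: float
    occupied_bins: int

    def minimum_location(self) -> tuple[float, float]:
        """Bin-center coordinates of the global free-energy minimum."""
        i, j = np.unravel_index(np.nanargmin(self.values), self.values.shape)
        x = 0.5 * (self.x_edges[i] + self.x_edges[i + 1])
        y = 0.5 * (self.y_edges[j] + self.y_edges[j + 1])
        return float(x), float(y)


def population_to_free_energy(
    populations: np.ndarray, temperature: float = DEFAULT_TEMPERATURE
) -> np.ndarray:
    """G_i = −k_B T ln(N_i/N_m) for (possibly fractional) bin populations.

    The core conversion behind the landscape: the most populated bin sits at
    G = 0 and a bin with N_m/e of its population at k_B T above it.  Zero
    populations map to NaN (unvisited, not infinitely high).
    """
    N = np.asarray(populations, float)
    nm = N.max()
    if nm <= 0:
        raise ValueError("populations must contain a positive entry")
    G = np.full_like(N, np.nan, dtype=float)
    occ = N > 0
    G[occ] = -KB * temperature * np.log(N[occ] / nm)
    G[N == nm] = 0.0
    return G


def free_energy_landscape(
    x_series: np.ndarray,
    y_series: np.ndarray,
    n_bins: int = 100,
    temperature: float = DEFAULT_TEMPERATURE,
    padding: float = 0.01,
) -> FreeEnergyGrid:
    """Population-based free-energy surface over two reaction coordinates.

    Histograms the series on an ``n_bins``×``n_bins`` grid spanning the data's
    bounding box (padded by ``padding`` fractionally) and converts counts to
    G_i = −k_B T ln(N_i/N_m).  The reaction coordinates may be principal
    components, RMSD values, distances — any per-frame scalars.
    """
    x = np.asarray(x_series, float).ravel()
    y = np.asarray(y_series, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y series must have equal length")
    if n_bins < 2:
        raise ValueError("need at least 2 bins per axis")

    def _edges(v):
        lo, hi = v.min(), v.max()
        span = hi - lo
        if span == 0.0:
            span = max(abs(hi), 1.0)
            return np.linspace(lo - 0.5 * span, hi + 0.5 * span, n_bins + 1)
        pad = padding * span
        return np.linspace(lo - pad, hi + pad, n_bins + 1)

    xe, ye = _edges(x), _edges(y)
    counts, _, _ = np.histogram2d(x, y, bins=[xe, ye])
    occupied = counts > 0
    n_occ = int(occupied.sum())
    if n_occ == 1:
        warnings.warn("all samples fall in a single bin", stacklevel=2)
    G = population_to_free_energy(counts, temperature)
    return FreeEnergyGrid(
        x_edges=xe, y_edges=ye, values=G, temperature=temperature, occupied_bins=n_occ
    )


def loop_distance_series(
    trajectory: Trajectory,
    loop_selection: Selection,
    ligand_selection: Selection,
    mode: str = "center",
) -> np.ndarray:
    """Per-frame loop–ligand distance (Å).

    ``mode='center'`` (default) measures center-of-geometry to
    center-of-geometry; ``mode='min'`` measures the minimum atom–atom
    distance.  Either serves as the displacement coordinate of a loop closing
    over a bound ligand.
    """
    if len(loop_selection) == 0 or len(ligand_selection) == 0:
        raise ValueError("selections must be non-empty")
    if mode not in ("center", "min"):
        raise ValueError("mode must be 'center' or 'min'")
    L = trajectory.coordinates[:, loop_selection.as_array(), :]
    G = trajectory.coordinates[:, ligand_selection.as_array(), :]
    if mode == "center":
        return np.linalg.norm(L.mean(axis=1) - G.mean(axis=1), axis=1)
    diff = L[:, :, None, :] - G[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=3)).min(axis=(1, 2))


def porcupine_field(pca_model: PCAModel, mode_index: int = 0) -> np.ndarray:
    """Per-atom displacement arrows for one principal mode.

    Arrow for atom a is the mode's (3,) component block scaled by
    √eigenvalue, i.e. the RMS-amplitude-weighted direction of motion — the
    data behind a porcupine plot.  The sign convention follows the model's
    eigenvector sign fix; flipping the eigenvector flips every arrow.
    """
    if not (0 <= mode_index < pca_model.n_modes):
        raise ValueError(
            f"mode {mode_index} out of range (model has {pca_model.n_modes})"
        )
    vec = pca_model.eigenvectors[mode_index].reshape(-1, 3)
    return vec * np.sqrt(pca_model.eigenvalues[mode_index])
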