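"""Superposition and structural-stability metrics: Kabsch, RMSD, RMSF.

RMSD series measure drift of a region from a reference frame after a
least-squares fit on a (possibly different) fit region; RMSF measures
per-residue fluctuation about the iterated mean structure.  Both are the
standard first-look stability surface for comparing ligand-free and
inhibitor-bound ensembles: bound systems typically show lower equilibrated
RMSD and damped loop RMSF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traj import Selection, Trajectory

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_series",
    "rmsf",
    "superpose_to_mean",
    "equilibrated_stats",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation + translation and the residual RMSD (Å)."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,), Å
    rmsd: float


def kabsch_superpose(
    reference_coords: np.ndarray,
    mobile_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``reference`` (Kabsch/SVD).

    Returns the proper rotation R and translation t minimising the (weighted)
    RMSD of ``mobile @ R.T + t`` against ``reference``.  Reflections are
    excluded by the usual determinant correction; rank-deficient (collinear or
    planar) point sets still succeed, with the SVD's smallest singular vector
    deciding the free axis.
    """
    ref = np.asarray(reference_coords, dtype=float)
    mob = np.asarray(mobile_coords, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("reference and mobile must both be (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0):
            raise ValueError("weights must be non-negative with one value per point")
        if not np.any(w > 0):
            raise ValueError("all-zero weights")
    wsum = w.sum()
    ref_c = (w[:, None] * ref).sum(axis=0) / wsum
    mob_c = (w[:, None] * mob).sum(axis=0) / wsum
    P = mob - mob_c
    Q = ref - ref_c
    H = (w[:, None] * P).T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    moved = P @ R.T + ref_c
    rmsd = float(np.sqrt((w[:, None] * (moved - ref) ** 2).sum() / wsum))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply a fitted rotation + translation to an (n, 3) coordinate array."""
    return np.asarray(coords, float) @ result.rotation.T + result.translation


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def rmsd_series(
    trajectory: Trajectory,
    reference_frame: int | np.ndarray,
    fit_selection: Selection,
    report_selection: Selection | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference after fitting on ``fit_selection``.

    ``report_selection`` defaults to the fit selection; fitting on a rigid
    scaffold while reporting on a mobile loop isolates the loop's motion from
    global tumbling.
    """
    if report_selection is None:
        report_selection = fit_selection
    if len(fit_selection) == 0 or len(report_selection) == 0:
        raise ValueError("fit and report selections must be non-empty")
    ref = (
        trajectory.coordinates[reference_frame]
        if isinstance(reference_frame, (int, np.integer))
        else np.asarray(reference_frame, float)
    )
    fit_idx = fit_selection.as_array()
    rep_idx = report_selection.as_array()
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        frame = trajectory.coordinates[f]
        sup = kabsch_superpose(ref[fit_idx], frame[fit_idx])
        moved = apply_superposition(frame[rep_idx], sup)
        out[f] = _plain_rmsd(moved, ref[rep_idx])
    return out


def superpose_to_mean(
    trajectory: Trajectory,
    fit_selection: Selection,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> np.ndarray:
    """Iteratively superpose all frames onto their mean structure.

    Frames are fit (on ``fit_selection``) to the current mean, the mean is
    recomputed, and the loop repeats until the mean moves less than ``tol`` Å
    RMS.  Returns the aligned (frames, atoms, 3) array; the input trajectory
    is not modified.
    """
    if len(fit_selection) == 0:
        raise ValueError("fit selection must be non-empty")
    fit_idx = fit_selection.as_array()
    coords = trajectory.coordinates.copy()
    mean = coords[0].copy()
    for _ in range(max_iter):
        for f in range(coords.shape[0]):
            sup = kabsch_superpose(mean[fit_idx], coords[f, fit_idx])
            coords[f] = apply_superposition(coords[f], sup)
        new_mean = coords.mean(axis=0)
        shift = np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean())
        mean = new_mean
        if shift < tol:
            break
    return coords


def rmsf(
    trajectory: Trajectory,
    selection: Selection,
    fit_selection: Selection | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF (Å) about the iterated mean structure.

    ``selection`` should pick one atom per residue (the alpha-carbon
    convention); returns ``(residue_ids, rmsf_values)`` aligned with the
    selection order.  Fluctuation of atom i is sqrt(⟨‖r_i − ⟨r_i⟩‖²⟩) over
    frames after removing global rigid-body motion.
    """
    if len(selection) == 0:
        raise ValueError("selection must be non-empty")
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if fit_selection is None:
        fit_selection = selection
    aligned = superpose_to_mean(trajectory, fit_selection)
    idx = selection.as_array()
    sub = aligned[:, idx, :]
    mean = sub.mean(axis=0)
    fluct = np.sqrt(((sub - mean) ** 2).sum(axis=2).mean(axis=0))
    res_ids = np.array([trajectory.topology.residue_of_atom(i) for i in idx])
    return res_ids, fluct


def equilibrated_stats(series: np.ndarray, window_fraction: float = 0.5):
    """Mean ± sample sd over the equilibrated tail of a per-frame series.

    The equilibrated window defaults to the second half of the series.
    """
    series = np.asarray(series, float)
    start = int(len(series) * (1.0 - window_fraction))
    tail = series[start:]
    sd = float(tail.std(ddof=1)) if len(tail) > 1 else 0.0
    return float(tail.mean()), sd
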