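"""Dynamic cross-correlation matrices (DCCM) of residue motions.

The DCCM entry for residues i and j is the normalized covariance of their
alpha-carbon displacement vectors about the time mean,

    C_ij = ⟨Δr_i·Δr_j⟩ / (⟨Δr_i²⟩ ⟨Δr_j²⟩)^(1/2),

after removing global rigid-body motion by superposition onto the mean
structure.  +1 means fully correlated motion, −1 fully anti-correlated;
display conventions mask |C| below a threshold (0.3 in the source figures)
to highlight the strongly coupled blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stability import superpose_to_mean
from .traj import Selection, Trajectory

__all__ = [
    "CorrelationMatrix",
    "dccm",
    "mask_correlations",
    "region_correlation_summary",
    "average_correlation_matrices",
    "read_correlation_tsv",
    "write_correlation_tsv",
]


@dataclass
class CorrelationMatrix:
    """Symmetric residue×residue correlation matrix with residue-id labels.

    Masked entries (below a display threshold) are NaN, never 0, so
    downstream consumers can distinguish "weak" from "absent".
    """

    matrix: np.ndarray
    residue_ids: np.ndarray
    mask_threshold: float | None = None

    def __post_init__(self):
        M = np.asarray(self.matrix, float)
        finite = np.isfinite(M)
        if not np.allclose(
            np.where(finite, M, 0.0), np.where(finite.T, M.T, 0.0), atol=1e-10
        ):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(M)) > 1.0 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.matrix = M
        self.residue_ids = np.asarray(self.residue_ids, int)

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]

    def value(self, res_i: int, res_j: int) -> float:
        i = int(np.flatnonzero(self.residue_ids == res_i)[0])
        j = int(np.flatnonzero(self.residue_ids == res_j)[0])
        return float(self.matrix[i, j])


def dccm(
    trajectory: Trajectory,
    selection: Selection,
    fit_selection: Selection | None = None,
) -> CorrelationMatrix:
    """Residue displacement cross-correlation matrix over a trajectory.

    ``selection`` picks one atom per residue (alpha-carbon convention).
    Frames are superposed onto their iterated mean before displacements are
    accumulated, so rigid-body motion does not masquerade as correlation.
    Residues with zero total fluctuation get 0 off-diagonal / 1 on the
    diagonal, with a warning.
    """
    if len(selection) == 0:
        raise ValueError("selection must be non-empty")
    if fit_selection is None:
        fit_selection = selection
    aligned = superpose_to_mean(trajectory, fit_selection)
    idx = selection.as_array()
    sub = aligned[:, idx, :]  # (F, n, 3)
    disp = sub - sub.mean(axis=0)
    inner = np.einsum("fid,fjd->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner).copy()
    zero = var <= 1e-18  # RMS fluctuation below 1e-9 Å counts as frozen
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} residue(s) with zero fluctuation; "
            "correlation rows zeroed",
            stacklevel=2,
        )
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    C = inner / denom
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    res_ids = np.array([trajectory.topology.residue_of_atom(i) for i in idx])
    return CorrelationMatrix(matrix=C, residue_ids=res_ids)


def mask_correlations(matrix: CorrelationMatrix, threshold: float) -> CorrelationMatrix:
    """Mask weak entries: |C_ij| < threshold become NaN; the diagonal stays."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("mask threshold must lie in [0, 1]")
    M = matrix.matrix.copy()
    weak = np.abs(M) < threshold
    np.fill_diagonal(weak, False)
    M[weak] = np.nan
    return CorrelationMatrix(
        matrix=M, residue_ids=matrix.residue_ids, mask_threshold=threshold
    )


def region_correlation_summary(
    matrix: CorrelationMatrix, region_a, region_b
) -> dict:
    """Block statistics between two residue-id regions.

    Returns mean, mean absolute value, and fraction-positive over the
    region_a × region_b submatrix; diagonal entries are excluded when the
    regions overlap.  Quantifies claims like "correlated movement between the
    loop and the hinge".
    """
    region_a = list(region_a)
    region_b = list(region_b)
    if not region_a or not region_b:
        raise ValueError("regions must be non-empty")
    pos = {rid: i for i, rid in enumerate(matrix.residue_ids)}
    missing = [r for r in list(region_a) + list(region_b) if r not in pos]
    if missing:
        raise ValueError(f"residues absent from matrix: {sorted(set(missing))}")
    ia = np.array([pos[r] for r in region_a])
    ib = np.array([pos[r] for r in region_b])
    block = matrix.matrix[np.ix_(ia, ib)]
    keep = ~np.equal.outer(ia, ib)  # drop self-pairs on overlap
    values = block[keep & np.isfinite(block)]
    if values.size == 0:
        return {"mean": np.nan, "mean_abs": np.nan, "fraction_positive": np.nan, "n": 0}
    return {
        "mean": float(values.mean()),
        "mean_abs": float(np.abs(values).mean()),
        "fraction_positive": float((values > 0).mean()),
        "n": int(values.size),
    }


def average_correlation_matrices(matrices: list[CorrelationMatrix]) -> CorrelationMatrix:
    """Element-wise average of per-replica DCCMs, re-clipped to [−1, 1]."""
    if not matrices:
        raise ValueError("no matrices to average")
    ids = matrices[0].residue_ids
    for m in matrices[1:]:
        if not np.array_equal(m.residue_ids, ids):
            raise ValueError("matrices cover different residue sets")
    avg = np.clip(np.mean([m.matrix for m in matrices], axis=0), -1.0, 1.0)
    np.fill_diagonal(avg, 1.0)
    return CorrelationMatrix(matrix=avg, residue_ids=ids)


def write_correlation_tsv(matrix: CorrelationMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.matrix, index=matrix.residue_ids, columns=matrix.residue_ids
    )
    df.to_csv(path, sep="\t", index_label="residue_id")


def read_correlation_tsv(path) -> CorrelationMatrix:
    df = pd.read_csv(path, sep="\t", index_col="residue_id")
    return CorrelationMatrix(
        matrix=df.to_numpy(float), residue_ids=df.index.to_numpy(int)
    )
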