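"""MM/GBSA combination, per-residue decomposition, and interaction geometry.

End-point binding free energies are assembled from per-frame additive
components for the complex, receptor, and ligand species:

    ΔG_bind = ΔE_internal + ΔE_elec + ΔE_vdW + ΔG_pol + ΔG_np   (−TΔS omitted)

with Δcomponent = complex − receptor − ligand per frame.  In the
single-trajectory convention all three species come from the same frames,
so the internal (bond/angle/dihedral) terms cancel exactly.  The entropy
term is deliberately left out: normal-mode estimates are noisy, and for
structurally similar complexes the comparison is dominated by the enthalpic
terms.

This module does not solve a Generalized-Born model; polar solvation enters
as data (from files or the synthetic generator).  A toy pairwise
Coulomb + Lennard-Jones evaluator stands in as a producer of per-residue
interaction tables, and a geometric hydrogen-bond occupancy completes the
interaction bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import COULOMB_CONSTANT
from .traj import Selection, Trajectory

__all__ = [
    "ENERGY_COMPONENTS",
    "EnergyTable",
    "BindingEnergyResult",
    "ResidueContribution",
    "mmgbsa_combine",
    "per_residue_decompose",
    "toy_pair_energy",
    "hbond_occupancy",
    "read_energy_table_tsv",
    "write_energy_table_tsv",
]

ENERGY_COMPONENTS = ("E_internal", "E_elec", "E_vdw", "G_pol", "G_np")


@dataclass
class EnergyTable:
    """Per-frame additive energy components (kcal/mol) for one species."""

    components: dict  # name -> (n_frames,) array
    species: str = ""

    def __post_init__(self):
        if not self.components:
            raise ValueError("energy table needs at least one component")
        lengths = {len(np.asarray(v)) for v in self.components.values()}
        if len(lengths) > 1:
            raise ValueError("all components must have equal frame counts")
        for name, values in self.components.items():
            arr = np.asarray(values, float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"component {name} has non-finite values")
            self.components[name] = arr

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.components.values())))

    def component(self, name: str) -> np.ndarray:
        return self.components.get(name, np.zeros(self.n_frames))


@dataclass(frozen=True)
class BindingEnergyResult:
    """Δ-component means ± sd and the (entropy-free) total binding energy."""

    component_means: dict  # name -> mean (kcal/mol)
    component_sds: dict
    total_mean: float
    total_sd: float
    n_frames: int

    def __post_init__(self):
        # additivity is this module's conservation law
        assert abs(self.total_mean - sum(self.component_means.values())) < 1e-10


@dataclass(frozen=True)
class ResidueContribution:
    residue_id: int
    contribution: float  # kcal/mol, mean over frames
    significant: bool


def mmgbsa_combine(
    complex_table: EnergyTable,
    receptor_table: EnergyTable,
    ligand_table: EnergyTable,
) -> BindingEnergyResult:
    """Combine per-frame species tables into ΔG_binding = Σ Δ-component means.

    Δcomponent_f = complex_f − receptor_f − ligand_f; means and sample
    standard deviations are taken over frames; the reported total is the sum
    of the component means (equivalently the mean of the per-frame totals),
    with the entropy term omitted.
    """
    n = complex_table.n_frames
    if receptor_table.n_frames != n or ligand_table.n_frames != n:
        raise ValueError(
            f"frame counts differ: complex {n}, receptor "
            f"{receptor_table.n_frames}, ligand {ligand_table.n_frames}"
        )
    means, sds = {}, {}
    total_per_frame = np.zeros(n)
    for comp in ENERGY_COMPONENTS:
        delta = (
            complex_table.component(comp)
            - receptor_table.component(comp)
            - ligand_table.component(comp)
        )
        means[comp] = float(delta.mean())
        sds[comp] = float(delta.std(ddof=1)) if n > 1 else 0.0
        total_per_frame += delta
    return BindingEnergyResult(
        component_means=means,
        component_sds=sds,
        total_mean=float(sum(means.values())),
        total_sd=float(total_per_frame.std(ddof=1)) if n > 1 else 0.0,
        n_frames=n,
    )


def per_residue_decompose(
    pairwise_energy_table: pd.DataFrame, threshold: float = 1.0
) -> list[ResidueContribution]:
    """Per-residue mean interaction energies with a significance threshold.

    Input: a long table with columns ``frame``, ``residue_id``, ``energy``
    giving each residue's interaction energy with the ligand in each frame.
    Output contributions sum to the mean total interaction energy exactly.
    A residue is flagged significant when |mean contribution| ≥ ``threshold``
    (two-sided — strongly unfavorable residues are reported too).
    """
    df = pairwise_energy_table
    required = {"frame", "residue_id", "energy"}
    if not required.issubset(df.columns):
        raise ValueError(f"pairwise energy table needs columns {sorted(required)}")
    if df.duplicated(subset=["frame", "residue_id"]).any():
        dupes = df[df.duplicated(subset=["frame", "residue_id"])]["residue_id"].unique()
        raise ValueError(f"duplicated residue ids in table: {sorted(map(int, dupes))}")
    means = df.groupby("residue_id")["energy"].mean()
    return [
        ResidueContribution(
            residue_id=int(rid),
            contribution=float(mean),
            significant=bool(abs(mean) >= threshold),
        )
        for rid, mean in means.items()
    ]


def toy_pair_energy(
    complex_frame: np.ndarray,
    charges: np.ndarray,
    lj_params: np.ndarray,
    dielectric: float = 1.0,
    nonpolar_gamma: float = 0.0,
    nonpolar_cutoff: float = 4.5,
) -> np.ndarray:
    """Pairwise Coulomb + Lennard-Jones (+ contact non-polar) energy matrix.

    E_ij = k_e·q_i q_j/(ε·r_ij) + 4ε_ij[(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶]
           + γ·[r_ij < cutoff]

    ``lj_params`` is (n, 2): per-particle (σ_i Å, ε_i kcal/mol), combined by
    Lorentz–Berthelot rules (arithmetic σ, geometric ε).  Returns the
    symmetric (n, n) matrix with zero diagonal; the total interaction energy
    is half its sum.  No periodicity; coincident particles are an error.
    """
    X = np.asarray(complex_frame, float)
    q = np.asarray(charges, float)
    lj = np.asarray(lj_params, float)
    n = X.shape[0]
    if q.shape != (n,) or lj.shape != (n, 2):
        raise ValueError("charges must be (n,) and lj_params (n, 2)")
    diff = X[:, None, :] - X[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] == 0.0):
        raise ValueError("coincident particles (r = 0) in pair energy")
    with np.errstate(divide="ignore", invalid="ignore"):
        coulomb = COULOMB_CONSTANT * np.outer(q, q) / (dielectric * r)
        sigma = 0.5 * (lj[:, 0][:, None] + lj[:, 0][None, :])
        eps = np.sqrt(np.outer(lj[:, 1], lj[:, 1]))
        sr6 = (sigma / r) ** 6
        lj_energy = 4.0 * eps * (sr6**2 - sr6)
        nonpolar = nonpolar_gamma * (r < nonpolar_cutoff)
    E = coulomb + lj_energy + nonpolar
    E[~off] = 0.0
    return E


def hbond_occupancy(
    trajectory: Trajectory,
    donor_selection: Selection,
    acceptor_selection: Selection,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    hydrogen_selection: Selection | None = None,
) -> pd.DataFrame:
    """Geometric hydrogen-bond occupancy per donor–acceptor pair.

    A frame counts when the donor-heavy-atom → acceptor distance is ≤
    ``dist_cutoff`` Å and, if ``hydrogen_selection`` supplies one hydrogen
    per donor (parallel order), the donor–H–acceptor angle is ≥
    ``angle_cutoff`` degrees; without hydrogens the criterion is
    distance-only.  Returns a table (donor, acceptor, occupancy) with
    occupancy = satisfied-frame fraction in [0, 1].
    """
    if len(donor_selection) == 0 or len(acceptor_selection) == 0:
        raise ValueError("donor and acceptor selections must be non-empty")
    if hydrogen_selection is not None and len(hydrogen_selection) != len(donor_selection):
        raise ValueError("hydrogen selection must parallel the donor selection")
    coords = trajectory.coordinates
    d_idx = donor_selection.as_array()
    a_idx = acceptor_selection.as_array()
    D = coords[:, d_idx, :]  # (F, nd, 3)
    A = coords[:, a_idx, :]  # (F, na, 3)
    diff = D[:, :, None, :] - A[:, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=3))  # (F, nd, na)
    ok = dist <= dist_cutoff
    if hydrogen_selection is not None:
        H = coords[:, hydrogen_selection.as_array(), :]
        v1 = D - H  # H->D
        v2 = A[:, None, :, :] - H[:, :, None, :]  # H->A
        cos = (v1[:, :, None, :] * v2).sum(axis=3) / (
            np.linalg.norm(v1, axis=2)[:, :, None] * np.linalg.norm(v2, axis=3) + 1e-12
        )
        angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        ok = ok & (angle >= angle_cutoff)
    occ = ok.mean(axis=0)
    top = trajectory.topology
    rows = []
    for i, di in enumerate(d_idx):
        for j, aj in enumerate(a_idx):
            if di == aj:
                continue
            rows.append(
                {
                    "donor": int(di),
                    "acceptor": int(aj),
                    "donor_residue": top.residue_of_atom(di),
                    "acceptor_residue": top.residue_of_atom(aj),
                    "occupancy": float(occ[i, j]),
                }
            )
    return pd.DataFrame(rows)


def write_energy_table_tsv(table: EnergyTable, path) -> None:
    """Long-form TSV: frame, component, value, species."""
    rows = []
    for comp, values in table.components.items():
        for f, v in enumerate(values):
            rows.append((f, comp, v, table.species))
    pd.DataFrame(rows, columns=["frame", "component", "value", "species"]).to_csv(
        path, sep="\t", index=False
    )


def read_energy_table_tsv(path) -> EnergyTable:
    df = pd.read_csv(path, sep="\t")
    species = str(df["species"].iloc[0]) if "species" in df and len(df) else ""
    components = {
        comp: grp.sort_values("frame")["value"].to_numpy()
        for comp, grp in df.groupby("component")
    }
    return EnergyTable(components=components, species=species)
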