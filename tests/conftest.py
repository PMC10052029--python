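import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import kinetraj as kt


@pytest.fixture(scope="session")
def loop_system():
    """Two-lobe bead protein with a plantable open/closed loop."""
    top, open_frame, closed_frame = kt.synth.make_loop_protein(50, (10, 17), seed=1)
    return top, open_frame, closed_frame


LOOP_SELECTIONS = {
    "fit": "calpha and not resid 10-17",
    "report": "calpha",
    "loop": "calpha and resid 10-17",
    "hinge": "calpha and resid 26-28",
    "ligand": "ligand",
}


@pytest.fixture(scope="session")
def two_system_reports(loop_system):
    """Pipeline reports for an 'open' and a 'closed' synthetic system.

    The open system's loop dwells near the open conformation and fluctuates;
    the closed system's loop stays folded onto the ligand — the planted
    qualitative contrast between a ligand-free and an inhibitor-bound kinase.
    """
    top, open_frame, closed_frame = loop_system
    rng = np.random.default_rng(0)
    path_open = np.clip(0.15 + 0.1 * rng.standard_normal(300), 0.0, 0.5)
    path_closed = np.clip(0.99 + 0.01 * rng.standard_normal(300), 0.95, 1.0)
    traj_open = kt.synth.interpolate_trajectory(
        open_frame, closed_frame, path_open, topology=top, jitter_sigma=0.15, seed=1
    )
    traj_closed = kt.synth.interpolate_trajectory(
        open_frame, closed_frame, path_closed, topology=top, jitter_sigma=0.15, seed=2
    )
    report_open = kt.pipeline.run_pipeline(
        kt.pipeline.RunConfig(trajectory=traj_open, selections=LOOP_SELECTIONS, seed=1)
    )
    report_closed = kt.pipeline.run_pipeline(
        kt.pipeline.RunConfig(trajectory=traj_closed, selections=LOOP_SELECTIONS, seed=1)
    )
    return report_open, report_closed


@pytest.fixture(scope="session")
def planted_block_dccm():
    """DCCM estimated from a planted ±-correlated two-block displacement field."""
    planted = kt.synth.PlantedCovariance(
        blocks=(tuple(range(10)), tuple(range(10, 20))),
        intra_correlation=0.9,
        inter_correlation=-0.8,
    )
    traj = kt.synth.sample_correlated_displacements(planted, 5000, seed=2)
    sel = kt.traj.select(traj.topology, "resid 1-20")
    fit = kt.traj.select(traj.topology, "resid 21-24")
    return planted, kt.correlation.dccm(traj, sel, fit)
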