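"""Synthetic-system generators: planted truth must be recoverable."""

import numpy as np
import pytest

import kinetraj as kt
from kinetraj.synth import (
    PlantedCovariance,
    WellSpec,
    interpolate_trajectory,
    make_energy_tables,
    make_loop_protein,
    sample_correlated_displacements,
    sample_markov_chain,
    sample_overdamped_dynamics,
    stationary_well_occupancy,
)


class TestOverdampedDynamics:
    def test_symmetric_double_well_equal_occupancy(self):
        # fast-mixing regime: shallow wells, warm, coarse (but stable) step
        ws = WellSpec(
            centers=((-2.0,), (2.0,)),
            depths=(1.0, 1.0),
            widths=(1.0, 1.0),
            temperature=600.0,
            friction=0.5,
            timestep=0.4,
        )
        paths = [sample_overdamped_dynamics(ws, 100_000, seed=s) for s in (1, 2)]
        occ = np.bincount(
            ws.assign_well(np.concatenate(paths)), minlength=2
        ) / sum(len(p) for p in paths)
        assert abs(occ[0] - 0.5) < 0.02

    def test_zero_temperature_stays_in_starting_well(self):
        ws = WellSpec(
            centers=((-2.0,), (2.0,)),
            depths=(2.0, 2.0),
            widths=(1.0, 1.0),
            temperature=1e-9,
            timestep=0.05,
        )
        path = sample_overdamped_dynamics(ws, 5000, seed=0, x0=np.array([-2.0]))
        assert np.all(ws.assign_well(path) == 0)

    def test_asymmetric_well_matches_quadrature_boltzmann_weight(self):
        ws = WellSpec(
            centers=((-2.0,), (2.0,)),
            depths=(2.0, 4.0),
            widths=(1.0, 1.0),
            temperature=300.0,
            friction=0.5,
            timestep=0.05,
        )
        theory = stationary_well_occupancy(ws)
        paths = [
            sample_overdamped_dynamics(ws, 250_000, seed=s, x0=np.array([2.0]))
            for s in (1, 2)
        ]
        occ = np.bincount(
            ws.assign_well(np.concatenate(paths)), minlength=2
        ) / sum(len(p) for p in paths)
        assert abs(occ[0] - theory[0]) < 0.025

    def test_unstable_timestep_rejected(self):
        ws = WellSpec(
            centers=((-1.0,), (1.0,)),
            depths=(5.0, 5.0),
            widths=(0.3,) * 2,
            timestep=1.0,
        )
        with pytest.raises(ValueError, match="stability"):
            sample_overdamped_dynamics(ws, 10, seed=0)

    def test_wellspec_validation(self):
        with pytest.raises(ValueError, match="2 wells"):
            WellSpec(centers=((0.0,),), depths=(1.0,), widths=(1.0,))
        with pytest.raises(ValueError, match="positive"):
            WellSpec(centers=((0.0,), (1.0,)), depths=(1.0, -1.0), widths=(1.0, 1.0))


class TestLoopProtein:
    def test_non_loop_residues_identical_between_frames(self, loop_system):
        top, open_frame, closed_frame = loop_system
        loop = np.arange(9, 17)
        mask = np.ones(top.n_atoms, bool)
        mask[loop] = False
        np.testing.assert_array_equal(open_frame[mask], closed_frame[mask])

    def test_closed_loop_is_nearer_the_ligand(self, loop_system):
        top, open_frame, closed_frame = loop_system
        loop = np.arange(9, 17)
        lig = open_frame[-1]
        d_open = np.linalg.norm(open_frame[loop] - lig, axis=1).min()
        d_closed = np.linalg.norm(closed_frame[loop] - lig, axis=1).min()
        assert d_closed < d_open

    def test_loop_rmsd_equals_planted_displacement_norm(self, loop_system):
        top, open_frame, closed_frame = loop_system
        loop = np.arange(9, 17)
        disp = closed_frame[loop] - open_frame[loop]
        expected = np.linalg.norm(disp) / np.sqrt(len(loop))
        plain_rmsd = np.sqrt(((disp) ** 2).sum(axis=1).mean())
        assert plain_rmsd == pytest.approx(expected, abs=1e-12)

    def test_bad_loop_span_rejected(self):
        with pytest.raises(ValueError, match="outside residue range"):
            make_loop_protein(20, (15, 25), seed=0)


class TestInterpolation:
    def test_constant_open_path_reproduces_open_frame(self, loop_system):
        top, open_frame, closed_frame = loop_system
        traj = interpolate_trajectory(
            open_frame, closed_frame, np.zeros(5), topology=top
        )
        for f in range(5):
            np.testing.assert_array_equal(traj.coordinates[f], open_frame)

    def test_unit_path_value_reaches_closed_frame(self, loop_system):
        top, open_frame, closed_frame = loop_system
        traj = interpolate_trajectory(
            open_frame, closed_frame, np.array([0.0, 1.0]), topology=top
        )
        np.testing.assert_allclose(traj.coordinates[1], closed_frame, atol=1e-10)

    def test_out_of_range_path_rejected(self, loop_system):
        top, open_frame, closed_frame = loop_system
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            interpolate_trajectory(open_frame, closed_frame, np.array([1.2]))

    def test_jitter_gives_isotropic_rmsf(self, loop_system):
        # E||dr||^2 = 3 sigma^2 for isotropic Gaussian displacement
        top, open_frame, closed_frame = loop_system
        sigma = 0.2
        traj = interpolate_trajectory(
            open_frame,
            closed_frame,
            np.zeros(2000),
            topology=top,
            jitter_sigma=sigma,
            seed=3,
        )
        sel = kt.traj.select(top, "calpha and not resid 10-17")
        _, fluct = kt.stability.rmsf(traj, sel, sel)
        assert fluct.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)


class TestMarkovChain:
    def test_identity_matrix_is_constant(self):
        seq = sample_markov_chain(np.eye(4), 50, seed=0, start_state=2)
        assert np.all(seq == 2)

    def test_permutation_matrix_alternates(self):
        seq = sample_markov_chain(np.array([[0.0, 1.0], [1.0, 0.0]]), 100, seed=0, start_state=0)
        np.testing.assert_array_equal(seq[::2], 1 - seq[1::2])
        assert set(np.unique(seq)) == {0, 1}

    def test_empirical_stationary_distribution(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        seq = sample_markov_chain(T, 100_000, seed=3)
        emp = np.bincount(seq, minlength=2) / len(seq)
        np.testing.assert_allclose(emp, [2 / 3, 1 / 3], atol=0.01)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sample_markov_chain(np.array([[1.5, -0.5], [0.5, 0.5]]), 10, seed=0)
        with pytest.raises(ValueError, match="sum to 1"):
            sample_markov_chain(np.array([[0.5, 0.4], [0.5, 0.5]]), 10, seed=0)


class TestCorrelatedDisplacements:
    def test_perfect_correlation_gives_proportional_displacements(self):
        planted = PlantedCovariance(
            blocks=((0, 1),), intra_correlation=1.0, inter_correlation=0.0
        )
        traj = sample_correlated_displacements(planted, 200, seed=0)
        disp = traj.coordinates[:, :2, :] - traj.coordinates[:, :2, :].mean(axis=0)
        # both residues share one latent field: displacement vectors equal
        np.testing.assert_allclose(disp[:, 0, :], disp[:, 1, :], atol=1e-10)

    def test_zero_correlation_vanishes_with_sampling_error(self):
        n = 4000
        planted = PlantedCovariance(
            blocks=((0,), (1,)), intra_correlation=0.9, inter_correlation=0.0
        )
        traj = sample_correlated_displacements(planted, n, seed=1)
        sel = kt.traj.select(traj.topology, "resid 1-2")
        fit = kt.traj.select(traj.topology, "resid 3-6")
        C = kt.correlation.dccm(traj, sel, fit)
        assert abs(C.matrix[0, 1]) < 3 / np.sqrt(n)

    @pytest.mark.parametrize(
        "intra,inter",
        [(0.9, -0.8), (0.7, 0.2), (0.95, -0.5)],
    )
    def test_block_correlations_recovered(self, intra, inter):
        planted = PlantedCovariance(
            blocks=(tuple(range(8)), tuple(range(8, 16))),
            intra_correlation=intra,
            inter_correlation=inter,
        )
        traj = sample_correlated_displacements(planted, 5000, seed=4)
        sel = kt.traj.select(traj.topology, "resid 1-16")
        fit = kt.traj.select(traj.topology, "resid 17-20")
        C = kt.correlation.dccm(traj, sel, fit)
        intra_m = kt.correlation.region_correlation_summary(C, range(1, 9), range(1, 9))
        inter_m = kt.correlation.region_correlation_summary(C, range(1, 9), range(9, 17))
        assert intra_m["mean"] == pytest.approx(intra, abs=0.05)
        assert inter_m["mean"] == pytest.approx(inter, abs=0.05)

    def test_non_psd_covariance_rejected_at_construction(self):
        with pytest.raises(ValueError, match="PSD"):
            PlantedCovariance(
                blocks=((0,), (1,), (2,)),
                intra_correlation=1.0,
                inter_correlation=-0.9,
            )


class TestEnergyTables:
    def test_zero_sd_reproduces_planted_totals_exactly(self):
        means = {
            "complex": {"E_elec": -47.72, "E_vdw": -18.60, "G_pol": 41.28, "G_np": -5.82}
        }
        cpx, rec, lig = make_energy_tables(means, 0.0, 10, seed=0)
        result = kt.energetics.mmgbsa_combine(cpx, rec, lig)
        assert result.total_mean == pytest.approx(-30.86, abs=1e-10)

    def test_planted_mean_recovery_within_clt_bound(self):
        n, sd = 1000, 3.0
        means = {"complex": {"E_vdw": -20.0}, "receptor": {"E_vdw": -5.0}}
        cpx, rec, lig = make_energy_tables(means, sd, n, seed=5)
        assert cpx.component("E_vdw").mean() == pytest.approx(
            -20.0, abs=4 * sd / np.sqrt(n)
        )
        result = kt.energetics.mmgbsa_combine(cpx, rec, lig)
        assert result.component_means["E_vdw"] == pytest.approx(
            -15.0, abs=4 * sd * np.sqrt(3) / np.sqrt(n)
        )

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            make_energy_tables({}, 1.0, 1, seed=0)


class TestDeterminism:
    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_generators_are_pure_functions_of_seed(self, seed):
        ws = WellSpec(
            centers=((-2.0,), (2.0,)), depths=(1.0, 1.0), widths=(1.0, 1.0), timestep=0.05
        )
        p1 = sample_overdamped_dynamics(ws, 500, seed=seed)
        p2 = sample_overdamped_dynamics(ws, 500, seed=seed)
        np.testing.assert_array_equal(p1, p2)
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        np.testing.assert_array_equal(
            sample_markov_chain(T, 500, seed=seed),
            sample_markov_chain(T, 500, seed=seed),
        )
        planted = PlantedCovariance(blocks=((0, 1), (2, 3)))
        t1 = sample_correlated_displacements(planted, 50, seed=seed)
        t2 = sample_correlated_displacements(planted, 50, seed=seed)
        np.testing.assert_array_equal(t1.coordinates, t2.coordinates)
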