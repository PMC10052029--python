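"""Markov state models: estimation, validation, coarse-graining, kinetics."""

import numpy as np
import pytest

import kinetraj as kt
from kinetraj.msm import (
    chapman_kolmogorov,
    cluster_microstates,
    estimate_transition_matrix,
    from_transition_matrix,
    implied_timescales,
    mfpt,
    pcca_metastates,
    representative_frames,
)
from kinetraj.synth import sample_markov_chain
from oracles import simulate_first_passage_times

TWO_STATE = np.array([[0.9, 0.1], [0.2, 0.8]])
THREE_STATE = np.array([[0.9, 0.08, 0.02], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])


def _block_chain(block_size=3, n_blocks=3, intra=0.98, inter=0.01):
    n = block_size * n_blocks
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            T[i, j] = (
                intra / block_size
                if i // block_size == j // block_size
                else inter / (n - block_size)
            )
        T[i] /= T[i].sum()
    return T


class TestClustering:
    def test_separated_clouds_partition_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(50, 2)) + [0, 0]
        b = rng.normal(size=(50, 2)) + [20, 0]
        labels = cluster_microstates(np.vstack([a, b]), k=2, seed=0)
        assert len(set(labels[:50])) == 1
        assert len(set(labels[50:])) == 1
        assert labels[0] != labels[50]

    def test_single_cluster_disallowed(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_microstates(np.zeros((10, 2)), k=1)

    def test_same_seed_reproduces_labels(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        l1 = cluster_microstates(X, k=5, seed=42)
        l2 = cluster_microstates(X, k=5, seed=42)
        np.testing.assert_array_equal(l1, l2)

    def test_k_exceeding_distinct_points_rejected(self):
        X = np.repeat(np.arange(3.0)[:, None], 4, axis=0)
        with pytest.raises(ValueError, match="distinct"):
            cluster_microstates(X, k=5)


class TestTransitionEstimation:
    def test_alternating_sequence_gives_permutation_matrix(self):
        labels = np.tile([0, 1], 50)
        model = estimate_transition_matrix(labels, lag=1, mode="raw")
        np.testing.assert_allclose(
            model.transition_matrix, [[0.0, 1.0], [1.0, 0.0]], atol=1e-12
        )

    def test_planted_chain_recovered_entrywise(self):
        chain = sample_markov_chain(TWO_STATE, 100_000, seed=1)
        model = estimate_transition_matrix(chain, lag=1, mode="raw")
        np.testing.assert_allclose(model.transition_matrix, TWO_STATE, atol=0.01)

    def test_rows_sum_to_one(self):
        chain = sample_markov_chain(THREE_STATE, 5000, seed=2)
        for mode in ("raw", "symmetrized"):
            model = estimate_transition_matrix(chain, lag=2, mode=mode)
            np.testing.assert_allclose(
                model.transition_matrix.sum(axis=1), 1.0, atol=1e-10
            )
            assert model.eigenvalues[0] == pytest.approx(1.0, abs=1e-8)
            pi = model.stationary_distribution
            np.testing.assert_allclose(
                pi @ model.transition_matrix, pi, atol=1e-8
            )

    def test_counts_never_cross_replica_boundaries(self):
        # replica 1 ends in 0, replica 2 starts in 1: no 0->1 count at lag 1
        replicas = [np.array([0, 0, 0]), np.array([1, 1, 1])]
        model = estimate_transition_matrix(replicas, lag=1, mode="raw")
        # both states survive trimming only if connected; here they are not,
        # so the larger/first component is kept alone
        assert model.n_states == 1

    def test_symmetrized_estimate_satisfies_detailed_balance(self):
        chain = sample_markov_chain(THREE_STATE, 20_000, seed=3)
        model = estimate_transition_matrix(chain, lag=1, mode="symmetrized")
        pi = model.stationary_distribution
        T = model.transition_matrix
        flux = pi[:, None] * T
        np.testing.assert_allclose(flux, flux.T, atol=1e-8)

    def test_lag_exceeding_replica_length_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            estimate_transition_matrix(np.array([0, 1, 0]), lag=3)


class TestImpliedTimescales:
    def test_closed_form_timescale_from_eigenvalue(self):
        # deterministic 2-state chain with lambda_2 = exp(-1)
        lam2 = np.exp(-1)
        p = (1 - lam2) / 2
        T = np.array([[1 - p, p], [p, 1 - p]])
        model = from_transition_matrix(T, lag=1)
        t2 = -1.0 / np.log(abs(np.real(model.eigenvalues[1])))
        assert t2 == pytest.approx(1.0, abs=1e-12)

    def test_markov_data_gives_flat_timescales(self):
        chain = sample_markov_chain(TWO_STATE, 100_000, seed=4)
        lam2 = np.sort(np.linalg.eigvals(TWO_STATE))[0].real  # 0.7
        exact = -1.0 / np.log(abs(lam2))
        table = implied_timescales(chain, lags=[1, 2, 3, 5], n_timescales=1)
        ts = table[table["defined"]]["timescale"].to_numpy()
        assert len(ts) == 4
        np.testing.assert_allclose(ts, exact, rtol=0.1)

    def test_negative_eigenvalue_reported_undefined(self):
        labels = np.tile([0, 1], 500)  # lambda_2 = -1
        table = implied_timescales(labels, lags=[1], n_timescales=1, mode="raw")
        assert not table["defined"].iloc[0]

    def test_empty_lag_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            implied_timescales(np.array([0, 1, 0, 1]), lags=[])


class TestChapmanKolmogorov:
    def test_exact_propagation_identity_for_true_chain(self):
        # the CK identity T(n*tau) = T(tau)^n holds exactly for a Markov matrix
        T = THREE_STATE
        np.testing.assert_allclose(
            np.linalg.matrix_power(T, 3),
            np.linalg.matrix_power(np.linalg.matrix_power(T, 1), 3),
            atol=1e-14,
        )

    def test_markov_chain_passes(self):
        chain = sample_markov_chain(TWO_STATE, 100_000, seed=5)
        ck = chapman_kolmogorov(chain, lag=1, n_multiples=10, n_metastates=2)
        assert ck["passed"], f"max deviation {ck['max_deviation']}"

    def test_lumped_hidden_state_fails(self):
        # hide one metastable state of a 3-state chain: the lumped
        # 2-state process is non-Markovian and CK must detect it
        T3 = np.array(
            [[0.9, 0.1, 0.0], [0.1, 0.88, 0.02], [0.0, 0.02, 0.98]]
        )
        hidden = sample_markov_chain(T3, 100_000, seed=6)
        lumped = np.where(hidden == 0, 0, 1)
        ck = chapman_kolmogorov(lumped, lag=1, n_multiples=10, n_metastates=2)
        assert not ck["passed"], f"max deviation {ck['max_deviation']}"


class TestPCCA:
    def test_three_block_chain_recovered_crisply(self):
        chain = sample_markov_chain(_block_chain(), 50_000, seed=7)
        model = estimate_transition_matrix(chain, lag=1)
        part = pcca_metastates(model, 3)
        # microstates of the same planted block share a metastate
        blocks = model.active_states // 3
        for b in range(3):
            assigned = part.crisp_assignment[blocks == b]
            assert len(set(assigned)) == 1
        assert len(set(part.crisp_assignment)) == 3

    def test_one_metastate_per_microstate_is_a_permutation(self):
        chain = sample_markov_chain(TWO_STATE, 5000, seed=8)
        model = estimate_transition_matrix(chain, lag=1)
        part = pcca_metastates(model, model.n_states)
        perm = part.memberships
        np.testing.assert_allclose(perm.sum(axis=0), 1.0, atol=1e-6)
        np.testing.assert_allclose(perm.sum(axis=1), 1.0, atol=1e-8)
        assert set(part.crisp_assignment) == set(range(model.n_states))

    def test_membership_rows_sum_to_one(self):
        chain = sample_markov_chain(_block_chain(), 20_000, seed=9)
        model = estimate_transition_matrix(chain, lag=1)
        part = pcca_metastates(model, 2)
        np.testing.assert_allclose(part.memberships.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(part.memberships >= 0) and np.all(part.memberships <= 1)

    def test_reducible_matrix_rejected(self):
        T = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = from_transition_matrix(T)
        with pytest.raises(ValueError, match="reducible"):
            pcca_metastates(model, 2)


class TestMFPT:
    def test_two_state_geometric_closed_form(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        model = from_transition_matrix(T, lag=1)
        assert mfpt(model, [0], [1]).lag_units == pytest.approx(10.0, abs=1e-9)

    def test_source_equals_sink_is_zero(self):
        model = from_transition_matrix(TWO_STATE)
        assert mfpt(model, [1], [1]).lag_units == 0.0

    def test_three_state_matches_simulated_first_passages(self):
        model = from_transition_matrix(THREE_STATE, lag=1)
        analytic = mfpt(model, [0], [2]).lag_units
        simulated = simulate_first_passage_times(
            THREE_STATE, 0, [2], n_walkers=100_000, seed=10
        ).mean()
        assert analytic == pytest.approx(simulated, rel=0.02)

    def test_unreachable_sink_reported_infinite(self):
        T = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.1, 0.1, 0.8]])
        model = from_transition_matrix(T)
        res = mfpt(model, [0], [2])
        assert not res.reachable and np.isinf(res.lag_units)

    def test_physical_units_use_lag_and_frame_interval(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        model = from_transition_matrix(T, lag=3, frame_interval=0.5)
        res = mfpt(model, [0], [1])
        assert res.physical == pytest.approx(10.0 * 3 * 0.5)

    def test_monotone_in_direct_transition_probability(self):
        # raising the direct source->sink probability can only speed passage
        rng = np.random.default_rng(11)
        for _ in range(10):
            T = rng.dirichlet(np.ones(4), size=4)
            base = mfpt(from_transition_matrix(T), [0], [3]).lag_units
            T2 = T.copy()
            boost = 0.5 * (1 - T2[0, 3])
            T2[0, :3] *= (1 - T2[0, 3] - boost) / T2[0, :3].sum()
            T2[0, 3] += boost
            T2[0] /= T2[0].sum()
            faster = mfpt(from_transition_matrix(T2), [0], [3]).lag_units
            assert faster <= base + 1e-9


class TestRepresentativeFrames:
    def test_single_frame_metastate_returns_that_frame(self):
        labels = np.array([0, 0, 0, 1])
        proj = np.array([[0.0], [0.1], [-0.1], [5.0]])
        model = estimate_transition_matrix(
            np.array([0, 0, 1, 0, 0, 1, 0]), lag=1
        )
        part = pcca_metastates(model, 2)
        reps = representative_frames(part, labels, proj)
        meta_of_1 = part.crisp_assignment[list(part.active_states).index(1)]
        assert reps[meta_of_1] == 3

    def test_equidistant_tie_breaks_to_lower_index(self):
        labels = np.array([0, 0, 1, 1])
        proj = np.array([[1.0], [-1.0], [10.0], [10.0]])
        model = estimate_transition_matrix(
            np.array([0, 1, 0, 1, 0, 0, 1]), lag=1
        )
        part = pcca_metastates(model, 2)
        reps = representative_frames(part, labels, proj)
        meta_of_0 = part.crisp_assignment[list(part.active_states).index(0)]
        assert reps[meta_of_0] == 0  # frames 0 and 1 equidistant from centroid 0

    def test_gaussian_cloud_representative_is_near_centroid(self):
        rng = np.random.default_rng(12)
        chain = sample_markov_chain(_block_chain(block_size=2, n_blocks=2), 2000, seed=13)
        proj = rng.normal(size=(2000, 2)) + chain[:, None] * 3.0
        model = estimate_transition_matrix(chain, lag=1)
        part = pcca_metastates(model, 2)
        reps = representative_frames(part, chain, proj)
        label_to_meta = {
            int(s): int(part.crisp_assignment[i])
            for i, s in enumerate(part.active_states)
        }
        frame_meta = np.array([label_to_meta[int(s)] for s in chain])
        for m, frame in reps.items():
            members = np.flatnonzero(frame_meta == m)
            centroid = proj[members].mean(axis=0)
            dists = np.sort(np.linalg.norm(proj[members] - centroid, axis=1))
            cut = dists[max(0, int(0.1 * len(dists)) - 1)]
            assert np.linalg.norm(proj[frame] - centroid) <= cut + 1e-12


class TestCoarseKinetics:
    def test_three_well_metastates_match_boltzmann_and_step_through_middle(self):
        """Coarse 3-state model of a 3-well Brownian walk: metastate weights
        reproduce the quadrature Boltzmann occupancies, and end-to-end hops
        route through the intermediate well (the stepwise pathway)."""
        ws = kt.synth.WellSpec(
            centers=((-4.0,), (0.0,), (4.0,)),
            depths=(2.5, 1.2, 3.0),
            widths=(1.0, 1.0, 1.0),
            temperature=500.0,
            friction=0.5,
            timestep=0.2,
            confinement=0.3,
        )
        path = kt.synth.sample_overdamped_dynamics(ws, 150_000, seed=14)
        labels = cluster_microstates(path, k=30, seed=0)
        model = estimate_transition_matrix(labels, lag=10)
        part = pcca_metastates(model, 3)
        centers = np.array(
            [path[labels == s].mean() for s in model.active_states]
        )
        meta_center = np.array(
            [centers[part.crisp_assignment == m].mean() for m in range(3)]
        )
        order = np.argsort(meta_center)  # left, middle, right wells
        pi_meta = np.array(
            [
                model.stationary_distribution[part.crisp_assignment == m].sum()
                for m in range(3)
            ]
        )
        exact = kt.synth.stationary_well_occupancy(ws)
        np.testing.assert_allclose(pi_meta[order], exact, atol=0.06)
        # stepwise pathway: direct end-to-end hops are much rarer than hops
        # through the intermediate in the coarse transition matrix
        Tc = part.coarse_transition_matrix
        l, m_, r = order
        assert Tc[l, r] < Tc[l, m_]
        assert Tc[r, l] < Tc[r, m_]
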