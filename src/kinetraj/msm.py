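"""Markov state models: estimation, validation, coarse-graining, kinetics.

A Markov state model discretizes a trajectory (typically its projection onto
principal components) into k microstates via K-means, counts transitions at
a lag time τ, and row-normalizes the counts into a transition matrix T(τ).
Validation uses the implied-timescale test (t_i = −τ/ln|λ_i(τ)| should be
lag-independent for Markovian data) and the Chapman–Kolmogorov test
(T(τ)ⁿ ≈ T(nτ)).  PCCA+ coarse-grains microstates into metastable sets from
the sign structure of the dominant eigenvectors, and mean first passage
times between sets quantify the kinetics — e.g. the stepwise open →
intermediate → closed transition of a flexible loop.

Transition counts never cross replica boundaries.  The default estimator
symmetrizes counts, (C+Cᵀ)/2, which enforces detailed balance by
construction; the raw row-normalized estimator is retained for oracle tests
against planted non-reversible chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MSMModel",
    "MetastablePartition",
    "MFPTResult",
    "cluster_microstates",
    "from_transition_matrix",
    "estimate_transition_matrix",
    "implied_timescales",
    "chapman_kolmogorov",
    "pcca_metastates",
    "mfpt",
    "representative_frames",
]

#: sentinel reported for timescales whose eigenvalue has |λ| ≥ 1
TIMESCALE_SENTINEL = np.inf


def _as_replica_list(labels) -> list[np.ndarray]:
    if isinstance(labels, np.ndarray) and labels.ndim == 1:
        return [np.asarray(labels, int)]
    if isinstance(labels, (list, tuple)) and labels and np.isscalar(labels[0]):
        return [np.asarray(labels, int)]
    return [np.asarray(r, int) for r in labels]


def cluster_microstates(
    projections: np.ndarray, k: int, max_iterations: int = 100, seed: int = 0
) -> np.ndarray:
    """K-means microstate assignment of projected frames.

    k-means++ initialization with a fixed seed and a single initialization
    run, so identical inputs give identical labels.  ``projections`` is
    (frames, d); returns integer labels in [0, k).
    """
    from sklearn.cluster import KMeans

    X = np.asarray(projections, float)
    if X.ndim == 1:
        X = X[:, None]
    if k < 2:
        raise ValueError("need at least 2 microstates")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=max_iterations,
        random_state=seed,
    )
    return km.fit_predict(X)


@dataclass
class MSMModel:
    """Estimated Markov state model at a fixed lag.

    ``active_states`` maps transition-matrix indices back to the original
    microstate labels; states outside the largest (strongly) connected set
    of the count graph were ergodically trimmed and are listed in
    ``trimmed_states``.
    """

    labels: list  # per-replica microstate label arrays
    lag: int  # frames
    count_matrix: np.ndarray  # (k, k) over active states
    transition_matrix: np.ndarray  # row-stochastic
    active_states: np.ndarray  # original labels, index order of T
    trimmed_states: np.ndarray
    eigenvalues: np.ndarray  # descending |·|
    stationary_distribution: np.ndarray
    mode: str = "symmetrized"
    frame_interval: float | None = None  # physical time per frame

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def state_index(self, label: int) -> int:
        hits = np.flatnonzero(self.active_states == label)
        if hits.size == 0:
            raise KeyError(f"microstate {label} not in the active set")
        return int(hits[0])


def from_transition_matrix(
    T: np.ndarray, lag: int = 1, frame_interval: float | None = None, mode: str = "raw"
) -> MSMModel:
    """Wrap a known row-stochastic matrix as an MSMModel (for exact kinetics).

    Lets closed-form quantities (MFPTs, timescales, coarse-graining) be
    computed on a chain whose transition matrix is specified rather than
    estimated.
    """
    T = np.asarray(T, float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("matrix must be row-stochastic")
    evals = np.linalg.eigvals(T)
    evals = np.real_if_close(evals[np.argsort(-np.abs(evals))], tol=1e6)
    k = T.shape[0]
    return MSMModel(
        labels=[],
        lag=lag,
        count_matrix=np.zeros_like(T),
        transition_matrix=T,
        active_states=np.arange(k),
        trimmed_states=np.array([], dtype=int),
        eigenvalues=evals,
        stationary_distribution=_stationary_distribution(T),
        mode=mode,
        frame_interval=frame_interval,
    )


def _count_transitions(replicas: list[np.ndarray], lag: int, n_states: int) -> np.ndarray:
    C = np.zeros((n_states, n_states))
    for seq in replicas:
        if lag < len(seq):
            np.add.at(C, (seq[:-lag], seq[lag:]), 1.0)
    return C


def estimate_transition_matrix(
    labels,
    lag: int,
    mode: str = "symmetrized",
    frame_interval: float | None = None,
) -> MSMModel:
    """Estimate a transition matrix from microstate labels at a given lag.

    Counts use the sliding window within each replica (never across
    boundaries).  ``mode='raw'`` row-normalizes the count matrix;
    ``mode='symmetrized'`` (default) row-normalizes (C+Cᵀ)/2, which yields a
    reversible chain.  States outside the largest connected set of the count
    graph are trimmed before normalization.
    """
    if mode not in ("raw", "symmetrized"):
        raise ValueError("mode must be 'raw' or 'symmetrized'")
    replicas = _as_replica_list(labels)
    shortest = min(len(r) for r in replicas)
    if lag < 1 or lag >= shortest:
        raise ValueError(f"lag {lag} must be in [1, shortest replica length {shortest})")
    n_states = int(max(r.max() for r in replicas)) + 1
    C = _count_transitions(replicas, lag, n_states)
    C_eff = 0.5 * (C + C.T) if mode == "symmetrized" else C
    # ergodic trimming: largest connected set of the positive-count graph
    graph = csr_matrix((C_eff > 0).astype(int))
    connection = "weak" if mode == "symmetrized" else "strong"
    n_comp, comp = connected_components(graph, directed=True, connection=connection)
    # ignore states never observed at all
    observed = (C.sum(axis=0) + C.sum(axis=1)) > 0
    sizes = np.array([np.sum((comp == c) & observed) for c in range(n_comp)])
    keep_comp = int(sizes.argmax())
    active_mask = (comp == keep_comp) & observed
    active = np.flatnonzero(active_mask)
    trimmed = np.flatnonzero(observed & ~active_mask)
    if trimmed.size:
        warnings.warn(
            f"ergodically trimmed {trimmed.size} state(s): {trimmed.tolist()}",
            stacklevel=2,
        )
    sub = C_eff[np.ix_(active, active)]
    rows = sub.sum(axis=1)
    if np.any(rows == 0):  # isolated state in the kept set (lag pathologies)
        raise ValueError("active set contains a state with no outgoing counts")
    T = sub / rows[:, None]
    evals = np.linalg.eigvals(T)
    order = np.argsort(-np.abs(evals))
    evals = evals[order]
    evals = np.real_if_close(evals, tol=1e6)
    pi = _stationary_distribution(T)
    return MSMModel(
        labels=replicas,
        lag=lag,
        count_matrix=C[np.ix_(active, active)],
        transition_matrix=T,
        active_states=active,
        trimmed_states=trimmed,
        eigenvalues=evals,
        stationary_distribution=pi,
        mode=mode,
        frame_interval=frame_interval,
    )


def _stationary_distribution(T: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def implied_timescales(
    labels,
    lags,
    n_timescales: int = 2,
    mode: str = "symmetrized",
) -> pd.DataFrame:
    """Implied-timescale table over a list of lags.

    t_i(τ) = −τ / ln|λ_i(τ)| for i ≥ 2 (the stationary eigenvalue carries no
    timescale).  Eigenvalues with λ ≤ 0 are reported as undefined (NaN) and
    |λ| ≥ 1 as an infinite sentinel, both flagged in the ``defined`` column.
    Lag-independence of t_i is the Markovianity check.
    """
    lags = list(lags)
    if not lags:
        raise ValueError("empty lag list")
    rows = []
    for lag in lags:
        model = estimate_transition_matrix(labels, lag, mode=mode)
        evals = np.real(model.eigenvalues)
        for i in range(1, min(n_timescales + 1, len(evals))):
            lam = evals[i]
            if lam <= 0.0:
                ts, defined = np.nan, False
            elif abs(lam) >= 1.0:
                ts, defined = TIMESCALE_SENTINEL, False
            else:
                ts, defined = -lag / np.log(abs(lam)), True
            rows.append(
                {
                    "lag": lag,
                    "timescale_index": i + 1,
                    "timescale": ts,
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MetastablePartition:
    """Fuzzy metastable memberships of microstates plus a crisp assignment."""

    memberships: np.ndarray  # (k, m), rows sum to 1
    crisp_assignment: np.ndarray  # (k,) argmax metastate per microstate
    coarse_transition_matrix: np.ndarray  # (m, m)
    active_states: np.ndarray  # original microstate labels

    @property
    def n_metastates(self) -> int:
        return self.memberships.shape[1]

    def metastate_members(self, m: int) -> np.ndarray:
        """Original microstate labels crisply assigned to metastate m."""
        return self.active_states[self.crisp_assignment == m]


def _dominant_right_eigenvectors(T: np.ndarray, pi: np.ndarray, m: int) -> np.ndarray:
    """Right eigenvectors of a reversible T via the symmetrized problem."""
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(-evals)
    psi = evecs[:, order[:m]] / sqrt_pi[:, None]
    # normalize the stationary eigenvector to a constant 1
    psi[:, 0] = psi[:, 0] / psi[0, 0]
    return psi


def pcca_metastates(msm_model: MSMModel, n_metastates: int) -> MetastablePartition:
    """PCCA+ coarse-graining of microstates into metastable sets.

    Rows of the dominant right-eigenvector matrix lie (approximately) in a
    simplex whose vertices are the pure metastable states; the algorithm
    finds the most spread-out rows as vertices and expresses every microstate
    as a convex combination (the fuzzy membership).  Requires an irreducible,
    reversible transition matrix; ``n_metastates`` should not exceed the
    number of eigenvalues near 1 (a gap after λ_m is the usual heuristic).
    """
    T = msm_model.transition_matrix
    k = T.shape[0]
    if not (2 <= n_metastates <= k):
        raise ValueError(f"n_metastates must be in [2, {k}]")
    graph = csr_matrix((T > 0).astype(int))
    n_comp, comp = connected_components(graph, directed=True, connection="strong")
    if n_comp > 1:
        blocks = [np.flatnonzero(comp == c).tolist() for c in range(n_comp)]
        raise ValueError(f"transition matrix is reducible; disconnected blocks: {blocks}")
    pi = msm_model.stationary_distribution
    X = _dominant_right_eigenvectors(T, pi, n_metastates)

    # inner-simplex vertex search
    m = n_metastates
    vertices = [int(np.argmax(np.linalg.norm(X, axis=1)))]
    Y = X - X[vertices[0]]
    for _ in range(1, m):
        # deflate against directions already chosen
        for v in vertices[1:]:
            d = Y[v] / np.linalg.norm(Y[v])
            Y = Y - np.outer(Y @ d, d)
        norms = np.linalg.norm(Y, axis=1)
        norms[vertices] = -1.0
        vertices.append(int(np.argmax(norms)))
    A = np.linalg.inv(X[vertices])
    chi = X @ A
    chi = np.clip(chi, 0.0, 1.0)
    chi = chi / chi.sum(axis=1, keepdims=True)
    crisp = chi.argmax(axis=1)

    D = np.diag(pi)
    M = chi.T @ D @ chi
    coarse = np.linalg.solve(M, chi.T @ D @ T @ chi)
    coarse = np.clip(coarse, 0.0, None)
    coarse = coarse / coarse.sum(axis=1, keepdims=True)
    return MetastablePartition(
        memberships=chi,
        crisp_assignment=crisp,
        coarse_transition_matrix=coarse,
        active_states=msm_model.active_states,
    )


def chapman_kolmogorov(
    labels,
    lag: int,
    n_multiples: int = 5,
    n_metastates: int = 2,
    tolerance: float = 0.05,
    mode: str = "symmetrized",
) -> dict:
    """Chapman–Kolmogorov test on metastable self-transition probabilities.

    Compares, for each metastable set A and each multiple n, the model
    prediction P[A→A after n steps of T(τ)] against the same probability from
    a matrix estimated directly at lag nτ.  Multiples whose lag reaches the
    shortest replica length are truncated with a warning.  Returns the
    per-point table, the maximum absolute deviation, and pass/fail at
    ``tolerance``.
    """
    replicas = _as_replica_list(labels)
    shortest = min(len(r) for r in replicas)
    model = estimate_transition_matrix(replicas, lag, mode=mode)
    partition = pcca_metastates(model, n_metastates)
    pi = model.stationary_distribution
    sets = [
        np.flatnonzero(partition.crisp_assignment == m_)
        for m_ in range(n_metastates)
    ]
    usable = [n for n in range(1, n_multiples + 1) if n * lag < shortest]
    if len(usable) < n_multiples:
        warnings.warn(
            f"truncated CK multiples to {usable} (replica length {shortest})",
            stacklevel=2,
        )
    rows = []
    Tn = np.eye(model.n_states)
    for n in range(1, max(usable) + 1 if usable else 1):
        Tn = Tn @ model.transition_matrix
        if n not in usable:
            continue
        est_model = estimate_transition_matrix(replicas, n * lag, mode=mode)
        for m_, members in enumerate(sets):
            w = pi[members] / pi[members].sum()
            predicted = float(w @ Tn[np.ix_(members, members)].sum(axis=1))
            # map the set into the n·τ model's active states
            labels_set = partition.active_states[members]
            est_idx = [
                est_model.state_index(s)
                for s in labels_set
                if s in est_model.active_states
            ]
            if not est_idx:
                continue
            w_est = est_model.stationary_distribution[est_idx]
            w_est = w_est / w_est.sum()
            estimated = float(
                w_est
                @ est_model.transition_matrix[np.ix_(est_idx, est_idx)].sum(axis=1)
            )
            rows.append(
                {
                    "multiple": n,
                    "metastate": m_,
                    "predicted": predicted,
                    "estimated": estimated,
                    "deviation": abs(predicted - estimated),
                }
            )
    table = pd.DataFrame(rows)
    max_dev = float(table["deviation"].max()) if len(table) else np.nan
    return {"table": table, "max_deviation": max_dev, "passed": bool(max_dev <= tolerance)}


@dataclass(frozen=True)
class MFPTResult:
    """Mean first passage time in lag units and, when resolvable, physical time."""

    lag_units: float
    physical: float | None
    reachable: bool


def mfpt(msm_model: MSMModel, source_states, sink_states) -> MFPTResult:
    """Mean first passage time from a source set to an absorbing sink set.

    States are original microstate labels.  Solves (I − T_nn) m = 1 over
    non-sink states and averages m over the source set weighted by the
    stationary distribution restricted to it.  Physical time is
    lag_units × lag × frame_interval when the model carries a frame interval.
    """
    src = [msm_model.state_index(s) for s in np.atleast_1d(source_states)]
    snk = [msm_model.state_index(s) for s in np.atleast_1d(sink_states)]
    if set(src) <= set(snk):
        return MFPTResult(0.0, 0.0 if msm_model.frame_interval else None, True)
    T = msm_model.transition_matrix
    k = T.shape[0]
    non_sink = np.array([i for i in range(k) if i not in set(snk)])
    # reachability of the sink from every source state
    graph = csr_matrix((T > 0).astype(int))
    n_comp, comp = connected_components(graph, directed=True, connection="strong")
    reach = _reachable_to(T, set(snk))
    if not all(i in reach or i in set(snk) for i in src):
        return MFPTResult(np.inf, np.inf if msm_model.frame_interval else None, False)
    A = np.eye(len(non_sink)) - T[np.ix_(non_sink, non_sink)]
    m = np.linalg.solve(A, np.ones(len(non_sink)))
    m_full = np.zeros(k)
    m_full[non_sink] = m
    pi = msm_model.stationary_distribution
    w = pi[src] / pi[src].sum()
    t_lag = float(w @ m_full[src])
    physical = (
        t_lag * msm_model.lag * msm_model.frame_interval
        if msm_model.frame_interval is not None
        else None
    )
    return MFPTResult(t_lag, physical, True)


def _reachable_to(T: np.ndarray, sinks: set) -> set:
    """States from which some sink is reachable (reverse BFS on T > 0)."""
    k = T.shape[0]
    adj_rev = [np.flatnonzero(T[:, j] > 0) for j in range(k)]
    seen = set(sinks)
    frontier = list(sinks)
    while frontier:
        j = frontier.pop()
        for i in adj_rev[j]:
            if int(i) not in seen:
                seen.add(int(i))
                frontier.append(int(i))
    return seen


def representative_frames(
    partition: MetastablePartition, labels, projections: np.ndarray
) -> dict:
    """Representative frame per metastate: nearest to the metastate centroid.

    Frames inherit their microstate's crisp metastate; each metastate's
    centroid is the mean of its member frames in projection space (which
    weights microstates by their occupancy), and the frame minimizing the
    Euclidean distance to the centroid represents the metastate.  Ties break
    to the lowest frame index; a metastate left empty after trimming maps to
    ``None``.
    """
    flat_labels = np.concatenate(_as_replica_list(labels))
    X = np.asarray(projections, float)
    if X.ndim == 1:
        X = X[:, None]
    if len(flat_labels) != len(X):
        raise ValueError("labels and projections must cover the same frames")
    label_to_meta = {
        int(s): int(partition.crisp_assignment[i])
        for i, s in enumerate(partition.active_states)
    }
    frame_meta = np.array([label_to_meta.get(int(s), -1) for s in flat_labels])
    out = {}
    for m_ in range(partition.n_metastates):
        members = np.flatnonzero(frame_meta == m_)
        if members.size == 0:
            warnings.warn(f"metastate {m_} has no frames after trimming", stacklevel=2)
            out[m_] = None
            continue
        centroid = X[members].mean(axis=0)
        d = np.linalg.norm(X[members] - centroid, axis=1)
        # argmin returns the first minimum -> lowest frame index on ties
        out[m_] = int(members[int(np.argmin(d))])
    return out
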