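"""Independent reference computations used to check the library.

Everything here is deliberately naive — grid searches, path enumeration,
direct simulation — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def brute_force_min_rmsd(ref: np.ndarray, mob: np.ndarray, seed: int = 0) -> float:
    """Minimum RMSD over proper rotations by quaternion grid refinement.

    Centers both point sets (the optimal translation matches centroids for
    any rotation), scans a coarse random quaternion grid, then refines
    around the best rotation with shrinking perturbations.
    """
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)

    def rmsd_of(q):
        R = _quat_to_matrix(q)
        return np.sqrt(((mob_c @ R.T - ref_c) ** 2).sum(axis=1).mean())

    rng = np.random.default_rng(seed)
    grid = rng.standard_normal((4000, 4))
    best_q, best = None, np.inf
    for q in grid:
        v = rmsd_of(q)
        if v < best:
            best, best_q = v, q
    scale = 0.3
    for _ in range(40):
        cands = best_q + scale * rng.standard_normal((200, 4))
        for q in cands:
            v = rmsd_of(q)
            if v < best:
                best, best_q = v, q
        scale *= 0.7
    return float(best)


def brute_force_edge_betweenness(nodes, edges_with_weights) -> dict:
    """Weighted edge betweenness by explicit shortest-path enumeration.

    For every unordered node pair (s, t), enumerates all minimum-weight
    paths by depth-first search and credits each edge on them with
    (paths through edge) / (total paths).  Matches the unnormalized
    undirected convention.
    """
    nodes = list(nodes)
    adj: dict = {n: {} for n in nodes}
    for (u, v), w in edges_with_weights.items():
        adj[u][v] = w
        adj[v][u] = w

    def all_shortest_paths(s, t):
        # Dijkstra distances then DFS enumeration of optimal paths
        import heapq

        dist = {n: np.inf for n in nodes}
        dist[s] = 0.0
        heap = [(0.0, s)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist[u] + 1e-15:
                continue
            for v, w in adj[u].items():
                if d + w < dist[v] - 1e-12:
                    dist[v] = d + w
                    heapq.heappush(heap, (dist[v], v))
        if not np.isfinite(dist[t]):
            return []
        paths = []

        def dfs(u, path):
            if u == t:
                paths.append(list(path))
                return
            for v, w in adj[u].items():
                if abs(dist[u] + w - dist[v]) < 1e-9 and v not in path:
                    path.append(v)
                    dfs(v, path)
                    path.pop()

        dfs(s, [s])
        return paths

    eb = {tuple(sorted(e)): 0.0 for e in edges_with_weights}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            share = 1.0 / len(paths)
            for p in paths:
                for u, v in zip(p[:-1], p[1:]):
                    eb[tuple(sorted((u, v)))] += share
    return eb


def simulate_first_passage_times(
    T: np.ndarray, source: int, sinks, n_walkers: int, seed: int = 0, max_steps: int = 100000
) -> np.ndarray:
    """Direct simulation of first passage times, vectorized over walkers."""
    rng = np.random.default_rng(seed)
    sinks = set(np.atleast_1d(sinks).tolist())
    cum = np.cumsum(T, axis=1)
    state = np.full(n_walkers, source)
    time_hit = np.full(n_walkers, -1, dtype=int)
    alive = np.ones(n_walkers, bool)
    for step in range(1, max_steps + 1):
        u = rng.random(alive.sum())
        nxt = np.empty(alive.sum(), dtype=int)
        cur = state[alive]
        for s in np.unique(cur):
            m = cur == s
            nxt[m] = np.searchsorted(cum[s], u[m], side="right")
        state[alive] = np.minimum(nxt, T.shape[0] - 1)
        hit = alive & np.isin(state, list(sinks))
        time_hit[hit] = step
        alive &= ~hit
        if not alive.any():
            break
    if alive.any():
        raise RuntimeError("some walkers never reached the sink")
    return time_hit.astype(float)
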