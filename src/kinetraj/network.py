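"""Residue-interaction networks and Girvan–Newman community analysis.

Residues are nodes; an edge joins two residues that stay within a distance
cutoff (default 4.5 Å, minimum heavy-atom distance) for at least a fraction
of the frames (default 75%).  Edges carry the dynamical distance

    d_ij = −ln |C_ij|,

so strongly correlated residues are "close".  The Girvan–Newman divisive
algorithm repeatedly removes the edge of highest weighted betweenness,
tracking modularity, and the best partition's communities are the protein's
cooperative modules; summed betweenness of the edges spanning two
communities gauges the strength of the allosteric channel between them.
Communities with fewer than three residues are dropped and their nodes
reported as unassigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix
from .traj import Trajectory

__all__ = [
    "ResidueGraph",
    "CommunityPartition",
    "contact_edges",
    "weight_edges",
    "girvan_newman_communities",
    "intercommunity_strengths",
    "network_summary",
    "export_graph_json",
]

#: clamp for |C| before taking −ln, to avoid infinite distances
CORRELATION_EPS = 1e-6
#: minimum community size retained in a partition
MIN_COMMUNITY_SIZE = 3


@dataclass
class ResidueGraph:
    """Weighted residue graph: nodes are residue ids, weights are −ln|C|."""

    graph: nx.Graph  # edge attrs: weight (distance), correlation (|C|)

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class CommunityPartition:
    """Partition of surviving residues into communities plus link strengths.

    ``community_of`` maps residue id → community index for residues in
    communities of size ≥ 3; residues in dropped (smaller) communities are in
    ``unassigned``.  ``intercommunity_links`` maps a community index pair to
    the summed edge betweenness of edges spanning it.
    """

    community_of: dict
    community_sizes: dict
    unassigned: list
    intercommunity_links: dict = field(default_factory=dict)
    modularity: float = float("nan")


def contact_edges(
    trajectory: Trajectory,
    cutoff: float = 4.5,
    occupancy: float = 0.75,
    mode: str = "heavy",
    neighbor_offset: int = 2,
    include_ligand: bool = True,
) -> list[tuple[int, int]]:
    """Residue pairs in contact for at least ``occupancy`` of the frames.

    Contact distance is the minimum heavy-atom distance between the residues
    (``mode='heavy'``; ``mode='calpha'`` restricts to alpha carbons — on
    bead models the two coincide).  Pairs closer than ``neighbor_offset`` in
    sequence are excluded, since backbone-adjacent contacts are trivially
    permanent.  The occupancy comparison is ≥, so a pair exactly at threshold
    keeps its edge.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not (0.0 < occupancy <= 1.0):
        raise ValueError("occupancy must lie in (0, 1]")
    if mode not in ("heavy", "calpha"):
        raise ValueError("mode must be 'heavy' or 'calpha'")
    top = trajectory.topology
    residues = [
        r for r in top.residues if include_ligand or not r["is_ligand"]
    ]
    atom_groups = []
    for r in residues:
        idx = r["atom_indices"]
        if mode == "heavy":
            idx = [i for i in idx if top.atoms[i].element.upper() != "H"]
        else:
            idx = [i for i in idx if top.atoms[i].name == "CA"] or list(idx)
        atom_groups.append(np.asarray(idx, int))
    coords = trajectory.coordinates
    n_res = len(residues)
    n_frames = coords.shape[0]
    hit_counts = np.zeros((n_res, n_res))
    if all(len(g) == 1 for g in atom_groups):
        # bead models: one atom per residue, fully vectorized
        idx = np.concatenate(atom_groups)
        X = coords[:, idx, :]
        d2 = ((X[:, :, None, :] - X[:, None, :, :]) ** 2).sum(axis=3)
        hit_counts = np.triu((d2 <= cutoff**2).sum(axis=0).astype(float), k=1)
    else:
        # min heavy-atom distance per residue pair, vectorized over frames
        for i in range(n_res):
            Xi = coords[:, atom_groups[i], :]
            for j in range(i + 1, n_res):
                Xj = coords[:, atom_groups[j], :]
                d2 = ((Xi[:, :, None, :] - Xj[:, None, :, :]) ** 2).sum(axis=3)
                hits = d2.reshape(n_frames, -1).min(axis=1) <= cutoff**2
                hit_counts[i, j] = hits.sum()
    edges = []
    for i in range(n_res):
        for j in range(i + 1, n_res):
            same_chain = residues[i]["chain_id"] == residues[j]["chain_id"]
            both_protein = not residues[i]["is_ligand"] and not residues[j]["is_ligand"]
            if (
                same_chain
                and both_protein
                and abs(residues[i]["res_id"] - residues[j]["res_id"]) < neighbor_offset
            ):
                continue
            if hit_counts[i, j] / n_frames >= occupancy:
                edges.append((residues[i]["res_id"], residues[j]["res_id"]))
    return edges


def weight_edges(
    edges: list[tuple[int, int]], correlation_matrix: CorrelationMatrix
) -> ResidueGraph:
    """Assign dynamical distances d_ij = −ln|C_ij| to contact edges.

    |C_ij| is clamped to [1e-6, 1]: perfectly correlated residues are at
    distance 0, and residues whose correlation underflows the clamp get the
    finite ceiling −ln(1e-6) rather than an infinite edge.
    """
    known = set(int(r) for r in correlation_matrix.residue_ids)
    G = nx.Graph()
    for u, v in edges:
        if u not in known or v not in known:
            raise ValueError(f"edge ({u}, {v}) references a residue absent from the matrix")
        if u == v:
            continue
        c = correlation_matrix.value(u, v)
        c_abs = abs(c) if np.isfinite(c) else 0.0
        clamped = min(max(c_abs, CORRELATION_EPS), 1.0)
        G.add_edge(u, v, weight=float(-np.log(clamped)), correlation=float(c_abs))
    return ResidueGraph(graph=G)


def _max_betweenness_edge(G: nx.Graph) -> tuple[int, int]:
    """Edge of highest weighted betweenness; ties break lexicographically."""
    eb = nx.edge_betweenness_centrality(G, weight="weight", normalized=False)
    best_val = max(eb.values())
    candidates = [tuple(sorted(e)) for e, v in eb.items() if abs(v - best_val) < 1e-12]
    return min(candidates)


def girvan_newman_communities(residue_graph: ResidueGraph) -> CommunityPartition:
    """Girvan–Newman divisive community detection with modularity selection.

    Repeatedly removes the edge of highest weighted betweenness (shortest
    paths under the d = −ln|C| distances, lexicographic tie rule), computing
    the modularity of each intermediate component partition, and returns the
    partition maximizing modularity.  Modularity is evaluated on the
    unweighted original graph — using the distance weights would reward
    weakly correlated edges.  Communities smaller than 3 residues are dropped
    and their nodes listed as unassigned.
    """
    G0 = residue_graph.graph
    if G0.number_of_nodes() == 0:
        return CommunityPartition({}, {}, [], {}, float("nan"))
    G = G0.copy()
    best_partition = [set(c) for c in nx.connected_components(G)]
    best_q = (
        nx.algorithms.community.modularity(G0, best_partition, weight=None)
        if G0.number_of_edges()
        else 0.0
    )
    while G.number_of_edges() > 0:
        u, v = _max_betweenness_edge(G)
        G.remove_edge(u, v)
        parts = [set(c) for c in nx.connected_components(G)]
        q = nx.algorithms.community.modularity(G0, parts, weight=None)
        if q > best_q + 1e-12:
            best_q = q
            best_partition = parts
    ordered = sorted(best_partition, key=lambda c: min(c))
    community_of: dict = {}
    sizes: dict = {}
    unassigned: list = []
    cid = 0
    for comm in ordered:
        if len(comm) < MIN_COMMUNITY_SIZE:
            unassigned.extend(sorted(comm))
            continue
        for node in comm:
            community_of[node] = cid
        sizes[cid] = len(comm)
        cid += 1
    partition = CommunityPartition(
        community_of=community_of,
        community_sizes=sizes,
        unassigned=sorted(unassigned),
        modularity=best_q,
    )
    partition.intercommunity_links = intercommunity_strengths(residue_graph, partition)
    return partition


def intercommunity_strengths(
    residue_graph: ResidueGraph, partition: CommunityPartition
) -> dict:
    """Betweenness-weighted strength of every intercommunity connection.

    Strength of a community pair is the summed weighted edge betweenness —
    computed on the full graph, so it reflects the shortest-path flow the
    spanning edges actually carry.  Pairs with no spanning edge are absent.
    """
    G = residue_graph.graph
    unknown = [n for n in partition.community_of if n not in G]
    if unknown:
        raise ValueError(f"partition nodes absent from graph: {sorted(unknown)}")
    if G.number_of_edges() == 0:
        return {}
    eb = nx.edge_betweenness_centrality(G, weight="weight", normalized=False)
    links: dict = {}
    for (u, v), b in eb.items():
        cu = partition.community_of.get(u)
        cv = partition.community_of.get(v)
        if cu is None or cv is None or cu == cv:
            continue
        key = tuple(sorted((cu, cv)))
        links[key] = links.get(key, 0.0) + float(b)
    return links


def network_summary(partition: CommunityPartition) -> dict:
    """Community and pathway counts: the report format of a network analysis."""
    return {
        "n_communities": len(partition.community_sizes),
        "n_pathways": len(partition.intercommunity_links),
    }


def export_graph_json(
    residue_graph: ResidueGraph, partition: CommunityPartition | None, path
) -> None:
    """Nodes (with community id), edges (weight, correlation) as JSON."""
    G = residue_graph.graph
    data = {
        "nodes": [
            {
                "residue_id": int(n),
                "community": (
                    partition.community_of.get(n) if partition is not None else None
                ),
            }
            for n in sorted(G.nodes)
        ],
        "edges": [
            {
                "u": int(u),
                "v": int(v),
                "weight": G[u][v]["weight"],
                "correlation": G[u][v]["correlation"],
            }
            for u, v in sorted(tuple(sorted(e)) for e in G.edges)
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
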