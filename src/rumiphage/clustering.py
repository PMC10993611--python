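"""Viral-cluster (VC) construction: a homology graph with dual coverage
filters, clustered by Markov clustering (MCL).

An edge joins two genomes when some hit passes the E-value gate and the
merged >=90%-identity HSP regions cover strictly more than 70% of the
larger genome and 90% of the smaller genome. MCL is implemented from
scratch on a dense column-stochastic matrix: self-loops of weight 1,
expansion (matrix power) alternating with inflation (entrywise power and
column renormalisation), with pruning of tiny entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .alignment import AlignmentHit, _span_on_axis, union_intervals
from .catalog import PhageRecord


@dataclass
class ViralCluster:
    """A graph-level grouping of genomes (one MCL cluster)."""

    vc_id: str
    members: set[str]
    animal_hosts: set[str] = field(default_factory=set)
    git_sites: set[str] = field(default_factory=set)
    size_rank: int | None = None
    broad_range: bool | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.vc_id}: empty member set")


# --------------------------------------------------------------------------
# coverage and graph construction
# --------------------------------------------------------------------------

def pairwise_coverage(
    hits: Sequence[AlignmentHit],
    genome_a: str,
    len_a: int,
    genome_b: str,
    len_b: int,
    min_identity: float = 90.0,
) -> tuple[float, float]:
    """Merged-HSP coverage of the larger and smaller genome of a pair.

    HSPs below ``min_identity`` percent identity are ignored. Hits may be
    given in either orientation (a as query or b as query). Ties in length
    treat ``genome_a`` as the larger genome.
    """
    if len_a < 1 or len_b < 1:
        raise ValueError("genome lengths must be >= 1")
    spans: dict[str, list[tuple[int, int]]] = {genome_a: [], genome_b: []}
    for h in hits:
        if h.pct_identity < min_identity:
            continue
        if h.query_id == genome_a and h.subject_id == genome_b:
            spans[genome_a].append(_span_on_axis(h, "query"))
            spans[genome_b].append(_span_on_axis(h, "subject"))
        elif h.query_id == genome_b and h.subject_id == genome_a:
            spans[genome_b].append(_span_on_axis(h, "query"))
            spans[genome_a].append(_span_on_axis(h, "subject"))
        else:
            raise ValueError(
                f"hit {h.query_id}->{h.subject_id} is not between "
                f"{genome_a} and {genome_b}"
            )
    cov_a = union_intervals(spans[genome_a]).covered_bp / len_a
    cov_b = union_intervals(spans[genome_b]).covered_bp / len_b
    if len_a >= len_b:
        return cov_a, cov_b
    return cov_b, cov_a


def build_vc_graph(
    all_hits: Sequence[AlignmentHit],
    lengths: Mapping[str, int],
    evalue_max: float = 1e-10,
    cov_large_min: float = 0.70,
    cov_small_min: float = 0.90,
    min_identity: float = 90.0,
) -> nx.Graph:
    """Homology graph over genomes from all-vs-all hits.

    Hits are first gated at ``evalue <= evalue_max``; an edge is added iff
    the merged >= ``min_identity``-identity regions of the retained hits
    cover strictly more than ``cov_large_min`` of the larger genome AND
    ``cov_small_min`` of the smaller genome. Self-hits are ignored.
    """
    pair_hits: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in all_hits:
        for gid in (h.query_id, h.subject_id):
            if gid not in lengths:
                raise KeyError(f"no length for genome {gid}")
        if h.query_id == h.subject_id:
            continue
        if h.evalue > evalue_max:
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        pair_hits.setdefault(key, []).append(h)

    graph = nx.Graph()
    graph.add_nodes_from(lengths)
    for (a, b), hits in pair_hits.items():
        cov_large, cov_small = pairwise_coverage(
            hits, a, lengths[a], b, lengths[b], min_identity=min_identity
        )
        if cov_large > cov_large_min and cov_small > cov_small_min:
            graph.add_edge(a, b, weight=1.0)
    return graph


# --------------------------------------------------------------------------
# Markov clustering
# --------------------------------------------------------------------------

def _mcl_matrix(
    adj: np.ndarray,
    inflation: float,
    expansion: int,
    max_iter: int,
    tol: float,
    prune: float,
) -> np.ndarray:
    """Iterate expansion/inflation on a column-stochastic matrix to a limit."""
    n = adj.shape[0]
    M = adj.astype(np.float64).copy()
    np.fill_diagonal(M, 1.0)  # self-loops
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        # a fully pruned column retreats to its self-loop
        dead = np.flatnonzero(colsum[0] == 0.0)
        if dead.size:
            M[dead, dead] = 1.0
            colsum = M.sum(axis=0, keepdims=True)
        M /= colsum
        if np.abs(M - prev).max() < tol:
            break
    return M


def _clusters_from_limit(M: np.ndarray, nodes: Sequence[str]) -> list[set[str]]:
    """Read clusters from the limit matrix's attractor structure.

    Attractors are nodes with positive diagonal mass; attractors connected
    through positive entries form one attractor system, whose cluster is
    the system plus every node it attracts. Nodes attracted by several
    systems go to the largest cluster (ties: smallest member id); nodes
    attracted by none become singletons.
    """
    n = M.shape[0]
    eps = 1e-12
    attractors = [i for i in range(n) if M[i, i] > eps]
    # attractor systems: connected components among attractor rows/columns
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (M[i, j] > eps or M[j, i] > eps):
                sys_graph.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]

    raw: list[set[int]] = []
    for system in systems:
        members = set(system)
        for i in system:
            members |= set(np.flatnonzero(M[i, :] > eps).tolist())
        raw.append(members)

    assigned: dict[int, int] = {}
    order = sorted(
        range(len(raw)),
        key=lambda k: (-len(raw[k]), min(nodes[i] for i in raw[k])),
    )
    for k in order:
        for i in raw[k]:
            assigned.setdefault(i, k)
    clusters: dict[int, set[str]] = {}
    for i in range(n):
        k = assigned.get(i)
        if k is None:
            clusters[len(raw) + i] = {nodes[i]}  # unattracted singleton
        else:
            clusters.setdefault(k, set()).add(nodes[i])
    return list(clusters.values())


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 6.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
) -> list[ViralCluster]:
    """Markov clustering of the homology graph into viral clusters.

    Every node lands in exactly one cluster; isolated nodes become
    singleton clusters. Output order and ids are deterministic:
    clusters sorted by size (desc) then smallest member id.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.is_directed():
        raise ValueError("graph must be undirected (symmetric)")
    nodes = sorted(graph.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        adj[idx[a], idx[b]] = w
        adj[idx[b], idx[a]] = w
    limit = _mcl_matrix(adj, inflation, expansion, max_iter, tol, prune)
    member_sets = _clusters_from_limit(limit, nodes)
    member_sets.sort(key=lambda s: (-len(s), min(s)))
    return [
        ViralCluster(vc_id=f"VC_{k + 1:05d}", members=members)
        for k, members in enumerate(member_sets)
    ]


def vc_annotate(
    clusters: Sequence[ViralCluster], metadata: Mapping[str, PhageRecord]
) -> list[ViralCluster]:
    """Fill host/site unions, size ranks, and the broad-range flag.

    A cluster is broad-range iff its members span three or more animal
    hosts. Ranks order clusters by member count (desc), ties by vc_id.
    """
    out = []
    for vc in clusters:
        missing = vc.members - metadata.keys()
        if missing:
            raise KeyError(f"{vc.vc_id}: no metadata for {sorted(missing)}")
        hosts = {metadata[m].animal_host for m in vc.members}
        out.append(
            replace(
                vc,
                members=set(vc.members),
                animal_hosts=hosts,
                git_sites={metadata[m].git_site for m in vc.members},
                broad_range=len(hosts) >= 3,
            )
        )
    ranked = sorted(out, key=lambda vc: (-len(vc.members), vc.vc_id))
    for rank, vc in enumerate(ranked, start=1):
        vc.size_rank = rank
    return out
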