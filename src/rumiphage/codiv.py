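"""Co-diversification of phages with their animal hosts.

For a viral cluster whose members come from three or more animal hosts,
patristic (branch-length) distances between all tip pairs of its
phylogenetic tree are split into within-host and between-host pairs, and
two one-tailed Wilcoxon rank-sum tests are run on the same pair sets:
if between-host distances are significantly larger the cluster is called
co-evolved; if significantly smaller, not co-evolved; otherwise
inconclusive.

All tip pairs are pooled even though shared tree paths make pairwise
distances non-independent; this mirrors the procedure the verdicts are
defined by and is a documented caveat, not an oversight.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.stats import norm, rankdata

from .catalog import proportion


@dataclass
class LabeledTree:
    """A phylogenetic tree with branch lengths plus a tip -> animal-host map.

    Rooting is irrelevant for patristic distances, so arbitrarily rooted
    Newick input is accepted.
    """

    tree: dendropy.Tree
    tip_hosts: dict[str, str]

    @classmethod
    def from_newick(
        cls, newick: str, tip_hosts: Mapping[str, str]
    ) -> "LabeledTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree=tree, tip_hosts=dict(tip_hosts))

    @classmethod
    def from_file(cls, path: str | Path, tip_hosts: Mapping[str, str]) -> "LabeledTree":
        return cls.from_newick(Path(path).read_text(), tip_hosts)


@dataclass(frozen=True)
class CoevolutionResult:
    vc_id: str
    n_within_pairs: int
    n_between_pairs: int
    p_coevolved: float
    p_not_coevolved: float
    verdict: str


# --------------------------------------------------------------------------
# patristic distances
# --------------------------------------------------------------------------

def patristic_matrix(tree: LabeledTree) -> tuple[list[str], np.ndarray]:
    """Tip labels and the symmetric matrix of path branch-length sums.

    Computed by breadth-first path sums over the (unrooted) node graph,
    so the result is independent of where the input tree is rooted.
    """
    taxa = [leaf.taxon for leaf in tree.tree.leaf_node_iter()]
    if any(t is None for t in taxa):
        raise ValueError("tree has an unlabeled tip")
    labels = sorted(t.label for t in taxa)
    if len(labels) < 2:
        raise ValueError("need at least 2 tips")
    for lab in labels:
        if lab not in tree.tip_hosts:
            raise ValueError(f"tip {lab!r} has no host label")

    # adjacency over dendropy nodes (edge lengths; None treated as 0)
    adj: dict[int, list[tuple[int, float]]] = {}
    node_of: dict[int, dendropy.Node] = {}
    leaf_id: dict[str, int] = {}
    for node in tree.tree.preorder_node_iter():
        nid = id(node)
        node_of[nid] = node
        adj.setdefault(nid, [])
        if node.parent_node is not None:
            pid = id(node.parent_node)
            bl = node.edge.length or 0.0
            if bl < 0:
                raise ValueError("negative branch length")
            adj[nid].append((pid, bl))
            adj.setdefault(pid, []).append((nid, bl))
        if node.is_leaf():
            leaf_id[node.taxon.label] = nid

    index = {lab: k for k, lab in enumerate(labels)}
    dmat = np.zeros((len(labels), len(labels)))
    for lab in labels:
        dist = {leaf_id[lab]: 0.0}
        stack = [leaf_id[lab]]
        while stack:
            cur = stack.pop()
            for nbr, bl in adj[cur]:
                if nbr not in dist:
                    dist[nbr] = dist[cur] + bl
                    stack.append(nbr)
        i = index[lab]
        for other, k in index.items():
            dmat[i, k] = dist[leaf_id[other]]
    np.fill_diagonal(dmat, 0.0)
    return labels, dmat


# --------------------------------------------------------------------------
# Wilcoxon rank-sum test
# --------------------------------------------------------------------------

def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str
) -> tuple[float, float]:
    """One-tailed Wilcoxon rank-sum test; returns (rank sum of x, p).

    Midranks are used for ties. The p-value is exact (full enumeration of
    rank assignments) when the pooled sample has <= 12 observations and no
    ties; otherwise a normal approximation with tie correction and a
    continuity correction of 1/2 is used.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less'")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    total = n + m
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n].sum())
    has_ties = np.unique(pooled).size < total

    if total <= 12 and not has_ties:
        all_ranks = range(1, total + 1)
        count = 0
        n_comb = math.comb(total, n)
        for combo in itertools.combinations(all_ranks, n):
            s = sum(combo)
            if alternative == "greater":
                count += s >= w
            else:
                count += s <= w
        return w, count / n_comb

    mean = n * (total + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n * m / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    if var <= 0:  # all values identical
        return w, 1.0
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (w - mean - 0.5) / sd
        return w, float(norm.sf(z))
    z = (w - mean + 0.5) / sd
    return w, float(norm.cdf(z))


# --------------------------------------------------------------------------
# per-cluster classification
# --------------------------------------------------------------------------

def within_between_distances(
    tree: LabeledTree,
) -> tuple[np.ndarray, np.ndarray]:
    """Patristic distances split into within-host and between-host pairs."""
    labels, dmat = patristic_matrix(tree)
    within, between = [], []
    for i, j in itertools.combinations(range(len(labels)), 2):
        if tree.tip_hosts[labels[i]] == tree.tip_hosts[labels[j]]:
            within.append(dmat[i, j])
        else:
            between.append(dmat[i, j])
    return np.asarray(within), np.asarray(between)


def coevolution_classify(
    tree: LabeledTree, alpha: float = 0.05, vc_id: str = ""
) -> CoevolutionResult:
    """Classify one cluster as co-evolved / not co-evolved / inconclusive.

    Requires tips from at least three animal hosts and at least one
    within-host pair. ``p_coevolved`` tests whether between-host distances
    are greater than within-host distances; ``p_not_coevolved`` is the
    exactly opposite one-tailed test on the same pair sets.
    """
    hosts = {tree.tip_hosts[leaf.taxon.label] for leaf in tree.tree.leaf_node_iter()}
    if len(hosts) < 3:
        raise ValueError(
            f"{vc_id or 'tree'}: needs >= 3 animal hosts, found {len(hosts)}"
        )
    within, between = within_between_distances(tree)
    if within.size == 0:
        raise ValueError(f"{vc_id or 'tree'}: no within-host tip pair")
    _, p_co = wilcoxon_rank_sum(between, within, alternative="greater")
    _, p_not = wilcoxon_rank_sum(between, within, alternative="less")
    if p_co < alpha:
        verdict = "coevolved"
    elif p_not < alpha:
        verdict = "not_coevolved"
    else:
        verdict = "inconclusive"
    return CoevolutionResult(
        vc_id=vc_id,
        n_within_pairs=int(within.size),
        n_between_pairs=int(between.size),
        p_coevolved=float(p_co),
        p_not_coevolved=float(p_not),
        verdict=verdict,
    )


def summarize_verdicts(results: Sequence[CoevolutionResult]) -> dict[str, float]:
    """Percentage of clusters per verdict."""
    if not results:
        raise ValueError("no results to summarize")
    total = len(results)
    out = {}
    for verdict in ("coevolved", "not_coevolved", "inconclusive"):
        count = sum(r.verdict == verdict for r in results)
        out[verdict] = proportion(count, total)
    return out
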