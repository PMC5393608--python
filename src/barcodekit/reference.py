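"""Brute-force reference implementations used to validate the fast paths.

These are deliberately naive and independent of the production algorithms:
exhaustive topology search scored by least squares stands against neighbour
joining, and dendropy's bipartition encoding stands against the package's
own split bookkeeping.  They are exercised by the test-suite and the
validation script, not by the pipeline itself.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import dendropy
import numpy as np

Edge = Tuple[int, int]


# ---------------------------------------------------------------------------
# random additive trees
# ---------------------------------------------------------------------------

def random_additive_tree(
    n_leaves: int, rng: np.random.Generator,
    min_len: float = 0.1, max_len: float = 1.0,
) -> Tuple[List[str], np.ndarray, Set[FrozenSet[str]]]:
    """Random unrooted binary tree with U(min_len, max_len) branch lengths.

    Returns (leaf ids, additive distance matrix, nontrivial splits
    canonicalized on the side not containing the smallest id).
    """
    ids = [f"t{i:02d}" for i in range(n_leaves)]
    edges, lengths, next_node = _random_topology(n_leaves, rng)
    for e in edges:
        lengths[e] = rng.uniform(min_len, max_len)
    D = _path_lengths(n_leaves, edges, lengths)
    splits = topology_splits(ids, edges)
    return ids, D, splits


def _random_topology(n_leaves, rng):
    """Sequential random attachment; leaves are nodes 0..n-1."""
    edges: List[Edge] = [(0, 1)]
    next_node = n_leaves  # internal nodes numbered from n_leaves
    lengths: Dict[Edge, float] = {}
    for leaf in range(2, n_leaves):
        k = int(rng.integers(0, len(edges)))
        a, b = edges.pop(k)
        mid = next_node
        next_node += 1
        edges.extend([(a, mid), (mid, b), (mid, leaf)])
    return edges, lengths, next_node


def _adjacency(edges: Sequence[Edge], lengths: Dict[Edge, float]):
    adj: Dict[int, List[Tuple[int, float]]] = {}
    for e in edges:
        a, b = e
        w = lengths[e]
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    return adj


def _path_lengths(n_leaves: int, edges, lengths) -> np.ndarray:
    adj = _adjacency(edges, lengths)
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]
    return D


def topology_splits(
    ids: Sequence[str], edges: Sequence[Edge]
) -> Set[FrozenSet[str]]:
    """Nontrivial splits of an unrooted topology given as an edge list."""
    n = len(ids)
    adj: Dict[int, List[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    ref = min(range(n), key=lambda i: ids[i])
    splits: Set[FrozenSet[str]] = set()
    for a, b in edges:
        # leaves on b's side of edge (a, b)
        side = set()
        stack = [b]
        seen = {a, b}
        while stack:
            u = stack.pop()
            if u < n:
                side.add(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(side) < 2 or len(side) > n - 2:
            continue
        if ref in side:
            side = set(range(n)) - side
        splits.add(frozenset(ids[i] for i in side))
    return splits


# ---------------------------------------------------------------------------
# exhaustive least-squares topology search
# ---------------------------------------------------------------------------

def enumerate_topologies(n_leaves: int) -> List[List[Edge]]:
    """All unrooted binary topologies over leaves 0..n-1 (1, 3, 15, 105...)."""
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    # internal node ids start at n_leaves; the seed topology is the star on
    # leaves 0, 1, 2
    start = [(n_leaves, 0), (n_leaves, 1), (n_leaves, 2)]
    topologies = [list(start)]
    next_internal = n_leaves + 1
    for leaf in range(3, n_leaves):
        grown = []
        for topo in topologies:
            for k in range(len(topo)):
                t2 = [e for i, e in enumerate(topo) if i != k]
                a, b = topo[k]
                mid = next_internal
                t2.extend([(a, mid), (mid, b), (mid, leaf)])
                grown.append(t2)
        topologies = grown
        next_internal += 1
    return topologies


def least_squares_fit(
    D: np.ndarray, edges: Sequence[Edge]
) -> Tuple[float, np.ndarray]:
    """Unconstrained least-squares branch lengths for one topology.

    Returns (sum of squared residuals, fitted lengths).
    """
    n = D.shape[0]
    adj: Dict[int, List[Tuple[int, int]]] = {}
    for idx, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, idx))
        adj.setdefault(b, []).append((a, idx))
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([D[i, j] for i, j in pairs])
    for row, (i, j) in enumerate(pairs):
        # DFS path i -> j, recording traversed edge indices
        stack = [(i, [])]
        seen = {i}
        path = None
        while stack:
            u, used = stack.pop()
            if u == j:
                path = used
                break
            for v, idx in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append((v, used + [idx]))
        A[row, path] = 1.0
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(((A @ coef - y) ** 2).sum())
    return rss, coef


def best_topology_splits(
    ids: Sequence[str], D: np.ndarray
) -> Set[FrozenSet[str]]:
    """Splits of the least-squares-best topology (exhaustive search)."""
    best_rss, best_edges = np.inf, None
    for edges in enumerate_topologies(len(ids)):
        rss, _ = least_squares_fit(D, edges)
        if rss < best_rss:
            best_rss, best_edges = rss, edges
    return topology_splits(ids, best_edges)


# ---------------------------------------------------------------------------
# independent split enumeration (dendropy)
# ---------------------------------------------------------------------------

def dendropy_splits(newick: str) -> Set[FrozenSet[str]]:
    """Nontrivial splits of a newick tree via dendropy's bipartitions."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = labels[0]
    n = len(labels)
    tree.encode_bipartitions()
    out: Set[FrozenSet[str]] = set()
    for bp in tree.bipartition_encoding:
        side = {
            t.label
            for t in tree.taxon_namespace.bitmask_taxa_list(bp.split_bitmask)
        }
        if ref in side:
            side = set(labels) - side
        if 2 <= len(side) <= n - 2:
            out.add(frozenset(side))
    return out
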