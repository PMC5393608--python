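"""Neighbour-joining trees, nonparametric bootstrap, and clade support.

The tree builder is the classic Saitou-Nei agglomeration: repeatedly join
the pair minimizing the Q-criterion, estimate the two pendant branch
lengths, and replace the pair by their ancestor.  Negative estimated branch
lengths are clamped to zero (lengths are not used by any success criterion
here).  Ties in Q are broken by the lexicographically smallest pair of
cluster keys (a cluster's key is its smallest leaf id), which makes the
whole construction deterministic.

Bootstrap support for an internal edge is the percentage of column-resampled
replicates whose NJ tree contains the same bipartition of the leaf set,
annotated onto the reference tree built from the full alignment.
"""

from __future__ import annotations

import logging
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from ._kernels import (
    MODEL_IDS,
    encode,
    nj_join_sequence,
    pack_codes,
    packed_distance_matrix,
)
from .distances import DEFAULT_MODEL, DistanceMatrix, impute_undefined
from .model import InputError, LocusAlignment

logger = logging.getLogger(__name__)

Split = FrozenSet[str]


class SupportTree:
    """An unrooted tree over specimens with optional per-edge support (0-100).

    Thin wrapper around a :class:`dendropy.Tree`; supports are stored as
    internal-node labels, the convention used by common tree viewers.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._splits: Optional[Dict[Split, Optional[int]]] = None

    # -- construction / serialization -----------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "SupportTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise InputError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        )
        return s.strip() + "\n"

    # -- leaves and splits ----------------------------------------------
    @property
    def leaf_labels(self) -> List[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.leaf_labels)

    def splits(self) -> Dict[Split, Optional[int]]:
        """Nontrivial bipartitions -> support (None when unannotated).

        Each internal edge defines a bipartition; the side not containing
        the reference leaf (the lexicographically smallest label) is the
        canonical key.  When a rooted representation shows the same split on
        two edges (a two-child root), the larger support is kept.
        """
        if self._splits is not None:
            return self._splits
        leaves = set(self.leaf_labels)
        ref = min(leaves)
        out: Dict[Split, Optional[int]] = {}
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            if len(below) < 2 or len(below) > len(leaves) - 2:
                continue
            key = frozenset(leaves - below) if ref in below else below
            sup = _parse_support(node.label)
            if key in out:
                prev = out[key]
                out[key] = sup if prev is None else (
                    prev if sup is None else max(prev, sup)
                )
            else:
                out[key] = sup
        self._splits = out
        return out

    def patristic_matrix(self) -> Tuple[List[str], np.ndarray]:
        """Leaf labels plus the matrix of path-length distances."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = sorted(self.leaf_labels)
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                out[i, j] = out[j, i] = d
        return labels, out

    def enclosing_clades(self, leaf_label: str):
        """Yield (other_leaf_labels, support) walking from a leaf to the root.

        Used to find a specimen's local neighbourhood: the smallest
        well-supported clade around it.
        """
        node = None
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == leaf_label:
                node = lf
                break
        if node is None:
            raise InputError(f"unknown leaf id {leaf_label!r}")
        anc = node.parent_node
        while anc is not None:
            others = [
                lf.taxon.label
                for lf in anc.leaf_iter()
                if lf.taxon.label != leaf_label
            ]
            sup = _parse_support(anc.label) if anc.parent_node is not None else None
            yield others, sup, anc.parent_node is None
            anc = anc.parent_node


def _parse_support(label) -> Optional[int]:
    if label is None or label == "":
        return None
    try:
        return int(round(float(label)))
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def _rank_array(ids: Sequence[str]) -> np.ndarray:
    order = {sid: k for k, sid in enumerate(sorted(ids))}
    return np.array([order[sid] for sid in ids], dtype=np.int64)


def _join_sequence(ids: Sequence[str], D: np.ndarray):
    n = len(ids)
    if n < 2:
        raise InputError("neighbour joining requires at least 2 taxa")
    if np.isnan(D).any():
        raise InputError("distance matrix contains undefined entries; impute first")
    return nj_join_sequence(np.ascontiguousarray(D, dtype=float), _rank_array(ids))


def _nj_newick(ids: Sequence[str], D: np.ndarray) -> str:
    n = len(ids)
    if n == 2:
        h = D[0, 1] / 2.0
        return f"({_nwk_label(ids[0])}:{h:.17g},{_nwk_label(ids[1])}:{h:.17g});"
    joins, join_lens, final_ids, final_lens = _join_sequence(ids, D)
    node = {k: _nwk_label(sid) for k, sid in enumerate(ids)}
    for step in range(joins.shape[0]):
        a, b = int(joins[step, 0]), int(joins[step, 1])
        la, lb = join_lens[step]
        node[n + step] = f"({node.pop(a)}:{la:.17g},{node.pop(b)}:{lb:.17g})"
    parts = [
        f"{node[int(c)]}:{l:.17g}" for c, l in zip(final_ids, final_lens)
    ]
    return "(" + ",".join(parts) + ");"


def _nwk_label(label: str) -> str:
    if any(c in label for c in "():;, '\t\n[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def neighbor_joining(dm: DistanceMatrix) -> SupportTree:
    """Saitou-Nei NJ tree from a fully defined distance matrix."""
    return SupportTree.from_newick(_nj_newick(dm.ids, dm.values))


def nj_split_masks(ids: Sequence[str], D: np.ndarray) -> Set[int]:
    """Nontrivial splits of the NJ tree as leaf-index bitmasks.

    Masks are canonicalized to the side not containing the smallest id.
    Fast path used by the bootstrap (no Newick construction/parsing).
    """
    n = len(ids)
    if n < 4:
        return set()
    joins, _, _, _ = _join_sequence(ids, D)
    members: Dict[int, int] = {k: 1 << k for k in range(n)}
    universe = (1 << n) - 1
    ref_bit = 1 << min(range(n), key=lambda k: ids[k])
    out: Set[int] = set()
    for step in range(joins.shape[0]):
        a, b = int(joins[step, 0]), int(joins[step, 1])
        merged = members[a] | members[b]
        members[n + step] = merged
        if 2 <= merged.bit_count() <= n - 2:
            out.add(universe ^ merged if merged & ref_bit else merged)
    return out


def nj_splits(ids: Sequence[str], D: np.ndarray) -> Set[Split]:
    """Nontrivial splits of the NJ tree, canonicalized on the smallest id."""
    out: Set[Split] = set()
    for mask in nj_split_masks(ids, D):
        out.add(frozenset(ids[k] for k in range(len(ids)) if mask & (1 << k)))
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def alignment_distance(
    aln: LocusAlignment,
    model: str = DEFAULT_MODEL,
    epsilon: float = 1e-3,
) -> DistanceMatrix:
    """Convenience: model distances with imputation of undefined pairs."""
    from .distances import distance_matrix

    return distance_matrix(aln, model=model, undefined="impute", epsilon=epsilon)


def bootstrap_support(
    aln: LocusAlignment,
    model: str = DEFAULT_MODEL,
    replicates: int = 1000,
    seed: int = 0,
    epsilon: float = 1e-3,
) -> SupportTree:
    """Reference NJ tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement ``replicates`` times with one RNG
    seeded by ``seed``; support is the rounded percentage of replicate NJ
    trees containing each reference bipartition.
    """
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    if len(aln) < 3:
        raise InputError("bootstrap requires at least 3 sequences")
    ids = aln.ids
    codes = np.ascontiguousarray(
        np.vstack([encode(aln[i].residues) for i in ids])
    )
    model_id = MODEL_IDS[model]

    def matrix_for(c: np.ndarray) -> np.ndarray:
        c0, c1, v = pack_codes(c)
        values = packed_distance_matrix(c0, c1, v, model_id)
        if np.isnan(values).any():
            dm = DistanceMatrix(ids, values, model,
                                undefined_pairs=[("", "")])
            impute_undefined(dm, epsilon)
            return dm.values
        return values

    ref = SupportTree.from_newick(_nj_newick(ids, matrix_for(codes)))

    counts: Dict[int, int] = {}
    rng = np.random.default_rng(seed)
    L = codes.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        for mask in nj_split_masks(ids, matrix_for(np.ascontiguousarray(codes[:, cols]))):
            counts[mask] = counts.get(mask, 0) + 1

    bit = {sid: 1 << k for k, sid in enumerate(ids)}
    universe = (1 << len(ids)) - 1
    ref_bit = bit[min(ids)]
    n = len(ids)
    for node in ref.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = 0
        for lf in node.leaf_iter():
            below |= bit[lf.taxon.label]
        size = below.bit_count()
        if size < 2 or size > n - 2:
            continue
        key = universe ^ below if below & ref_bit else below
        pct = 100.0 * counts.get(key, 0) / replicates
        node.label = str(int(np.floor(pct + 0.5)))
    ref._splits = None
    return ref


# ---------------------------------------------------------------------------
# monophyly criterion
# ---------------------------------------------------------------------------

def has_supported_monophyly(
    tree: SupportTree,
    leaves: Iterable[str],
    threshold: Optional[int] = 50,
) -> bool:
    """Do ``leaves`` form one clade with support strictly above ``threshold``?

    In an unrooted tree the clade is the bipartition {leaves | rest}.
    Singletons, the full leaf set and (n-1)-subsets are vacuously true (no
    internal edge is implied).  ``threshold=None`` checks topology only.
    """
    want = frozenset(leaves)
    if not want:
        raise InputError("empty leaf set")
    all_leaves = frozenset(tree.leaf_labels)
    unknown = want - all_leaves
    if unknown:
        raise InputError(f"unknown leaf id(s): {sorted(unknown)[:5]}")
    n = len(all_leaves)
    if len(want) in (1, n - 1, n):
        return True
    splits = tree.splits()
    ref = min(all_leaves)
    key = frozenset(all_leaves - want) if ref in want else want
    if key not in splits:
        return False
    if threshold is None:
        return True
    sup = splits[key]
    return sup is not None and sup > threshold
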