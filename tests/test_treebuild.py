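"""NJ construction, bootstrap, and the supported-monophyly criterion."""

import numpy as np
import pytest

import dendropy

from barcodekit.distances import DistanceMatrix
from barcodekit.model import AlignedSequence, InputError, LocusAlignment
from barcodekit.reference import (
    best_topology_splits,
    dendropy_splits,
    random_additive_tree,
)
from barcodekit.treebuild import (
    SupportTree,
    bootstrap_support,
    has_supported_monophyly,
    neighbor_joining,
)


def dm(ids, values):
    return DistanceMatrix(list(ids), np.array(values, dtype=float))


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        t = neighbor_joining(dm("ab", [[0, 0.3], [0.3, 0]]))
        assert t.tree.length() == pytest.approx(0.3)

    def test_three_taxa_hand_solved(self):
        # d(AB)=2, d(AC)=4, d(BC)=4 -> pendants A=1, B=1, C=3
        t = neighbor_joining(dm("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in t.tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxa_additive_recovery(self):
        # distances generated from ((A:1,B:1):1,(C:1,D:1):1)
        D = [
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ]
        t = neighbor_joining(dm("ABCD", D))
        assert t.splits() == {frozenset({"C", "D"}): None}
        labels, P = t.patristic_matrix()
        assert labels == list("ABCD")
        assert np.abs(P - np.array(D, float)).max() < 1e-9

    def test_undefined_entries_rejected(self):
        bad = dm("abc", [[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(InputError):
            neighbor_joining(bad)

    def test_single_taxon_rejected(self):
        with pytest.raises(InputError):
            neighbor_joining(dm("a", [[0]]))

    def test_additive_recovery_random_trees(self, rng):
        """NJ recovers the generating topology and path lengths on additive
        matrices; least-squares exhaustive search agrees for small n."""
        for _ in range(40):
            n = int(rng.integers(4, 9))
            ids, D, true_splits = random_additive_tree(n, rng)
            tree = neighbor_joining(DistanceMatrix(ids, D.copy()))
            assert set(tree.splits()) == true_splits
            labels, P = tree.patristic_matrix()
            order = [ids.index(l) for l in labels]
            assert np.abs(P - D[np.ix_(order, order)]).max() < 1e-9
            if n <= 6:
                assert best_topology_splits(ids, D) == true_splits

    def test_agrees_with_skbio_on_random_matrices(self, rng):
        """Independent cross-check against scikit-bio's NJ (topology only)."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sk_nj

        for _ in range(10):
            n = int(rng.integers(5, 9))
            ids = [f"t{i}" for i in range(n)]
            M = rng.uniform(0.2, 1.0, size=(n, n))
            D = (M + M.T) / 2.0
            np.fill_diagonal(D, 0.0)
            mine = neighbor_joining(DistanceMatrix(ids, D.copy())).splits()
            sk = sk_nj(skbio.DistanceMatrix(D, ids))
            theirs = dendropy_splits(str(sk).strip())
            assert set(mine) == theirs


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment(rng, n_per=4, L=500, between=0.2, within=0.01):
        bases = "ACGT"
        anc = rng.integers(0, 4, L)

        def mutate(s, p):
            s = s.copy()
            hit = rng.random(L) < p
            s[hit] = (s[hit] + rng.integers(1, 4, hit.sum())) % 4
            return s

        g1 = mutate(anc, between / 2)
        g2 = mutate(anc, between / 2)
        rows = []
        for k in range(n_per):
            rows.append(("x%d" % k, mutate(g1, within)))
            rows.append(("y%d" % k, mutate(g2, within)))
        return LocusAlignment(
            "L",
            [
                AlignedSequence(sid, "L", "".join(bases[b] for b in s))
                for sid, s in rows
            ],
        )

    def test_deterministic_given_seed(self, rng):
        aln = self._two_clade_alignment(rng)
        t1 = bootstrap_support(aln, replicates=30, seed=7)
        t2 = bootstrap_support(aln, replicates=30, seed=7)
        assert t1.splits() == t2.splits()
        assert t1.to_newick() == t2.to_newick()

    def test_supports_within_range(self, rng):
        aln = self._two_clade_alignment(rng, within=0.05)
        t = bootstrap_support(aln, replicates=50, seed=3)
        sups = [s for s in t.splits().values() if s is not None]
        assert sups and all(0 <= s <= 100 for s in sups)

    def test_clean_two_clade_signal_saturates(self, rng):
        """Deep two-group divergence yields 100% support for the group split."""
        aln = self._two_clade_alignment(rng, n_per=4, L=500)
        t = bootstrap_support(aln, replicates=100, seed=11)
        group = frozenset(f"y{k}" for k in range(4))
        assert t.splits()[group] == 100

    def test_taxon_order_invariance(self, rng):
        """Same seed (hence same column resamples): supports do not depend on
        the order sequences are listed in."""
        aln = self._two_clade_alignment(rng, within=0.04)
        rows = list(aln)
        shuffled = LocusAlignment("L", rows[::-1])
        t1 = bootstrap_support(aln, replicates=40, seed=5)
        t2 = bootstrap_support(shuffled, replicates=40, seed=5)
        assert t1.splits() == t2.splits()

    def test_replicates_validation(self, rng):
        aln = self._two_clade_alignment(rng)
        with pytest.raises(InputError):
            bootstrap_support(aln, replicates=0, seed=1)


class TestSupportedMonophyly:
    @pytest.mark.parametrize(
        "newick,leaves,threshold,expected",
        [
            ("((a1,a2)75,(b1,b2)60);", {"a1", "a2"}, 50, True),
            ("((a1,a2)75,(b1,b2)60);", {"a1", "b1"}, 50, False),
            ("((a1,a2)45,(b1,b2)45);", {"a1", "a2"}, 50, False),
        ],
    )
    def test_spec_examples(self, newick, leaves, threshold, expected):
        t = SupportTree.from_newick(newick)
        assert has_supported_monophyly(t, leaves, threshold) is expected

    def test_vacuous_cases(self):
        t = SupportTree.from_newick("((a1,a2)10,(b1,b2)10);")
        assert has_supported_monophyly(t, {"a1"}, 50)  # singleton
        assert has_supported_monophyly(t, {"a1", "a2", "b1"}, 50)  # n-1
        assert has_supported_monophyly(t, {"a1", "a2", "b1", "b2"}, 50)

    def test_unknown_leaf_rejected(self):
        t = SupportTree.from_newick("((a1,a2)75,(b1,b2)60);")
        with pytest.raises(InputError):
            has_supported_monophyly(t, {"zz"}, 50)

    def test_agrees_with_bipartition_enumeration(self, rng):
        """Random trees with random supports: decision matches a brute-force
        oracle reading dendropy's bipartition encoding directly."""
        for _ in range(40):
            n = int(rng.integers(4, 11))
            ids, D, _ = random_additive_tree(n, rng)
            tree = neighbor_joining(DistanceMatrix(ids, D.copy()))
            for node in tree.tree.preorder_node_iter():
                if not node.is_leaf() and node.parent_node is not None:
                    node.label = str(int(rng.integers(0, 101)))
            tree._splits = None
            newick = tree.to_newick()
            for _ in range(6):
                k = int(rng.integers(1, n + 1))
                subset = set(rng.choice(ids, size=k, replace=False))
                got = has_supported_monophyly(tree, subset, 50)
                assert got == _oracle_monophyly(newick, subset, 50)


def _oracle_monophyly(newick, leaves, threshold):
    """Enumerate bipartitions with dendropy and read edge support labels."""
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    labels = {lf.taxon.label for lf in t.leaf_node_iter()}
    n = len(labels)
    if len(leaves) in (1, n - 1, n):
        return True
    hits = []
    for node in t.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == set(leaves) or (labels - below) == set(leaves):
            try:
                hits.append(int(node.label))
            except (TypeError, ValueError):
                hits.append(None)
    if not hits:
        return False
    sups = [h for h in hits if h is not None]
    return bool(sups) and max(sups) > threshold
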