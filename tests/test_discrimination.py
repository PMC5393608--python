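"""Best-hit ranking, both success criteria, and misidentification flagging."""

import numpy as np
import pytest

from barcodekit.discrimination import (
    DiscriminationRecord,
    best_hits,
    build_score_table,
    discrimination_rate,
    flag_misidentifications,
    similarity_success,
    tree_success,
)
from barcodekit.model import InputError
from barcodekit.simulate import preset, simulate_dataset
from barcodekit.treebuild import SupportTree

from conftest import make_dataset, mutate


class TestBestHits:
    def test_conspecific_unique_top_hit(self, two_species_dataset):
        hl = best_hits("a1", two_species_dataset, ["rbcL"])
        assert hl.self_excluded
        assert hl.top_set == {"a2"}

    def test_singleton_keeps_self_hit(self):
        base = "ACGT" * 25
        ds = make_dataset(
            [("s1", "Solo x", "Solo"), ("o1", "Other y", "Other")],
            {"rbcL": {"s1": base, "o1": mutate(base, range(0, 100, 9), "T")}},
        )
        hl = best_hits("s1", ds, ["rbcL"])
        assert not hl.self_excluded
        assert hl.top_set == {"s1"}  # self-score is maximal

    def test_equal_scores_share_top_set(self):
        base = "ACGT" * 25
        ds = make_dataset(
            [
                ("q", "Qq x", "Qq"),
                ("c1", "Qq x", "Qq"),
                ("h1", "Hh y", "Hh"),
            ],
            {"rbcL": {"q": base, "c1": base, "h1": base}},
        )
        hl = best_hits("q", ds, ["rbcL"])
        assert hl.top_set == {"c1", "h1"}

    def test_query_without_marker_rejected(self, two_species_dataset):
        ds = make_dataset(
            [("a1", "A x", "A"), ("b1", "B y", "B")],
            {"rbcL": {"b1": "ACGT" * 10}},
        )
        with pytest.raises(InputError):
            best_hits("a1", ds, ["rbcL"])

    def test_multilocus_scores_sum_over_shared_loci(self):
        base = "ACGT" * 25
        ds = make_dataset(
            [("q", "Qq x", "Qq"), ("r", "Qq x", "Qq"), ("s", "Ss y", "Ss")],
            {
                "L1": {"q": base, "r": base, "s": base},
                "L2": {"q": base, "r": base},
            },
        )
        hl = best_hits("q", ds, ["L1", "L2"])
        scores = dict(hl.hits)
        assert scores["r"] == 2 * scores["s"]  # r shares both loci


class TestSimilaritySuccess:
    def test_perfect_gap_both_succeed(self, two_species_dataset):
        recs = similarity_success(two_species_dataset, ["rbcL"], "species", "n2")
        assert len(recs) == 2 and all(r.success for r in recs)
        rs = discrimination_rate(recs)
        assert (rs.successes, rs.total) == (2, 2)

    def test_planted_intruder_fails_both_species(self):
        """a1 of species A sits inside B's cluster: A and B both fail."""
        base = "ACGT" * 30
        far = mutate(base, range(0, 120, 7), "T")
        ds = make_dataset(
            [
                ("a1", "Aa x", "Aa"),
                ("a2", "Aa x", "Aa"),
                ("a3", "Aa x", "Aa"),
                ("b1", "Bb y", "Bb"),
                ("b2", "Bb y", "Bb"),
            ],
            {
                "rbcL": {
                    "a1": far,  # planted inside B's cluster
                    "a2": base,
                    "a3": mutate(base, [11], "A"),
                    "b1": far,
                    "b2": mutate(far, [13], "A"),
                }
            },
        )
        recs = {r.taxon: r for r in similarity_success(ds, ["rbcL"], "species", "n2")}
        assert not recs["Aa x"].success
        assert not recs["Bb y"].success
        assert "a1" in recs["Aa x"].reason or "b" in recs["Aa x"].reason

    def test_singleton_vacuous_success_switch(self):
        base = "ACGT" * 25
        ds = make_dataset(
            [("s1", "Solo x", "Solo"), ("o1", "Other y", "Other"),
             ("o2", "Other y", "Other")],
            {
                "rbcL": {
                    "s1": base,
                    "o1": mutate(base, range(0, 100, 9), "T"),
                    "o2": mutate(base, range(0, 100, 9), "T"),
                }
            },
        )
        n1 = {r.taxon: r for r in similarity_success(ds, ["rbcL"], "species", "n1")}
        assert n1["Solo x"].success  # self-hit retained -> vacuous success
        strict = similarity_success(
            ds, ["rbcL"], "species", "n1", include_vacuous_singletons=False
        )
        assert "Solo x" not in {r.taxon for r in strict}
        n2 = similarity_success(ds, ["rbcL"], "species", "n2")
        assert {r.taxon for r in n2} == {"Other y"}

    def test_genus_level_accepts_congeneric_heterospecific_hits(self):
        base = "ACGT" * 30
        sister = mutate(base, range(0, 120, 11), "T")  # closest to g1
        ds = make_dataset(
            [
                ("g1", "Gen alpha", "Gen"),
                ("g1b", "Gen alpha", "Gen"),
                ("g2", "Gen beta", "Gen"),
                ("h1", "Hen gamma", "Hen"),
                ("h2", "Hen gamma", "Hen"),
            ],
            {
                "rbcL": {
                    "g1": base,
                    "g1b": mutate(base, range(0, 120, 6), "T"),  # farther
                    "g2": sister,
                    "h1": mutate(base, range(0, 120, 5), "C"),
                    "h2": mutate(base, range(1, 120, 5), "C"),
                }
            },
        )
        # g1's best hit is its congener g2, not its conspecific g1b:
        # species-level fails but genus-level passes
        species = {r.taxon: r for r in similarity_success(ds, ["rbcL"], "species", "n2")}
        assert not species["Gen alpha"].success
        genus = {r.taxon: r for r in similarity_success(ds, ["rbcL"], "genus", "n2")}
        assert genus["Gen"].success


class TestTreeSuccess:
    def _dataset(self):
        return make_dataset(
            [
                ("a1", "Aa x", "Aa"), ("a2", "Aa x", "Aa"),
                ("b1", "Bb y", "Bb"), ("b2", "Bb y", "Bb"),
                ("c1", "Cc z", "Cc"),
            ],
            {"rbcL": {i: "ACGT" for i in ("a1", "a2", "b1", "b2", "c1")}},
        )

    def test_supported_clades_succeed_singleton_excluded(self):
        tree = SupportTree.from_newick("((a1,a2)90,((b1,b2)80,c1)70);")
        recs = {r.taxon: r for r in tree_success(tree, self._dataset(), "species")}
        assert recs["Aa x"].success and recs["Bb y"].success
        assert "Cc z" not in recs  # singleton cannot be tested

    def test_interleaved_species_fail(self):
        tree = SupportTree.from_newick("((a1,b1)90,(a2,b2)90,c1);")
        recs = {r.taxon: r for r in tree_success(tree, self._dataset(), "species")}
        assert not recs["Aa x"].success and not recs["Bb y"].success
        assert "single clade" in recs["Aa x"].reason

    def test_low_support_fails_with_reason(self):
        tree = SupportTree.from_newick("((a1,a2)40,(b1,b2)80,c1);")
        recs = {r.taxon: r for r in tree_success(tree, self._dataset(), "species")}
        assert not recs["Aa x"].success
        assert "support" in recs["Aa x"].reason
        assert recs["Bb y"].success

    def test_genus_level(self):
        ds = make_dataset(
            [
                ("ga1", "GA s1", "GA"), ("ga2", "GA s2", "GA"),
                ("gb1", "GB s1", "GB"), ("gb2", "GB s2", "GB"),
                ("x1", "X s1", "X"),
            ],
            {"rbcL": {i: "ACGT" for i in ("ga1", "ga2", "gb1", "gb2", "x1")}},
        )
        # gb1 breaks into the gA clade's sister position: gB is paraphyletic
        tree = SupportTree.from_newick("(((ga1,ga2)95,gb1)90,gb2,x1);")
        recs = {r.taxon: r for r in tree_success(tree, ds, "genus")}
        assert recs["GA"].success
        assert not recs["GB"].success
        assert "X" not in recs  # singleton genus excluded


class TestRate:
    def test_arithmetic(self):
        recs = [
            DiscriminationRecord(f"t{i}", "species", "tree", ("L",), "n2",
                                 i < 5, "")
            for i in range(8)
        ]
        rs = discrimination_rate(recs)
        assert (rs.successes, rs.total, rs.rate) == (5, 8, 0.625)

    def test_empty_undefined(self):
        with pytest.raises(InputError):
            discrimination_rate([])

    def test_mixed_settings_rejected(self):
        recs = [
            DiscriminationRecord("a", "species", "tree", ("L",), "n2", True, ""),
            DiscriminationRecord("b", "genus", "tree", ("L",), "n2", True, ""),
        ]
        with pytest.raises(InputError):
            discrimination_rate(recs)


class TestLabelSymmetry:
    def test_swapping_two_species_names_preserves_rates(self):
        """Relabelling all members of two species by exchanging their names
        must leave discrimination rates unchanged."""
        config = preset("strong_gap", n_genera=2, seed=5)
        ds, _ = simulate_dataset(config)
        sp = ds.species_labels()
        x, y = sp[0], sp[3]
        genus_for = {
            s.assigned_species: s.assigned_genus for s in ds.specimens.values()
        }
        # exchange the labels wholesale (keep each name's original genus so
        # the metadata invariant still holds for single-token names)
        swap = {}
        for sid in ds.specimen_ids:
            if ds.species_of(sid) == x:
                swap[sid] = y
            elif ds.species_of(sid) == y:
                swap[sid] = x
        relabelled = ds.relabel(swap, genus_for)
        r1 = discrimination_rate(
            similarity_success(ds, ["rbcL"], "species", "n2")
        )
        r2 = discrimination_rate(
            similarity_success(relabelled, ["rbcL"], "species", "n2")
        )
        assert (r1.successes, r1.total) == (r2.successes, r2.total)


class TestFlagging:
    def test_zero_swaps_no_flags(self):
        ds, truth = simulate_dataset(
            preset("strong_gap", n_genera=4, seed=3, swap_rate=0.0)
        )
        assert not truth.swaps
        rep = flag_misidentifications(ds, replicates=50, seed=9)
        assert rep.flags == []

    def test_planted_swap_recovered_with_proposal(self):
        ds, truth = simulate_dataset(
            preset("strong_gap", n_genera=4, seed=11, swap_rate=0.08)
        )
        assert truth.swaps  # this seed plants at least one swap
        rep = flag_misidentifications(ds, replicates=50, seed=13)
        assert {f.specimen_id for f in rep.flags} == truth.swapped_ids
        for f in rep.flags:
            assert f.proposed_species == truth.true_species[f.specimen_id]
            assert f.n_markers_agreeing >= 2

    def test_below_quorum_not_flagged_but_logged(self):
        ds, truth = simulate_dataset(
            preset("strong_gap", n_genera=4, seed=11, swap_rate=0.08)
        )
        rep = flag_misidentifications(
            ds, marker_sets=[("rbcL",)], quorum=2, replicates=50, seed=13
        )
        assert rep.flags == []  # one marker set can never reach quorum 2
        assert any("below quorum" in n or "insufficient" in n for n in rep.notes)

    def test_quorum_validation(self, two_species_dataset):
        with pytest.raises(InputError):
            flag_misidentifications(two_species_dataset, quorum=0)
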