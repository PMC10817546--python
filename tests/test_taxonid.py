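"""Annotation, trees, alignment, and clade-rule classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from amfdiv.simcomm import SPACER_ANCHORS
from amfdiv.taxonid import (
    ClassifyThresholds,
    annotate_best_hit,
    bootstrap_support,
    center_star_align,
    classify_genus_bin,
    diagnostic_sites,
    nj_tree,
    p_distance,
    p_distance_matrix,
    precluster_alignment_free,
    species_summary,
    trim_rrna,
)

from conftest import mutate_seq, random_seq


class TestAnnotate:
    TAX = {
        "A1": ("P", "C", "O", "F", "G1", "G1 s1"),
        "B1": ("P", "C", "O", "F", "G2", "G2 s1"),
    }

    def test_best_hit(self):
        rng = np.random.default_rng(0)
        ref = random_seq(rng, 150)
        other = random_seq(rng, 150)
        ann = annotate_best_hit("o1", mutate_seq(rng, ref, 3), [("A1", ref), ("B1", other)], self.TAX)
        assert ann.accession == "A1"
        assert ann.genus == "G1"
        assert not ann.ambiguous

    def test_below_min_identity_unclassified(self):
        rng = np.random.default_rng(1)
        ann = annotate_best_hit(
            "o1", random_seq(rng, 150), [("A1", random_seq(rng, 150))], self.TAX
        )
        assert ann.accession is None and ann.lineage is None

    def test_cross_genus_tie_flagged_ambiguous(self):
        seq = "ACGT" * 40
        ann = annotate_best_hit("o1", seq, [("B1", seq), ("A1", seq)], self.TAX)
        assert ann.ambiguous
        assert ann.accession == "A1"  # lexicographic resolution


class TestTrimRrna:
    def test_explicit_bounds(self):
        seq, ok = trim_rrna("XXXSPACERYYY", bounds=(3, 9))
        assert (seq, ok) == ("SPACER", True)

    def test_anchor_based(self):
        left, right = SPACER_ANCHORS["ITS1"]
        spacer = "ACGTACGTACGTACGT"
        seq = "TT" + left + spacer + right + "GG"
        out, ok = trim_rrna(seq, region="ITS1")
        assert ok and out == spacer

    def test_anchor_one_mismatch(self):
        left, right = SPACER_ANCHORS["ITS2"]
        left_mut = "A" + left[1:] if left[0] != "A" else "C" + left[1:]
        spacer = "TTTTCCCCGGGG"
        out, ok = trim_rrna(left_mut + spacer + right, region="ITS2")
        assert ok and out == spacer

    def test_missing_anchor_flagged(self):
        out, ok = trim_rrna("ACGT" * 30, region="ITS1")
        assert not ok and out == "ACGT" * 30


class TestPDistance:
    def test_identical(self):
        assert p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_hand_case_pairwise_deletion(self):
        # aligned: A-CGT vs AACGA -> comparable 4 cols, 1 diff
        assert p_distance("A-CGT", "AACGA", aligned=True) == pytest.approx(0.25)

    def test_all_gap_columns_raise(self):
        with pytest.raises(ValueError):
            p_distance("--", "AA", aligned=True)

    def test_matrix_symmetric_zero_diag(self):
        aln = {"a": "ACGT", "b": "ACGA", "c": "TCGA"}
        d = p_distance_matrix(aln)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)
        assert d.loc["a", "b"] == pytest.approx(0.25)
        assert d.loc["a", "c"] == pytest.approx(0.5)


def _random_additive_matrix(rng, n):
    """Distances realized by a random binary tree with positive lengths."""
    labels = [f"L{i}" for i in range(n)]
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    clusters = [{l: 0.0} for l in labels]  # leaf -> distance to cluster root
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        la, lb = rng.uniform(0.05, 1.0, 2)
        a, b = clusters[i], clusters[j]
        for x, dx in a.items():
            for y, dy in b.items():
                D.loc[x, y] = D.loc[y, x] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in a.items()}
        merged.update({y: dy + lb for y, dy in b.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return D


class TestNjTree:
    def test_four_taxa_textbook_example(self):
        labels = list("abcd")
        d = pd.DataFrame(
            [
                [0, 3, 7, 8],
                [3, 0, 6, 7],
                [7, 6, 0, 5],
                [8, 7, 5, 0],
            ],
            index=labels,
            columns=labels,
            dtype=float,
        )
        tree = nj_tree(d)
        tt = tree.tip_tip_distances()
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert tt[a, b] == pytest.approx(d.loc[a, b], abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_recovers_additive_distances_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        D = _random_additive_matrix(rng, n)
        tree = nj_tree(D)
        tt = tree.tip_tip_distances()
        for a in D.index:
            for b in D.index:
                if a != b:
                    assert tt[a, b] == pytest.approx(D.loc[a, b], abs=1e-8)

    def test_deterministic_tie_break(self):
        labels = list("abcd")
        d = pd.DataFrame(1.0, index=labels, columns=labels)
        np.fill_diagonal(d.values, 0.0)
        t1 = nj_tree(d)
        t2 = nj_tree(d)
        assert str(t1) == str(t2)

    def test_validation(self):
        labels = list("ab")
        d = pd.DataFrame([[0, 1], [1, 0]], index=labels, columns=labels, dtype=float)
        with pytest.raises(ValueError):
            nj_tree(d)  # fewer than 3 taxa
        labels = list("abc")
        bad = pd.DataFrame(
            [[0, 1, 2], [9, 0, 1], [2, 1, 0]], index=labels, columns=labels, dtype=float
        )
        with pytest.raises(ValueError):
            nj_tree(bad)  # asymmetric


class TestBootstrapSupport:
    def test_clean_signal_full_support(self):
        rng = np.random.default_rng(2)
        anc = random_seq(rng, 200)
        g1 = mutate_seq(rng, anc, 30)
        aln = {
            "a1": anc,
            "a2": mutate_seq(rng, anc, 2),
            "b1": g1,
            "b2": mutate_seq(rng, g1, 2),
        }
        tree, supports = bootstrap_support(aln, n_reps=100, seed=0)
        assert len(supports) == 1
        (bp, sup), = supports.items()
        assert sup >= 95.0
        assert bp in (frozenset({"a1", "a2"}), frozenset({"b1", "b2"}))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        anc = random_seq(rng, 120)
        aln = {f"x{i}": mutate_seq(rng, anc, 6) for i in range(5)}
        _, s1 = bootstrap_support(aln, n_reps=50, seed=9)
        _, s2 = bootstrap_support(aln, n_reps=50, seed=9)
        assert s1 == s2


class TestCenterStar:
    def test_equal_length_no_indels(self):
        rng = np.random.default_rng(4)
        anc = random_seq(rng, 100)
        seqs = {"c": anc, "a": mutate_seq(rng, anc, 5), "b": mutate_seq(rng, anc, 5)}
        aln = center_star_align(seqs)
        assert set(aln) == set(seqs)
        lens = {len(v) for v in aln.values()}
        assert lens == {100}
        for k in seqs:
            assert aln[k].replace("-", "") == seqs[k]

    def test_insertion_padded(self):
        seqs = {"long": "ACGTACGTTTACGTACGTAA", "short": "ACGTACGTACGTACGTAA"}
        aln = center_star_align(seqs)
        assert len(aln["long"]) == len(aln["short"])
        assert aln["short"].count("-") == 2
        assert aln["short"].replace("-", "") == seqs["short"]

    def test_single_sequence(self):
        assert center_star_align({"x": "ACGT"}) == {"x": "ACGT"}


class TestDiagnosticSites:
    def test_hand_example(self):
        aln = {"r1": "AACGT", "r2": "AACGT", "s1": "ATCGA", "s2": "ATCGA"}
        species = {"r1": "sp1", "r2": "sp1", "s1": "sp2", "s2": "sp2"}
        out = diagnostic_sites(aln, species)
        assert out["sp1"] == [1, 4]
        assert out["sp2"] == [1, 4]

    def test_single_species_empty(self):
        assert diagnostic_sites({"r1": "ACGT"}, {"r1": "sp1"}) == {}


class TestPrecluster:
    def test_two_genera_split(self):
        rng = np.random.default_rng(5)
        g1 = random_seq(rng, 150)
        g2 = random_seq(rng, 150)
        seqs = {
            "g1a": g1,
            "g1b": mutate_seq(rng, g1, 5),
            "g2a": g2,
            "g2b": mutate_seq(rng, g2, 5),
        }
        clusters = precluster_alignment_free(seqs)
        members = sorted(tuple(c["members"]) for c in clusters)
        assert ("g1a", "g1b") in members
        assert ("g2a", "g2b") in members
        assert all(c["alignable"] for c in clusters)

    def test_singleton_input(self):
        assert precluster_alignment_free({"x": "ACGT" * 20}) == [
            {"members": ["x"], "alignable": True}
        ]


class TestClassifyGenusBin:
    def _genus(self, seed=6):
        rng = np.random.default_rng(seed)
        anc = random_seq(rng, 200)
        sp1 = mutate_seq(rng, anc, 10)
        sp2 = mutate_seq(rng, anc, 10)
        ref_spacers = {"R1": sp1, "R2": sp2}
        ref_species = {"R1": "Genus sp1", "R2": "Genus sp2"}
        return rng, sp1, sp2, ref_spacers, ref_species

    def test_species_call_near_reference(self):
        rng, sp1, sp2, ref_spacers, ref_species = self._genus()
        otus = {"O1": mutate_seq(rng, sp1, 2), "O2": mutate_seq(rng, sp2, 2)}
        calls, tree = classify_genus_bin(
            "Genus", otus, ref_spacers, ref_species, n_boot=50, seed=0
        )
        verdicts = {c.otu_id: (c.verdict, c.label) for c in calls}
        assert verdicts["O1"] == ("species", "Genus sp1")
        assert verdicts["O2"] == ("species", "Genus sp2")

    def test_reference_free_pair_becomes_vt(self):
        rng, sp1, sp2, ref_spacers, ref_species = self._genus(seed=7)
        novel = mutate_seq(rng, sp1, 16)  # ~8% away: congeneric but no species
        otus = {
            "O1": novel,
            "O2": mutate_seq(rng, novel, 2),
        }
        calls, _ = classify_genus_bin(
            "Genus", otus, ref_spacers, ref_species, n_boot=50, seed=0
        )
        verdicts = {c.otu_id: c for c in calls}
        assert verdicts["O1"].verdict == "vt_species"
        assert verdicts["O1"].label == verdicts["O2"].label
        assert verdicts["O1"].label.startswith("VT_Genus_")

    def test_distant_otu_excluded(self):
        rng, sp1, sp2, ref_spacers, ref_species = self._genus(seed=8)
        far = random_seq(rng, 200)  # unrelated, p-distance >> t_genus
        calls, _ = classify_genus_bin(
            "Genus", {"O1": far, "O2": mutate_seq(rng, sp1, 2)},
            ref_spacers, ref_species, n_boot=50, seed=0,
        )
        v = {c.otu_id: c.verdict for c in calls}
        assert v["O1"] == "excluded_vt_higher"
        assert v["O2"] == "species"

    def test_tiny_bin_fallback_without_tree(self):
        rng, sp1, _, ref_spacers, ref_species = self._genus(seed=9)
        calls, tree = classify_genus_bin(
            "Genus", {"O1": mutate_seq(rng, sp1, 2)}, {"R1": sp1},
            {"R1": "Genus sp1"},
        )
        assert tree is None
        assert calls[0].verdict == "species"


class TestSpeciesSummary:
    def test_counts_venn_endemics(self):
        from amfdiv.taxonid import TaxonCall

        counts = pd.DataFrame(
            {
                "O1": [5, 0, 0],
                "O2": [2, 3, 0],
                "O3": [0, 0, 7],
                "O4": [0, 1, 0],
            },
            index=["s1", "s2", "s3"],
        )
        biotopes = {"s1": "meadow", "s2": "forest", "s3": "valley"}
        calls = [
            TaxonCall("O1", "species", "SpA", 90, 0.0),
            TaxonCall("O2", "species", "SpB", 90, 0.0),
            TaxonCall("O3", "vt_species", "VT_G_1", float("nan"), 0.1),
            TaxonCall("O4", "excluded_vt_higher", "VTX_G", float("nan"), 0.3),
        ]
        out = species_summary(calls, counts, biotopes)
        assert out["per_biotope"]["meadow"] == {
            "n_otus": 2, "n_species": 2, "n_vt_species": 0,
        }
        assert out["per_biotope"]["forest"]["n_otus"] == 2
        assert out["per_biotope"]["forest"]["n_species"] == 1  # excluded VTX not counted
        assert out["per_biotope"]["valley"] == {
            "n_otus": 1, "n_species": 0, "n_vt_species": 1,
        }
        assert out["venn"][("meadow",)] == 1  # SpA only in meadow
        assert out["venn"][("forest", "meadow")] == 1  # SpB shared
        assert out["endemics"]["meadow"] == ["SpA"]
        assert out["endemics"]["valley"] == []  # VT labels not listed as endemics
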