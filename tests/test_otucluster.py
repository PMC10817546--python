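"""Identity convention, dereplication and two-step OTU clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amfdiv.otucluster import (
    DereplicatedSeq,
    build_otu_table,
    chimera_check,
    closed_ref_map,
    denovo_cluster,
    dereplicate,
    global_identity,
    two_step_cluster,
)

from conftest import mutate_seq, oracle_identity, random_seq


class TestGlobalIdentity:
    def test_identical(self):
        assert global_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_single_terminal_gap(self):
        # ACGT vs ACG: 3 matches over 4 columns (terminal gap counted)
        assert global_identity("ACGT", "ACG") == pytest.approx(0.75)

    def test_single_mismatch(self):
        assert global_identity("ACGTACGTAC", "ACGTTCGTAC") == pytest.approx(0.9)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = random_seq(rng, int(rng.integers(30, 80)))
            b = mutate_seq(rng, a, int(rng.integers(0, 10)))
            assert global_identity(a, b) == pytest.approx(global_identity(b, a))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            global_identity("", "ACGT")

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_independent_gotoh_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 90))
        a = random_seq(rng, n)
        kind = rng.integers(0, 3)
        if kind == 0:
            b = mutate_seq(rng, a, int(rng.integers(0, max(2, n // 5))))
        elif kind == 1:
            b = random_seq(rng, int(rng.integers(20, 90)))
        else:
            cut = int(rng.integers(1, n))
            b = a[:cut] + a[cut + int(rng.integers(0, min(4, n - cut))) :]
            if not b:
                b = a[:1]
        assert global_identity(a, b) == pytest.approx(oracle_identity(a, b), abs=1e-9)


class TestDereplicate:
    def test_counts_and_order(self):
        reads = [
            ("s1", "AAAA"),
            ("s2", "AAAA"),
            ("s1", "CCCC"),
            ("s1", "AAAA"),
            ("s3", "GGGG"),
        ]
        out = dereplicate(reads)
        assert [(d.sequence, d.total_abundance) for d in out] == [
            ("AAAA", 3),
            ("CCCC", 1),
            ("GGGG", 1),
        ]
        assert out[0].per_sample_counts == {"s1": 2, "s2": 1}

    def test_total_abundance_validation(self):
        with pytest.raises(ValueError):
            DereplicatedSeq("AAAA", 5, {"s1": 2})


class TestClosedRefMap:
    def test_exact_hit_and_miss(self):
        rng = np.random.default_rng(1)
        ref = random_seq(rng, 200)
        far = random_seq(rng, 200)
        dereps = [
            DereplicatedSeq(ref, 4, {"s1": 4}),
            DereplicatedSeq(mutate_seq(rng, ref, 3), 2, {"s1": 2}),  # ~98.5%
            DereplicatedSeq(far, 9, {"s1": 9}),
        ]
        assign, unmapped = closed_ref_map(dereps, [("ACC1", ref)])
        assert [(i, a) for i, a, _ in assign] == [(0, "ACC1"), (1, "ACC1")]
        assert unmapped == [2]

    def test_singletons_are_eligible(self):
        rng = np.random.default_rng(2)
        ref = random_seq(rng, 200)
        dereps = [DereplicatedSeq(mutate_seq(rng, ref, 2), 1, {"s1": 1})]
        assign, unmapped = closed_ref_map(dereps, [("ACC1", ref)])
        assert len(assign) == 1 and unmapped == []

    def test_tie_breaks_to_lexicographically_smaller_accession(self):
        seq = "ACGT" * 50
        dereps = [DereplicatedSeq(seq, 3, {"s1": 3})]
        assign, _ = closed_ref_map(dereps, [("B", seq), ("A", seq)])
        assert assign[0][1] == "A"


class TestChimeraCheck:
    def _parents(self, rng, n=200, d=20):
        p1 = random_seq(rng, n)
        p2 = mutate_seq(rng, p1, d)  # ~90% apart from p1
        return p1, p2

    def test_true_chimera_detected(self):
        rng = np.random.default_rng(3)
        p1, p2 = self._parents(rng)
        q = p1[:100] + p2[100:]
        assert chimera_check(q, [p1, p2]) is True

    def test_pure_parent_not_chimera(self):
        rng = np.random.default_rng(4)
        p1, p2 = self._parents(rng)
        assert chimera_check(p1, [p1, p2]) is False

    def test_near_parent_not_chimera(self):
        # within the radius of one parent -> explained by a single parent
        rng = np.random.default_rng(5)
        p1, p2 = self._parents(rng)
        q = mutate_seq(rng, p1, 3)
        assert chimera_check(q, [p1, p2]) is False

    def test_fewer_than_two_centroids_vacuous(self):
        assert chimera_check("ACGT" * 30, ["ACGT" * 30]) is False


class TestDenovoCluster:
    def test_greedy_abundance_order_and_singleton_removal(self):
        rng = np.random.default_rng(6)
        a = random_seq(rng, 200)
        b = mutate_seq(rng, a, 2)  # 99% -> joins a's cluster
        c = mutate_seq(rng, a, 40)  # ~80% -> own centroid
        lone = mutate_seq(rng, c, 40)
        dereps = [
            DereplicatedSeq(a, 10, {"s1": 10}),
            DereplicatedSeq(b, 3, {"s1": 3}),
            DereplicatedSeq(c, 5, {"s1": 5}),
            DereplicatedSeq(lone, 1, {"s1": 1}),
        ]
        records, assignments, discards = denovo_cluster(dereps)
        assert [r.otu_id for r in records] == ["DN0001", "DN0002"]
        got = dict((i, o) for i, o, _ in assignments)
        assert got == {0: "DN0001", 1: "DN0001", 2: "DN0002"}
        assert discards == [(3, "residual_singleton")]

    def test_two_singletons_can_rescue_each_other(self):
        rng = np.random.default_rng(7)
        a = random_seq(rng, 200)
        b = mutate_seq(rng, a, 2)
        dereps = [
            DereplicatedSeq(a, 1, {"s1": 1}),
            DereplicatedSeq(b, 1, {"s2": 1}),
        ]
        records, assignments, discards = denovo_cluster(dereps)
        assert len(records) == 1 and discards == []
        assert {i for i, _, _ in assignments} == {0, 1}

    def test_chimera_discarded_in_pass(self):
        rng = np.random.default_rng(8)
        p1 = random_seq(rng, 200)
        p2 = mutate_seq(rng, p1, 20)
        chim = p1[:100] + p2[100:]
        dereps = [
            DereplicatedSeq(p1, 10, {"s1": 10}),
            DereplicatedSeq(p2, 8, {"s1": 8}),
            DereplicatedSeq(chim, 2, {"s1": 2}),
        ]
        _, _, discards = denovo_cluster(dereps)
        assert (2, "chimera") in discards


class TestBuildOtuTable:
    def test_counts_sum_and_shape(self):
        dereps = [
            DereplicatedSeq("AAAA", 3, {"s1": 2, "s2": 1}),
            DereplicatedSeq("CCCC", 2, {"s2": 2}),
        ]
        table = build_otu_table(dereps, [(0, "X"), (1, "Y")], samples=["s1", "s2"])
        assert table.counts.shape == (2, 2)
        assert int(table.counts.values.sum()) == 5
        assert int(table.counts.loc["s2", "Y"]) == 2

    def test_roundtrip_tsv(self, tmp_path):
        dereps = [DereplicatedSeq("AAAA", 3, {"s1": 2, "s2": 1})]
        table = build_otu_table(dereps, [(0, "X")], samples=["s1", "s2"])
        p = tmp_path / "t.tsv"
        table.to_tsv(p)
        back = type(table).from_tsv(p)
        assert back.counts.equals(table.counts)


class TestTwoStep:
    def test_reference_ids_prefixed_and_read_conservation(self):
        rng = np.random.default_rng(9)
        ref = random_seq(rng, 200)
        novel = random_seq(rng, 200)
        dereps = [
            DereplicatedSeq(mutate_seq(rng, ref, 2), 6, {"s1": 6}),
            DereplicatedSeq(novel, 4, {"s1": 4}),
            DereplicatedSeq(mutate_seq(rng, novel, 1), 3, {"s2": 3}),
        ]
        records, table, discards = two_step_cluster(dereps, [("AMF0101", ref)])
        ids = {r.otu_id for r in records}
        assert "REF_AMF0101" in ids
        assert any(i.startswith("DN") for i in ids)
        total_in = sum(d.total_abundance for d in dereps)
        discarded = sum(dereps[i].total_abundance for i, _ in discards)
        assert int(table.counts.values.sum()) + discarded == total_in
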