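"""Two-stage clustering, representative selection, and recovery on synthetic families."""

import numpy as np
import pytest

from rnapscreen import align, cluster, synthetic
from rnapscreen.cluster import IdentityMatrix
from rnapscreen.seqio import EnzymeRecord


def hand_matrix(ids, values):
    return IdentityMatrix(ids=ids, values=np.array(values, dtype=float), kind="global")


class TestIdentityMatrix:
    def test_single_record(self):
        m = cluster.build_identity_matrix(
            [EnzymeRecord(accession="a", protein_seq="MKVL")]
        )
        assert m.values.tolist() == [[100.0]]

    def test_matches_per_pair_oracle(self, small_library):
        m = cluster.build_identity_matrix(small_library)
        for i, ri in enumerate(small_library):
            for j, rj in enumerate(small_library):
                if i == j:
                    continue
                expected = align.global_identity(
                    ri.protein_seq, rj.protein_seq
                ).identity_pct
                assert m.values[i, j] == pytest.approx(expected)

    def test_symmetric_on_random_library(self, rng):
        records = [
            EnzymeRecord(
                accession=f"r{i}",
                protein_seq="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40)),
            )
            for i in range(20)
        ]
        m = cluster.build_identity_matrix(records)
        assert np.allclose(m.values, m.values.T)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster.build_identity_matrix([])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            hand_matrix(["a", "b"], [[100, 50], [60, 100]])


class TestStage1:
    def test_two_planted_families_recovered(self):
        records, truth = synthetic.generate_rnap_library(
            2, [4, 3], within_div=0.02, between_div=0.6, rng_seed=11
        )
        m = cluster.build_identity_matrix(records)
        cs = cluster.cluster_stage1(m)
        got = {frozenset(c) for c in cs.clusters}
        want = {
            frozenset(a for a, f in truth.family_label.items() if f == k)
            for k in (0, 1)
        }
        assert got == want

    def test_singleton_library(self):
        m = hand_matrix(["a"], [[100.0]])
        cs = cluster.cluster_stage1(m)
        assert cs.clusters == [frozenset({"a"})]

    def test_threshold_is_strict(self):
        m = hand_matrix(["a", "b"], [[100, 85], [85, 100]])
        assert len(cluster.cluster_stage1(m, 85.0)) == 2
        m2 = hand_matrix(["a", "b"], [[100, 85.1], [85.1, 100]])
        assert len(cluster.cluster_stage1(m2, 85.0)) == 1

    def test_raising_threshold_never_merges(self, rng):
        vals = rng.uniform(0, 100, size=(8, 8))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 100.0)
        m = hand_matrix([f"r{i}" for i in range(8)], vals)
        sizes = [
            len(cluster.cluster_stage1(m, t)) for t in (20, 40, 60, 80, 95)
        ]
        assert sizes == sorted(sizes)


class TestStage2:
    def _library(self):
        # below the 85% global threshold (distinct tails), but sharing a long
        # exact core: high local identity at ~78% bidirectional coverage
        common = "MKVLAQSTYWDEFGHIKNPRMKVLAQSTYWDEFGHI"
        a = common + "AAAAAAAAAA"
        b = common + "DDDDDDDDDD"
        return [
            EnzymeRecord(accession="a", protein_seq=a),
            EnzymeRecord(accession="b", protein_seq=b),
        ]

    def test_merges_on_local_similarity(self):
        records = self._library()
        m = cluster.build_identity_matrix(records)
        assert m.values[0, 1] < 85.0
        s1 = cluster.cluster_stage1(m)
        assert len(s1) == 2
        s2 = cluster.cluster_stage2(s1, records, matrix=m)
        assert len(s2) == 1

    def test_low_coverage_prevents_merge(self):
        # short shared motif inside otherwise unrelated sequences
        core = "MKVLAQSTYW"
        a = core + "DDDDDDDDDDDDDDDDDDDDDDDDDDDDDD"
        b = core + "HHHHHHHHHHHHHHHHHHHHHHHHHHHHHH"
        records = [
            EnzymeRecord(accession="a", protein_seq=a),
            EnzymeRecord(accession="b", protein_seq=b),
        ]
        m = cluster.build_identity_matrix(records)
        s1 = cluster.cluster_stage1(m)
        s2 = cluster.cluster_stage2(s1, records, matrix=m)
        assert len(s2) == 2

    def test_idempotent_and_coarsening(self):
        records, _ = synthetic.generate_rnap_library(
            3, [3, 2, 2], within_div=0.05, between_div=0.5, rng_seed=5
        )
        m = cluster.build_identity_matrix(records)
        s1 = cluster.cluster_stage1(m)
        s2 = cluster.cluster_stage2(s1, records, matrix=m)
        assert len(s2) <= len(s1)
        s2b = cluster.cluster_stage2(s2, records, matrix=m)
        assert [set(c) for c in s2b.clusters] == [set(c) for c in s2.clusters]
        # coarsening: every stage-1 cluster sits inside one stage-2 family
        for c1 in s1.clusters:
            assert sum(1 for c2 in s2.clusters if c1 <= c2) == 1


class TestRepresentative:
    def test_singleton(self):
        m = hand_matrix(["a"], [[100.0]])
        assert cluster.select_representative({"a"}, m) == "a"

    def test_smallest_row_sum_wins(self):
        vals = [
            [100, 90, 50],
            [90, 100, 40],
            [50, 40, 100],
        ]
        m = hand_matrix(["a", "b", "c"], vals)
        # row sums excl. diagonal: a=140, b=130, c=90
        assert cluster.select_representative({"a", "b", "c"}, m) == "c"
        assert cluster.select_representative({"a", "b"}, m) == "b"

    def test_tie_breaks_lexicographically(self):
        vals = [
            [100, 80, 80],
            [80, 100, 80],
            [80, 80, 100],
        ]
        m = hand_matrix(["b", "a", "c"], vals)
        assert cluster.select_representative({"a", "b", "c"}, m) == "a"

    def test_cluster_scope_option(self):
        vals = [
            [100, 95, 10],
            [95, 100, 90],
            [10, 90, 100],
        ]
        m = hand_matrix(["a", "b", "c"], vals)
        # library-wide: a has the smallest total (105 vs 185 vs 100) -> c
        assert cluster.select_representative({"a", "b"}, m, scope="library") == "a"
        # within-cluster {a,b}: equal sums -> lexicographic
        assert cluster.select_representative({"a", "b"}, m, scope="cluster") == "a"

    def test_missing_member_rejected(self):
        m = hand_matrix(["a"], [[100.0]])
        with pytest.raises(KeyError):
            cluster.select_representative({"zz"}, m)


class TestRecoveryProperty:
    def test_ari_one_on_separated_families(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in range(3):
            records, truth = synthetic.generate_rnap_library(
                4, [5, 4, 3, 1], within_div=0.05, between_div=0.40, rng_seed=seed
            )
            m = cluster.build_identity_matrix(records)
            cs = cluster.cluster_stage1(m)
            labels = cs.labels()
            pred = [labels[r.accession] for r in records]
            true = [truth.family_label[r.accession] for r in records]
            assert adjusted_rand_score(true, pred) == 1.0

    def test_partition_invariant(self):
        records, _ = synthetic.generate_rnap_library(
            3, [4, 2, 1], within_div=0.03, between_div=0.5, rng_seed=2
        )
        m = cluster.build_identity_matrix(records)
        for cs in (cluster.cluster_stage1(m),):
            members = [a for c in cs.clusters for a in c]
            assert sorted(members) == sorted(r.accession for r in records)
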