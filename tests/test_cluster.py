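import pytest
from sklearn.metrics import adjusted_rand_score

from lcsclust.align import align_affine
from lcsclust.cluster import (
    ClusterConfig,
    cluster_greedy,
    order_sequences,
    verify_result,
)
from lcsclust.seqio import SequenceRecord
from lcsclust.synth import SynthConfig, generate_read_set
from oracles import random_dna


@pytest.fixture(scope="module")
def fixture_220():
    """The standard labelled fixture: 20 families of 11 reads, 150 bases."""
    cfg = SynthConfig(n_seeds=20, reads_per_seed=10, read_length=150,
                      sub_rate=0.03, indel_rate=0.005,
                      min_seed_divergence=0.2, seed=7)
    return generate_read_set(cfg)


class TestClusterGreedy:
    def test_empty_input(self):
        res = cluster_greedy([], ClusterConfig())
        assert res.clusters == [] and res.assignments == {}

    def test_exact_duplicates_join(self):
        recs = [SequenceRecord("a", "ACGTACGTACGT"),
                SequenceRecord("b", "ACGTACGTACGT")]
        res = cluster_greedy(recs, ClusterConfig(s=0.9, k=2, t=1))
        assert len(res.clusters) == 1
        assert sorted(i for i, _ in res.clusters[0].members) == [0, 1]

    def test_ground_truth_recovery(self, fixture_220):
        records, labels = fixture_220
        res = cluster_greedy(records, ClusterConfig(s=0.9, k=9, t=1))
        pred = [res.assignments[i] for i in range(len(records))]
        assert adjusted_rand_score(labels, pred) >= 0.98

    def test_partition_and_member_identity(self, fixture_220):
        records, _ = fixture_220
        res = cluster_greedy(records, ClusterConfig(s=0.9, k=9, t=1))
        assert sorted(res.assignments) == list(range(len(records)))
        assert verify_result(res) == []
        # stored identities are >= s and representatives are first members
        for ci, cl in enumerate(res.clusters):
            assert cl.members[0] == (cl.representative, 1.0)
            for idx, ident in cl.members:
                assert ident >= res.config.s
                assert res.assignments[idx] == ci

    def test_representative_is_first_in_processing_order(self, fixture_220):
        records, _ = fixture_220
        res = cluster_greedy(records, ClusterConfig(s=0.9, k=9, t=1))
        rank = {idx: pos for pos, idx in enumerate(res.processing_order)}
        for cl in res.clusters:
            rep_rank = rank[cl.representative]
            assert all(rank[i] >= rep_rank for i, _ in cl.members)

    def test_pathological_reads_found_singletons(self):
        recs = [SequenceRecord("n", "N" * 50),
                SequenceRecord("short", "ACG"),
                SequenceRecord("ok", "ACGTACGTACGTACGT")]
        res = cluster_greedy(recs, ClusterConfig(s=0.9, k=9, t=1))
        assert len(res.clusters) == 3

    def test_best_hit_picks_highest_identity(self):
        # q is acceptable to both representatives but much closer to r1;
        # block sequences keep the pairwise identities controlled
        recs = [SequenceRecord("r0", "A" * 40),
                SequenceRecord("r1", "A" * 30 + "C" * 10),
                SequenceRecord("q", "A" * 32 + "C" * 8)]
        ident0 = align_affine(recs[2], recs[0]).identity  # 32/40
        ident1 = align_affine(recs[2], recs[1]).identity  # 38/40
        assert ident1 > ident0 >= 0.78
        assert align_affine(recs[1], recs[0]).identity < 0.78  # 30/40
        cfg = dict(s=0.78, k=1, t=1, ordering="input")
        first = cluster_greedy(recs, ClusterConfig(assignment="first", **cfg))
        best = cluster_greedy(recs, ClusterConfig(assignment="best", **cfg))
        assert first.assignments[2] == 0
        assert best.assignments[2] == 1

    def test_cluster_count_monotone_in_s_degenerate_filters(self):
        cfg = SynthConfig(n_seeds=5, reads_per_seed=8, read_length=60,
                          sub_rate=0.08, indel_rate=0.01, seed=3)
        records, _ = generate_read_set(cfg)
        prev = None
        for s in (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 1.0):
            res = cluster_greedy(
                records, ClusterConfig(s=s, k=1, t=1, ordering="input")
            )
            if prev is not None:
                assert len(res.clusters) >= prev
            prev = len(res.clusters)

    def test_stage_counts_are_a_cascade(self, fixture_220):
        records, _ = fixture_220
        sc = cluster_greedy(records, ClusterConfig(s=0.9, k=9, t=1)).stage_counts
        assert sc.shortword_pairs >= sc.lcs_pairs >= sc.aligned_pairs >= sc.accepted_pairs
        assert sc.lcs_pairs >= sc.aligned_pairs  # first-hit may stop early


class TestOrderSequences:
    def test_length_desc(self):
        recs = [SequenceRecord("a", "A" * 100), SequenceRecord("b", "A" * 400),
                SequenceRecord("c", "A" * 150)]
        assert order_sequences(recs, "length_desc") == [1, 2, 0]

    def test_input_identity(self):
        recs = [SequenceRecord("a", "AC"), SequenceRecord("b", "GT")]
        assert order_sequences(recs, "input") == [0, 1]

    def test_stable_on_ties(self):
        recs = [SequenceRecord(str(i), "ACGT") for i in range(5)]
        assert order_sequences(recs, "length_desc") == [0, 1, 2, 3, 4]


def test_config_validation():
    with pytest.raises(ValueError):
        ClusterConfig(s=1.5)
    with pytest.raises(ValueError):
        ClusterConfig(t=0)
    with pytest.raises(ValueError):
        ClusterConfig(ordering="random")
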