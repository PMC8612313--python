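import numpy as np
import pytest

from rumorgroups.cluster_engine import (
    ClusterParams,
    Labeling,
    group_table,
    hac_cluster,
    hybrid_cluster,
    knn_predict,
)
from rumorgroups.similarity import DistanceMatrix, distance_matrix
from rumorgroups.synthgen import SynthSpec, generate_corpus
from rumorgroups.corpus_io import messages_from_frame, preprocess

from _oracles import naive_agglomerate, canonical, same_partition, random_distance_matrix
from conftest import make_doc


def matrix_from_values(values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(values=values, doc_index=tuple(f"d{i}" for i in range(len(values))))


def synthetic_docs(seed, n_groups=4, per_group=30, singles=5, mutation=0.05):
    spec = SynthSpec(
        n_groups=n_groups, size_distribution="fixed", fixed_size=per_group,
        n_singletons=singles, combined_pairs=0, mutation_rate=mutation, seed=seed,
    )
    corpus = generate_corpus(spec)
    msgs = messages_from_frame(corpus.messages)
    return preprocess(msgs, tokenizer="whitespace", stopwords=(), char_filter=None)


class TestHacCluster:
    def test_identical_docs_share_a_label(self):
        docs = [make_doc("a", ["x", "y"]), make_doc("b", ["x", "y"])]
        labeling = hac_cluster(distance_matrix(docs), 0.6)
        assert labeling.labels[0] == labeling.labels[1]

    def test_all_far_docs_stay_apart(self):
        m = matrix_from_values([[0, 0.9, 0.8], [0.9, 0, 0.95], [0.8, 0.95, 0]])
        labeling = hac_cluster(m, 0.6)
        assert len(set(labeling.labels.tolist())) == 3

    def test_two_planted_triplets(self):
        # within-group distances < 0.2, between > 0.9
        v = np.full((6, 6), 0.95)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    v[i, j] = 0.0 if i == j else 0.1
        labeling = hac_cluster(matrix_from_values(v), 0.6)
        labs = labeling.labels
        assert labs[0] == labs[1] == labs[2]
        assert labs[3] == labs[4] == labs[5]
        assert labs[0] != labs[3]
        oracle = naive_agglomerate(v, 0.6)
        assert same_partition(labs, oracle)

    def test_empty_corpus(self):
        assert len(hac_cluster(distance_matrix([]), 0.6)) == 0

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_agrees_with_bruteforce_oracle_on_small_corpora(self, linkage):
        # exhaustive seeded sweep over random matrices of up to 8 docs
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 9))
            dist = random_distance_matrix(rng, n)
            lam = float(rng.uniform(0.2, 0.9))
            labeling = hac_cluster(matrix_from_values(dist), lam, linkage)
            oracle = naive_agglomerate(dist, lam, linkage)
            assert same_partition(labeling.labels, oracle), (seed, n, lam)


class TestKnnPredict:
    def test_majority_vote(self):
        dist = np.array([[0.1, 0.2, 0.3]])
        preds = knn_predict(dist, np.array([5, 5, 2]), k=3)
        assert preds[0] == 5

    def test_tie_breaks_toward_smallest_label(self):
        dist = np.array([[0.1, 0.2]])
        preds = knn_predict(dist, np.array([7, 3]), k=2)
        assert preds[0] == 3

    def test_zero_overlap_neighbors_do_not_vote(self):
        dist = np.array([[1.0, 1.0, 1.0]])
        preds = knn_predict(dist, np.array([0, 1, 2]), k=3)
        assert preds[0] == -1

    def test_vote_reach_mutes_neighbors_beyond_threshold(self):
        dist = np.array([[0.5, 0.95, 0.95]])
        preds = knn_predict(dist, np.array([4, 0, 0]), k=3, vote_reach=0.6)
        assert preds[0] == 4  # the two 0-labeled neighbors are out of reach


class TestHybridCluster:
    def test_reduces_to_full_hac_at_u_one(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            docs = synthetic_docs(
                seed,
                n_groups=int(rng.integers(2, 8)),
                per_group=int(rng.integers(2, 12)),
                singles=int(rng.integers(0, 6)),
            )
            assert len(docs) <= 500
            full = hac_cluster(distance_matrix(docs), 0.6)
            hybrid = hybrid_cluster(docs, ClusterParams(train_portion_u=1.0, seed=seed))
            assert same_partition(hybrid.labels, full.labels), seed

    def test_recovers_planted_partition_through_subsampling(self):
        docs = synthetic_docs(3, n_groups=2, per_group=10, singles=0)
        params = ClusterParams(train_portion_u=0.5, seed=11)
        pred = hybrid_cluster(docs, params)
        gold = hac_cluster(distance_matrix(docs), 0.6)
        assert same_partition(pred.labels, gold.labels)
        assert pred.n_groups == 2

    def test_all_far_corpus_every_doc_own_group(self):
        docs = [make_doc(f"d{i}", [f"u{i}a", f"u{i}b", f"u{i}c"]) for i in range(10)]
        pred = hybrid_cluster(docs, ClusterParams(train_portion_u=0.5, seed=0))
        assert len(set(pred.labels.tolist())) == 10
        assert (pred.labels >= 0).all()

    def test_conservation_and_no_sentinel_left(self):
        docs = synthetic_docs(9, n_groups=5, per_group=8, singles=7)
        pred = hybrid_cluster(docs, ClusterParams(train_portion_u=0.4, seed=2))
        assert len(pred) == len(docs)
        assert (pred.labels >= 0).all()
        assert sum(pred.group_sizes().values()) == len(docs)

    def test_determinism(self):
        docs = synthetic_docs(5, n_groups=4, per_group=10, singles=5)
        params = ClusterParams(train_portion_u=0.5, seed=21)
        a = hybrid_cluster(docs, params)
        b = hybrid_cluster(docs, params)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.pass_, b.pass_)

    def test_pass2_labels_do_not_collide_with_pass1(self):
        docs = synthetic_docs(13, n_groups=4, per_group=10, singles=10)
        pred = hybrid_cluster(docs, ClusterParams(train_portion_u=0.5, seed=4))
        pass1 = set(pred.labels[pred.pass_ == 1].tolist())
        pass2 = set(pred.labels[pred.pass_ == 2].tolist())
        assert not pass1 & pass2

    def test_tiny_train_portion_is_parameter_error(self):
        docs = synthetic_docs(1, n_groups=2, per_group=3, singles=0)
        with pytest.raises(ValueError, match="at least 2"):
            hybrid_cluster(docs, ClusterParams(train_portion_u=0.1, seed=0))

    def test_degenerate_sample_without_clusters_falls_back_to_second_pass(self):
        # every pairwise distance is 1: the sampled half is all singletons,
        # KNN is skipped and the second pass labels everything
        docs = [make_doc(f"d{i}", [f"v{i}x", f"v{i}y"]) for i in range(8)]
        pred = hybrid_cluster(docs, ClusterParams(train_portion_u=0.5, seed=1))
        assert (pred.labels >= 0).all()
        assert len(set(pred.labels.tolist())) == 8
        assert (pred.pass_ == 2).all()


class TestGroupTable:
    def test_sizes_and_order(self):
        labeling = Labeling(labels=np.array([0, 0, 1]), doc_index=("a", "b", "c"))
        table = group_table(labeling)
        assert table["size"].tolist() == [2, 1]
        assert table["size"].sum() == 3

    def test_empty(self):
        table = group_table(Labeling(labels=np.empty(0, dtype=int), doc_index=()))
        assert table.empty

    def test_size_ties_ordered_by_smallest_member_id(self):
        labels = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 2, 2])
        ids = tuple(f"m{i:02d}" for i in [5, 6, 7, 8, 9, 0, 1, 2, 3, 4, 10, 11])
        table = group_table(Labeling(labels=labels, doc_index=ids))
        assert table["group_id"].tolist() == [1, 0, 2]

    def test_exemplar_is_longest_member(self):
        docs = [make_doc("a", ["x", "y"]), make_doc("b", ["x", "y", "z"])]
        labeling = Labeling(labels=np.array([0, 0]), doc_index=("a", "b"))
        table = group_table(labeling, docs)
        assert table.loc[0, "exemplar"] == "b"

    def test_incomplete_labeling_rejected(self):
        labeling = Labeling(labels=np.array([0, -1]), doc_index=("a", "b"))
        with pytest.raises(ValueError, match="sentinel"):
            group_table(labeling)
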