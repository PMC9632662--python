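import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdrlink.netdata import DataError, ROLE_DRUG, ROLE_MIRNA
from mdrlink.classifier import (
    ModelConfig,
    PairDataset,
    PipelineConfig,
    assemble_features,
    compute_metrics,
    cross_validate,
    network_features,
    predict_scores,
    rank_drug_leave_out,
    sample_pairs,
    train_svm,
)
from mdrlink.hetesim import hetesim_features
from mdrlink.similarity import sequence_similarity
from mdrlink.synthetic import SimConfig, simulate_all

from conftest import make_assoc, make_sim, random_network, random_similarity


def pairwise_auc_oracle(labels, scores):
    """Naive O(n^2) probability that a positive outranks a negative."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def separable_dataset(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(-3, 0.3, size=(n // 2, 2)),
        rng.normal(3, 0.3, size=(n // 2, 2)),
    ])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    pairs = np.column_stack([np.arange(n), np.zeros(n, dtype=int)])
    return PairDataset(pairs, y, X)


class TestSamplePairs:
    def test_negative_count_is_three_times_positives(self):
        rng = np.random.default_rng(0)
        assoc = make_assoc(random_network(rng, 10, 10, density=0.1))
        ds = sample_pairs(assoc, ratio=3.0, seed=1)
        n_pos = assoc.n_associations
        assert int(ds.labels.sum()) == n_pos
        assert len(ds) == n_pos + 3 * n_pos

    def test_exhausted_negatives_take_all(self, caplog):
        A = np.ones((3, 3), dtype=int)
        A[0, 0] = 0
        with caplog.at_level("WARNING", logger="mdrlink.classifier"):
            ds = sample_pairs(make_assoc(A), ratio=3.0, seed=0)
        assert (ds.labels == 0).sum() == 1
        assert "taking all" in caplog.text

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(4)
        assoc = make_assoc(random_network(rng, 8, 6))
        a = sample_pairs(assoc, seed=7)
        b = sample_pairs(assoc, seed=7)
        assert np.array_equal(a.pairs, b.pairs)
        assert np.array_equal(a.labels, b.labels)

    def test_positives_all_included(self):
        assoc = make_assoc([[1, 0], [0, 1]])
        ds = sample_pairs(assoc, ratio=1.0, seed=0)
        pos = {tuple(p) for p, l in zip(ds.pairs, ds.labels) if l == 1}
        assert pos == {(0, 0), (1, 1)}


class TestAssembleFeatures:
    def _inputs(self, d):
        rng = np.random.default_rng(1)
        assoc = make_assoc(random_network(rng, 5, 4))
        SM = make_sim(random_similarity(rng, 5), ROLE_MIRNA)
        SD = make_sim(random_similarity(rng, 4), ROLE_DRUG)
        H = hetesim_features(assoc, SM, SD)
        X_M = rng.random((5, d))
        X_D = rng.random((4, d))
        return assoc, H, X_M, X_D

    @pytest.mark.parametrize("d,width", [(50, 114), (1, 16), (5, 24)])
    def test_feature_width_is_14_plus_2d(self, d, width):
        assoc, H, X_M, X_D = self._inputs(d)
        ds = sample_pairs(assoc, ratio=1.0, seed=0)
        out = assemble_features(ds, H, X_M, X_D)
        assert out.features.shape == (len(ds), width)

    def test_block_order_hetesim_drug_mirna(self):
        assoc, H, X_M, X_D = self._inputs(3)
        pairs = np.array([[2, 1]])
        out = assemble_features(pairs, H, X_M, X_D)
        expected = np.concatenate([H.scores[2, 1, :], X_D[1], X_M[2]])
        assert np.allclose(out.features[0], expected)

    def test_out_of_range_pair_errors(self):
        _, H, X_M, X_D = self._inputs(3)
        with pytest.raises(DataError, match="range"):
            assemble_features(np.array([[9, 0]]), H, X_M, X_D)

    def test_single_family_allowed(self):
        assoc, H, X_M, X_D = self._inputs(3)
        ds = sample_pairs(assoc, ratio=1.0, seed=0)
        assert assemble_features(ds, H=H).features.shape[1] == 14
        assert assemble_features(ds, X_M=X_M, X_D=X_D).features.shape[1] == 6


class TestTrainSvm:
    def test_separable_toy_perfect_training_accuracy(self):
        ds = separable_dataset()
        model = train_svm(ds, ModelConfig())
        scores = predict_scores(model, ds.features)
        assert np.array_equal((scores >= 0.5).astype(int), ds.labels)

    def test_dual_feasibility(self):
        ds = separable_dataset(seed=3)
        model = train_svm(ds, ModelConfig(C=64.0))
        alpha = model.alpha
        assert np.all(alpha >= -1e-6) and np.all(alpha <= 64.0 + 1e-6)
        assert abs(model.dual_coef.sum()) < 1e-6  # sum alpha_i y_i = 0

    def test_explicit_kernel_decision_matches_solver(self):
        ds = separable_dataset(seed=5)
        model = train_svm(ds, ModelConfig())
        assert np.allclose(
            model.kernel_decision_function(ds.features),
            model.decision_function(ds.features),
            atol=1e-8,
        )

    def test_single_class_errors(self):
        ds = separable_dataset()
        ds.labels[:] = 1
        with pytest.raises(DataError, match="both classes"):
            train_svm(ds, ModelConfig())


class TestPredictScores:
    def test_probability_scores_in_unit_interval(self):
        ds = separable_dataset(seed=9)
        model = train_svm(ds, ModelConfig())
        s = predict_scores(model, ds.features, score_mode="probability")
        assert s.min() >= 0 and s.max() <= 1

    def test_rank_order_identical_across_modes(self):
        ds = separable_dataset(seed=11)
        model = train_svm(ds, ModelConfig())
        rng = np.random.default_rng(1)
        X_test = rng.normal(0, 3, size=(30, 2))
        prob = predict_scores(model, X_test, score_mode="probability")
        dec = predict_scores(model, X_test, score_mode="decision")
        assert np.array_equal(np.argsort(prob), np.argsort(dec))

    def test_width_mismatch_errors(self):
        ds = separable_dataset()
        model = train_svm(ds, ModelConfig())
        with pytest.raises(DataError, match="width"):
            predict_scores(model, np.zeros((3, 5)))


class TestComputeMetrics:
    def test_hand_computed_confusion_table(self):
        # TP=50, FP=10, TN=30, FN=10
        labels = np.array([1] * 50 + [0] * 10 + [0] * 30 + [1] * 10)
        scores = np.array([0.9] * 50 + [0.9] * 10 + [0.1] * 30 + [0.1] * 10)
        m = compute_metrics(labels, scores, threshold=0.5)
        assert m["recall"] == pytest.approx(0.8333, abs=1e-4)
        assert m["acc"] == pytest.approx(0.8, abs=1e-4)
        assert m["f1"] == pytest.approx(0.8333, abs=1e-4)
        assert m["mcc"] == pytest.approx(0.5833, abs=1e-4)

    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(labels, scores, threshold=0.5)
        assert all(m[k] == 1.0 for k in ("auc", "acc", "pre", "recall", "f1", "mcc"))

    def test_constant_scores_auc_half(self):
        m = compute_metrics(np.array([0, 1, 0, 1]), np.full(4, 0.5))
        assert m["auc"] == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(DataError, match="both classes"):
            compute_metrics(np.ones(4), np.random.default_rng(0).random(4))

    def test_matches_naive_pairwise_auc_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = rng.integers(6, 30)
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                labels[0], labels[1] = 0, 1
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            m = compute_metrics(labels, scores)
            assert m["auc"] == pytest.approx(pairwise_auc_oracle(labels, scores))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_metric_ranges(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 40)
        labels = rng.integers(0, 2, size=n)
        labels[0], labels[1] = 0, 1
        scores = rng.random(n)
        m = compute_metrics(labels, scores)
        for k in ("auc", "acc", "pre", "recall", "f1"):
            assert 0 <= m[k] <= 1
        assert -1 <= m["mcc"] <= 1


@pytest.fixture(scope="module")
def small_synthetic():
    cfg = SimConfig(n_mirna=40, n_drug=24, k_clusters=2, seed=5)
    assoc, seqs, dsim, labels = simulate_all(cfg)
    seq_sim = sequence_similarity(seqs, assoc.row_index)
    return assoc, seq_sim, dsim, labels


class TestCrossValidate:
    def test_fold_partition_and_determinism(self, small_synthetic):
        assoc, seq_sim, dsim, _ = small_synthetic
        pipe = PipelineConfig(d=5)
        a = cross_validate(assoc, seq_sim, dsim, pipeline=pipe, k=3, seed=2,
                           leakage_mode="paper")
        b = cross_validate(assoc, seq_sim, dsim, pipeline=pipe, k=3, seed=2,
                           leakage_mode="paper")
        assert a.folds == b.folds
        assert len(a.folds) == 3
        for key, val in a.mean.items():
            assert val == pytest.approx(np.mean([f[key] for f in a.folds]), abs=1e-12)

    def test_k_too_small_errors(self, small_synthetic):
        assoc, seq_sim, dsim, _ = small_synthetic
        with pytest.raises(DataError, match="k >= 2"):
            cross_validate(assoc, seq_sim, dsim, k=1)

    def test_strict_mode_not_above_paper_mode(self):
        # leakage inflates performance; compare medians over 5 seeds
        pipe = PipelineConfig(d=5)
        strict, paper = [], []
        for seed in range(5):
            cfg = SimConfig(n_mirna=30, n_drug=20, k_clusters=2, seed=seed)
            assoc, seqs, dsim, _ = simulate_all(cfg)
            seq_sim = sequence_similarity(seqs, assoc.row_index)
            strict.append(cross_validate(assoc, seq_sim, dsim, pipeline=pipe,
                                         k=3, seed=seed, leakage_mode="strict").mean["auc"])
            paper.append(cross_validate(assoc, seq_sim, dsim, pipeline=pipe,
                                        k=3, seed=seed, leakage_mode="paper").mean["auc"])
        assert np.median(strict) <= np.median(paper)


class TestRankDrugLeaveOut:
    def test_ranking_properties(self, small_synthetic):
        assoc, seq_sim, dsim, labels = small_synthetic
        drug_id = assoc.col_index.ids[0]
        pipe = PipelineConfig(d=5)
        rank = rank_drug_leave_out(assoc, drug_id, seq_sim, dsim, pipeline=pipe, seed=3)
        assert len(rank.mirna_ids) == assoc.nm
        assert np.all(np.diff(rank.scores) <= 1e-12)  # descending
        again = rank_drug_leave_out(assoc, drug_id, seq_sim, dsim, pipeline=pipe, seed=3)
        assert rank.mirna_ids == again.mirna_ids

    def test_unknown_drug_errors(self, small_synthetic):
        assoc, seq_sim, dsim, _ = small_synthetic
        with pytest.raises(KeyError):
            rank_drug_leave_out(assoc, "no-such-drug", seq_sim, dsim)

    def test_true_partners_rank_above_permutation_baseline(self, small_synthetic):
        assoc, seq_sim, dsim, labels = small_synthetic
        x = 0
        drug_id = assoc.col_index.ids[x]
        pipe = PipelineConfig(d=5)
        rank = rank_drug_leave_out(assoc, drug_id, seq_sim, dsim, pipeline=pipe, seed=3)
        positions = {m: i for i, m in enumerate(rank.mirna_ids)}
        partners = [assoc.row_index.ids[i] for i in np.flatnonzero(assoc.A[:, x])]
        median_rank = np.median([positions[m] for m in partners])
        # permutation baseline: median rank of a uniformly placed subset
        rng = np.random.default_rng(0)
        baseline = np.median([
            np.median(rng.choice(assoc.nm, size=len(partners), replace=False))
            for _ in range(500)
        ])
        assert median_rank < baseline
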