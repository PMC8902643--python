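import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circlink.data import EntityVocabulary
from circlink.evaluation import (
    CapacityError,
    ConfusionCounts,
    LabeledPairSet,
    compute_auc,
    compute_auc_trapezoid,
    compute_metrics,
    confusion_at_threshold,
    cross_validate,
    fit_pipeline,
    make_folds,
    rank_candidates,
    sample_negatives,
    summarize_table,
    build_fused_adjacencies,
    build_entity_vocabularies,
)


def pair_counting_auc(probs, labels):
    """O(n^2) oracle: fraction of (positive, negative) pairs won, ties count half."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestSampleNegatives:
    @pytest.fixture
    def grid(self):
        return (
            EntityVocabulary("circRNA", ("c1", "c2")),
            EntityVocabulary("disease", ("d1", "d2")),
        )

    def test_forced_single_remaining_pair(self, grid):
        circ, dis = grid
        positives = [("c1", "d1"), ("c1", "d2"), ("c2", "d1")]
        assert sample_negatives(positives, circ, dis, 1, seed=0) == [("c2", "d2")]

    def test_capacity_error_on_full_grid(self, grid):
        circ, dis = grid
        positives = [("c1", "d1"), ("c1", "d2"), ("c2", "d1"), ("c2", "d2")]
        with pytest.raises(CapacityError):
            sample_negatives(positives, circ, dis, 1, seed=0)

    def test_negatives_disjoint_and_distinct(self):
        circ = EntityVocabulary("circRNA", tuple(f"c{i}" for i in range(30)))
        dis = EntityVocabulary("disease", tuple(f"d{i}" for i in range(10)))
        rng = np.random.default_rng(3)
        positives = list(
            {(f"c{rng.integers(30)}", f"d{rng.integers(10)}") for _ in range(60)}
        )
        negs = sample_negatives(positives, circ, dis, len(positives), seed=5)
        assert len(negs) == len(positives)
        assert len(set(negs)) == len(negs)
        assert not set(negs) & set(positives)

    def test_seed_controls_reproducibility(self, grid):
        circ = EntityVocabulary("circRNA", tuple(f"c{i}" for i in range(10)))
        dis = EntityVocabulary("disease", tuple(f"d{i}" for i in range(10)))
        positives = [("c0", "d0")]
        a = sample_negatives(positives, circ, dis, 20, seed=1)
        b = sample_negatives(positives, circ, dis, 20, seed=1)
        c = sample_negatives(positives, circ, dis, 20, seed=2)
        assert a == b
        assert a != c


class TestFolds:
    def _balanced_set(self, n_pos, n_neg):
        pairs = tuple((f"c{i}", "d0") for i in range(n_pos + n_neg))
        labels = (1,) * n_pos + (0,) * n_neg
        return LabeledPairSet(pairs=pairs, labels=labels)

    def test_small_balanced_stratification(self):
        ps = self._balanced_set(5, 5)
        folds = make_folds(ps, 5, seed=0)
        y = ps.labels_array
        for f in range(5):
            idx = folds.test_indices(f)
            assert len(idx) == 2
            assert y[idx].sum() == 1

    def test_partition_disjoint_exhaustive(self):
        ps = self._balanced_set(17, 13)
        folds = make_folds(ps, 4, seed=1)
        all_idx = np.concatenate([folds.test_indices(f) for f in range(4)])
        assert sorted(all_idx) == list(range(30))

    def test_stratification_within_one(self):
        ps = self._balanced_set(11, 19)
        folds = make_folds(ps, 5, seed=2)
        y = ps.labels_array
        pos_counts = [y[folds.test_indices(f)].sum() for f in range(5)]
        assert max(pos_counts) - min(pos_counts) <= 1

    def test_fivefold_split_of_balanced_benchmark_size(self):
        # 725 positives + 725 sampled negatives split 5 ways -> 290 per test fold
        ps = self._balanced_set(725, 725)
        folds = make_folds(ps, 5, seed=3)
        assert [len(folds.test_indices(f)) for f in range(5)] == [290] * 5

    def test_too_many_folds(self):
        ps = self._balanced_set(2, 1)
        with pytest.raises(ValueError):
            make_folds(ps, 4, seed=0)


class TestLabeledPairSet:
    def test_conflicting_labels_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            LabeledPairSet(pairs=(("c", "d"), ("c", "d")), labels=(1, 0))

    def test_duplicate_entry_rejected(self):
        with pytest.raises(ValueError):
            LabeledPairSet(pairs=(("c", "d"), ("c", "d")), labels=(1, 1))


class TestConfusion:
    def test_clean_split(self):
        c = confusion_at_threshold([0.9, 0.1], [1, 0], 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_both_called_positive(self):
        c = confusion_at_threshold([0.6, 0.6], [0, 1], 0.5)
        assert (c.fp, c.tp) == (1, 1)

    def test_tie_at_threshold_calls_positive(self):
        c = confusion_at_threshold([0.5], [1], 0.5)
        assert c.tp == 1 and c.fn == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_at_threshold([], [], 0.5)


class TestMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert (r.accuracy, r.sensitivity, r.precision, r.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_counts(self):
        r = compute_metrics(ConfusionCounts(tp=40, fn=10, fp=5, tn=45))
        assert r.accuracy == pytest.approx(0.85)
        assert r.sensitivity == pytest.approx(0.80)
        assert r.precision == pytest.approx(0.888889, abs=1e-6)
        assert r.f1 == pytest.approx(0.842105, abs=1e-6)

    def test_degenerate_precision_flagged_not_zeroed(self):
        r = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
        assert np.isnan(r.precision)
        assert "precision" in r.degenerate

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_accuracy_between_class_rates_and_f1_harmonic(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if tp + fn == 0 or tn + fp == 0 or tp + fp == 0 or tp == 0:
                continue
            r = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            spec = tn / (tn + fp)
            assert min(r.sensitivity, spec) - 1e-12 <= r.accuracy <= max(r.sensitivity, spec) + 1e-12
            harmonic = 2 * r.precision * r.sensitivity / (r.precision + r.sensitivity)
            assert r.f1 == pytest.approx(harmonic)


class TestAUC:
    def test_hand_counted_example(self):
        assert compute_auc([0.9, 0.3, 0.6, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert compute_auc([0.8, 0.9, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_is_half(self):
        assert compute_auc([0.5, 0.5], [1, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.5, 0.6], [1, 1])

    def test_matches_pair_counting_and_trapezoid(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            probs = rng.choice([0.1, 0.25, 0.5, 0.5, 0.75, 0.9], size=n)  # force ties
            expected = pair_counting_auc(probs, labels)
            assert compute_auc(probs, labels) == pytest.approx(expected)
            assert compute_auc_trapezoid(probs, labels) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from([0.0, 0.2, 0.4, 0.5, 0.6, 0.8, 1.0]),
                      st.integers(0, 1)),
            min_size=2, max_size=60,
        ).filter(lambda rows: 0 < sum(y for _, y in rows) < len(rows))
    )
    def test_midrank_statistic_equals_pair_counting_oracle(self, rows):
        probs = [p for p, _ in rows]
        labels = [y for _, y in rows]
        assert compute_auc(probs, labels) == pytest.approx(pair_counting_auc(probs, labels))


class TestSummarize:
    def test_constant_values_have_zero_sd(self):
        row = summarize_table({"auc": [0.9, 0.9, 0.9]})
        assert row.mean["auc"] == pytest.approx(0.9)
        assert row.sd["auc"] == 0.0

    def test_nan_sentinels_excluded(self):
        row = summarize_table({"precision": [0.8, float("nan"), 0.9]})
        assert row.mean["precision"] == pytest.approx(0.85)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            summarize_table({"auc": [0.9]})


@pytest.fixture(scope="module")
def result(small_planted, fast_ern_config, fast_psn_config):
    return cross_validate(
        small_planted.tables, fast_ern_config, fast_psn_config,
        k=3, seed=11, n_classifiers=1,
    )


class TestCrossValidate:
    def test_reports_one_row_per_fold(self, result):
        assert len(result.per_fold) == 3
        assert len(result.roc) == 3
        for r in result.per_fold:
            assert 0.0 <= r.auc <= 1.0

    def test_every_pair_scored_exactly_once(self, result):
        assert np.all(np.isfinite(result.probabilities))

    def test_summary_recomputable_from_fold_values(self, result):
        vals = result.summary.per_fold["accuracy"]
        finite = [v for v in vals if np.isfinite(v)]
        assert result.summary.mean["accuracy"] == pytest.approx(np.mean(finite))

    def test_rerun_identical(self, small_planted, fast_ern_config, fast_psn_config, result):
        again = cross_validate(
            small_planted.tables, fast_ern_config, fast_psn_config,
            k=3, seed=11, n_classifiers=1,
        )
        assert np.array_equal(again.probabilities, result.probabilities)
        assert again.summary.mean == result.summary.mean

    def test_leakage_guard_masks_test_positives(self, small_planted):
        tables = small_planted.tables
        circ_vocab, disease_vocab = build_entity_vocabularies(tables)
        cd = tables["circRNA-disease"]
        masked = set(list(cd.pairs)[:3])
        circ_adj, _ = build_fused_adjacencies(tables, circ_vocab, disease_vocab, masked)
        # the disease block is the first column block of the circ adjacency
        relation, block_vocab = circ_adj.column_blocks[0]
        assert relation == "circRNA-disease"
        for c, d in masked:
            if d in block_vocab:
                i = circ_adj.row_vocab.index_of(c)
                j = block_vocab.index_of(d)
                assert circ_adj.values[i, j] == 0
        # unmasked positives are present
        kept = [p for p in cd.pairs if p not in masked][:3]
        for c, d in kept:
            assert circ_adj.values[
                circ_adj.row_vocab.index_of(c), block_vocab.index_of(d)
            ] == 1


@pytest.fixture(scope="module")
def pipeline(small_planted, fast_ern_config, fast_psn_config):
    return fit_pipeline(
        small_planted.tables, fast_ern_config, fast_psn_config, seed=5
    )


class TestRankCandidates:
    def test_all_candidates_scored_and_sorted(self, pipeline):
        table, _ = rank_candidates(pipeline, "dis_0001")
        assert len(table) == len(pipeline.circ_embeddings.row_vocab)
        assert list(table["rank"]) == list(range(1, len(table) + 1))
        assert (np.diff(table["probability"].to_numpy()) <= 1e-12).all()

    def test_tie_break_is_lexicographic(self, pipeline):
        table, _ = rank_candidates(pipeline, "dis_0001")
        probs = table["probability"].to_numpy()
        names = table["circRNA"].to_list()
        for i in range(len(table) - 1):
            if probs[i] == probs[i + 1]:
                assert names[i] < names[i + 1]

    def test_recall_without_positives_is_nan(self, pipeline):
        _, recall = rank_candidates(pipeline, "dis_0001", known_positives=None)
        assert np.isnan(recall)

    def test_recall_counts_strictly_above_threshold(self, pipeline):
        table, recall = rank_candidates(
            pipeline, "dis_0001",
            known_positives=list(table_names := table_top(pipeline)),
            recall_threshold=0.0,
        )
        # every known positive has probability > 0, so recall is 1
        assert recall == 1.0

    def test_unknown_disease_without_profile_rejected(self, pipeline):
        with pytest.raises(ValueError, match="outside the vocabulary"):
            rank_candidates(pipeline, "no_such_disease")

    def test_unknown_disease_with_profile_embedded(self, pipeline):
        profile = np.zeros(pipeline.disease_embedder.input_dim)
        profile[:3] = 1
        table, _ = rank_candidates(
            pipeline, "novel disease", disease_profile=profile
        )
        assert np.all((table["probability"] > 0) & (table["probability"] < 1))


def table_top(pipeline, n=3):
    """Names of a few circRNAs from the vocabulary (helper for recall checks)."""
    return pipeline.circ_embeddings.row_vocab.names[:n]
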