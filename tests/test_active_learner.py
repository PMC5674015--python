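import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histolearn import (
    DataValidationError,
    FeatureStore,
    ForestParams,
    LabelSet,
    PredictionResult,
    SlideMeta,
    apply_label_edits,
    build_heatmap,
    evaluate_auc,
    predict_confidence,
    rank_slides,
    run_learning_loop,
    select_instances,
    train_forest,
    trapezoidal_auc,
)
from histolearn.active_learner import load_model, save_model
from histolearn.synthetic_data import make_seed_labels, truth_oracle


def _separable_store(rng, k=60, f=5):
    """Store where feature 0 alone separates the classes."""
    feats = rng.normal(size=(k, f))
    y = np.where(np.arange(k) % 2 == 0, 1, -1)
    feats[:, 0] = np.where(y == 1, 5.0, -5.0) + rng.normal(0, 0.1, size=k)
    store = FeatureStore(
        feats, np.arange(k), np.full(k, "s1"), rng.uniform(0, 100, (k, 2)),
        [f"f{i}" for i in range(f)],
    )
    labels = LabelSet()
    for oid, lab in zip(store.object_ids, y):
        labels.add(int(oid), int(lab), "truth")
    return store, labels


class TestTrainForest:
    def test_default_mtry_is_root_of_feature_count(self):
        assert ForestParams().resolve_mtry(48) == 7
        assert ForestParams().n_trees == 100
        assert ForestParams().max_depth == 10

    def test_single_class_training_rejected(self, rng):
        store, _ = _separable_store(rng)
        labels = LabelSet()
        labels.add(0, 1, "seed")
        labels.add(2, 1, "seed")
        with pytest.raises(DataValidationError, match="both classes"):
            train_forest(store, labels)

    def test_two_separable_objects_classified_perfectly(self, rng):
        store, truth = _separable_store(rng)
        labels = LabelSet()
        labels.add(0, truth.entries[0], "seed")
        labels.add(1, truth.entries[1], "seed")
        model = train_forest(store, labels)
        pred = predict_confidence(model, store)
        got = {int(o): int(p) for o, p in zip(pred.object_ids, pred.predicted)}
        # the training set itself is reproduced perfectly
        assert got[0] == truth.entries[0] and got[1] == truth.entries[1]

    def test_ignore_entries_excluded_from_snapshot(self, rng):
        store, truth = _separable_store(rng)
        labels = LabelSet()
        for oid in range(6):
            labels.add(oid, truth.entries[oid], "seed")
        labels.add(7, 0, "review")  # IGNORE
        model = train_forest(store, labels)
        assert 7 not in [o for o, _ in model.training_snapshot]

    def test_same_seed_reproduces_predictions(self, rng):
        store, truth = _separable_store(rng)
        labels = LabelSet()
        for oid in range(10):
            labels.add(oid, truth.entries[oid], "seed")
        p1 = predict_confidence(train_forest(store, labels, ForestParams(seed=5)), store)
        p2 = predict_confidence(train_forest(store, labels, ForestParams(seed=5)), store)
        np.testing.assert_array_equal(p1.votes_pos, p2.votes_pos)

    def test_model_archive_round_trip(self, rng, tmp_path):
        store, truth = _separable_store(rng)
        labels = LabelSet()
        for oid in range(10):
            labels.add(oid, truth.entries[oid], "seed")
        model = train_forest(store, labels)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert back.training_snapshot == model.training_snapshot
        np.testing.assert_array_equal(
            predict_confidence(back, store).votes_pos,
            predict_confidence(model, store).votes_pos,
        )


class TestVoteMarginConfidence:
    def test_contract_against_per_tree_vote_oracle(self, small_benchmark, rng):
        """Confidence must equal |sum of per-tree ±1 votes| extracted tree by tree."""
        _slides, store, truth, _val = small_benchmark
        labels = make_seed_labels(truth, per_class=10, seed=0)
        model = train_forest(store, labels)
        pred = predict_confidence(model, store)
        n = model.n_trees
        # brute-force per-tree extraction
        votes = np.zeros(store.n_objects, dtype=int)
        for est in model.forest.estimators_:
            votes += (est.predict(store.features) == 1).astype(int)
        np.testing.assert_array_equal(pred.votes_pos, votes)
        np.testing.assert_array_equal(pred.confidence, np.abs(2 * votes - n))
        assert np.all(pred.confidence % 2 == n % 2)
        np.testing.assert_array_equal(
            pred.predicted, np.where(votes * 2 > n, 1, -1)
        )

    def test_feature_dimension_mismatch_rejected(self, rng):
        store, truth = _separable_store(rng)
        labels = LabelSet()
        for oid in range(10):
            labels.add(oid, truth.entries[oid], "seed")
        model = train_forest(store, labels)
        other = FeatureStore(
            rng.normal(size=(4, 3)), np.arange(4), np.full(4, "s"),
            np.zeros((4, 2)), ["a", "b", "c"],
        )
        with pytest.raises(DataValidationError, match="features"):
            predict_confidence(model, other)


def _fake_pred(object_ids, confidence, n_trees=100):
    object_ids = np.asarray(object_ids)
    confidence = np.asarray(confidence)
    votes = (n_trees - confidence) // 2
    return PredictionResult(
        object_ids=object_ids,
        votes_pos=votes,
        predicted=np.where(votes * 2 > n_trees, 1, -1),
        confidence=confidence,
        n_trees=n_trees,
    )


class TestSelectInstances:
    def test_planted_minimum_confidence_objects_selected(self):
        conf = np.full(100, 100)
        conf[[3, 11, 19, 27, 35, 43, 51, 59]] = 0
        pred = _fake_pred(np.arange(100), conf)
        assert select_instances(pred, LabelSet(), k=8) == [3, 11, 19, 27, 35, 43, 51, 59]

    def test_labeled_and_ignored_objects_excluded(self):
        pred = _fake_pred(np.arange(10), np.zeros(10, dtype=int))
        labels = LabelSet()
        labels.add(0, 1, "seed")
        labels.add(1, 0, "review")  # IGNORE still excluded
        chosen = select_instances(pred, labels, k=8)
        assert 0 not in chosen and 1 not in chosen

    def test_fewer_than_k_warns_and_returns_all(self):
        pred = _fake_pred(np.arange(5), np.arange(5) * 2)
        with pytest.warns(UserWarning, match="unlabeled"):
            chosen = select_instances(pred, LabelSet(), k=8)
        assert chosen == [0, 1, 2, 3, 4]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 100), min_size=9, max_size=60), st.data())
    def test_matches_sort_oracle(self, conf, data):
        conf = np.array(conf) * 2  # even parity with N=100
        ids = np.arange(len(conf)) * 3  # non-contiguous ids
        labeled = data.draw(st.sets(st.sampled_from(list(ids)), max_size=len(ids) - 8))
        labels = LabelSet()
        for oid in labeled:
            labels.add(int(oid), 1, "seed")
        pred = _fake_pred(ids, conf, n_trees=200)
        got = select_instances(pred, labels, k=8)
        # brute-force oracle: sort unlabeled by (confidence, object_id)
        pool = [(c, i) for c, i in zip(conf, ids) if int(i) not in labeled]
        expected = [i for _, i in sorted(pool)[:8]]
        assert got == expected


class TestHeatmap:
    def _slide_pred(self, rng, k=200, w=2048, h=1024):
        feats = rng.normal(size=(k, 4))
        xy = rng.uniform([0, 0], [w, h], size=(k, 2))
        store = FeatureStore(feats, np.arange(k), np.full(k, "s1"), xy,
                             [f"f{i}" for i in range(4)])
        conf = rng.integers(0, 51, size=k) * 2
        return store, SlideMeta("s1", w, h, 0.5), _fake_pred(np.arange(k), conf)

    def test_single_object_at_origin(self, rng):
        store = FeatureStore(rng.normal(size=(1, 2)), [0], ["s1"], [[0.0, 0.0]], ["a", "b"])
        slide = SlideMeta("s1", 1000, 1000, 0.5)
        hm = build_heatmap(_fake_pred([0], [0]), store, slide, cell_size_px=256)
        assert hm.object_count[0, 0] == 1
        assert hm.object_count.sum() == 1

    def test_counts_conserved_and_partitioned(self, rng):
        store, slide, pred = self._slide_pred(rng)
        hm = build_heatmap(pred, store, slide, cell_size_px=300, threshold_norm=0.25)
        assert hm.object_count.sum() == store.n_objects
        assert np.all(hm.low_confidence_count <= hm.object_count)
        assert np.all(hm.positive_count <= hm.object_count)
        # low + high partition all objects at the threshold
        n_low = int(np.sum(pred.confidence_norm <= 0.25))
        assert hm.low_confidence_count.sum() == n_low

    def test_grid_dimensions(self, rng):
        store, slide, pred = self._slide_pred(rng, w=2048, h=1000)
        hm = build_heatmap(pred, store, slide, cell_size_px=512)
        assert hm.object_count.shape == (2, 4)  # ceil(1000/512), ceil(2048/512)

    def test_planted_cluster_is_hotspot(self, rng):
        k = 500
        feats = rng.normal(size=(k, 3))
        xy = rng.uniform([0, 0], [4096, 4096], size=(k, 2))
        xy[:60] = rng.normal([3800, 300], 40, size=(60, 2)).clip(0, 4095)
        conf = np.full(k, 100)
        conf[:60] = 0  # the planted cluster is low-confidence
        store = FeatureStore(feats, np.arange(k), np.full(k, "s1"), xy, ["a", "b", "c"])
        slide = SlideMeta("s1", 4096, 4096, 0.5)
        hm = build_heatmap(_fake_pred(np.arange(k), conf), store, slide, cell_size_px=512)
        r, c = np.unravel_index(np.argmax(hm.low_confidence_count), hm.object_count.shape)
        assert (r, c) == (0, 7)  # cell containing (3800, 300)

    def test_out_of_bounds_object_named(self, rng):
        store = FeatureStore(rng.normal(size=(1, 2)), [77], ["s1"], [[5000.0, 10.0]],
                             ["a", "b"])
        slide = SlideMeta("s1", 1000, 1000, 0.5)
        with pytest.raises(DataValidationError, match="77"):
            build_heatmap(_fake_pred([77], [0]), store, slide)


class TestRankSlides:
    def _heatmap(self, slide_id, conf, rng, w=1000):
        k = len(conf)
        store = FeatureStore(rng.normal(size=(k, 2)), np.arange(k),
                             np.full(k, slide_id), rng.uniform(0, w, (k, 2)),
                             ["a", "b"])
        slide = SlideMeta(slide_id, w, w, 0.5)
        return build_heatmap(_fake_pred(np.arange(k), np.asarray(conf)), store, slide)

    def test_unanimous_slide_ranks_last(self, rng):
        hm_sure = self._heatmap("sure", np.full(50, 100), rng)
        hm_unsure = self._heatmap("unsure", np.zeros(50, dtype=int), rng)
        ranking = rank_slides([hm_sure, hm_unsure])
        assert list(ranking["slide_id"]) == ["unsure", "sure"]

    def test_ties_break_lexically(self, rng):
        hms = [self._heatmap(s, np.zeros(10, dtype=int), rng) for s in ("b", "a")]
        ranking = rank_slides(hms)
        assert list(ranking["slide_id"]) == ["a", "b"]

    def test_matches_recomputed_fractions(self, rng):
        hms = [
            self._heatmap(f"s{i}", rng.integers(0, 51, size=40) * 2, rng)
            for i in range(5)
        ]
        ranking = rank_slides(hms)
        fracs = {
            h.slide_id: h.n_low_confidence / h.n_objects for h in hms
        }
        expected = sorted(fracs, key=lambda s: (-fracs[s], s))
        assert list(ranking["slide_id"]) == expected


class TestAuc:
    def test_perfect_separation(self):
        y = np.array([1, 1, -1, -1])
        auc, roc = trapezoidal_auc(y, np.array([0.9, 0.8, 0.2, 0.1]))
        assert auc == 1.0
        assert roc[0].tolist() == [0.0, 0.0] or roc[-1].tolist() == [1.0, 1.0]

    def test_constant_scores_give_half(self):
        y = np.array([1, -1, 1, -1, -1])
        auc, _ = trapezoidal_auc(y, np.full(5, 0.5))
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(DataValidationError, match="both classes"):
            trapezoidal_auc(np.ones(4), np.arange(4.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        y = rng.choice([-1, 1], size=n)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        scores = rng.integers(0, 25, size=n) / 25.0  # many ties
        auc, _ = trapezoidal_auc(y, scores)
        pos, neg = scores[y == 1], scores[y == -1]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_evaluate_auc_on_separable_benchmark(self, rng):
        store, truth = _separable_store(rng, k=100)
        train = LabelSet()
        for oid in range(20):
            train.add(oid, truth.entries[oid], "seed")
        validation = LabelSet(role="validation")
        for oid in range(20, 100):
            validation.add(oid, truth.entries[oid], "truth")
        model = train_forest(store, train)
        auc, roc = evaluate_auc(model, store, validation)
        assert auc == 1.0
        assert roc.shape[1] == 2


class TestLabelEdits:
    def test_relabel_and_back_is_identity(self):
        labels = LabelSet()
        labels.add(1, 1, "seed")
        once = apply_label_edits(labels, [(1, -1)])
        back = apply_label_edits(once, [(1, 1)])
        assert back.entries == labels.entries

    def test_ignore_removes_from_training_counts(self):
        labels = LabelSet()
        labels.add(1, 1, "seed")
        labels.add(2, -1, "seed")
        edited = apply_label_edits(labels, [(2, 0)])
        assert edited.n_effective() == 1
        assert edited.source[2] == "review"

    def test_unknown_object_rejected(self):
        with pytest.raises(KeyError, match="42"):
            apply_label_edits(LabelSet(), [(42, 1)])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 30), st.sampled_from([1, -1, 0])),
                    min_size=1, max_size=100))
    def test_batch_equals_sequential_application(self, edits):
        labels = LabelSet()
        for oid in range(31):
            labels.add(oid, 1, "seed")
        batch = apply_label_edits(labels, edits)
        seq = labels
        for e in edits:
            seq = apply_label_edits(seq, [e])
        assert batch.entries == seq.entries
        assert batch.source == seq.source


class TestLearningLoop:
    def test_zero_iterations_returns_seed_model(self, small_benchmark):
        _s, store, truth, val = small_benchmark
        seed_labels = make_seed_labels(truth, seed=1)
        model, labels, history = run_learning_loop(
            store, seed_labels, truth_oracle(truth), max_iterations=0,
            validation=val, master_seed=1,
        )
        assert len(history.records) == 1
        assert labels.n_effective() == 8
        assert model.training_snapshot == sorted(
            (o, l) for o, l in seed_labels.entries.items()
        )

    def test_training_size_bookkeeping(self, small_benchmark):
        _s, store, truth, val = small_benchmark
        seed_labels = make_seed_labels(truth, seed=2)
        _m, labels, history = run_learning_loop(
            store, seed_labels, truth_oracle(truth), k=8, max_iterations=3,
            candidates=set(truth.entries), master_seed=2,
        )
        sizes = [r["train_size"] for r in history.records]
        assert sizes == [8, 16, 24, 32]
        assert labels.n_effective() == 32

    def test_missing_stop_criterion_rejected(self, small_benchmark):
        _s, store, truth, _v = small_benchmark
        with pytest.raises(DataValidationError, match="stop criterion"):
            run_learning_loop(store, make_seed_labels(truth, seed=0),
                              truth_oracle(truth))

    def test_loop_is_deterministic_byte_for_byte(self, small_benchmark, tmp_path):
        _s, store, truth, val = small_benchmark
        outputs = []
        for run in range(2):
            seed_labels = make_seed_labels(truth, seed=7)
            model, _l, history = run_learning_loop(
                store, seed_labels, truth_oracle(truth), k=8, max_iterations=2,
                validation=val, candidates=set(truth.entries), master_seed=7,
            )
            hist_path = tmp_path / f"h{run}.csv"
            pred_path = tmp_path / f"p{run}.csv"
            history.save_csv(hist_path)
            predict_confidence(model, store).to_frame(store).to_csv(pred_path, index=False)
            outputs.append((hist_path.read_bytes(), pred_path.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_validation_slides_never_labeled(self, small_benchmark):
        _s, store, truth, val = small_benchmark
        seed_labels = make_seed_labels(truth, seed=3)
        _m, labels, _h = run_learning_loop(
            store, seed_labels, truth_oracle(truth), k=8, max_iterations=2,
            candidates=set(truth.entries), master_seed=3,
        )
        assert set(labels.entries) <= set(truth.entries)
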