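"""Majority vote, the tabular feature matrix, and the tabular learner."""

import itertools

import numpy as np
import pandas as pd
import pytest

from her2mil import synthetic
from her2mil.aggregator import (
    FEATURE_COLUMNS,
    TabularLearner,
    TabularLearnerConfig,
    build_feature_matrix,
    majority_vote,
    predict_slide,
    train_tabular_learner,
    vote_predictions,
)
from her2mil.mil_features import HISTOGRAM_EDGES, SlideFeatures, compute_features


def _features(slide_id, p1_star, f=None, label_indices=(0, 0, 0)):
    f = f or {h: 0.0 for h in HISTOGRAM_EDGES}
    p1, p2, p3 = label_indices
    return SlideFeatures(slide_id, 10, p1_star, p1, p2, p3, dict(f))


def _separable_rows(n=40, seed=0):
    """Rows where the positive class has high P1* and top-bin mass."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        label = i % 2
        base = 0.7 if label else 0.25
        f = {h: 0.0 for h in HISTOGRAM_EDGES}
        f[0.9 if label else 0.5] = 0.5 + rng.uniform(0, 0.2)
        rows.append(
            _features(f"s{i}", base + rng.uniform(-0.05, 0.05), f).to_row()
            | {"P": label}
        )
    df = pd.DataFrame(rows)
    return df[["slide_id"] + FEATURE_COLUMNS + ["P"]]


class TestMajorityVote:
    def test_two_of_three(self):
        assert majority_vote(1, 1, 0) == 1

    def test_unanimous_negative(self):
        assert majority_vote(0, 0, 0) == 0

    def test_exhaustive_truth_table(self):
        for triple in itertools.product((0, 1), repeat=3):
            assert majority_vote(*triple) == int(sum(triple) >= 2)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(1, 2, 0)

    def test_vote_predictions_map(self):
        feats = [
            _features("a", 0.6, label_indices=(1, 1, 0)),
            _features("b", 0.2, label_indices=(0, 0, 1)),
        ]
        assert vote_predictions(feats) == {"a": 1, "b": 0}


class TestFeatureMatrix:
    def test_training_schema(self):
        feats = [_features(f"s{i}", 0.5) for i in range(3)]
        df = build_feature_matrix(feats, {f"s{i}": i % 2 for i in range(3)})
        assert list(df.columns) == ["slide_id"] + FEATURE_COLUMNS + ["P"]
        assert len(df) == 3

    def test_inference_mode_has_no_label(self):
        df = build_feature_matrix([_features("s", 0.5)])
        assert "P" not in df.columns

    def test_binary_indices_excluded_by_default_and_optional(self):
        feats = [_features("s", 0.5, label_indices=(1, 0, 1))]
        assert "P2" not in build_feature_matrix(feats).columns
        df = build_feature_matrix(feats, include_binary_indices=True)
        assert {"P1", "P2", "P3"} <= set(df.columns)

    def test_duplicate_slide_id_rejected(self):
        feats = [_features("s", 0.5), _features("s", 0.6)]
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_matrix(feats)

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_feature_matrix([_features("s", 0.5)], {"other": 1})


class TestTabularLearner:
    def test_separable_rows_reach_training_accuracy_one(self):
        rows = _separable_rows()
        cfg = TabularLearnerConfig(epochs=50, seed=1)
        learner = train_tabular_learner(rows, cfg)
        acc = (learner.predict(rows) == rows["P"]).mean()
        assert acc == 1.0
        # the monitored metric is recorded per epoch
        assert any("accuracy" in h for h in learner.model.history)

    def test_bag_recovery_heldout(self, default_bags):
        feats = [
            compute_features(b.slide_id, b.probabilities) for b in default_bags
        ]
        labels = {b.slide_id: b.label for b in default_bags}
        train_f, test_f = feats[:100], feats[100:]
        learner = train_tabular_learner(
            build_feature_matrix(train_f, labels),
            TabularLearnerConfig(epochs=100, seed=2),
        )
        tm = build_feature_matrix(test_f)
        calls = learner.predict(tm)
        truth = np.array([labels[s] for s in tm["slide_id"]])
        assert (calls == truth).mean() >= 0.9

    def test_degenerate_capacity_trains(self):
        rows = _separable_rows(n=10)
        cfg = TabularLearnerConfig(hidden_layers=(1, 1, 1), epochs=5, seed=3)
        learner = train_tabular_learner(rows, cfg)
        assert learner.predict_proba(rows.drop(columns=["P"])).shape == (10,)

    def test_single_class_rejected(self):
        rows = _separable_rows(n=10)
        rows["P"] = 1
        with pytest.raises(ValueError, match="single class"):
            train_tabular_learner(rows)

    def test_predict_slide_deterministic_and_extremes(self):
        rows = _separable_rows()
        learner = train_tabular_learner(rows, TabularLearnerConfig(epochs=50, seed=4))
        zeros = build_feature_matrix([_features("z", 0.0)])
        saturated = build_feature_matrix(
            [_features("o", 1.0, {h: (1.0 if h == 0.9 else 0.0) for h in HISTOGRAM_EDGES})]
        )
        call0, p0 = predict_slide(learner, zeros)
        call1, p1 = predict_slide(learner, saturated)
        assert (call0, call1) == (0, 1)
        assert predict_slide(learner, zeros) == (call0, p0)

    def test_missing_feature_column_named(self):
        rows = _separable_rows()
        learner = train_tabular_learner(rows, TabularLearnerConfig(epochs=5, seed=5))
        broken = build_feature_matrix([_features("m", 0.5)]).drop(columns=["F0.7"])
        with pytest.raises(ValueError, match="F0.7"):
            learner.predict_proba(broken)

    def test_label_column_rejected_at_inference(self):
        rows = _separable_rows()
        learner = train_tabular_learner(rows, TabularLearnerConfig(epochs=5, seed=6))
        with pytest.raises(ValueError, match="label"):
            predict_slide(learner, rows.head(1))

    def test_save_load_roundtrip(self, tmp_path):
        rows = _separable_rows()
        learner = train_tabular_learner(rows, TabularLearnerConfig(epochs=20, seed=7))
        path = tmp_path / "model.json"
        learner.save(path)
        back = TabularLearner.load(path)
        X = rows.drop(columns=["P"])
        assert np.allclose(learner.predict_proba(X), back.predict_proba(X))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TabularLearnerConfig(hidden_layers=(0, 1, 1)).validate()
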