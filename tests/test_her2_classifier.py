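"""Weak labelling, the HER2 tile classifier, and per-slide probability vectors."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from her2mil import synthetic
from her2mil.her2_classifier import (
    SlideProbabilities,
    assign_slide_labels_to_tiles,
    group_tiles_by_slide,
    load_probabilities_csv,
    predict_slide_probabilities,
    probabilities_from_frame,
    probabilities_to_frame,
    train_her2_classifier,
)
from her2mil.mil_features import compute_features
from her2mil.tile_model import (
    ConstantTileClassifier,
    OracleTileClassifier,
    TileClassifierConfig,
)
from her2mil.tiler import extract_tiles, filter_background


def _cohort_tiles(slides):
    tiles, cue = [], {}
    for img, truth in slides:
        for t in filter_background(extract_tiles(img, 64)):
            r, c = t.origin_y // 64, t.origin_x // 64
            tiles.append(t)
            cue[(t.slide_id, t.origin_x, t.origin_y)] = bool(
                truth.positive_mask[r, c]
            )
    return tiles, cue


class TestWeakLabelling:
    def test_tiles_inherit_slide_label(self, small_slide_spec):
        image, _ = synthetic.generate_synthetic_slide(small_slide_spec, slide_id="p")
        tiles = extract_tiles(image, 64)[:3]
        labelled = assign_slide_labels_to_tiles(tiles, {"p": 1})
        assert [lab for _, lab in labelled] == [1, 1, 1]
        # pixels and ordering untouched
        assert [t for t, _ in labelled] == tiles

    def test_empty_tile_list(self):
        assert assign_slide_labels_to_tiles([], {"p": 1}) == []

    def test_missing_label_names_slide(self, small_slide_spec):
        a, _ = synthetic.generate_synthetic_slide(small_slide_spec, slide_id="a")
        b, _ = synthetic.generate_synthetic_slide(small_slide_spec, slide_id="b")
        tiles = extract_tiles(a, 64)[:2] + extract_tiles(b, 64)[:2]
        with pytest.raises(ValueError, match="'b'"):
            assign_slide_labels_to_tiles(tiles, {"a": 1})


class TestTraining:
    def test_planted_cue_auc(self, cue_slide_cohort):
        train, test = cue_slide_cohort
        train_tiles, _ = _cohort_tiles(train)
        test_tiles, test_cue = _cohort_tiles(test)
        labels = {img.slide_id: img.label for img, _ in train}
        labelled = assign_slide_labels_to_tiles(train_tiles, labels)
        model = train_her2_classifier(labelled, TileClassifierConfig(seed=5))
        probs = model.predict_proba(test_tiles)
        truth = [test_cue[(t.slide_id, t.origin_x, t.origin_y)] for t in test_tiles]
        assert roc_auc_score(truth, probs) >= 0.85

    def test_inference_deterministic(self, cue_slide_cohort):
        train, _ = cue_slide_cohort
        tiles, _ = _cohort_tiles(train[:4])
        labels = {img.slide_id: img.label for img, _ in train[:4]}
        if len(set(labels.values())) < 2:  # ensure both classes
            labels = {k: i % 2 for i, k in enumerate(labels)}
        model = train_her2_classifier(
            assign_slide_labels_to_tiles(tiles, labels), TileClassifierConfig(seed=6)
        )
        p1 = model.predict_proba(tiles[:5])
        p2 = model.predict_proba(tiles[:5])
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, small_slide_spec):
        image, _ = synthetic.generate_synthetic_slide(small_slide_spec, slide_id="n")
        tiles = filter_background(extract_tiles(image, 64))
        labelled = assign_slide_labels_to_tiles(tiles, {"n": 0})
        with pytest.raises(ValueError, match="single class"):
            train_her2_classifier(labelled)


class TestSlideProbabilities:
    def test_constant_model_contract(self, small_slide_spec):
        image, _ = synthetic.generate_synthetic_slide(small_slide_spec, slide_id="s")
        tiles = extract_tiles(image, 64)[:4]
        sps = predict_slide_probabilities(ConstantTileClassifier(0.7), {"s": tiles})
        assert len(sps) == 1
        assert np.allclose(sps[0].p, 0.7)

    def test_shapes_per_slide(self, small_slide_spec):
        image, _ = synthetic.generate_synthetic_slide(small_slide_spec, slide_id="s")
        tiles = extract_tiles(image, 64)
        sps = predict_slide_probabilities(
            ConstantTileClassifier(0.5), {"a": tiles[:3], "b": tiles[3:8]}
        )
        assert [len(s.p) for s in sps] == [3, 5]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="s"):
            predict_slide_probabilities(ConstantTileClassifier(0.5), {"s": []})

    def test_row_major_tile_order(self, small_slide_spec):
        image, _ = synthetic.generate_synthetic_slide(small_slide_spec, slide_id="s")
        tiles = extract_tiles(image, 64)
        shuffled = [tiles[i] for i in np.random.default_rng(0).permutation(len(tiles))]
        sps = predict_slide_probabilities(ConstantTileClassifier(0.5), {"s": shuffled})
        assert sps[0].tile_keys == [(t.origin_x, t.origin_y) for t in tiles]

    def test_vector_validation(self):
        with pytest.raises(ValueError, match="empty"):
            SlideProbabilities("s", np.empty(0), [])
        with pytest.raises(ValueError, match="outside"):
            SlideProbabilities("s", np.array([1.2]), [(0, 0)])

    def test_oracle_chaining_P3_equals_planted_fraction_threshold(
        self, cue_slide_cohort
    ):
        train, _ = cue_slide_cohort
        tiles, cue = _cohort_tiles(train)
        oracle = OracleTileClassifier({k for k, v in cue.items() if v})
        sps = predict_slide_probabilities(oracle, group_tiles_by_slide(tiles))
        for sp in sps:
            planted = np.mean(
                [cue[(sp.slide_id, x, y)] for x, y in sp.tile_keys]
            )
            assert compute_features(sp.slide_id, sp.p).P3 == int(planted >= 0.35)

    def test_probability_csv_roundtrip(self, tmp_path):
        sps = [
            SlideProbabilities("a", np.array([0.1, 0.9]), [(0, 0), (64, 0)]),
            SlideProbabilities("b", np.array([0.5]), [(0, 64)]),
        ]
        path = tmp_path / "probs.csv"
        probabilities_to_frame(sps).to_csv(path, index=False)
        back = load_probabilities_csv(path)
        assert [s.slide_id for s in back] == ["a", "b"]
        assert np.array_equal(back[0].p, sps[0].p)
        assert back[1].tile_keys == [(0, 64)]
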