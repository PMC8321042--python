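"""End-to-end orchestration of the five-stage cascade.

Stage 1 tiles every slide and drops bright background tiles; Stage 2 either
passes all tiles through ("all_tiles") or keeps only tiles a cancer
classifier flags ("cancer_subset"); Stage 3 trains the HER2 tile classifier
on weakly labelled training tiles and scores every tile; Stage 4 turns each
slide's probability vector into the feature row (P1*, P1, P2, P3,
F0.5..F0.9); Stage 5 makes the slide call by majority vote and/or the
tabular learner. Crossing the two Stage-2 branches with the two Stage-5
strategies yields the four pipeline variants.

Every stage boundary is a CSV on disk, so any stage can be re-run or
replaced independently; a run manifest records configuration, derived seeds
and tile/slide counts at every stage. One global seed fans out
deterministically to per-stage seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import aggregator, cancer_filter, her2_classifier, mil_features, tiler
from .evaluation import EvaluationReport, evaluate
from .tile_model import TileClassifierConfig

logger = logging.getLogger(__name__)

BRANCHES = ("all_tiles", "cancer_subset")
AGGREGATIONS = ("majority_vote", "tabular", "both")


@dataclass
class PipelineConfig:
    tile_size: int = 512
    stride: Optional[int] = None  # None = no overlap (stride = tile_size)
    gray_threshold: float = 0.8
    branch: str = "all_tiles"
    aggregation: str = "both"
    her2_config: Optional[TileClassifierConfig] = None
    cancer_config: Optional[TileClassifierConfig] = None
    tabular_config: Optional[aggregator.TabularLearnerConfig] = None
    feature_config: mil_features.FeatureConfig = field(
        default_factory=mil_features.FeatureConfig
    )
    seed: int = 0

    def validate(self) -> None:
        if self.branch not in BRANCHES:
            raise ValueError(f"branch must be one of {BRANCHES}; got {self.branch!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(
                f"aggregation must be one of {AGGREGATIONS}; got {self.aggregation!r}"
            )

    def stage_seeds(self) -> Dict[str, int]:
        """Deterministic per-stage seeds fanned out from the global seed."""
        rng = np.random.default_rng(self.seed)
        names = ("cancer", "her2", "tabular")
        return {name: int(rng.integers(0, 2**31 - 1)) for name in names}


@dataclass
class PipelineResult:
    predictions: pd.DataFrame  # slide_id, vote_call, tabular_call, tabular_probability
    vote_report: Optional[EvaluationReport]
    tabular_report: Optional[EvaluationReport]
    manifest: Dict[str, object]


def _stage1(
    slides: Sequence[tiler.SlideImage], config: PipelineConfig
) -> Tuple[List[tiler.Tile], List[tiler.Tile]]:
    all_tiles: List[tiler.Tile] = []
    for slide in slides:
        all_tiles.extend(tiler.extract_tiles(slide, config.tile_size, config.stride))
    kept = tiler.filter_background(all_tiles, config.gray_threshold)
    return all_tiles, kept


def run_pipeline(
    train_slides: Sequence[tiler.SlideImage],
    test_slides: Sequence[tiler.SlideImage],
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
    cancer_model=None,
    her2_model=None,
) -> PipelineResult:
    """Run Stage 1 -> (2A|2B) -> 3 -> 4 -> 5 and evaluate on the test slides.

    Training slides must carry labels (used both to weakly label tiles for
    the HER2 classifier and to fit the tabular learner). A pre-trained
    ``cancer_model`` must be supplied for the cancer_subset branch — e.g. a
    classifier trained on four-class histology tiles, or an oracle in tests.
    An optional pre-trained ``her2_model`` skips Stage-3 training.
    """
    config.validate()
    seeds = config.stage_seeds()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "config": {
            "tile_size": config.tile_size,
            "stride": config.stride or config.tile_size,
            "gray_threshold": config.gray_threshold,
            "branch": config.branch,
            "aggregation": config.aggregation,
            "seed": config.seed,
            "stage_seeds": seeds,
        },
        "counts": {},
    }
    counts: Dict[str, object] = manifest["counts"]  # type: ignore[assignment]

    train_labels = {s.slide_id: s.label for s in train_slides}
    unlabelled = sorted(sid for sid, lab in train_labels.items() if lab is None)
    if unlabelled and her2_model is None:
        raise ValueError(f"training slides without labels: {unlabelled}")
    test_labels = {
        s.slide_id: s.label for s in test_slides if s.label is not None
    }

    # ---- Stage 1: tiling + background filter
    train_all, train_kept = _stage1(train_slides, config)
    test_all, test_kept = _stage1(test_slides, config)
    counts["stage1_extracted"] = {"train": len(train_all), "test": len(test_all)}
    counts["stage1_kept"] = {"train": len(train_kept), "test": len(test_kept)}
    logger.info(
        "stage 1: kept %d/%d train and %d/%d test tiles",
        len(train_kept), len(train_all), len(test_kept), len(test_all),
    )
    if out is not None:
        tiler.tile_manifest(train_all + test_all, train_kept + test_kept).to_csv(
            out / "tile_manifest.csv", index=False
        )

    # ---- Stage 2: pass-through or cancer pre-filter
    if config.branch == "cancer_subset":
        if cancer_model is None:
            raise ValueError(
                "branch 'cancer_subset' requires a trained cancer_model "
                "(train one with cancer_filter.train_cancer_classifier)"
            )
        train_fwd = cancer_filter.filter_cancer_tiles(cancer_model, train_kept)
        test_fwd = cancer_filter.filter_cancer_tiles(cancer_model, test_kept)
    else:
        train_fwd, test_fwd = list(train_kept), list(test_kept)
    counts["stage2_forwarded"] = {"train": len(train_fwd), "test": len(test_fwd)}
    if out is not None:
        tiler.tile_manifest(train_kept + test_kept, train_fwd + test_fwd).to_csv(
            out / "filtered_manifest.csv", index=False
        )

    # ---- Stage 3: HER2 tile classifier
    if her2_model is None:
        her2_cfg = config.her2_config or TileClassifierConfig(seed=seeds["her2"])
        labelled = her2_classifier.assign_slide_labels_to_tiles(
            train_fwd, {k: int(v) for k, v in train_labels.items()}
        )
        her2_model = her2_classifier.train_her2_classifier(labelled, her2_cfg)

    def _score(tiles: Sequence[tiler.Tile], tag: str):
        groups = her2_classifier.group_tiles_by_slide(tiles)
        empty = [
            s.slide_id
            for s in (train_slides if tag == "train" else test_slides)
            if s.slide_id not in groups
        ]
        if empty:
            raise ValueError(
                f"stage 3 ({tag}): no tiles survived filtering for slides {empty}"
            )
        sps = her2_classifier.predict_slide_probabilities(her2_model, groups)
        if out is not None:
            her2_classifier.probabilities_to_frame(sps).to_csv(
                out / f"probabilities_{tag}.csv", index=False
            )
        return sps

    train_probs = _score(train_fwd, "train")
    test_probs = _score(test_fwd, "test")
    counts["stage3_slides"] = {"train": len(train_probs), "test": len(test_probs)}

    # ---- Stage 4: slide features
    def _features(sps) -> List[mil_features.SlideFeatures]:
        return [
            mil_features.compute_features(sp.slide_id, sp.p, config.feature_config)
            for sp in sps
        ]

    train_feats = _features(train_probs)
    test_feats = _features(test_probs)
    if out is not None:
        pd.DataFrame([f.to_row() for f in train_feats]).to_csv(
            out / "features_train.csv", index=False
        )
        pd.DataFrame([f.to_row() for f in test_feats]).to_csv(
            out / "features_test.csv", index=False
        )

    # ---- Stage 5: aggregation
    pred_rows: Dict[str, Dict[str, object]] = {
        f.slide_id: {"slide_id": f.slide_id} for f in test_feats
    }
    vote_report = tabular_report = None
    if config.aggregation in ("majority_vote", "both"):
        votes = aggregator.vote_predictions(test_feats)
        for sid, call in votes.items():
            pred_rows[sid]["vote_call"] = call
        if test_labels:
            vote_report = evaluate(votes, test_labels)
    if config.aggregation in ("tabular", "both"):
        tab_cfg = config.tabular_config or aggregator.TabularLearnerConfig(
            seed=seeds["tabular"]
        )
        matrix = aggregator.build_feature_matrix(
            train_feats, {k: int(v) for k, v in train_labels.items()}
        )
        learner = aggregator.train_tabular_learner(matrix, tab_cfg)
        test_matrix = aggregator.build_feature_matrix(test_feats)
        proba = learner.predict_proba(test_matrix)
        calls = (proba >= 0.5).astype(int)
        tab_calls = dict(zip(test_matrix["slide_id"], calls))
        for sid, pr in zip(test_matrix["slide_id"], proba):
            pred_rows[sid]["tabular_call"] = int(tab_calls[sid])
            pred_rows[sid]["tabular_probability"] = float(pr)
        if test_labels:
            tabular_report = evaluate(
                {k: int(v) for k, v in tab_calls.items()}, test_labels
            )

    predictions = pd.DataFrame(list(pred_rows.values()))
    if out is not None:
        predictions.to_csv(out / "predictions.csv", index=False)
    if vote_report is not None:
        manifest["vote_metrics"] = vote_report.to_dict()
    if tabular_report is not None:
        manifest["tabular_metrics"] = tabular_report.to_dict()
    if out is not None:
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(predictions, vote_report, tabular_report, manifest)
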