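"""Stage 3: the per-tile HER2 classifier and its weak-label training scheme.

Under multiple-instance learning, no tile-level HER2 annotation exists: every
tile inherits its slide's binary HER2 status as a (noisy) training label.
The classifier then emits, for each tile, the probability p_ij that tile i
of slide j is HER2-positive; those per-slide probability vectors are the
contract consumed by the feature stage.

Training monitors precision per epoch (precision is not a differentiable
loss; optimization is cross-entropy) and uses a one-cycle learning-rate
schedule with the same augmentation family as the cancer pre-filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import precision_score

from .tile_model import TileClassifier, TileClassifierConfig
from .tiler import Tile


@dataclass
class SlideProbabilities:
    """The vector p_ij of per-tile HER2 probabilities for one slide."""

    slide_id: str
    p: np.ndarray
    tile_keys: List[Tuple[int, int]]  # (origin_x, origin_y), row-major order

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size != len(self.tile_keys):
            raise ValueError("probability vector and tile_keys lengths differ")
        if self.p.size == 0:
            raise ValueError(f"slide {self.slide_id}: empty probability vector")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError(f"slide {self.slide_id}: probabilities outside [0, 1]")


def assign_slide_labels_to_tiles(
    tiles: Sequence[Tile], slide_labels: Dict[str, int]
) -> List[Tuple[Tile, int]]:
    """Weak labelling: each tile inherits its slide's binary HER2 status.

    Tile pixels and ordering are untouched. Tiles whose slide has no label
    are an error naming the offending slides, not a silent drop.
    """
    missing = sorted({t.slide_id for t in tiles if t.slide_id not in slide_labels})
    if missing:
        raise ValueError(f"no slide label for slide_ids: {missing}")
    return [(t, int(slide_labels[t.slide_id])) for t in tiles]


def train_her2_classifier(
    labelled_tiles: Sequence[Tuple[Tile, int]],
    config: TileClassifierConfig = TileClassifierConfig(),
) -> TileClassifier:
    """Fit the HER2 tile classifier on weakly labelled tiles."""
    if not labelled_tiles:
        raise ValueError("no labelled tiles to train on")
    tiles = [t for t, _ in labelled_tiles]
    y = [lab for _, lab in labelled_tiles]
    clf = TileClassifier(config)
    clf.fit(
        tiles,
        y,
        metric=lambda yt, yp: precision_score(yt, yp, zero_division=0),
        metric_name="precision",
    )
    return clf


def predict_slide_probabilities(
    model, tiles_by_slide: Dict[str, Sequence[Tile]]
) -> List[SlideProbabilities]:
    """One probability vector per slide, tiles kept in row-major grid order."""
    out: List[SlideProbabilities] = []
    for slide_id, tiles in tiles_by_slide.items():
        if len(tiles) == 0:
            raise ValueError(f"slide {slide_id}: no tiles to score")
        ordered = sorted(tiles, key=lambda t: (t.origin_y, t.origin_x))
        p = model.predict_proba(ordered)
        out.append(
            SlideProbabilities(
                slide_id=slide_id,
                p=p,
                tile_keys=[(t.origin_x, t.origin_y) for t in ordered],
            )
        )
    return out


def group_tiles_by_slide(tiles: Sequence[Tile]) -> Dict[str, List[Tile]]:
    groups: Dict[str, List[Tile]] = {}
    for t in tiles:
        groups.setdefault(t.slide_id, []).append(t)
    return groups


def probabilities_to_frame(slides: Sequence[SlideProbabilities]) -> pd.DataFrame:
    """Per-tile probability CSV: slide_id, origin_x, origin_y, probability.

    This table is the hand-off between the imaging half (Stages 1-3) and the
    aggregation half (Stages 4-5), letting the latter run standalone.
    """
    rows = [
        {"slide_id": sp.slide_id, "origin_x": x, "origin_y": y, "probability": p}
        for sp in slides
        for (x, y), p in zip(sp.tile_keys, sp.p)
    ]
    return pd.DataFrame(rows, columns=["slide_id", "origin_x", "origin_y", "probability"])


def probabilities_from_frame(df: pd.DataFrame) -> List[SlideProbabilities]:
    """Inverse of :func:`probabilities_to_frame` (slides in first-seen order)."""
    out = []
    for sid, grp in df.groupby("slide_id", sort=False):
        out.append(
            SlideProbabilities(
                slide_id=str(sid),
                p=grp["probability"].to_numpy(),
                tile_keys=list(zip(grp["origin_x"], grp["origin_y"])),
            )
        )
    return out


def load_probabilities_csv(path) -> List[SlideProbabilities]:
    return probabilities_from_frame(pd.read_csv(Path(path)))
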