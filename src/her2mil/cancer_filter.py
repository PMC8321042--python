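"""Stage 2B: keep only tiles classified as containing cancer.

The pre-filter is a binary cancer / no-cancer tile classifier. Its training
labels come from four-class breast-histology annotations (as in the BACH
challenge) collapsed to two classes: "normal" and "benign" become
"no cancer"; "in situ carcinoma" and "invasive carcinoma" become "cancer"
(in-situ is kept as cancer because at tile resolution it is not reliably
distinguishable from invasive cancer).

A tile whose predicted cancer probability is >= 0.5 is kept; the tie at
exactly 0.5 goes to the positive class, matching the >= convention used by
the downstream slide indices.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import List, Sequence, Tuple

from sklearn.metrics import accuracy_score

from .tile_model import TileClassifier, TileClassifierConfig
from .tiler import Tile

logger = logging.getLogger(__name__)

NO_CANCER = "no cancer"
CANCER = "cancer"

#: Four-class -> binary collapsing map.
LABEL_COLLAPSE = {
    "normal": NO_CANCER,
    "benign": NO_CANCER,
    "in situ carcinoma": CANCER,
    "invasive carcinoma": CANCER,
}

CANCER_DECISION_THRESHOLD = 0.5


def collapse_labels(raw_label: str) -> str:
    """Map a four-class histology label to its binary cancer label.

    Unknown strings are rejected rather than silently defaulted — a typo in
    a label file must never become a training label.
    """
    try:
        return LABEL_COLLAPSE[raw_label]
    except KeyError:
        raise ValueError(
            f"unknown tile class label {raw_label!r}; expected one of "
            f"{sorted(LABEL_COLLAPSE)}"
        ) from None


def train_cancer_classifier(
    tiles: Sequence[Tile],
    labels: Sequence[str],
    config: TileClassifierConfig = TileClassifierConfig(),
) -> TileClassifier:
    """Fit the cancer/no-cancer tile classifier.

    ``labels`` may be the four raw class strings (collapsed internally) or
    already-binary "cancer"/"no cancer" strings. Training is two-phase
    (head epochs, then full-network epochs) with accuracy monitored.
    """
    binary = [
        lab if lab in (NO_CANCER, CANCER) else collapse_labels(lab) for lab in labels
    ]
    y = [1 if lab == CANCER else 0 for lab in binary]
    clf = TileClassifier(config)
    clf.fit(tiles, y, metric=accuracy_score, metric_name="accuracy")
    return clf


def filter_cancer_tiles(
    model, tiles: Sequence[Tile], threshold: float = CANCER_DECISION_THRESHOLD
) -> List[Tile]:
    """Keep tiles whose predicted cancer probability is >= threshold.

    Order is preserved; kept/removed counts and per-slide removal fractions
    are emitted to the log for inspection.
    """
    if len(tiles) == 0:
        return []
    probs = model.predict_proba(tiles)
    kept = [t for t, p in zip(tiles, probs) if p >= threshold]
    removed = len(tiles) - len(kept)
    logger.info(
        "cancer filter: kept %d / %d tiles (removed %d, %.2f%%)",
        len(kept), len(tiles), removed, 100.0 * removed / len(tiles),
    )
    total = Counter(t.slide_id for t in tiles)
    kept_counts = Counter(t.slide_id for t in kept)
    for sid in sorted(total):
        frac_removed = 1.0 - kept_counts.get(sid, 0) / total[sid]
        logger.info("cancer filter: slide %s removed %.2f%% of tiles", sid, 100 * frac_removed)
    return kept


def removal_summary(
    tiles: Sequence[Tile], kept: Sequence[Tile]
) -> Tuple[int, int, float]:
    """(kept_count, removed_count, removed_fraction) for reporting."""
    removed = len(tiles) - len(kept)
    frac = removed / len(tiles) if tiles else 0.0
    return len(kept), removed, frac
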