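"""Stage 5: the final slide-level HER2 call.

Two aggregation strategies over the per-slide features:

* **Majority vote** — the slide is called positive when at least two of the
  three binary indices P1, P2, P3 agree; with three binary voters no tie is
  possible. Fully deterministic.
* **Tabular learner** — a fully connected network (hidden layers 500/250/125
  by default) trained on the non-binarized mean probability P1* and the five
  histogram features F0.5..F0.9. The binary indices P2/P3 are excluded from
  the default feature matrix (they add no measurable signal on top of the
  continuous features); a flag restores them for experimentation. Accuracy is
  the monitored metric — it is not differentiable, so optimization is
  cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score

from .mil_features import HISTOGRAM_EDGES, SlideFeatures
from .nn import MLPClassifier, MLPConfig

#: Feature columns of the tabular training matrix (plus optional label P).
FEATURE_COLUMNS = ["P1_star"] + [f"F{h}" for h in HISTOGRAM_EDGES]
INDEX_COLUMNS = ["P1", "P2", "P3"]
LABEL_COLUMN = "P"


def majority_vote(P1: int, P2: int, P3: int) -> int:
    """1 iff at least two of the three binary indices are 1."""
    votes = (P1, P2, P3)
    for v in votes:
        if v not in (0, 1):
            raise ValueError(f"indices must be binary 0/1; got {v!r}")
    return int(sum(votes) >= 2)


def build_feature_matrix(
    features: Sequence[SlideFeatures],
    labels: Optional[Dict[str, int]] = None,
    include_binary_indices: bool = False,
) -> pd.DataFrame:
    """One row per slide: slide_id, P1*, F0.5..F0.9 [, P1..P3][, label P].

    In training mode (``labels`` supplied) every slide must have a label;
    duplicate slide ids are rejected.
    """
    ids = [f.slide_id for f in features]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate slide_ids in feature matrix: {dupes}")
    if labels is not None:
        missing = sorted(set(ids) - set(labels))
        if missing:
            raise ValueError(f"missing labels for slides: {missing}")
    rows = []
    for f in features:
        row: Dict[str, object] = {"slide_id": f.slide_id, "P1_star": f.P1_star}
        for h in HISTOGRAM_EDGES:
            row[f"F{h}"] = f.F[h]
        if include_binary_indices:
            row.update({"P1": f.P1, "P2": f.P2, "P3": f.P3})
        if labels is not None:
            row[LABEL_COLUMN] = int(labels[f.slide_id])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TabularLearnerConfig:
    hidden_layers: Tuple[int, int, int] = (500, 250, 125)
    epochs: int = 200
    lr_max: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def validate(self) -> None:
        if any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class TabularLearner:
    """Dense network over the per-slide feature row, with standardization."""

    def __init__(self, config: TabularLearnerConfig = TabularLearnerConfig()):
        config.validate()
        self.config = config
        self.feature_columns: List[str] = list(FEATURE_COLUMNS)
        self.model: Optional[MLPClassifier] = None
        self.mean_: Optional[np.ndarray] = None
        self.scale_: Optional[np.ndarray] = None

    def _design(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in rows.columns]
        if missing:
            raise ValueError(f"feature matrix is missing columns: {missing}")
        return rows[self.feature_columns].to_numpy(dtype=float)

    def fit(self, rows: pd.DataFrame) -> "TabularLearner":
        if LABEL_COLUMN not in rows.columns:
            raise ValueError(f"training rows need the label column {LABEL_COLUMN!r}")
        if len(rows) < 2:
            raise ValueError("need at least 2 training rows")
        # optional experiment: include the binary indices when present
        self.feature_columns = [
            c for c in list(FEATURE_COLUMNS) + INDEX_COLUMNS if c in rows.columns
        ]
        y = rows[LABEL_COLUMN].to_numpy(dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("training rows contain a single class")
        X = self._design(rows)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Xs = (X - self.mean_) / self.scale_
        self.model = MLPClassifier(
            Xs.shape[1],
            2,
            MLPConfig(
                hidden_layers=tuple(self.config.hidden_layers),
                lr_max=self.config.lr_max,
                batch_size=self.config.batch_size,
                seed=self.config.seed,
            ),
        )
        self.model.fit(Xs, y, self.config.epochs, metric=accuracy_score,
                       metric_name="accuracy")
        return self

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("tabular learner is not fitted")
        Xs = (self._design(rows) - self.mean_) / self.scale_
        return self.model.predict_proba(Xs)[:, 1]

    def predict(self, rows: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        """Binary calls: positive iff P(positive) >= threshold (0.5 default)."""
        return (self.predict_proba(rows) >= threshold).astype(int)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        state = {
            "config": {
                "hidden_layers": list(self.config.hidden_layers),
                "epochs": self.config.epochs,
                "lr_max": self.config.lr_max,
                "batch_size": self.config.batch_size,
                "seed": self.config.seed,
            },
            "feature_columns": self.feature_columns,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "model": self.model.state_dict(),
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path) -> "TabularLearner":
        state = json.loads(Path(path).read_text())
        cfg = dict(state["config"])
        cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
        learner = cls(TabularLearnerConfig(**cfg))
        learner.feature_columns = state["feature_columns"]
        learner.mean_ = np.asarray(state["mean"])
        learner.scale_ = np.asarray(state["scale"])
        learner.model = MLPClassifier.from_state_dict(state["model"])
        return learner


def vote_predictions(features: Sequence[SlideFeatures]) -> Dict[str, int]:
    """Majority-vote call for every slide."""
    return {f.slide_id: majority_vote(f.P1, f.P2, f.P3) for f in features}


def train_tabular_learner(
    rows: pd.DataFrame, config: TabularLearnerConfig = TabularLearnerConfig()
) -> TabularLearner:
    return TabularLearner(config).fit(rows)


def predict_slide(model: TabularLearner, row: pd.DataFrame) -> Tuple[int, float]:
    """(binary call, positive-class probability) for a single feature row."""
    if LABEL_COLUMN in row.columns:
        raise ValueError("inference rows must not carry the label column")
    proba = float(model.predict_proba(row)[0])
    return int(proba >= 0.5), proba
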