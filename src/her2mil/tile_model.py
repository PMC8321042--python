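"""Shared tile-classification machinery for Stages 2B and 3.

A tile classifier is a feature extractor (downsampling the RGB tile to a
small fixed resolution and flattening to [0, 1] floats) followed by a dense
softmax network trained with Adam under a one-cycle learning-rate schedule.
Training is two-phase when requested: head-only epochs (output layer only,
hidden weights frozen) followed by full-network epochs — the standard
fine-tuning recipe. Data augmentation (flips, right-angle rotations, moderate
zoom up to 1.1x, shear warp, luminosity and contrast jitter) is applied to
training tiles only; inference is deterministic.

Backbones are named presets. The desk-scale presets train in seconds on a
CPU; the paper-scale deep backbones (densenet201, resnet152) are documented
configuration targets that require an external deep-learning backend and
pretrained weights, so selecting them here raises with a clear message.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize, warp, AffineTransform

from .nn import MLPClassifier, MLPConfig
from .tiler import Tile

DEFAULT_AUGMENTATIONS = ("flips", "rotations", "zoom", "warp", "luminosity", "contrast")

#: Desk-scale backbone presets: input downsample size and hidden layout.
BACKBONES: Dict[str, dict] = {
    "small": {"input_size": 16, "hidden_layers": (128, 64)},
    "tiny": {"input_size": 8, "hidden_layers": (32,)},
}
#: Paper-scale architectures: recognized names, not trainable in this package.
PAPER_SCALE_BACKBONES = ("densenet201", "resnet152")


@dataclass(frozen=True)
class TileClassifierConfig:
    """Training configuration shared by the cancer and HER2 tile classifiers."""

    backbone: str = "small"
    head_epochs: int = 3
    full_epochs: int = 3
    augmentations: Tuple[str, ...] = DEFAULT_AUGMENTATIONS
    n_augment: int = 2  # augmented copies per training tile
    lr_max: float = 5e-3
    batch_size: int = 32
    seed: int = 0

    def validate(self) -> None:
        if self.backbone in PAPER_SCALE_BACKBONES:
            raise ValueError(
                f"backbone {self.backbone!r} is a paper-scale architecture that "
                "needs a deep-learning backend and pretrained weights; use a "
                f"desk-scale preset from {sorted(BACKBONES)}"
            )
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; options: {sorted(BACKBONES)}")
        if self.head_epochs < 0 or self.full_epochs < 0:
            raise ValueError("epoch counts must be >= 0")


def tile_features(pixels: np.ndarray, input_size: int) -> np.ndarray:
    """Downsample one RGB tile to (input_size, input_size) and flatten to [0,1]."""
    small = resize(
        np.asarray(pixels, dtype=float) / 255.0,
        (input_size, input_size, 3),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    return small.ravel()


def augment_tile(
    pixels: np.ndarray, augmentations: Sequence[str], rng: np.random.Generator
) -> np.ndarray:
    """One random augmented variant of a tile (uint8 in, uint8 out)."""
    img = np.asarray(pixels, dtype=float)
    if "flips" in augmentations:
        if rng.random() < 0.5:
            img = img[:, ::-1]
        if rng.random() < 0.5:
            img = img[::-1, :]
    if "rotations" in augmentations:
        img = np.rot90(img, k=int(rng.integers(0, 4)))
    if "zoom" in augmentations and rng.random() < 0.5:
        z = rng.uniform(1.0, 1.1)
        h, w = img.shape[:2]
        ch, cw = int(round(h / z)), int(round(w / z))
        y0 = (h - ch) // 2
        x0 = (w - cw) // 2
        img = resize(img[y0 : y0 + ch, x0 : x0 + cw], (h, w, 3), order=1,
                     anti_aliasing=False, preserve_range=True)
    if "warp" in augmentations and rng.random() < 0.5:
        tf = AffineTransform(shear=rng.uniform(-0.1, 0.1))
        img = warp(img, tf.inverse, mode="edge", preserve_range=True)
    if "luminosity" in augmentations:
        img = img + rng.uniform(-15, 15)
    if "contrast" in augmentations:
        img = (img - 128.0) * rng.uniform(0.9, 1.1) + 128.0
    return np.clip(img, 0, 255).astype(np.uint8)


class TileClassifier:
    """Binary tile classifier: downsampled-pixel features + dense softmax net.

    With zero training epochs the classifier falls back to predicting the
    empirical class prior — an uncalibrated but well-defined model that keeps
    the pipeline runnable end to end.
    """

    def __init__(self, config: TileClassifierConfig):
        config.validate()
        self.config = config
        preset = BACKBONES[config.backbone]
        self.input_size: int = preset["input_size"]
        self._hidden: Tuple[int, ...] = tuple(preset["hidden_layers"])
        self.model: Optional[MLPClassifier] = None
        self.prior: Optional[float] = None  # P(class 1) fallback

    # -- features -----------------------------------------------------------

    def featurize(self, tiles: Sequence[Tile]) -> np.ndarray:
        return np.stack([tile_features(t.pixels, self.input_size) for t in tiles])

    # -- training -----------------------------------------------------------

    def fit(
        self,
        tiles: Sequence[Tile],
        labels: Sequence[int],
        metric=None,
        metric_name: str = "metric",
    ) -> "TileClassifier":
        labels = np.asarray(labels, dtype=int)
        if len(tiles) != len(labels):
            raise ValueError("tiles and labels must have equal length")
        if len(tiles) < 2:
            raise ValueError("need at least 2 training tiles")
        classes = np.unique(labels)
        if classes.size < 2:
            raise ValueError(
                "training set contains a single class; both classes are required"
            )
        self.prior = float(labels.mean())
        total_epochs = self.config.head_epochs + self.config.full_epochs
        if total_epochs == 0:
            self.model = None  # prior-only model
            return self
        rng = np.random.default_rng(self.config.seed)
        aug_tiles: List[np.ndarray] = []
        aug_labels: List[int] = []
        for t, y in zip(tiles, labels):
            aug_tiles.append(tile_features(t.pixels, self.input_size))
            aug_labels.append(int(y))
            for _ in range(self.config.n_augment if self.config.augmentations else 0):
                variant = augment_tile(t.pixels, self.config.augmentations, rng)
                aug_tiles.append(tile_features(variant, self.input_size))
                aug_labels.append(int(y))
        X = np.stack(aug_tiles)
        y = np.asarray(aug_labels)
        self.model = MLPClassifier(
            X.shape[1],
            2,
            MLPConfig(
                hidden_layers=self._hidden,
                lr_max=self.config.lr_max,
                batch_size=self.config.batch_size,
                seed=self.config.seed,
            ),
        )
        if self.config.head_epochs > 0:
            self.model.fit(X, y, self.config.head_epochs, trainable_layers=[-1],
                           metric=metric, metric_name=metric_name)
        if self.config.full_epochs > 0:
            self.model.fit(X, y, self.config.full_epochs,
                           metric=metric, metric_name=metric_name)
        return self

    # -- inference ----------------------------------------------------------

    def predict_proba(self, tiles: Sequence[Tile]) -> np.ndarray:
        """P(positive class) for each tile, in [0, 1]."""
        if self.prior is None:
            raise RuntimeError("classifier is not fitted")
        if len(tiles) == 0:
            return np.empty(0)
        if self.model is None:
            return np.full(len(tiles), self.prior)
        return self.model.predict_proba(self.featurize(tiles))[:, 1]

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        state = {
            "config": {
                "backbone": self.config.backbone,
                "head_epochs": self.config.head_epochs,
                "full_epochs": self.config.full_epochs,
                "augmentations": list(self.config.augmentations),
                "n_augment": self.config.n_augment,
                "lr_max": self.config.lr_max,
                "batch_size": self.config.batch_size,
                "seed": self.config.seed,
            },
            "prior": self.prior,
            "model": self.model.state_dict() if self.model is not None else None,
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path) -> "TileClassifier":
        state = json.loads(Path(path).read_text())
        cfg = state["config"]
        cfg["augmentations"] = tuple(cfg["augmentations"])
        clf = cls(TileClassifierConfig(**cfg))
        clf.prior = state["prior"]
        if state["model"] is not None:
            clf.model = MLPClassifier.from_state_dict(state["model"])
        return clf


class OracleTileClassifier:
    """A classifier that reads planted ground truth — for tests and chaining.

    ``positive_keys`` is a set of (slide_id, origin_x, origin_y) triples; a
    tile in the set scores ``p_pos``, any other tile scores ``p_neg``.
    """

    def __init__(self, positive_keys, p_pos: float = 1.0, p_neg: float = 0.0):
        self.positive_keys = set(positive_keys)
        self.p_pos = p_pos
        self.p_neg = p_neg

    def predict_proba(self, tiles: Sequence[Tile]) -> np.ndarray:
        return np.array(
            [
                self.p_pos
                if (t.slide_id, t.origin_x, t.origin_y) in self.positive_keys
                else self.p_neg
                for t in tiles
            ]
        )


class ConstantTileClassifier:
    """Predicts one fixed probability for every tile."""

    def __init__(self, p: float):
        self.p = float(p)

    def predict_proba(self, tiles: Sequence[Tile]) -> np.ndarray:
        return np.full(len(tiles), self.p)
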