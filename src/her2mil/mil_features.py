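"""Slide-level positivity indices and histogram features from tile probabilities.

Given the vector ``p`` of per-tile HER2-positivity probabilities for one
slide (the output contract of the tile classifier), this module computes:

* ``P1*`` — the plain arithmetic mean of ``p`` over all T tiles, and its
  binarization ``P1 = 1[P1* >= 0.5]``;
* ``P2`` — ``1[(1/T) * sum(p_i * G(p_i)) >= 0.66]`` where ``G(p) = 1[p >= 0.5]``
  is the super-threshold indicator, i.e. the mean over *all* T tiles of the
  masked probabilities (sub-threshold tiles contribute 0);
* ``P3`` — ``1[(1/T) * sum(G(p_i)) >= 0.35]``, positive when at least 35% of
  tiles clear the 0.5 cutoff;
* ``F_h`` for ``h in {0.5, 0.6, 0.7, 0.8, 0.9}`` — the fraction of tiles whose
  probability falls in the decile bin ``[h, h + 0.1)``; by default the top bin
  is closed at 1.0 so certain-positive tiles are counted.

All comparisons are ``>=`` with no floating-point slack: the quantities are
means of well-scaled numbers and the thresholds are design constants, not
estimated values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

HISTOGRAM_EDGES: Tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds and variants for the slide-feature computation.

    g_threshold
        Cutoff of the indicator G; a tile counts as positive when its
        probability is >= this value.
    p2_threshold, p3_threshold
        Decision cutoffs for the P2 masked-mean and P3 positive-fraction
        indices.
    top_bin_closed
        When True (default) the last histogram bin is [0.9, 1.0], so a tile
        with probability exactly 1.0 is counted; when False every bin is
        half-open [h, h+0.1).
    p2_over_positive_tiles
        When True, P2 averages the super-threshold probabilities over the
        *count of super-threshold tiles* rather than over all T tiles
        (a prose-style conditional mean). Default False: divide by T.
    """

    g_threshold: float = 0.5
    p2_threshold: float = 0.66
    p3_threshold: float = 0.35
    top_bin_closed: bool = True
    p2_over_positive_tiles: bool = False


DEFAULT_CONFIG = FeatureConfig()


@dataclass
class SlideFeatures:
    """One row of the per-slide feature table."""

    slide_id: str
    T: int
    P1_star: float
    P1: int
    P2: int
    P3: int
    F: Dict[float, float] = field(default_factory=dict)

    def to_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {
            "slide_id": self.slide_id,
            "T": self.T,
            "P1_star": self.P1_star,
            "P1": self.P1,
            "P2": self.P2,
            "P3": self.P3,
        }
        for h in HISTOGRAM_EDGES:
            row[f"F{h}"] = self.F[h]
        return row


def _validated(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"probability vector must be 1-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(
            "empty probability vector: no tiles survived filtering for this "
            "slide, so no slide-level features can be computed"
        )
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        bad = arr[(arr < 0.0) | (arr > 1.0)][0]
        raise ValueError(f"probabilities must lie in [0, 1]; found {bad}")
    return arr


def indicator_G(p: float, threshold: float = 0.5) -> int:
    """Super-threshold indicator: 1 iff ``p >= threshold`` (0.5 by default)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1]; got {p}")
    return int(p >= threshold)


def positivity_P1(
    p: Sequence[float], config: FeatureConfig = DEFAULT_CONFIG
) -> Tuple[float, int]:
    """Mean tile probability and its binarization at 0.5.

    Returns ``(P1_star, P1)`` where ``P1_star`` is the arithmetic average of
    the tile probabilities and ``P1 = 1`` iff ``P1_star >= g_threshold``.
    """
    arr = _validated(p)
    p1_star = float(arr.mean())
    return p1_star, int(p1_star >= config.g_threshold)


def positivity_P2(p: Sequence[float], config: FeatureConfig = DEFAULT_CONFIG) -> int:
    """Masked-mean index: threshold the mean of ``p * G(p)`` at 0.66.

    Sub-threshold tiles contribute zero to the sum but still count in the
    denominator T (the default, formula-style reading); set
    ``config.p2_over_positive_tiles`` for the conditional-mean variant that
    divides by the number of super-threshold tiles instead.
    """
    arr = _validated(p)
    mask = arr >= config.g_threshold
    if config.p2_over_positive_tiles:
        if not mask.any():
            return 0
        masked_mean = float(arr[mask].mean())
    else:
        masked_mean = float((arr * mask).mean())
    return int(masked_mean >= config.p2_threshold)


def positivity_P3(p: Sequence[float], config: FeatureConfig = DEFAULT_CONFIG) -> int:
    """Positive-fraction index: 1 iff >= 35% of tiles have probability >= 0.5."""
    arr = _validated(p)
    frac = float((arr >= config.g_threshold).mean())
    return int(frac >= config.p3_threshold)


def frequency_Fh(
    p: Sequence[float], h: float, config: FeatureConfig = DEFAULT_CONFIG
) -> float:
    """Fraction of tile probabilities in the decile bin ``[h, h + 0.1)``.

    ``h`` must be one of 0.5, 0.6, 0.7, 0.8, 0.9. Under the default
    ``top_bin_closed`` the bin at h = 0.9 is ``[0.9, 1.0]``.
    """
    if h not in HISTOGRAM_EDGES:
        raise ValueError(f"h must be one of {HISTOGRAM_EDGES}; got {h}")
    arr = _validated(p)
    hi = h + 0.1
    if config.top_bin_closed and h == HISTOGRAM_EDGES[-1]:
        in_bin = (arr >= h) & (arr <= 1.0)
    else:
        in_bin = (arr >= h) & (arr < hi)
    return float(in_bin.mean())


def compute_features(
    slide_id: str, p: Sequence[float], config: FeatureConfig = DEFAULT_CONFIG
) -> SlideFeatures:
    """Assemble P1*, P1, P2, P3 and the five F_h values for one slide."""
    arr = _validated(p)
    p1_star, p1 = positivity_P1(arr, config)
    return SlideFeatures(
        slide_id=slide_id,
        T=int(arr.size),
        P1_star=p1_star,
        P1=p1,
        P2=positivity_P2(arr, config),
        P3=positivity_P3(arr, config),
        F={h: frequency_Fh(arr, h, config) for h in HISTOGRAM_EDGES},
    )


def features_table(
    slide_probabilities: Sequence[Tuple[str, Sequence[float]]],
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Feature rows for many slides as a DataFrame (slide_id, T, P1_star, ...)."""
    rows = [compute_features(sid, p, config).to_row() for sid, p in slide_probabilities]
    return pd.DataFrame(rows)


def features_from_probability_csv(
    path, config: FeatureConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Compute the feature table from a per-tile probability CSV.

    Expects columns ``slide_id`` and ``probability`` (extra columns such as
    tile origins are ignored). Slides appear in first-occurrence order.
    """
    df = pd.read_csv(path)
    pairs = [
        (str(sid), grp["probability"].to_numpy())
        for sid, grp in df.groupby("slide_id", sort=False)
    ]
    return features_table(pairs, config)
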