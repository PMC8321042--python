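"""Synthetic slides and probability bags with planted ground truth.

Every downstream stage of the pipeline is testable without real whole-slide
images: this module fabricates (a) RGB slide rasters with bright glass-like
background, darker stained-tissue cells, and a controllable fraction of
"positive-cue" tissue cells whose color/texture correlates with the slide
label; and (b) per-slide bags of tile probabilities drawn from a two-component
Beta mixture, emulating the output of the tile classifier.

The cue is deliberately simple — a hue shift toward blue/purple plus a higher
density of dark nuclear blobs — so that a small classifier can recover it
quickly. This is a stand-in for cancer morphology at desk scale, not a
simulation of H&E staining physics.

Tissue and positive cells are placed by exact count (``round(fraction *
n_cells)``) via a seeded permutation, so generated fractions are exact within
rounding and identical specs yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .tiler import SlideImage, LUMA_WEIGHTS

#: Base colors (RGB) for the painted regions. Background is near-white glass;
#: negative tissue is eosin-pink; positive-cue tissue is shifted toward
#: haematoxylin blue-purple. Mean grays: background ~0.95, tissue ~0.55-0.65,
#: keeping them on opposite sides of the 0.8 background-filter threshold.
NEGATIVE_TISSUE_COLOR = (205, 140, 185)
POSITIVE_TISSUE_COLOR = (150, 120, 205)
NEGATIVE_BLOB_COLOR = (120, 85, 150)
POSITIVE_BLOB_COLOR = (80, 70, 140)
NEGATIVE_BLOBS_PER_CELL = 4
POSITIVE_BLOBS_PER_CELL = 12


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Recipe for one synthetic slide.

    background_brightness is the target mean gray of background cells in
    [0, 1]; tissue_fraction the fraction of grid cells painted as tissue;
    positive_tile_fraction the fraction of *tissue* cells carrying the
    positive visual cue (meaningful for positive slides; presets use 0 for
    negative slides).
    """

    width_px: int = 2048
    height_px: int = 1536
    tile_px: int = 512
    background_brightness: float = 0.95
    tissue_fraction: float = 0.6
    positive_tile_fraction: float = 0.0
    slide_label: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.width_px < self.tile_px or self.height_px < self.tile_px:
            raise ValueError(
                f"slide dimensions {self.width_px}x{self.height_px} are smaller "
                f"than one {self.tile_px}-px tile; nothing can be generated"
            )
        if not 0.0 <= self.background_brightness <= 1.0:
            raise ValueError("background_brightness must lie in [0, 1]")
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must lie in [0, 1]")
        if not 0.0 <= self.positive_tile_fraction <= 1.0:
            raise ValueError("positive_tile_fraction must lie in [0, 1]")
        if self.slide_label not in (0, 1):
            raise ValueError("slide_label must be 0 or 1")


@dataclass
class SlideGroundTruth:
    """Per-grid-cell truth recorded alongside a generated slide.

    Both masks are (rows, cols) booleans over the non-overlapping tile grid;
    ``positive_mask`` is a subset of ``tissue_mask``.
    """

    tile_px: int
    tissue_mask: np.ndarray
    positive_mask: np.ndarray

    def to_frame(self, slide_id: str, slide_label: int) -> pd.DataFrame:
        rows, cols = self.tissue_mask.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return pd.DataFrame(
            {
                "slide_id": slide_id,
                "tile_row": rr.ravel(),
                "tile_col": cc.ravel(),
                "is_tissue": self.tissue_mask.ravel().astype(int),
                "is_positive": self.positive_mask.ravel().astype(int),
                "slide_label": slide_label,
            }
        )


def _paint_blobs(
    cell: np.ndarray, n_blobs: int, color: Tuple[int, int, int], rng: np.random.Generator
) -> None:
    """Stamp dark elliptical blobs (nuclei stand-ins) onto a cell, in place."""
    t = cell.shape[0]
    yy, xx = np.mgrid[0:t, 0:t]
    for _ in range(n_blobs):
        cy, cx = rng.integers(0, t, size=2)
        r = rng.integers(max(2, t // 24), max(3, t // 10))
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        cell[mask] = 0.65 * cell[mask] + 0.35 * np.asarray(color, dtype=float)


def _paint_cell(
    t: int,
    kind: str,
    background_brightness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if kind == "background":
        base = background_brightness * 255.0
        cell = np.full((t, t, 3), base, dtype=float)
        cell += rng.normal(0.0, 2.0, size=cell.shape)
    else:
        color = POSITIVE_TISSUE_COLOR if kind == "positive" else NEGATIVE_TISSUE_COLOR
        blob_color = POSITIVE_BLOB_COLOR if kind == "positive" else NEGATIVE_BLOB_COLOR
        n_blobs = POSITIVE_BLOBS_PER_CELL if kind == "positive" else NEGATIVE_BLOBS_PER_CELL
        cell = np.tile(np.asarray(color, dtype=float), (t, t, 1))
        cell += rng.normal(0.0, 8.0, size=cell.shape)
        _paint_blobs(cell, n_blobs, blob_color, rng)
    return np.clip(cell, 0, 255)


def generate_synthetic_slide(
    spec: SyntheticSlideSpec, slide_id: Optional[str] = None
) -> Tuple[SlideImage, SlideGroundTruth]:
    """Render one synthetic slide and its ground-truth tile masks.

    The raster is painted cell by cell on the non-overlapping ``tile_px``
    grid: bright background cells above the Stage-1 brightness threshold,
    tissue cells below it, and (on positive slides) a planted fraction of
    cue-bearing tissue cells. Identical spec => bit-identical pixels.
    """
    spec.validate()
    if slide_id is None:
        slide_id = f"synth_{spec.seed}"
    rng = np.random.default_rng(spec.seed)
    t = spec.tile_px
    rows = spec.height_px // t
    cols = spec.width_px // t
    n_cells = rows * cols

    n_tissue = int(round(spec.tissue_fraction * n_cells))
    order = rng.permutation(n_cells)
    tissue_idx = order[:n_tissue]
    n_pos = int(round(spec.positive_tile_fraction * n_tissue))
    positive_idx = tissue_idx[:n_pos]  # permutation already random

    tissue_mask = np.zeros(n_cells, dtype=bool)
    tissue_mask[tissue_idx] = True
    positive_mask = np.zeros(n_cells, dtype=bool)
    positive_mask[positive_idx] = True

    pixels = np.empty((spec.height_px, spec.width_px, 3), dtype=np.uint8)
    # right/bottom remainders (outside the grid) are painted as background
    pixels[:] = np.uint8(np.clip(spec.background_brightness * 255.0, 0, 255))
    for cell in range(n_cells):
        r, c = divmod(cell, cols)
        if positive_mask[cell]:
            kind = "positive"
        elif tissue_mask[cell]:
            kind = "tissue"
        else:
            kind = "background"
        painted = _paint_cell(t, kind, spec.background_brightness, rng)
        pixels[r * t : (r + 1) * t, c * t : (c + 1) * t] = painted.astype(np.uint8)

    image = SlideImage(slide_id=slide_id, pixels=pixels, label=spec.slide_label)
    truth = SlideGroundTruth(
        tile_px=t,
        tissue_mask=tissue_mask.reshape(rows, cols),
        positive_mask=positive_mask.reshape(rows, cols),
    )
    return image, truth


def generate_slide_dataset(
    n_slides: int,
    positive_slide_fraction: float = 0.5,
    positive_tile_fraction: float = 0.6,
    seed: int = 0,
    **spec_kwargs,
) -> List[Tuple[SlideImage, SlideGroundTruth]]:
    """A cohort of synthetic slides with exactly-balanced labels.

    Positive slides carry ``positive_tile_fraction`` of cue tiles; negative
    slides carry none. Per-slide seeds are derived deterministically from
    ``seed``. Extra keyword arguments are forwarded to SyntheticSlideSpec.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    rng = np.random.default_rng(seed)
    n_pos = int(round(positive_slide_fraction * n_slides))
    labels = np.zeros(n_slides, dtype=int)
    labels[rng.permutation(n_slides)[:n_pos]] = 1
    slides = []
    for j, label in enumerate(labels):
        spec = SyntheticSlideSpec(
            positive_tile_fraction=positive_tile_fraction if label == 1 else 0.0,
            slide_label=int(label),
            seed=int(rng.integers(0, 2**31 - 1)),
            **spec_kwargs,
        )
        slides.append(generate_synthetic_slide(spec, slide_id=f"slide_{j:03d}"))
    return slides


# ---------------------------------------------------------------------------
# Probability bags


@dataclass(frozen=True)
class ProbabilityBagSpec:
    """Recipe for bags of per-tile probabilities with planted slide labels.

    Positive slides mix draws from a high-mean and a low-mean Beta component
    (the positive-tile rate controls the mixture); negative slides draw only
    from the low component. ``tiles_per_slide`` may be an int or an inclusive
    (low, high) range.
    """

    n_slides: int = 200
    tiles_per_slide: Union[int, Tuple[int, int]] = 50
    positive_slide_fraction: float = 0.5
    high_component_mean: float = 0.8
    low_component_mean: float = 0.2
    positive_tile_rate_in_positive_slides: float = 0.6
    component_concentration: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_slides < 1:
            raise ValueError("n_slides must be >= 1")
        tps = self.tiles_per_slide
        lo = tps if isinstance(tps, int) else tps[0]
        if lo < 1:
            raise ValueError("tiles_per_slide must be >= 1")
        if not 0.5 < self.high_component_mean < 1.0:
            raise ValueError("high_component_mean must lie in (0.5, 1)")
        if not 0.0 < self.low_component_mean < 0.5:
            raise ValueError("low_component_mean must lie in (0, 0.5)")
        if not 0.0 <= self.positive_tile_rate_in_positive_slides <= 1.0:
            raise ValueError("positive_tile_rate_in_positive_slides must lie in [0, 1]")
        if not 0.0 <= self.positive_slide_fraction <= 1.0:
            raise ValueError("positive_slide_fraction must lie in [0, 1]")


class BagSample(NamedTuple):
    slide_id: str
    probabilities: np.ndarray
    label: int


def _beta_params(mean: float, concentration: float) -> Tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def generate_probability_bags(spec: ProbabilityBagSpec) -> List[BagSample]:
    """Draw one probability bag per slide, reproducibly from the seed.

    Exactly ``round(n_slides * positive_slide_fraction)`` slides are labelled
    positive; within a positive slide, exactly ``round(rate * T)`` tiles draw
    from the high-mean component (positions shuffled).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_pos_slides = int(round(spec.n_slides * spec.positive_slide_fraction))
    labels = np.zeros(spec.n_slides, dtype=int)
    labels[rng.permutation(spec.n_slides)[:n_pos_slides]] = 1
    a_hi, b_hi = _beta_params(spec.high_component_mean, spec.component_concentration)
    a_lo, b_lo = _beta_params(spec.low_component_mean, spec.component_concentration)
    bags: List[BagSample] = []
    for j, label in enumerate(labels):
        if isinstance(spec.tiles_per_slide, int):
            t_count = spec.tiles_per_slide
        else:
            lo, hi = spec.tiles_per_slide
            t_count = int(rng.integers(lo, hi + 1))
        if label == 1:
            n_hi = int(round(spec.positive_tile_rate_in_positive_slides * t_count))
        else:
            n_hi = 0
        p = np.empty(t_count)
        p[:n_hi] = rng.beta(a_hi, b_hi, size=n_hi)
        p[n_hi:] = rng.beta(a_lo, b_lo, size=t_count - n_hi)
        rng.shuffle(p)
        bags.append(BagSample(f"bag_{j:03d}", np.clip(p, 0.0, 1.0), int(label)))
    return bags


def bags_to_frame(bags: List[BagSample]) -> pd.DataFrame:
    """Long-format CSV table: slide_id, tile_index, probability, slide_label."""
    records = [
        {
            "slide_id": bag.slide_id,
            "tile_index": i,
            "probability": p,
            "slide_label": bag.label,
        }
        for bag in bags
        for i, p in enumerate(bag.probabilities)
    ]
    return pd.DataFrame(records)


def expected_tissue_gray(color: Tuple[int, int, int] = NEGATIVE_TISSUE_COLOR) -> float:
    """Mean gray of an unblobbed tissue cell — handy for threshold sanity checks."""
    return float(np.dot(color, LUMA_WEIGHTS) / 255.0)
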