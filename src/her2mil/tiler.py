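"""Stage 1: decompose a slide raster into fixed-size tiles and drop background.

A slide is cut on a regular grid into square tiles (512x512 px by default;
"no stride" means the stride equals the tile size, i.e. non-overlapping
tiles). Partial tiles at the right/bottom borders are discarded, so the tile
count is ``floor((W - size)/stride + 1) * floor((H - size)/stride + 1)``
whenever both dimensions reach the tile size, else zero.

Background removal: a tile whose mean grayscale brightness (Rec. 601 luma,
scaled to [0, 1], 1 = white) is strictly greater than the threshold (0.8 by
default) is dropped — bright, near-white regions are glass, not tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image
import tifffile

#: Rec. 601 luma weights for RGB -> grayscale conversion.
LUMA_WEIGHTS: Tuple[float, float, float] = (0.299, 0.587, 0.114)

DEFAULT_TILE_SIZE = 512
DEFAULT_GRAY_THRESHOLD = 0.8


@dataclass(eq=False)
class SlideImage:
    """A rasterized slide: an 8-bit RGB array plus identifier and label.

    ``microns_per_pixel`` records the resolution the caller rendered the
    slide at (e.g. 0.5 for a 20x scan); it is metadata only — this module
    never resamples.
    """

    slide_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    label: Optional[int] = None
    microns_per_pixel: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3) RGB; got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8; got {px.dtype}")
        self.pixels = px

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]


@dataclass(eq=False)
class Tile:
    """A square crop of a slide with its grid origin and brightness statistic."""

    slide_id: str
    origin_x: int
    origin_y: int
    size_px: int
    pixels: np.ndarray  # (size, size, 3) uint8
    mean_gray: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mean_gray is None:
            self.mean_gray = mean_grayscale(self.pixels)


def mean_grayscale(
    pixels: np.ndarray, weights: Sequence[float] = LUMA_WEIGHTS
) -> float:
    """Mean luminance of an RGB array, scaled to [0, 1] (0 black, 1 white)."""
    px = np.asarray(pixels, dtype=float)
    if px.size == 0:
        raise ValueError("cannot compute mean grayscale of an empty tile")
    gray = px @ np.asarray(weights, dtype=float)
    return float(gray.mean() / 255.0)


def grid_origins(extent: int, tile_size: int, stride: int) -> List[int]:
    """Valid 0-based origins along one axis: 0, stride, ... with o + size <= extent."""
    if extent < tile_size:
        return []
    return list(range(0, extent - tile_size + 1, stride))


def extract_tiles(
    image: SlideImage,
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: Optional[int] = None,
) -> List[Tile]:
    """Cut the slide into tiles on a regular grid, row-major order.

    ``stride=None`` means non-overlapping tiles (stride = tile_size).
    Border regions too small for a full tile are discarded. An image smaller
    than one tile yields an empty list, not an error.
    """
    if tile_size < 1:
        raise ValueError(f"tile_size must be >= 1; got {tile_size}")
    if stride is None:
        stride = tile_size
    if stride < 1:
        raise ValueError(f"stride must be >= 1; got {stride}")
    tiles: List[Tile] = []
    for y in grid_origins(image.height_px, tile_size, stride):
        for x in grid_origins(image.width_px, tile_size, stride):
            crop = image.pixels[y : y + tile_size, x : x + tile_size]
            tiles.append(
                Tile(
                    slide_id=image.slide_id,
                    origin_x=x,
                    origin_y=y,
                    size_px=tile_size,
                    pixels=crop,
                )
            )
    return tiles


def filter_background(
    tiles: Sequence[Tile], threshold: float = DEFAULT_GRAY_THRESHOLD
) -> List[Tile]:
    """Keep the tiles with mean grayscale <= threshold, preserving order.

    The comparison is strict: a tile at exactly the threshold is kept,
    brighter tiles are dropped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1]; got {threshold}")
    return [t for t in tiles if t.mean_gray <= threshold]


# ---------------------------------------------------------------------------
# I/O


def read_slide_image(
    path,
    slide_id: Optional[str] = None,
    label: Optional[int] = None,
    tiff_level: int = 0,
    microns_per_pixel: Optional[float] = None,
) -> SlideImage:
    """Load a PNG or TIFF raster as a SlideImage.

    For multi-level (pyramidal) TIFFs, ``tiff_level`` selects the series
    level to read; PNGs ignore it.
    """
    path = Path(path)
    if slide_id is None:
        slide_id = path.stem
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            level = series.levels[tiff_level] if series.levels else series
            arr = level.asarray()
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return SlideImage(
        slide_id=slide_id,
        pixels=arr.astype(np.uint8),
        label=label,
        microns_per_pixel=microns_per_pixel,
    )


def write_slide_image(image: SlideImage, path) -> None:
    """Write the raster as PNG or TIFF depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        Image.fromarray(image.pixels).save(path)


def tile_manifest(
    all_tiles: Sequence[Tile], kept_tiles: Sequence[Tile]
) -> pd.DataFrame:
    """Manifest of every extracted tile with its background-filter outcome."""
    kept_keys = {(t.slide_id, t.origin_x, t.origin_y) for t in kept_tiles}
    rows = [
        {
            "slide_id": t.slide_id,
            "origin_x": t.origin_x,
            "origin_y": t.origin_y,
            "size_px": t.size_px,
            "mean_gray": t.mean_gray,
            "kept": int((t.slide_id, t.origin_x, t.origin_y) in kept_keys),
        }
        for t in all_tiles
    ]
    return pd.DataFrame(
        rows, columns=["slide_id", "origin_x", "origin_y", "size_px", "mean_gray", "kept"]
    )


def write_tile_images(tiles: Sequence[Tile], out_dir) -> List[Path]:
    """Materialize tiles as PNGs named ``<slide_id>__<x>_<y>.png``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in tiles:
        p = out_dir / f"{t.slide_id}__{t.origin_x}_{t.origin_y}.png"
        Image.fromarray(t.pixels).save(p)
        paths.append(p)
    return paths
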