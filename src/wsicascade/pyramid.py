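"""Tile-based pyramid decomposition of a slide.

A slide is formatted into ``N`` levels of non-overlapping square tiles.
Level ``N`` (the finest) holds the full-resolution raster; each coarser
level is the next level downsampled by ``2**zoom_step`` per axis with
area (block-average) interpolation.  Level 1 is the coarsest.  Tiles are
indexed ``(level, row, col)`` with 0-based row-major ``(row, col)``; border
tiles are zero-padded to the full tile size and carry a ``valid_region``
recording their true extent, which downstream consumers (attention maxima,
metrics) use to ignore padding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PyramidConfig",
    "TileIndex",
    "Tile",
    "TilePyramid",
    "grid_shape",
    "level_dimensions",
    "child_indices",
    "parent_index",
    "downsample",
]


@dataclass(frozen=True)
class PyramidConfig:
    """Tile size, number of levels and inter-level zoom.

    Consecutive levels differ by ``2**zoom_step`` in linear scale
    (``zoom_step=2`` → 4x linear, 16x area per level).
    """

    tile_size: int = 512
    num_levels: int = 3
    zoom_step: int = 2

    def __post_init__(self) -> None:
        if self.tile_size < 1:
            raise ValueError("tile_size must be >= 1")
        if self.num_levels < 1:
            raise ValueError("num_levels must be >= 1")
        if self.zoom_step < 1:
            raise ValueError("zoom_step must be >= 1")

    @property
    def scale(self) -> int:
        """Linear scale factor between consecutive levels, 2**zoom_step."""
        return 2**self.zoom_step


@dataclass(frozen=True, order=True)
class TileIndex:
    """1-based level (1 = coarsest, N = full resolution), 0-based row/col."""

    level: int
    row: int
    col: int


@dataclass(frozen=True)
class Tile:
    index: TileIndex
    pixels: np.ndarray  # (tile_size, tile_size[, 3]), zero-padded at borders
    valid_region: tuple[int, int]  # (height, width) of non-padded content


def grid_shape(height: int, width: int, tile_size: int) -> tuple[int, int]:
    """(n_rows, n_cols) of the tile grid covering a level raster."""
    return math.ceil(height / tile_size), math.ceil(width / tile_size)


def level_dimensions(
    slide_hw: tuple[int, int], config: PyramidConfig
) -> dict[int, tuple[int, int]]:
    """Pixel dimensions of every level, keyed by level (1..N).

    ``dims(N)`` are the slide dims; ``dims(l-1) = ceil(dims(l)/2**z)``.
    """
    h, w = slide_hw
    if h < 1 or w < 1:
        raise ValueError("slide dimensions must be >= 1x1")
    dims = {config.num_levels: (h, w)}
    s = config.scale
    for level in range(config.num_levels - 1, 0, -1):
        h, w = math.ceil(h / s), math.ceil(w / s)
        if h < 1 or w < 1:
            raise ValueError(
                f"level {level} would be empty; reduce num_levels or zoom_step"
            )
        dims[level] = (h, w)
    return dims


def downsample(raster: np.ndarray, factor: int) -> np.ndarray:
    """Area-average downsampling by an integer factor, rounded to uint8.

    Ragged edges average only over the pixels that exist (no padding bias).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return raster.copy()
    h, w = raster.shape[:2]
    oh, ow = math.ceil(h / factor), math.ceil(w / factor)
    padded = raster
    if (oh * factor, ow * factor) != (h, w):
        padded = np.zeros((oh * factor, ow * factor) + raster.shape[2:], raster.dtype)
        padded[:h, :w] = raster
    tail = padded.shape[2:]
    blocks = padded.reshape((oh, factor, ow, factor) + tail)
    acc = blocks.sum(axis=(1, 3), dtype=np.uint32)
    ri = np.arange(oh) * factor
    ci = np.arange(ow) * factor
    bh = np.minimum(ri + factor, h) - ri
    bw = np.minimum(ci + factor, w) - ci
    counts = np.multiply.outer(bh, bw).astype(np.float32)
    if raster.ndim == 3:
        counts = counts[..., None]
    out = acc / counts
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def child_indices(
    index: TileIndex, config: PyramidConfig, child_grid: tuple[int, int]
) -> list[TileIndex]:
    """Indices at level ``l+1`` whose floor-mapping parent is ``index``.

    A parent cell covers the 2**z x 2**z block of child tiles
    ``{(i', j') : floor(i' / 2**z) = i, floor(j' / 2**z) = j}``, clipped to
    the child grid (at most ``2**(2z)`` children; fewer on ragged edges).
    """
    if index.level >= config.num_levels:
        raise ValueError(
            f"level {index.level} is the finest level; it has no children"
        )
    s = config.scale
    n_rows, n_cols = child_grid
    rows = range(index.row * s, min((index.row + 1) * s, n_rows))
    cols = range(index.col * s, min((index.col + 1) * s, n_cols))
    return [TileIndex(index.level + 1, i, j) for i in rows for j in cols]


def parent_index(index: TileIndex, config: PyramidConfig) -> TileIndex:
    """The level-(l-1) cell covering a level-l tile: floor(i * 2**-z)."""
    if index.level <= 1:
        raise ValueError("level 1 is the coarsest level; it has no parent")
    s = config.scale
    return TileIndex(index.level - 1, index.row // s, index.col // s)


class TilePyramid:
    """Multi-level tile decomposition of one slide.

    Holds the per-level uint8 rasters and serves padded tiles on demand.
    Built with :meth:`from_image`, or read back from a tile store written
    by :meth:`save` (``level_{l}/tile_{i}_{j}.png`` + a JSON descriptor).
    """

    def __init__(self, levels: dict[int, np.ndarray], config: PyramidConfig):
        self.config = config
        self.levels = levels
        self.level_dims = {l: r.shape[:2] for l, r in levels.items()}
        expected = level_dimensions(levels[config.num_levels].shape[:2], config)
        if self.level_dims != expected:
            raise ValueError(
                f"level dimensions {self.level_dims} do not match the "
                f"config-implied dimensions {expected}"
            )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_image(
        cls, slide_image: np.ndarray, config: PyramidConfig | None = None
    ) -> "TilePyramid":
        if config is None:
            config = PyramidConfig()
        img = np.asarray(slide_image)
        if img.size == 0 or img.ndim not in (2, 3):
            raise ValueError("slide image must be a non-empty 2-D or 3-D array")
        if img.dtype != np.uint8:
            img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        level_dimensions(img.shape[:2], config)  # validates feasibility
        levels = {config.num_levels: img}
        for level in range(config.num_levels - 1, 0, -1):
            levels[level] = downsample(levels[level + 1], config.scale)
        return cls(levels, config)

    # -- geometry ---------------------------------------------------------

    def tile_grid(self, level: int) -> tuple[int, int]:
        h, w = self.level_dims[level]
        return grid_shape(h, w, self.config.tile_size)

    def n_tiles(self, level: int) -> int:
        r, c = self.tile_grid(level)
        return r * c

    def total_tiles(self) -> int:
        return sum(self.n_tiles(l) for l in self.levels)

    def indices(self, level: int) -> list[TileIndex]:
        r, c = self.tile_grid(level)
        return [TileIndex(level, i, j) for i in range(r) for j in range(c)]

    # -- tile access ------------------------------------------------------

    def get_tile(self, index: TileIndex) -> Tile:
        if index.level not in self.levels:
            raise KeyError(f"level {index.level} not in pyramid (1..{self.config.num_levels})")
        n_rows, n_cols = self.tile_grid(index.level)
        if not (0 <= index.row < n_rows and 0 <= index.col < n_cols):
            raise IndexError(
                f"tile ({index.row}, {index.col}) outside the level-{index.level} "
                f"grid of {n_rows} rows x {n_cols} cols"
            )
        t = self.config.tile_size
        raster = self.levels[index.level]
        r0, c0 = index.row * t, index.col * t
        h, w = self.level_dims[index.level]
        vh, vw = min(t, h - r0), min(t, w - c0)
        shape = (t, t) + raster.shape[2:]
        pixels = np.zeros(shape, dtype=raster.dtype)
        pixels[:vh, :vw] = raster[r0 : r0 + vh, c0 : c0 + vw]
        return Tile(index=index, pixels=pixels, valid_region=(vh, vw))

    def tiles(self, level: int) -> list[Tile]:
        return [self.get_tile(ix) for ix in self.indices(level)]

    def reassemble(self, level: int) -> np.ndarray:
        """Stitch the level's tiles (cropped to valid_region) back together."""
        h, w = self.level_dims[level]
        raster = self.levels[level]
        out = np.zeros((h, w) + raster.shape[2:], dtype=raster.dtype)
        t = self.config.tile_size
        for tile in self.tiles(level):
            vh, vw = tile.valid_region
            r0, c0 = tile.index.row * t, tile.index.col * t
            out[r0 : r0 + vh, c0 : c0 + vw] = tile.pixels[:vh, :vw]
        return out

    # -- persistence ------------------------------------------------------

    def save(self, out_dir: str | Path) -> Path:
        """Write the directory tile store: per-level padded tile PNGs + JSON."""
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for level in sorted(self.levels):
            d = out / f"level_{level}"
            d.mkdir(exist_ok=True)
            for tile in self.tiles(level):
                iio.imwrite(
                    d / f"tile_{tile.index.row}_{tile.index.col}.png", tile.pixels
                )
        desc = {
            "tile_size": self.config.tile_size,
            "num_levels": self.config.num_levels,
            "zoom_step": self.config.zoom_step,
            "level_dims": {str(l): list(d) for l, d in self.level_dims.items()},
        }
        with open(out / "pyramid.json", "w") as fh:
            json.dump(desc, fh, indent=2)
        return out

    @classmethod
    def load(cls, store_dir: str | Path) -> "TilePyramid":
        import imageio.v3 as iio

        store = Path(store_dir)
        with open(store / "pyramid.json") as fh:
            desc = json.load(fh)
        config = PyramidConfig(
            tile_size=desc["tile_size"],
            num_levels=desc["num_levels"],
            zoom_step=desc["zoom_step"],
        )
        levels: dict[int, np.ndarray] = {}
        for l_str, (h, w) in desc["level_dims"].items():
            level = int(l_str)
            n_rows, n_cols = grid_shape(h, w, config.tile_size)
            t = config.tile_size
            probe = np.asarray(iio.imread(store / f"level_{level}" / "tile_0_0.png"))
            raster = np.zeros((h, w) + probe.shape[2:], dtype=np.uint8)
            for i in range(n_rows):
                for j in range(n_cols):
                    px = np.asarray(
                        iio.imread(store / f"level_{level}" / f"tile_{i}_{j}.png")
                    )
                    vh = min(t, h - i * t)
                    vw = min(t, w - j * t)
                    raster[i * t : i * t + vh, j * t : j * t + vw] = px[:vh, :vw]
            levels[level] = raster
        return cls(levels, config)
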