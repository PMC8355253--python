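"""Coarse-to-fine cascade: attention maps, tile selection, mask assembly.

Inference starts by scoring *every* tile at level 1 (the coarsest).  A
binary attention map marks each attention cell whose maximum lesion
probability reaches ``alpha``; only tiles at the next level that fall under
an active cell are scored, and so on down to level N, whose selected
probability maps are thresholded at ``alpha`` and stitched into the final
slide-resolution mask (everything outside selected tiles is background).

Attention granularity:

- ``per_tile`` — one attention bit per tile; an active bit selects all
  ``2**(2z)`` child tiles under that tile's footprint.
- ``per_unit`` — each tile's attention cell is subdivided into
  ``2**z x 2**z`` units (16 for z = 2); a unit's footprint is exactly one
  next-level tile, so selection is unit-for-tile.  Strictly no coarser
  than per-tile selection, usually sharper.

Both modes produce identical final masks for the same models; ``per_unit``
may process fewer fine tiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .pyramid import PyramidConfig, Tile, TileIndex, TilePyramid, grid_shape

__all__ = [
    "CascadeConfig",
    "ProbabilityMap",
    "AttentionMap",
    "SelectionResult",
    "SegmentationMask",
    "infer_level",
    "compute_attention",
    "select_tiles",
    "assemble_mask",
    "run_cascade",
    "CascadeSegmenter",
]


@dataclass(frozen=True)
class CascadeConfig:
    """Probability threshold and attention granularity.

    ``alpha`` applies identically at every level unless overridden per
    level via ``alpha_per_level`` (1-based level -> threshold).
    """

    alpha: float = 0.5
    granularity: str = "per_unit"  # or "per_tile"
    zoom_step: int = 2
    alpha_per_level: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.granularity not in ("per_tile", "per_unit"):
            raise ValueError("granularity must be 'per_tile' or 'per_unit'")
        if self.zoom_step < 1:
            raise ValueError("zoom_step must be >= 1")
        if self.alpha_per_level:
            for a in self.alpha_per_level.values():
                if not 0.0 <= a <= 1.0:
                    raise ValueError("per-level alpha must be in [0, 1]")

    @property
    def units_per_tile_axis(self) -> int:
        return 2**self.zoom_step

    def level_alpha(self, level: int) -> float:
        if self.alpha_per_level and level in self.alpha_per_level:
            return self.alpha_per_level[level]
        return self.alpha


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel lesion probabilities for one tile (values in [0, 1])."""

    values: np.ndarray  # (tile_size, tile_size)
    index: TileIndex
    valid_region: tuple[int, int]

    def __post_init__(self) -> None:
        v = self.values
        vh, vw = self.valid_region
        if np.any(v[:vh, :vw] < 0) or np.any(v[:vh, :vw] > 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class AttentionMap:
    """Binary attention grid for one level.

    ``per_tile``: shape = tile grid.  ``per_unit``: shape = tile grid x
    units per axis; entry (i, j) refers to the unit whose footprint is the
    next level's tile (i, j).
    """

    level: int
    grid: np.ndarray  # bool
    granularity: str


@dataclass
class SelectionResult:
    """Which tiles were scored at each level, and how many existed."""

    selected: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    processed: dict[int, int] = field(default_factory=dict)
    total: dict[int, int] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "processed": self.processed,
            "total": self.total,
            "selected": {
                str(l): [list(ij) for ij in idx] for l, idx in self.selected.items()
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class SegmentationMask:
    """Slide-level binary mask plus the tiles that contributed to it."""

    mask: np.ndarray  # (H, W) uint8 at level-N resolution
    provenance: tuple[TileIndex, ...]


def infer_level(tiles: list[Tile], model) -> dict[TileIndex, ProbabilityMap]:
    """Run one level's model over a set of tiles of that level.

    Padded border regions are zeroed in the returned maps so they can never
    fire attention or contribute mask pixels.
    """
    if not tiles:
        return {}
    levels = {t.index.level for t in tiles}
    if len(levels) > 1:
        raise ValueError(f"tiles span multiple levels {sorted(levels)}")
    model_level = getattr(model, "level", None)
    if model_level is not None and model_level not in levels:
        raise ValueError(
            f"model serves level {model_level}, tiles are level {levels.pop()}"
        )
    out: dict[TileIndex, ProbabilityMap] = {}
    for tile in tiles:
        probs = np.asarray(model.predict_proba(tile.pixels), dtype=np.float64)
        if probs.shape != tile.pixels.shape[:2]:
            raise ValueError(
                f"model output {probs.shape} does not match tile {tile.pixels.shape[:2]}"
            )
        vh, vw = tile.valid_region
        masked = np.zeros_like(probs)
        masked[:vh, :vw] = probs[:vh, :vw]
        out[tile.index] = ProbabilityMap(
            values=masked, index=tile.index, valid_region=tile.valid_region
        )
    return out


def compute_attention(
    prob_maps: dict[TileIndex, ProbabilityMap],
    level_grid: tuple[int, int],
    config: CascadeConfig,
    level: int | None = None,
) -> AttentionMap:
    """Threshold per-cell maxima at alpha (inclusive: max >= alpha fires).

    Tiles without a probability map (never selected upstream) contribute
    all-zero attention.  Only valid (non-padded) pixels enter the maxima.
    """
    if level is None:
        if prob_maps:
            level = next(iter(prob_maps)).level
        else:
            raise ValueError("level must be given when prob_maps is empty")
    levels = {ix.level for ix in prob_maps}
    if levels and levels != {level}:
        raise ValueError(f"probability maps span levels {sorted(levels)}")
    alpha = config.level_alpha(level)
    n_rows, n_cols = level_grid
    u = config.units_per_tile_axis

    if config.granularity == "per_tile":
        grid = np.zeros((n_rows, n_cols), dtype=bool)
        for ix, pm in prob_maps.items():
            vh, vw = pm.valid_region
            if vh and vw:
                grid[ix.row, ix.col] = pm.values[:vh, :vw].max() >= alpha
        return AttentionMap(level=level, grid=grid, granularity="per_tile")

    grid = np.zeros((n_rows * u, n_cols * u), dtype=bool)
    for ix, pm in prob_maps.items():
        vh, vw = pm.valid_region
        t = pm.values.shape[0]
        step = t // u
        for a in range(u):
            for b in range(u):
                r0, c0 = a * step, b * step
                sub = pm.values[r0 : min(r0 + step, vh), c0 : min(c0 + step, vw)]
                if sub.size and sub.max() >= alpha:
                    grid[ix.row * u + a, ix.col * u + b] = True
    return AttentionMap(level=level, grid=grid, granularity="per_unit")


def select_tiles(
    attention: AttentionMap,
    next_grid: tuple[int, int],
    config: CascadeConfig,
) -> list[tuple[int, int]]:
    """Tiles of level l = attention.level + 1 under active attention cells.

    per_tile: tile (i, j) is selected iff the parent cell
    (floor(i * 2**-z), floor(j * 2**-z)) is active.  per_unit: the unit
    index space at level l-1 coincides with the tile index space at level
    l, so tile (i, j) is selected iff unit (i, j) is active.
    """
    n_rows, n_cols = next_grid
    s = config.units_per_tile_axis
    att = attention.grid
    if attention.granularity == "per_tile":
        need = (-(-n_rows // s), -(-n_cols // s))
        if att.shape[0] < need[0] or att.shape[1] < need[1]:
            raise ValueError(
                f"attention grid {att.shape} cannot cover a {next_grid} tile grid"
            )
        sel = att[
            np.arange(n_rows)[:, None] // s, np.arange(n_cols)[None, :] // s
        ]
    else:
        if att.shape[0] < n_rows or att.shape[1] < n_cols:
            raise ValueError(
                f"attention unit grid {att.shape} cannot cover a {next_grid} tile grid"
            )
        sel = att[:n_rows, :n_cols]
    rows, cols = np.nonzero(sel)
    return [(int(i), int(j)) for i, j in zip(rows, cols)]


def assemble_mask(
    prob_maps: dict[TileIndex, ProbabilityMap],
    config: CascadeConfig,
    slide_hw: tuple[int, int],
    tile_size: int,
    num_levels: int,
) -> SegmentationMask:
    """Threshold selected level-N maps at alpha and stitch the slide mask.

    Pixels outside selected tiles (and padded tile regions) are 0.
    """
    h, w = slide_hw
    mask = np.zeros((h, w), dtype=np.uint8)
    alpha = config.level_alpha(num_levels)
    claimed: set[tuple[int, int]] = set()
    for ix, pm in prob_maps.items():
        if ix.level != num_levels:
            raise ValueError(f"map at level {ix.level}; expected level {num_levels}")
        key = (ix.row, ix.col)
        if key in claimed:
            raise ValueError(f"tile {key} claimed twice")
        claimed.add(key)
        vh, vw = pm.valid_region
        r0, c0 = ix.row * tile_size, ix.col * tile_size
        mask[r0 : r0 + vh, c0 : c0 + vw] = (
            pm.values[:vh, :vw] >= alpha
        ).astype(np.uint8)
    return SegmentationMask(mask=mask, provenance=tuple(sorted(prob_maps)))


def run_cascade(
    pyramid: TilePyramid,
    models: list,
    config: CascadeConfig | None = None,
) -> tuple[SegmentationMask, SelectionResult]:
    """Full cascade inference on one pyramid.

    Level 1 is scored exhaustively; each subsequent level scores only tiles
    under active attention; the final mask comes from the selected level-N
    maps thresholded at alpha.
    """
    if config is None:
        config = CascadeConfig(zoom_step=pyramid.config.zoom_step)
    N = pyramid.config.num_levels
    if len(models) != N:
        raise ValueError(f"need one model per level: {N} levels, {len(models)} models")
    if config.zoom_step != pyramid.config.zoom_step:
        raise ValueError("cascade zoom_step must match the pyramid's")

    result = SelectionResult()
    tiles = pyramid.tiles(1)
    result.selected[1] = [(t.index.row, t.index.col) for t in tiles]
    prob_maps = infer_level(tiles, models[0])
    result.processed[1] = len(tiles)
    result.total[1] = pyramid.n_tiles(1)

    for level in range(2, N + 1):
        attention = compute_attention(
            prob_maps, pyramid.tile_grid(level - 1), config, level=level - 1
        )
        chosen = select_tiles(attention, pyramid.tile_grid(level), config)
        result.selected[level] = chosen
        result.total[level] = pyramid.n_tiles(level)
        result.processed[level] = len(chosen)
        tiles = [pyramid.get_tile(TileIndex(level, i, j)) for i, j in chosen]
        prob_maps = infer_level(tiles, models[level - 1])

    seg = assemble_mask(
        prob_maps, config, pyramid.level_dims[N], pyramid.config.tile_size, N
    )
    return seg, result


def render_overlay(
    slide_image: np.ndarray,
    mask: np.ndarray,
    color: tuple[int, int, int] = (255, 255, 0),
    opacity: float = 0.5,
) -> np.ndarray:
    """Tint mask-positive pixels over the slide (yellow by default)."""
    img = np.asarray(slide_image, dtype=np.float32).copy()
    m = np.asarray(mask) > 0
    if m.shape != img.shape[:2]:
        raise ValueError("mask and slide dimensions differ")
    tint = np.asarray(color, dtype=np.float32)
    img[m] = (1.0 - opacity) * img[m] + opacity * tint
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def dense_inference(
    pyramid: TilePyramid, model, alpha: float = 0.5
) -> np.ndarray:
    """Exhaustive level-N inference (no cascade): the reference mask."""
    N = pyramid.config.num_levels
    maps = infer_level(pyramid.tiles(N), model)
    cfg = CascadeConfig(alpha=alpha, zoom_step=pyramid.config.zoom_step)
    return assemble_mask(
        maps, cfg, pyramid.level_dims[N], pyramid.config.tile_size, N
    ).mask


class CascadeSegmenter(BaseEstimator):
    """Estimator facade: slide in, lesion mask out.

    Parameters
    ----------
    models
        One fitted segmenter per level (coarse first).  If omitted at
        ``fit`` time, clones of ``base_model`` are trained per level on
        level-appropriate downsampled tiles.
    tile_size, num_levels, zoom_step
        Pyramid geometry.
    alpha, granularity
        Cascade thresholding and attention granularity.
    """

    def __init__(
        self,
        models: list | None = None,
        base_model=None,
        tile_size: int = 512,
        num_levels: int = 3,
        zoom_step: int = 2,
        alpha: float = 0.5,
        granularity: str = "per_unit",
    ):
        self.models = models
        self.base_model = base_model
        self.tile_size = tile_size
        self.num_levels = num_levels
        self.zoom_step = zoom_step
        self.alpha = alpha
        self.granularity = granularity

    def _configs(self) -> tuple[PyramidConfig, CascadeConfig]:
        return (
            PyramidConfig(self.tile_size, self.num_levels, self.zoom_step),
            CascadeConfig(
                alpha=self.alpha,
                granularity=self.granularity,
                zoom_step=self.zoom_step,
            ),
        )

    def fit(self, slides: list[np.ndarray], masks: list[np.ndarray]) -> "CascadeSegmenter":
        """Train per-level models on downsampled slide/mask pairs.

        A level-l training example is the level-l raster of a slide pyramid
        with the mask downsampled the same way (pixel positive where the
        lesion fraction of its footprint reaches one half).
        """
        from sklearn.base import clone

        pcfg, _ = self._configs()
        if self.models is not None:
            self.models_ = list(self.models)
            return self
        if self.base_model is None:
            raise ValueError("provide either fitted `models` or a `base_model`")
        from .pyramid import downsample

        self.models_ = []
        for level in range(1, self.num_levels + 1):
            factor = pcfg.scale ** (self.num_levels - level)
            X, y = [], []
            for img, msk in zip(slides, masks):
                im_l = downsample(np.asarray(img, dtype=np.uint8), factor)
                mk_l = downsample(
                    np.asarray(msk, dtype=np.uint8) * 255, factor
                ) >= 128
                pyr = TilePyramid.from_image(
                    im_l, PyramidConfig(self.tile_size, 1, self.zoom_step)
                )
                for tile in pyr.tiles(1):
                    vh, vw = tile.valid_region
                    m = np.zeros(tile.pixels.shape[:2], dtype=np.uint8)
                    r0 = tile.index.row * self.tile_size
                    c0 = tile.index.col * self.tile_size
                    m[:vh, :vw] = mk_l[r0 : r0 + vh, c0 : c0 + vw]
                    X.append(tile.pixels)
                    y.append(m)
            model = clone(self.base_model)
            if hasattr(model, "level"):
                model.set_params(level=level)
            model.fit(np.stack(X), np.stack(y))
            self.models_.append(model)
        return self

    def predict(self, slide_image: np.ndarray) -> np.ndarray:
        seg, _ = self.predict_with_selection(slide_image)
        return seg.mask

    def predict_with_selection(
        self, slide_image: np.ndarray
    ) -> tuple[SegmentationMask, SelectionResult]:
        if not hasattr(self, "models_"):
            if self.models is None:
                raise ValueError("estimator is not fitted and has no models")
            self.models_ = list(self.models)
        pcfg, ccfg = self._configs()
        pyramid = TilePyramid.from_image(slide_image, pcfg)
        return run_cascade(pyramid, self.models_, ccfg)
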