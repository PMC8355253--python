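"""Attention, tile selection, mask assembly and cascade/dense equivalence."""

import numpy as np
import pytest

from wsicascade import (
    CascadeConfig,
    CascadeSegmenter,
    PyramidConfig,
    SlideSpec,
    TileIndex,
    TilePyramid,
    assemble_mask,
    compute_attention,
    generate_slide,
    infer_level,
    run_cascade,
    select_tiles,
)
from wsicascade.cascade import ProbabilityMap, dense_inference
from wsicascade.models import ThresholdSegmenter, make_threshold_oracle, oracle_cutoffs


def random_maps(level, grid, tile=64, seed=0, valid=None):
    rng = np.random.default_rng(seed)
    maps = {}
    for i in range(grid[0]):
        for j in range(grid[1]):
            ix = TileIndex(level, i, j)
            vals = rng.random((tile, tile))
            vr = valid or (tile, tile)
            masked = np.zeros_like(vals)
            masked[: vr[0], : vr[1]] = vals[: vr[0], : vr[1]]
            maps[ix] = ProbabilityMap(values=masked, index=ix, valid_region=vr)
    return maps


class ConstantModel:
    """predict_proba == constant everywhere (stub segmenter)."""

    def __init__(self, value, level=None):
        self.value = value
        self.level = level

    def predict_proba(self, X):
        return np.full(np.asarray(X).shape[:2], self.value, dtype=float)


# -- infer_level -----------------------------------------------------------

def test_infer_level_empty_and_mixed(small_pyramid):
    assert infer_level([], ConstantModel(0.0)) == {}
    tiles = [small_pyramid.get_tile(TileIndex(3, 0, 0)),
             small_pyramid.get_tile(TileIndex(2, 0, 0))]
    with pytest.raises(ValueError, match="levels"):
        infer_level(tiles, ConstantModel(0.0))


def test_infer_level_masks_padding():
    img = np.full((96, 96, 3), 255, dtype=np.uint8)
    pyr = TilePyramid.from_image(img, PyramidConfig(64, 1, 2))
    maps = infer_level(pyr.tiles(1), ConstantModel(1.0))
    border = maps[TileIndex(1, 1, 1)]
    assert border.valid_region == (32, 32)
    assert border.values[:32, :32].min() == 1.0
    assert border.values[32:, :].max() == 0.0  # padded rows contribute nothing


# -- attention -------------------------------------------------------------

@pytest.mark.parametrize("granularity", ["per_tile", "per_unit"])
def test_attention_matches_brute_force(granularity):
    cfg = CascadeConfig(alpha=0.5, granularity=granularity, zoom_step=2)
    grid = (3, 4)
    maps = random_maps(1, grid, tile=64, seed=3)
    att = compute_attention(maps, grid, cfg)
    u = 4
    for i in range(grid[0]):
        for j in range(grid[1]):
            vals = maps[TileIndex(1, i, j)].values
            if granularity == "per_tile":
                assert att.grid[i, j] == (vals.max() >= 0.5)
            else:
                for a in range(u):
                    for b in range(u):
                        sub = vals[a * 16 : (a + 1) * 16, b * 16 : (b + 1) * 16]
                        assert att.grid[i * u + a, j * u + b] == (sub.max() >= 0.5)


def test_attention_threshold_is_inclusive():
    cfg = CascadeConfig(alpha=0.5, granularity="per_unit", zoom_step=2)
    vals = np.zeros((64, 64))
    vals[40, 40] = 0.5  # exactly alpha, in sub-unit (2, 2)
    ix = TileIndex(1, 0, 0)
    maps = {ix: ProbabilityMap(values=vals, index=ix, valid_region=(64, 64))}
    att = compute_attention(maps, (1, 1), cfg)
    assert att.grid.sum() == 1
    assert att.grid[2, 2]
    per_tile = compute_attention(maps, (1, 1),
                                 CascadeConfig(alpha=0.5, granularity="per_tile"))
    assert per_tile.grid[0, 0]


def test_attention_all_zero_maps():
    cfg = CascadeConfig()
    maps = {k: ProbabilityMap(values=np.zeros((64, 64)), index=k,
                              valid_region=(64, 64))
            for k in [TileIndex(1, 0, 0), TileIndex(1, 0, 1)]}
    att = compute_attention(maps, (1, 2), cfg)
    assert not att.grid.any()


def test_attention_rejects_bad_alpha():
    with pytest.raises(ValueError, match="alpha"):
        CascadeConfig(alpha=1.5)


# -- selection -------------------------------------------------------------

def test_per_tile_selection_expands_to_children():
    from wsicascade.cascade import AttentionMap

    att = AttentionMap(level=1, grid=np.zeros((2, 2), dtype=bool),
                       granularity="per_tile")
    att.grid[0, 0] = True
    cfg = CascadeConfig(granularity="per_tile", zoom_step=2)
    sel = select_tiles(att, (8, 8), cfg)
    assert set(sel) == {(i, j) for i in range(4) for j in range(4)}
    # clipped at a ragged edge
    sel = select_tiles(att, (3, 2), cfg)
    assert set(sel) == {(i, j) for i in range(3) for j in range(2)}


def test_per_unit_selection_matches_geometry():
    from wsicascade.cascade import AttentionMap

    rng = np.random.default_rng(5)
    grid = rng.random((8, 8)) < 0.3
    att = AttentionMap(level=1, grid=grid, granularity="per_unit")
    cfg = CascadeConfig(granularity="per_unit", zoom_step=2)
    sel = select_tiles(att, (7, 6), cfg)
    # unit (i, j) of level 1 has exactly tile (i, j) of level 2 as footprint
    expected = {(i, j) for i in range(7) for j in range(6) if grid[i, j]}
    assert set(sel) == expected


def test_selection_shape_mismatch_errors():
    from wsicascade.cascade import AttentionMap

    att = AttentionMap(level=1, grid=np.zeros((1, 1), dtype=bool),
                       granularity="per_tile")
    with pytest.raises(ValueError, match="cover"):
        select_tiles(att, (9, 9), CascadeConfig(granularity="per_tile", zoom_step=2))


# -- mask assembly ---------------------------------------------------------

def test_assemble_mask_brute_force():
    cfg = CascadeConfig(alpha=0.5)
    grid = (2, 2)
    maps = random_maps(3, grid, tile=64, seed=9)
    seg = assemble_mask(maps, cfg, (128, 128), 64, 3)
    for ix, pm in maps.items():
        block = seg.mask[ix.row * 64 : (ix.row + 1) * 64,
                         ix.col * 64 : (ix.col + 1) * 64]
        assert np.array_equal(block, (pm.values >= 0.5).astype(np.uint8))


def test_assemble_mask_empty_and_footprint():
    cfg = CascadeConfig()
    seg = assemble_mask({}, cfg, (128, 128), 64, 3)
    assert seg.mask.sum() == 0
    ix = TileIndex(3, 1, 0)
    maps = {ix: ProbabilityMap(values=np.ones((64, 64)), index=ix,
                               valid_region=(64, 64))}
    seg = assemble_mask(maps, cfg, (128, 128), 64, 3)
    assert seg.mask[64:, :64].min() == 1
    assert seg.mask.sum() == 64 * 64
    assert seg.provenance == (ix,)


# -- full cascade ----------------------------------------------------------

def test_all_zero_models_process_only_level_one(small_pyramid):
    models = [ConstantModel(0.0) for _ in range(3)]
    seg, sel = run_cascade(small_pyramid, models, CascadeConfig())
    assert seg.mask.sum() == 0
    assert sel.processed[1] == small_pyramid.n_tiles(1)
    assert sel.processed[2] == 0 and sel.processed[3] == 0


def test_all_one_models_select_everything(small_pyramid):
    models = [ConstantModel(1.0) for _ in range(3)]
    seg, sel = run_cascade(small_pyramid, models, CascadeConfig())
    for level in (1, 2, 3):
        assert sel.processed[level] == small_pyramid.n_tiles(level)
    assert seg.mask.all()


def test_cascade_equals_dense_inference(small_slide):
    pyr = TilePyramid.from_image(small_slide.image, PyramidConfig(128, 3, 2))
    models = oracle_cutoffs(3, 2, small_slide.spec.lesion_marker_range[0],
                            small_slide.spec.marker_channel)
    for granularity in ("per_unit", "per_tile"):
        cfg = CascadeConfig(alpha=0.5, granularity=granularity, zoom_step=2)
        seg, sel = run_cascade(pyr, models, cfg)
        dense = dense_inference(pyr, models[-1], alpha=0.5)
        assert np.array_equal(seg.mask, dense)
        assert np.array_equal(seg.mask, small_slide.gt_mask)
        assert sel.processed[3] < pyr.n_tiles(3)


def test_per_unit_processes_no_more_than_per_tile(small_slide):
    pyr = TilePyramid.from_image(small_slide.image, PyramidConfig(128, 3, 2))
    models = oracle_cutoffs(3, 2, 220, 0)
    _, sel_unit = run_cascade(pyr, models, CascadeConfig(granularity="per_unit"))
    _, sel_tile = run_cascade(pyr, models, CascadeConfig(granularity="per_tile"))
    for level in (2, 3):
        assert sel_unit.processed[level] <= sel_tile.processed[level]


def test_alpha_monotonicity(small_slide):
    # raising alpha can only shrink attention, selection and the mask
    pyr = TilePyramid.from_image(small_slide.image, PyramidConfig(128, 3, 2))
    models = oracle_cutoffs(3, 2, 220, 0)
    prev_mask = None
    prev_proc = None
    for alpha in (0.25, 0.5, 0.75, 1.0):
        seg, sel = run_cascade(pyr, models,
                               CascadeConfig(alpha=alpha, granularity="per_unit"))
        if prev_mask is not None:
            assert np.all(seg.mask <= prev_mask)
            for level in (2, 3):
                assert sel.processed[level] <= prev_proc[level]
        prev_mask, prev_proc = seg.mask, sel.processed


def test_mask_positive_pixels_lie_in_selected_tiles(small_slide):
    pyr = TilePyramid.from_image(small_slide.image, PyramidConfig(128, 3, 2))
    models = oracle_cutoffs(3, 2, 220, 0)
    seg, sel = run_cascade(pyr, models, CascadeConfig())
    selected = set(sel.selected[3])
    rows, cols = np.nonzero(seg.mask)
    tiles_hit = {(r // 128, c // 128) for r, c in zip(rows, cols)}
    assert tiles_hit <= selected


def test_run_cascade_validates_model_count(small_pyramid):
    with pytest.raises(ValueError, match="one model per level"):
        run_cascade(small_pyramid, [ConstantModel(0.0)], CascadeConfig())


def test_selection_result_json_roundtrip(tmp_path, small_pyramid):
    import json

    models = [ConstantModel(1.0)] * 3
    _, sel = run_cascade(small_pyramid, models, CascadeConfig())
    text = sel.to_json(tmp_path / "sel.json")
    doc = json.loads((tmp_path / "sel.json").read_text())
    assert doc == json.loads(text)
    assert doc["processed"]["1"] == small_pyramid.n_tiles(1)


def test_cascade_estimator_facade(small_slide):
    models = oracle_cutoffs(3, 2, 220, 0)
    est = CascadeSegmenter(models=models, tile_size=128, num_levels=3,
                           zoom_step=2, alpha=0.5)
    mask = est.fit([], []).predict(small_slide.image)
    assert np.array_equal(mask, small_slide.gt_mask)
    params = est.get_params()
    assert params["alpha"] == 0.5 and params["tile_size"] == 128


def test_render_overlay_tints_only_mask_pixels(small_slide):
    from wsicascade.cascade import render_overlay

    overlay = render_overlay(small_slide.image, small_slide.gt_mask,
                             color=(255, 255, 0), opacity=1.0)
    outside = small_slide.gt_mask == 0
    assert np.array_equal(overlay[outside], small_slide.image[outside])
    assert np.all(overlay[small_slide.gt_mask == 1] == (255, 255, 0))
    with pytest.raises(ValueError, match="differ"):
        render_overlay(small_slide.image, small_slide.gt_mask[:10, :10])


def test_deterministic_end_to_end(small_slide):
    pyr = TilePyramid.from_image(small_slide.image, PyramidConfig(128, 3, 2))
    models = oracle_cutoffs(3, 2, 220, 0)
    a, sa = run_cascade(pyr, models, CascadeConfig())
    b, sb = run_cascade(pyr, models, CascadeConfig())
    assert np.array_equal(a.mask, b.mask)
    assert sa.selected == sb.selected
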