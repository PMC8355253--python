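"""Synthetic whole-slide images with exact ground-truth lesion masks.

Clinical WSI cohorts are rarely redistributable, so the rest of the package
is exercised on synthetic slides: a textured background with a small number
of elliptical "lesions" composited on top.  Lesions are rendered by exact
point-in-ellipse rasterization, so the ground-truth mask is the exact union
of the rendered supports and every area/containment question has a
brute-force answer.

Color model
-----------
One designated *marker channel* (default: red) carries the lesion signal:
it is exactly ``background_marker_level`` (default 0) outside lesions and
uniformly high (default 220–255) inside them.  Texture and visual noise
live in the remaining two channels.  Keeping the marker channel clean on
the background means that *any* area-average of a block touching a lesion
pixel is strictly above background in that channel — the property that
makes closed-form threshold segmenters exact at every pyramid level and the
cascade provably equivalent to exhaustive inference (see
:mod:`wsicascade.cascade`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SlideSpec",
    "SyntheticSlide",
    "Lesion",
    "generate_slide",
    "generate_dataset",
    "ellipse_mask",
    "save_slide",
    "load_slide",
]

#: Smallest slide side accepted by default — one full tile.
DEFAULT_MIN_SIDE = 512


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic slide.

    Identical specs (including ``seed``) generate bit-identical slides.

    Parameters
    ----------
    width, height
        Slide dimensions in pixels.
    n_lesions
        Number of elliptical lesions to render (may be 0).
    lesion_axis_range
        ``(min, max)`` range of the ellipse semi-axes in pixels.
    marker_channel
        RGB channel index carrying the lesion signal.
    lesion_marker_range
        ``(low, high)`` uniform range of the marker channel inside lesions.
    background_marker_level
        Constant marker-channel value of the background.
    background_rgb
        Base color of the background in the two non-marker channels
        (marker entry ignored).
    background_noise
        Amplitude of the smoothed noise texture added to the non-marker
        channels.
    texture_sigma
        Gaussian smoothing scale of the background texture, pixels.
    texture_cell
        Texture is rendered on a grid of ``texture_cell``-pixel cells and
        block-replicated (keeps generation cheap on large slides).
    cluster_prob
        Probability that a lesion is placed near the previous one instead
        of uniformly at random (lesions may form clusters).
    max_lesion_fraction
        Sparsity ceiling: generation fails if the lesion pixel fraction of
        the slide exceeds this value.
    seed
        RNG seed for this slide.
    """

    width: int = 4096
    height: int = 4096
    n_lesions: int = 3
    lesion_axis_range: tuple[int, int] = (48, 112)
    marker_channel: int = 0
    lesion_marker_range: tuple[int, int] = (220, 255)
    background_marker_level: int = 0
    background_rgb: tuple[int, int, int] = (70, 185, 210)
    background_noise: float = 25.0
    texture_sigma: float = 8.0
    texture_cell: int = 8
    cluster_prob: float = 0.3
    max_lesion_fraction: float = 0.01
    seed: int = 0

    def validate(self, min_side: int = DEFAULT_MIN_SIDE) -> None:
        if self.width < min_side or self.height < min_side:
            raise ValueError(
                f"slide dimensions {self.width}x{self.height} are smaller than "
                f"the minimum {min_side}x{min_side} (one tile)"
            )
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        lo, hi = self.lesion_axis_range
        if lo < 1 or hi < lo:
            raise ValueError("lesion_axis_range must satisfy 1 <= min <= max")
        if 2 * hi >= min(self.width, self.height):
            raise ValueError(
                f"a lesion with semi-axis {hi} cannot fit inside a "
                f"{self.width}x{self.height} slide"
            )
        if not 0 <= self.marker_channel <= 2:
            raise ValueError("marker_channel must be 0, 1 or 2")
        if not 0.0 <= self.cluster_prob <= 1.0:
            raise ValueError("cluster_prob must be in [0, 1]")


@dataclass(frozen=True)
class Lesion:
    """Parameters of one rendered ellipse (pixel coordinates)."""

    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # semi-axes (a, b)
    angle: float  # radians


@dataclass(frozen=True)
class SyntheticSlide:
    """A rendered slide: RGB image, exact binary ground truth, and its spec."""

    image: np.ndarray  # (H, W, 3) uint8
    gt_mask: np.ndarray  # (H, W) uint8, 1 = lesion
    spec: SlideSpec
    lesions: tuple[Lesion, ...] = ()

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.gt_mask.shape:
            raise ValueError("image and gt_mask dimensions differ")

    @property
    def lesion_fraction(self) -> float:
        return float(self.gt_mask.sum()) / self.gt_mask.size


def ellipse_mask(
    height: int,
    width: int,
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    """Exact point-in-ellipse rasterization on the pixel grid.

    A pixel ``(row, col)`` belongs to the ellipse iff its integer
    coordinates satisfy the rotated-ellipse inequality.  This is the same
    predicate the brute-force test oracle evaluates, so rendered area is
    exactly checkable.
    """
    cy, cx = center
    a, b = axes
    rows = np.arange(height, dtype=np.float64)[:, None]
    cols = np.arange(width, dtype=np.float64)[None, :]
    dy = rows - cy
    dx = cols - cx
    ct, st = np.cos(angle), np.sin(angle)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u * u) / (a * a) + (v * v) / (b * b) <= 1.0


def _ellipse_half_extents(a: float, b: float, angle: float) -> tuple[float, float]:
    # Tight axis-aligned bounding half-extents of a rotated ellipse.
    ct, st = np.cos(angle), np.sin(angle)
    ex = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
    ey = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
    return ey, ex


def _place_lesions(
    spec: SlideSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[Lesion]]:
    """Render all lesions; returns the exact union mask (uint8) + parameters."""
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    placed: list[Lesion] = []
    lo, hi = spec.lesion_axis_range
    prev_center: tuple[float, float] | None = None
    for _ in range(spec.n_lesions):
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        angle = rng.uniform(0.0, np.pi)
        ey, ex = _ellipse_half_extents(a, b, angle)
        y_lo, y_hi = ey, spec.height - 1 - ey
        x_lo, x_hi = ex, spec.width - 1 - ex
        if y_lo > y_hi or x_lo > x_hi:
            raise ValueError(
                f"lesion with semi-axes ({a:.0f}, {b:.0f}) cannot fit inside "
                f"a {spec.width}x{spec.height} slide"
            )
        if prev_center is not None and rng.uniform() < spec.cluster_prob:
            cy = np.clip(prev_center[0] + rng.normal(0, 2 * hi), y_lo, y_hi)
            cx = np.clip(prev_center[1] + rng.normal(0, 2 * hi), x_lo, x_hi)
        else:
            cy = rng.uniform(y_lo, y_hi)
            cx = rng.uniform(x_lo, x_hi)
        prev_center = (cy, cx)

        # Rasterize only inside the bounding box.
        r0 = int(np.floor(cy - ey))
        r1 = int(np.ceil(cy + ey)) + 1
        c0 = int(np.floor(cx - ex))
        c1 = int(np.ceil(cx + ex)) + 1
        local = ellipse_mask(r1 - r0, c1 - c0, (cy - r0, cx - c0), (a, b), angle)
        mask[r0:r1, c0:c1] |= local.astype(np.uint8)
        placed.append(Lesion(center=(cy, cx), axes=(a, b), angle=angle))
    return mask, placed


def generate_slide(spec: SlideSpec, min_side: int = DEFAULT_MIN_SIDE) -> SyntheticSlide:
    """Render one synthetic slide from its spec. Deterministic given the spec."""
    spec.validate(min_side=min_side)
    rng = np.random.default_rng(spec.seed)

    mask, lesions = _place_lesions(spec, rng)

    frac = float(mask.sum()) / mask.size
    if frac > spec.max_lesion_fraction:
        raise ValueError(
            f"lesion fraction {frac:.4f} exceeds the sparsity ceiling "
            f"{spec.max_lesion_fraction:.4f}; reduce n_lesions or axes"
        )

    image = np.empty((spec.height, spec.width, 3), dtype=np.uint8)
    texture_channels = [c for c in range(3) if c != spec.marker_channel]
    cell = max(1, spec.texture_cell)
    gh = -(-spec.height // cell)
    gw = -(-spec.width // cell)
    for c in texture_channels:
        base = float(spec.background_rgb[c])
        if spec.background_noise > 0:
            noise = rng.normal(0.0, 1.0, size=(gh, gw))
            noise = gaussian_filter(noise, spec.texture_sigma / cell, mode="reflect")
            # Renormalize: smoothing shrinks the variance.
            sd = noise.std()
            if sd > 0:
                noise *= spec.background_noise / sd
            # Quantize on the coarse grid, then replicate (cheap on big slides).
            small = np.clip(np.round(base + noise), 0, 255).astype(np.uint8)
            chan = np.repeat(np.repeat(small, cell, 0), cell, 1)
            image[..., c] = chan[: spec.height, : spec.width]
        else:
            image[..., c] = np.uint8(np.clip(round(base), 0, 255))

    marker = np.full(
        (spec.height, spec.width), spec.background_marker_level, dtype=np.uint8
    )
    n_lesion_px = int(mask.sum())
    if n_lesion_px:
        m_lo, m_hi = spec.lesion_marker_range
        marker[mask == 1] = rng.integers(
            m_lo, m_hi + 1, size=n_lesion_px, dtype=np.uint8
        )
    image[..., spec.marker_channel] = marker
    return SyntheticSlide(
        image=image, gt_mask=mask, spec=spec, lesions=tuple(lesions)
    )


def slide_seed(root_seed: int, index: int) -> int:
    """Per-slide substream seed: SeedSequence keyed by (root, index).

    Slides are independently reproducible — slide ``index`` of a dataset can
    be regenerated without generating the others.
    """
    return int(np.random.SeedSequence((root_seed, index)).generate_state(1)[0])


def train_test_split_sizes(n_slides: int, train_fraction: float) -> tuple[int, int]:
    """Round the train fraction to whole slides: round(f*n) train, rest test."""
    n_train = int(round(train_fraction * n_slides))
    return n_train, n_slides - n_train


def generate_dataset(
    n_slides: int,
    spec_template: SlideSpec | None = None,
    seed: int = 0,
    train_fraction: float = 0.68,
    out_dir: str | Path | None = None,
    min_side: int = DEFAULT_MIN_SIDE,
) -> tuple[list[SyntheticSlide], pd.DataFrame]:
    """Generate a reproducible dataset of slides plus a manifest.

    Each slide's spec is the template with a per-slide substream seed; the
    manifest records id, paths (if written), split assignment and seed.
    The split assigns ``round(train_fraction * n_slides)`` slides to train
    (e.g. 97/46 for 143 slides at 0.68), shuffled reproducibly.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    if spec_template is None:
        spec_template = SlideSpec()

    n_train, _ = train_test_split_sizes(n_slides, train_fraction)
    # Split assignment uses its own substream (spawn key distinct from any slide index).
    rng = np.random.default_rng(np.random.SeedSequence((seed, n_slides, 0x51)))
    order = rng.permutation(n_slides)
    split = np.array(["test"] * n_slides, dtype=object)
    split[order[:n_train]] = "train"

    slides: list[SyntheticSlide] = []
    records = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for k in range(n_slides):
        spec_k = replace(spec_template, seed=slide_seed(seed, k))
        slide = generate_slide(spec_k, min_side=min_side)
        slides.append(slide)
        path = mask_path = ""
        if out is not None:
            path, mask_path = save_slide(slide, out, f"slide_{k:04d}")
        records.append(
            {
                "slide_id": f"slide_{k:04d}",
                "path": str(path),
                "mask_path": str(mask_path),
                "split": split[k],
                "seed": spec_k.seed,
                "n_lesions": spec_k.n_lesions,
                "width": spec_k.width,
                "height": spec_k.height,
            }
        )
    manifest = pd.DataFrame.from_records(records)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        with open(out / "template.json", "w") as fh:
            json.dump(asdict(spec_template) | {"root_seed": seed}, fh, indent=2)
    return slides, manifest


def save_slide(
    slide: SyntheticSlide, out_dir: str | Path, stem: str
) -> tuple[Path, Path]:
    """Write image and mask as PNG (mask: 0 background / 255 lesion)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{stem}.png"
    mask_path = out / f"{stem}_mask.png"
    iio.imwrite(img_path, slide.image)
    iio.imwrite(mask_path, (slide.gt_mask * 255).astype(np.uint8))
    return img_path, mask_path


def load_slide(img_path: str | Path, mask_path: str | Path | None = None):
    """Read an image (and optional 0/255 mask) back as numpy arrays."""
    import imageio.v3 as iio

    image = np.asarray(iio.imread(img_path))
    mask = None
    if mask_path is not None:
        mask = (np.asarray(iio.imread(mask_path)) > 127).astype(np.uint8)
    return image, mask
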