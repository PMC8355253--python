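"""Closed-form threshold segmenters.

On slides from :mod:`wsicascade.synthetic`, the lesion signal lives in one
clean marker channel, so thresholding that channel IS an exact segmenter:
probability 1 where the channel crosses the cutoff, else 0.  At coarser
pyramid levels the lesion signal survives area-averaging at a reduced but
strictly positive amplitude, so a per-level cutoff schedule yields a model
family with the exact coarse-covers-fine property — the oracle family used
to verify cascade/exhaustive-inference equivalence bit for bit.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["ThresholdSegmenter", "make_threshold_oracle", "oracle_cutoffs"]


class ThresholdSegmenter(BaseEstimator):
    """probability = 1 where ``tile[..., channel] >= cutoff``, else 0."""

    def __init__(self, channel: int = 0, cutoff: float = 128.0, level: int | None = None):
        self.channel = channel
        self.cutoff = cutoff
        self.level = level

    def fit(self, X=None, y=None) -> "ThresholdSegmenter":
        if not 0 <= self.channel <= 2:
            raise ValueError("channel must be 0, 1 or 2")
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 3:
            return (X[..., self.channel] >= self.cutoff).astype(np.float64)
        return (X[..., self.channel] >= self.cutoff).astype(np.float64)

    def predict(self, X: np.ndarray, alpha: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= alpha).astype(np.uint8)


def make_threshold_oracle(
    channel: int, cutoff: float, level: int | None = None
) -> ThresholdSegmenter:
    """A segmenter thresholding one channel; tagged with its pyramid level."""
    return ThresholdSegmenter(channel=channel, cutoff=cutoff, level=level).fit()


def oracle_cutoffs(
    num_levels: int,
    zoom_step: int,
    lesion_marker_min: float = 220.0,
    marker_channel: int = 0,
) -> list[ThresholdSegmenter]:
    """One threshold oracle per level (index 0 = level 1 = coarsest).

    A single full-resolution lesion pixel of value >= ``m`` contributes at
    least ``m / 4**(z * (N - l))`` to the level-l area average covering it
    (uint8 rounding can halve that once more), so cutting at half that
    floor activates every block that touches a lesion while the zero
    background never does.  At the finest level the cutoff sits halfway
    between background (0) and the lesion minimum.
    """
    models = []
    for level in range(1, num_levels + 1):
        shrink = 4.0 ** (zoom_step * (num_levels - level))
        if level == num_levels:
            cutoff = lesion_marker_min / 2.0
        else:
            cutoff = max(lesion_marker_min / shrink / 4.0, 0.45)
        models.append(
            make_threshold_oracle(marker_channel, cutoff, level=level)
        )
    return models
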