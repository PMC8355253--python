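"""Pixel-level segmentation metrics, aggregation, and Fisher's LSD.

Metrics over the pixel confusion counts:

    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)          (sensitivity)
    F-measure   = 2 TP / (2 TP + FP + FN)
    Jaccard     = TP / (TP + FP + FN)  =  F / (2 - F)
    specificity = TN / (TN + FP)

Degenerate-slide conventions (``conventions="paper"``): a slide with no
ground-truth positives gets recall = NaN (excluded from group means); a
slide with no positive mass at all (TP = FP = FN = 0) records precision,
F-measure and Jaccard as 0.  ``conventions="strict"`` propagates NaN for
every 0/0 instead.

Fisher's LSD: pairwise method comparisons after a one-way ANOVA, using the
pooled mean-square error and the t distribution with N - k degrees of
freedom, with no multiplicity adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "LSDComparison",
    "confusion",
    "metrics",
    "f_measure_from_pr",
    "jaccard_from_f",
    "aggregate",
    "lsd_test",
    "throughput",
    "project_time",
]

METRIC_NAMES = ("precision", "recall", "f_measure", "jaccard", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f_measure: float
    jaccard: float
    specificity: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class LSDComparison:
    method_i: str
    method_j: str
    mean_difference: float
    std_error: float
    p_value: float
    ci_low: float
    ci_high: float


def confusion(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    ignore_mask: np.ndarray | None = None,
) -> ConfusionCounts:
    """Pixelwise confusion counts over non-ignored pixels."""
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    pred = pred > 0
    gt = gt > 0
    if ignore_mask is not None:
        ignore = np.asarray(ignore_mask) > 0
        if ignore.shape != gt.shape:
            raise ValueError("ignore_mask shape differs from the masks")
        keep = ~ignore
        pred, gt = pred[keep], gt[keep]
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(pred.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def f_measure_from_pr(precision: float, recall: float) -> float:
    """F = 2 P R / (P + R)."""
    if precision + recall == 0:
        return math.nan
    return 2.0 * precision * recall / (precision + recall)


def jaccard_from_f(f_measure: float) -> float:
    """Jaccard = F / (2 - F)."""
    return f_measure / (2.0 - f_measure)


def metrics(counts: ConfusionCounts, conventions: str = "paper") -> MetricSet:
    """Compute the metric set from confusion counts.

    ``conventions='paper'`` applies the degenerate-slide conventions
    described in the module docstring; ``'strict'`` leaves 0/0 as NaN.
    """
    if conventions not in ("paper", "strict"):
        raise ValueError("conventions must be 'paper' or 'strict'")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f = _ratio(2 * tp, 2 * tp + fp + fn)
    jac = _ratio(tp, tp + fp + fn)
    spec = _ratio(tn, tn + fp)
    flags: list[str] = []
    if conventions == "paper":
        if tp + fn == 0:
            flags.append("no_gt_positives_recall_nan")
            recall = math.nan
        if tp + fp + fn == 0:
            # No positive mass anywhere: record the zero convention.
            flags.append("no_positive_mass_zero")
            precision, f, jac = 0.0, 0.0, 0.0
        elif tp + fp == 0:
            # Prediction empty but lesions exist: zero precision-side scores.
            flags.append("empty_prediction_zero")
            precision = 0.0
    return MetricSet(
        precision=precision,
        recall=recall,
        f_measure=f,
        jaccard=jac,
        specificity=spec,
        flags=tuple(flags),
    )


def aggregate(
    slide_metrics: list[MetricSet],
    groups: list[str] | None = None,
    all_label: str = "All",
) -> pd.DataFrame:
    """Per-group metric means with NaN exclusion (macro, per-slide mean).

    Returns rows indexed by group (an overall row first), one column per
    metric.  ``groups`` assigns each slide a label (e.g. lesion-bearing vs
    lesion-free); omit it for the overall row only.
    """
    if not slide_metrics:
        raise ValueError("need at least one slide")
    df = pd.DataFrame([m.as_dict() for m in slide_metrics])
    rows = {all_label: df.mean(skipna=True)}
    if groups is not None:
        if len(groups) != len(slide_metrics):
            raise ValueError("one group label per slide required")
        df_g = df.assign(_group=groups)
        for g, sub in df_g.groupby("_group", sort=True):
            rows[str(g)] = sub[list(METRIC_NAMES)].mean(skipna=True)
    return pd.DataFrame(rows).T


def per_slide_table(slide_metrics: list[MetricSet]) -> pd.DataFrame:
    """Per-slide metric values (box-plot-ready long table)."""
    return pd.DataFrame([m.as_dict() for m in slide_metrics])


def lsd_test(
    scores: pd.DataFrame | dict[str, list[float]],
    alpha_level: float = 0.05,
    reference: str | None = None,
) -> list[LSDComparison]:
    """Fisher's LSD pairwise comparisons after one-way ANOVA.

    ``scores``: wide table, one column per method, one row per slide (NaN
    rows per method are dropped; unbalanced groups allowed).  For each
    ordered pair (I, J): mean difference, SE = sqrt(MSE (1/n_I + 1/n_J)),
    two-sided p from t with N - k df, and the (1 - alpha_level) CI.  If
    ``reference`` is given, only comparisons of that method against the
    others are returned.
    """
    if isinstance(scores, dict):
        scores = pd.DataFrame({k: pd.Series(v, dtype=float) for k, v in scores.items()})
    methods = list(scores.columns)
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    groups = {m: scores[m].dropna().to_numpy(dtype=float) for m in methods}
    for m, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"method '{m}' has fewer than 2 scores")
    n_total = sum(len(v) for v in groups.values())
    k = len(methods)
    df_err = n_total - k
    # Pooled within-group mean square (the ANOVA error term).
    sse = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    mse = sse / df_err
    tcrit = stats.t.ppf(1.0 - alpha_level / 2.0, df_err)

    pairs = (
        [(reference, m) for m in methods if m != reference]
        if reference is not None
        else [(a, b) for ai, a in enumerate(methods) for b in methods[ai + 1 :]]
    )
    out = []
    for mi, mj in pairs:
        vi, vj = groups[mi], groups[mj]
        diff = float(vi.mean() - vj.mean())
        se = math.sqrt(mse * (1.0 / len(vi) + 1.0 / len(vj)))
        if se == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
            t_stat = math.inf if diff else 0.0
        else:
            t_stat = diff / se
            p = 2.0 * stats.t.sf(abs(t_stat), df_err)
        out.append(
            LSDComparison(
                method_i=mi,
                method_j=mj,
                mean_difference=diff,
                std_error=se,
                p_value=float(p),
                ci_low=diff - tcrit * se,
                ci_high=diff + tcrit * se,
            )
        )
    return out


def lsd_table(comparisons: list[LSDComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method_i": c.method_i,
                "method_j": c.method_j,
                "mean_difference": c.mean_difference,
                "std_error": c.std_error,
                "p_value": c.p_value,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
            }
            for c in comparisons
        ]
    )


def throughput(patch_w: int, patch_h: int, seconds_per_patch: float) -> int:
    """Pixels per second, floored: floor(w * h / t)."""
    if patch_w < 1 or patch_h < 1:
        raise ValueError("patch dimensions must be positive")
    if seconds_per_patch <= 0:
        raise ValueError("seconds_per_patch must be positive")
    return math.floor(patch_w * patch_h / seconds_per_patch)


def project_time(
    total_pixels: int, patch_w: int, patch_h: int, seconds_per_patch: float
) -> int:
    """Projected seconds to process a slide: floor(P / (w h) * t)."""
    if total_pixels < 0:
        raise ValueError("total_pixels must be >= 0")
    if patch_w < 1 or patch_h < 1:
        raise ValueError("patch dimensions must be positive")
    if seconds_per_patch <= 0:
        raise ValueError("seconds_per_patch must be positive")
    return math.floor(total_pixels / (patch_w * patch_h) * seconds_per_patch)
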