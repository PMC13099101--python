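"""Quantile binning, LOESS smoothing and sign-reversal threshold detection.

Raw per-cell SHAP values against a continuous driver are noisy; to expose
the underlying association trend the driver range is split into quantile
bins, each bin contributing its mean driver value, mean SHAP value and a
normal-approximation confidence interval, and a LOESS (locally weighted
linear regression with tricube weights) curve is fitted through the bin
means.  A *threshold* is a driver value where the smoothed curve changes
sign — the point at which the driver's association with the synergy class
reverses into an association with trade-off (or vice versa).  Consecutive
crossings closer than one bin width merge into a *sensitive interval*.

A sign change is only counted when the smoothed curve is distinguishable
from zero on both sides (it must exceed the local bin CI half-width
somewhere within each adjacent sign run); this keeps pure-noise curves,
which wander around zero, from reporting spurious thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["BinnedCurve", "ThresholdSet", "bin_and_smooth", "detect_thresholds"]


@dataclass
class BinnedCurve:
    """Aggregated driver-vs-SHAP curve over quantile bins."""

    feature_mean: np.ndarray   # per-bin mean driver value (ordered)
    shap_mean: np.ndarray      # per-bin mean SHAP value
    ci_halfwidth: np.ndarray   # 1.96 * sd / sqrt(count)
    count: np.ndarray
    smoothed: np.ndarray       # LOESS fit evaluated at feature_mean
    n_bins_requested: int = 0
    n_bins_merged: int = 0


@dataclass
class ThresholdSet:
    """Detected sign reversals of a smoothed driver-SHAP curve."""

    crossings: list = field(default_factory=list)  # (x, direction)
    intervals: list = field(default_factory=list)  # (lo, hi) sensitive ranges

    # direction: 'synergy->trade-off' (curve goes + to -) or the reverse
    def locations(self) -> list:
        return [x for x, _ in self.crossings]


def bin_and_smooth(
    feature_values: np.ndarray,
    shap_values: np.ndarray,
    n_bins: int = 20,
    loess_frac: float = 0.5,
) -> BinnedCurve:
    """Quantile-bin a driver/SHAP scatter and LOESS-smooth the bin means.

    Fewer unique driver values than bins collapses duplicate quantile
    edges; the merge count is recorded on the curve.
    """
    x = np.asarray(feature_values, dtype=float).ravel()
    s = np.asarray(shap_values, dtype=float).ravel()
    if x.shape != s.shape:
        raise ValueError("feature and SHAP arrays must align")
    if len(x) < n_bins:
        raise ValueError("need at least as many samples as bins")
    bins = pd.qcut(x, q=n_bins, duplicates="drop")
    df = pd.DataFrame({"x": x, "s": s, "bin": bins})
    grp = df.groupby("bin", observed=True, sort=True)
    agg = grp.agg(
        feature_mean=("x", "mean"),
        shap_mean=("s", "mean"),
        sd=("s", "std"),
        count=("s", "size"),
    ).reset_index(drop=True)
    agg = agg.sort_values("feature_mean").reset_index(drop=True)
    counts = agg["count"].to_numpy(dtype=float)
    sd = agg["sd"].fillna(0.0).to_numpy(dtype=float)
    ci = 1.96 * sd / np.sqrt(np.maximum(counts, 1.0))
    fx = agg["feature_mean"].to_numpy()
    fy = agg["shap_mean"].to_numpy()
    if len(fx) >= 3:
        sm = lowess(fy, fx, frac=loess_frac, return_sorted=False)
    else:
        sm = fy.copy()
    return BinnedCurve(
        feature_mean=fx,
        shap_mean=fy,
        ci_halfwidth=ci,
        count=counts.astype(np.int64),
        smoothed=np.asarray(sm, dtype=float),
        n_bins_requested=n_bins,
        n_bins_merged=n_bins - len(fx),
    )


def _sign_runs(signs: np.ndarray) -> list:
    """Maximal runs of constant nonzero sign: list of (start, end_incl, sign)."""
    runs = []
    start = None
    cur = 0
    for i, sg in enumerate(signs):
        if sg == 0:
            if start is not None:
                runs.append((start, i - 1, cur))
                start, cur = None, 0
            continue
        if start is None:
            start, cur = i, sg
        elif sg != cur:
            runs.append((start, i - 1, cur))
            start, cur = i, sg
    if start is not None:
        runs.append((start, len(signs) - 1, cur))
    return runs


def detect_thresholds(
    curve: BinnedCurve,
    eps: float | None = None,
    require_significance: bool = True,
) -> ThresholdSet:
    """Find sign reversals of the smoothed curve.

    Crossing locations are linear interpolations between adjacent bins of
    opposite smoothed sign.  A reversal only counts when, on each side, the
    smoothed curve exceeds the per-bin CI half-width somewhere within the
    adjacent constant-sign run (``require_significance=False`` disables the
    gate).  Crossings closer than ``eps`` (default: one median bin width)
    merge into a sensitive interval.
    """
    y = curve.smoothed
    x = curve.feature_mean
    if len(y) < 3:
        raise ValueError("smoothed curve needs at least 3 points")
    if eps is None:
        eps = float(np.median(np.diff(x))) if len(x) > 1 else 0.0
    signs = np.sign(y).astype(int)
    runs = _sign_runs(signs)

    def run_significant(run) -> bool:
        if not require_significance:
            return True
        lo, hi, _ = run
        seg = slice(lo, hi + 1)
        return bool(np.any(np.abs(y[seg]) > curve.ci_halfwidth[seg]))

    crossings = []
    for left, right in zip(runs[:-1], runs[1:]):
        if left[2] == right[2]:
            continue
        if not (run_significant(left) and run_significant(right)):
            continue
        i, j = left[1], right[0]
        # interpolate across the (possibly zero-valued) gap between runs
        x0, y0 = x[i], y[i]
        x1, y1 = x[j], y[j]
        if y1 == y0:
            xc = 0.5 * (x0 + x1)
        else:
            xc = x0 - y0 * (x1 - x0) / (y1 - y0)
        direction = "synergy->trade-off" if left[2] > 0 else "trade-off->synergy"
        crossings.append((float(xc), direction))

    intervals = []
    merged = []
    i = 0
    while i < len(crossings):
        j = i
        while j + 1 < len(crossings) and crossings[j + 1][0] - crossings[j][0] < eps:
            j += 1
        if j > i:
            intervals.append((crossings[i][0], crossings[j][0]))
        else:
            merged.append(crossings[i])
        i = j + 1
    return ThresholdSet(crossings=merged, intervals=intervals)
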