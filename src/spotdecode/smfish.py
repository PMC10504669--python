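"""Threshold selection for single-molecule FISH spot-count curves.

A *threshold curve* records how many spots are detected as the detection
threshold increases; counts are non-increasing.  The elbow of the curve is
used as the final detection threshold, and the normalized area under the
curve serves as a signal/noise separability metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import simpson


@dataclass(frozen=True)
class ThresholdCurve:
    thresholds: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "counts", c)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("thresholds and counts must be equal-length 1D arrays")
        if len(t) < 3:
            raise ValueError("threshold curve needs at least 3 points")
        if not (np.diff(t) > 0).all():
            raise ValueError("thresholds must be strictly increasing")
        if (np.diff(c) > 0).any():
            raise ValueError("counts must be non-increasing with threshold")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def read_csv(cls, path) -> "ThresholdCurve":
        df = pd.read_csv(path)
        return cls(df["threshold"].to_numpy(), df["count"].to_numpy())

    def write_csv(self, path) -> None:
        pd.DataFrame({"threshold": self.thresholds, "count": self.counts}).to_csv(
            path, index=False
        )


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("axis is constant; cannot normalize")
    return (v - lo) / (hi - lo)


def elbow_threshold(curve: ThresholdCurve) -> float:
    """Threshold at the curve's elbow (knee) point.

    Both axes are min-max normalized, then the point with the maximum
    perpendicular distance to the chord joining the first and last points is
    chosen; ties break toward the smallest threshold.  Always returns an
    element of ``curve.thresholds``.
    """
    x = _minmax(curve.thresholds)
    y = _minmax(curve.counts)
    x0, y0 = x[0], y[0]
    dx, dy = x[-1] - x0, y[-1] - y0
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x0) - dx * (y - y0)) / norm
    # endpoints lie on the chord; restrict to interior so a flat (all-equal)
    # distance profile still yields an interior knee
    interior = dist[1:-1]
    # ties (within fp tolerance) break toward the smallest threshold
    near_max = np.flatnonzero(interior >= interior.max() - 1e-12)
    idx = 1 + int(near_max[0])
    return float(curve.thresholds[idx])


def normalized_auc(curve: ThresholdCurve) -> float:
    """Simpson's-rule area under the min-max-normalized curve, in [0, 1]."""
    x = _minmax(curve.thresholds)
    y = _minmax(curve.counts)
    return float(simpson(y, x=x))
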