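"""Microplate growth-curve smoothing and the growth-ratio statistic.

OD600 time series are smoothed by LOESS — locally weighted polynomial
regression of degree 2 with tricube weights over the nearest
``ceil(span * N)`` neighbors (span 0.45 by default) — and summarized by the
growth ratio: the top OD rate over sliding 1-h windows (or alternatively the
maximum smoothed OD) in the condition of interest, normalized by the same
statistic on the reference glucose medium.  Group differences in the ratio
are assessed with the Wilcoxon–Mann–Whitney test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stattests import TestResult, mann_whitney_u

__all__ = [
    "GrowthCurve",
    "smooth_od",
    "loess",
    "growth_ratio",
    "compare_growth",
    "curves_from_table",
    "curves_to_table",
]


@dataclass
class GrowthCurve:
    """OD readings over time for one strain x condition."""

    strain: str
    condition: str
    times: np.ndarray  # minutes from inoculation, strictly increasing
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD readings must be >= 0")


def loess(x: np.ndarray, y: np.ndarray, span: float = 0.45, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression on sorted x.

    At each point, a polynomial of the given degree is fitted by weighted
    least squares to the nearest ``ceil(span * N)`` neighbors with tricube
    weights; the fitted value at the point is returned.  No robustness
    iterations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = math.ceil(span * n)
    if k < degree + 2:
        raise ValueError(
            f"window of {k} points too small for degree {degree} (need >= {degree + 2})"
        )
    # nearest-k windows are contiguous on sorted x; slide the left edge
    lo = np.empty(n, dtype=np.int64)
    left = 0
    for i in range(n):
        left = max(left, i - k + 1)
        while left + k <= n - 1 and x[left + k] - x[i] < x[i] - x[left]:
            left += 1
        left = min(left, n - k)
        lo[i] = left
    idx = lo[:, None] + np.arange(k)[None, :]
    dx = x[idx] - x[:, None]
    dmax = np.abs(dx).max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    w = (1.0 - (np.abs(dx) / dmax) ** 3) ** 3
    # local design matrix in powers of dx; the intercept is the fitted value
    basis = dx[:, :, None] ** np.arange(degree + 1)[None, None, :]
    gram = np.einsum("nka,nk,nkb->nab", basis, w, basis)
    rhs = np.einsum("nka,nk,nk->na", basis, w, y[idx])
    beta = np.linalg.solve(gram, rhs[:, :, None])[:, :, 0]
    return beta[:, 0]


def smooth_od(curve: GrowthCurve, span: float = 0.45, degree: int = 2) -> GrowthCurve:
    """LOESS-smooth a growth curve on its own time grid."""
    if len(curve.times) < 10:
        raise ValueError("need >= 10 time points to smooth")
    fitted = loess(curve.times, curve.od, span=span, degree=degree)
    return GrowthCurve(
        strain=curve.strain,
        condition=curve.condition,
        times=curve.times.copy(),
        od=np.maximum(fitted, 0.0),
    )


def _top_rate_1h(curve: GrowthCurve, window_min: float = 60.0) -> float:
    """Maximum OD gain over sliding 1-h windows on the sampling grid.

    Windows that would extend past the end of the series are excluded.
    """
    dt = np.diff(curve.times)
    step = int(round(window_min / dt[0]))
    if step < 1 or not np.allclose(dt, dt[0]):
        raise ValueError("top-rate statistic needs a regular grid finer than the window")
    if step >= len(curve.od):
        raise ValueError("series shorter than one window")
    return float(np.max(curve.od[step:] - curve.od[:-step]))


def _max_od(curve: GrowthCurve, baseline_correct: bool = True) -> float:
    od = curve.od
    if baseline_correct:
        first_hour = curve.times <= curve.times[0] + 60.0
        od = od - od[first_hour].min()
    return float(od.max())


def growth_ratio(
    curve_cond: GrowthCurve,
    curve_ref: GrowthCurve,
    mode: str = "top-rate-1h",
    baseline_correct: bool = True,
) -> float:
    """Condition-to-reference growth ratio.

    ``top-rate-1h`` (default): maximum OD increase over sliding 60-min
    windows, condition over reference.  ``max-od``: maximum OD (after
    subtracting the first-hour minimum as media baseline) ratio.  Both
    curves should be smoothed on comparable grids.  Returns ``nan`` when the
    reference statistic is <= 0.
    """
    if mode == "top-rate-1h":
        ref = _top_rate_1h(curve_ref)
        cond = _top_rate_1h(curve_cond)
    elif mode == "max-od":
        ref = _max_od(curve_ref, baseline_correct)
        cond = _max_od(curve_cond, baseline_correct)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if ref <= 0:
        return math.nan
    return cond / ref


def compare_growth(ratios_group_a, ratios_group_b) -> TestResult:
    """Wilcoxon–Mann–Whitney comparison of growth ratios between two groups."""
    return mann_whitney_u(ratios_group_a, ratios_group_b, alternative="two-sided")


def curves_from_table(df: pd.DataFrame) -> dict[tuple[str, str], GrowthCurve]:
    """Long-format table (strain, condition, time_min, od) to curves."""
    curves = {}
    for (strain, condition), sub in df.groupby(["strain", "condition"], sort=False):
        sub = sub.sort_values("time_min")
        curves[(strain, condition)] = GrowthCurve(
            strain=strain,
            condition=condition,
            times=sub["time_min"].to_numpy(float),
            od=sub["od"].to_numpy(float),
        )
    return curves


def curves_to_table(curves: dict[tuple[str, str], GrowthCurve]) -> pd.DataFrame:
    """Curves to a long-format table (strain, condition, time_min, od)."""
    frames = [
        pd.DataFrame(
            {
                "strain": c.strain,
                "condition": c.condition,
                "time_min": c.times,
                "od": c.od,
            }
        )
        for c in curves.values()
    ]
    return pd.concat(frames, ignore_index=True)
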