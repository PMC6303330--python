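"""Summed probability distributions (SPDs) on the annual calendar grid.

An SPD sums the normalized calibrated densities of all dates in a set, so the
total mass equals the number of dates, and then applies a centered moving
average (default 200 years, realized as a symmetric 201-year window) to damp
small-scale calibration-curve artifacts.  Near the grid edges the window
shrinks symmetrically to the available years, which preserves constants and
linear trends everywhere; total mass is conserved exactly for probability
mass lying more than half a window from the edges — the regime of every
analysis window used here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calcurve import CalibrationCurve, _normalize_interval
from .calibrate import calibrate_many
from .dates import DateSet
from .errors import ArgumentError

__all__ = ["SPDSeries", "build_spd", "build_spd_from_arrays", "moving_average", "window_series"]


@dataclass(frozen=True)
class SPDSeries:
    """Per-year summed probability on a decreasing (oldest-first) cal BP grid."""

    cal_bp: np.ndarray
    values: np.ndarray
    n_dates: int
    smoothing_window: int
    label: str = ""

    @property
    def oldest(self) -> int:
        return int(self.cal_bp[0])

    @property
    def youngest(self) -> int:
        return int(self.cal_bp[-1])

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    def t_elapsed(self) -> np.ndarray:
        """Years elapsed since the oldest grid year (0, 1, 2, ...)."""
        return (self.cal_bp[0] - self.cal_bp).astype(float)

    def to_csv(self, path) -> None:
        pd.DataFrame({"cal_bp": self.cal_bp, "value": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_dates: int = 0, smoothing_window: int = 0, label: str = "") -> "SPDSeries":
        df = pd.read_csv(path)
        return cls(
            cal_bp=df["cal_bp"].to_numpy(np.int64),
            values=df["value"].to_numpy(float),
            n_dates=n_dates,
            smoothing_window=smoothing_window,
            label=label or str(path),
        )


def moving_average(values, width: int) -> np.ndarray:
    """Centered running mean with symmetric shrinking edge windows.

    ``width`` is the nominal window in years; the realized window is the odd
    span 2*(width//2) + 1 so it can be centered.  At position i the half
    width shrinks to min(width//2, i, n-1-i), keeping the window symmetric
    about i.  Constants and linear ramps are reproduced exactly everywhere.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if width < 1:
        raise ArgumentError("smoothing width must be >= 1")
    if width > n:
        raise ArgumentError(f"smoothing width {width} exceeds series span {n}")
    half = width // 2
    if half == 0:
        return x.copy()
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    cs = np.concatenate(([0.0], np.cumsum(x)))
    return (cs[idx + h + 1] - cs[idx - h]) / (2 * h + 1)


def build_spd_from_arrays(
    c14_ages,
    sigma_labs,
    curve: CalibrationCurve,
    window,
    smoothing: int = 200,
    label: str = "",
) -> SPDSeries:
    """Sum normalized calibrated densities over ``window`` and smooth.

    Vectorized core shared by the observed pipeline and the Monte-Carlo
    simulations, so simulated SPDs are built exactly as the observed one.
    """
    c14_ages = np.asarray(c14_ages, dtype=float)
    if c14_ages.size == 0:
        raise ArgumentError("cannot build an SPD from an empty date set")
    dens = calibrate_many(c14_ages, sigma_labs, curve, window=window)
    raw = dens.sum(axis=0)
    sl = curve.subgrid(window)
    return SPDSeries(
        cal_bp=curve.cal_bp[sl],
        values=moving_average(raw, smoothing) if smoothing > 1 else raw,
        n_dates=int(c14_ages.size),
        smoothing_window=int(smoothing),
        label=label,
    )


def build_spd(
    ds: DateSet,
    curve: CalibrationCurve,
    window=(20000, 10000),
    smoothing: int = 200,
    label: str | None = None,
) -> SPDSeries:
    """SPD of a vetted date set on the annual grid over ``window`` (cal BP)."""
    if len(ds) == 0:
        raise ArgumentError("cannot build an SPD from an empty date set")
    return build_spd_from_arrays(
        ds.c14_ages, ds.sigma_labs, curve, window, smoothing,
        label=label if label is not None else ds.label,
    )


def window_series(series: SPDSeries, interval) -> SPDSeries:
    """Slice a series to ``interval`` (inclusive), preserving orientation."""
    old, young = _normalize_interval(interval)
    lo = max(series.youngest, young)
    hi = min(series.oldest, old)
    if lo > hi:
        raise ArgumentError(
            f"interval ({old}, {young}) does not overlap series "
            f"[{series.oldest}, {series.youngest}]"
        )
    i0 = series.oldest - hi
    i1 = series.oldest - lo + 1
    return replace(series, cal_bp=series.cal_bp[i0:i1], values=series.values[i0:i1])
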