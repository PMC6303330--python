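"""Radiocarbon calibration curves.

A calibration curve maps calendar age (cal BP, years before 1950; larger =
older) to expected conventional radiocarbon age (14C yr BP) with a 1-sigma
curve error.  Curves are read from the standard IntCal ``.14c`` column layout
(comment lines starting with ``#``, then cal BP, 14C age, error; extra columns
ignored) and resampled onto an annual calendar grid by linear interpolation of
both the mean and the error.

All annual series in this package are stored oldest-to-youngest, i.e. the
``cal_bp`` grid is strictly decreasing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, FormatError

__all__ = ["CalibrationCurve", "read_curve", "write_curve"]


def _normalize_interval(interval) -> tuple[int, int]:
    """Return (older, younger) cal BP bounds regardless of input order."""
    a, b = int(interval[0]), int(interval[1])
    return (max(a, b), min(a, b))


@dataclass(frozen=True)
class CalibrationCurve:
    """A calibration curve resampled to an annual calendar grid.

    Attributes
    ----------
    cal_bp : ndarray of int
        Annual grid, strictly decreasing (oldest -> youngest).
    c14_age : ndarray of float
        Interpolated curve mean at each grid year (14C yr BP).
    sigma : ndarray of float
        Interpolated 1-sigma curve error at each grid year (14C yr).
    knots : DataFrame
        The source knots (columns ``cal_bp``, ``c14_age``, ``sigma``),
        ascending in cal_bp, restricted to the grid range.
    name : str
        Text label.
    """

    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray
    knots: pd.DataFrame = field(repr=False)
    name: str = "curve"

    @property
    def oldest(self) -> int:
        return int(self.cal_bp[0])

    @property
    def youngest(self) -> int:
        return int(self.cal_bp[-1])

    def contains(self, interval) -> bool:
        old, young = _normalize_interval(interval)
        return old <= self.oldest and young >= self.youngest

    def index_of(self, theta) -> np.ndarray:
        """Grid index of calendar year(s) ``theta`` (must lie on the grid)."""
        theta = np.asarray(theta)
        idx = self.oldest - theta
        if np.any(idx < 0) or np.any(idx >= self.cal_bp.size):
            raise ArgumentError(
                f"calendar year(s) outside curve grid "
                f"[{self.oldest}, {self.youngest}] cal BP"
            )
        return idx.astype(np.intp)

    def mu_sigma(self, theta) -> tuple[np.ndarray, np.ndarray]:
        """Curve mean and error at calendar year(s) ``theta`` on the grid."""
        idx = self.index_of(theta)
        return self.c14_age[idx], self.sigma[idx]

    def subgrid(self, interval) -> slice:
        """Slice object selecting ``interval`` (inclusive) on the annual grid."""
        old, young = _normalize_interval(interval)
        if old > self.oldest or young < self.youngest:
            raise ArgumentError(
                f"interval ({old}, {young}) exceeds curve grid "
                f"[{self.oldest}, {self.youngest}]"
            )
        return slice(self.oldest - old, self.oldest - young + 1)

    @classmethod
    def identity(cls, interval, sigma: float = 0.0, name: str = "identity") -> "CalibrationCurve":
        """Curve with mu(theta) = theta and constant error ``sigma``.

        A degenerate (sigma = 0) identity curve is permitted here for testing
        and round-trip oracles even though real curve files must have
        strictly positive errors.
        """
        old, young = _normalize_interval(interval)
        grid = np.arange(old, young - 1, -1, dtype=np.int64)
        knots = pd.DataFrame(
            {"cal_bp": [float(young), float(old)],
             "c14_age": [float(young), float(old)],
             "sigma": [float(sigma)] * 2}
        )
        return cls(
            cal_bp=grid,
            c14_age=grid.astype(float),
            sigma=np.full(grid.size, float(sigma)),
            knots=knots,
            name=name,
        )

    @classmethod
    def from_knots(cls, knots: pd.DataFrame, interval, name: str = "curve") -> "CalibrationCurve":
        """Build a curve from knots, interpolating onto an annual grid.

        ``interval`` is the (older, younger) cal BP range of the grid; knots
        must span it so interpolation never extrapolates.
        """
        knots = knots.loc[:, ["cal_bp", "c14_age", "sigma"]].astype(float).reset_index(drop=True)
        if len(knots) == 0:
            raise FormatError("curve has no knots")
        diffs = np.diff(knots["cal_bp"].to_numpy())
        if np.any(diffs == 0) or (np.any(diffs > 0) and np.any(diffs < 0)):
            raise FormatError("knot cal BP values must be strictly monotonic")
        if diffs.size and diffs[0] < 0:  # store ascending for interpolation
            knots = knots.iloc[::-1].reset_index(drop=True)
        if np.any(knots["sigma"].to_numpy() <= 0):
            raise FormatError("curve errors must be strictly positive")
        old, young = _normalize_interval(interval)
        kx = knots["cal_bp"].to_numpy()
        if old > kx[-1] or young < kx[0]:
            raise FormatError(
                f"knots span [{kx[0]:.0f}, {kx[-1]:.0f}] cal BP and cannot "
                f"support the requested grid ({old}, {young})"
            )
        grid = np.arange(old, young - 1, -1, dtype=np.int64)
        mu = np.interp(grid, kx, knots["c14_age"].to_numpy())
        sg = np.interp(grid, kx, knots["sigma"].to_numpy())
        inside = (kx >= young) & (kx <= old)
        return cls(cal_bp=grid, c14_age=mu, sigma=sg, knots=knots.loc[inside].reset_index(drop=True), name=name)


def read_curve(path, interval, name: str | None = None) -> CalibrationCurve:
    """Read an IntCal-style ``.14c`` file and resample it onto an annual grid.

    Lines starting with ``#`` are comments; data lines hold cal BP, 14C age
    and 1-sigma error in the first three comma- or whitespace-separated
    columns (further columns are ignored).
    """
    rows = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected at least 3 columns")
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric value") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows")
    knots = pd.DataFrame(rows, columns=["cal_bp", "c14_age", "sigma"])
    return CalibrationCurve.from_knots(knots, interval, name=name or str(path))


def write_curve(curve: CalibrationCurve, path) -> None:
    """Write the curve knots back out in the ``.14c`` column layout."""
    buf = io.StringIO()
    buf.write(f"# {curve.name}\n# CAL BP, 14C age, error\n")
    for _, row in curve.knots.iterrows():
        buf.write(f"{row.cal_bp:.1f},{row.c14_age:.2f},{row.sigma:.2f}\n")
    with open(path, "wt") as fh:
        fh.write(buf.getvalue())
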