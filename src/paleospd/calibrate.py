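"""Calibration of radiocarbon measurements and its Monte-Carlo inverse.

Calibration turns a lab measurement (14C age +/- 1-sigma lab error) into a
probability mass function over calendar years: for grid year theta with curve
mean mu(theta) and curve error s_c(theta),

    p(theta)  propto  N(c14_age | mu(theta), lab_sigma^2 + s_c(theta)^2),

normalized to sum to one over the grid.  "Back-calibration" is the reverse
simulation used by the Monte-Carlo null-model test: a calendar year is pushed
through the curve by drawing a 14C age from N(mu(theta), s_c(theta)) and
attaching a lab error resampled from an empirical pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calcurve import CalibrationCurve
from .errors import ArgumentError, DegenerateDensityError, OutOfRangeError

__all__ = [
    "CalibratedDensity",
    "calibrate_date",
    "calibrate_many",
    "back_calibrate_sample",
    "back_calibrate_many",
]

# a measurement further than this many combined sigmas from every grid year is
# treated as outside the curve's support
_SUPPORT_NSIGMA = 10.0


@dataclass(frozen=True)
class CalibratedDensity:
    """Per-year calendar probability mass for one measurement.

    ``cal_bp`` is the (decreasing) annual grid; ``prob`` sums to one.
    """

    cal_bp: np.ndarray
    prob: np.ndarray
    date_ref: str = ""

    def mode_year(self) -> int:
        """Grid year of maximum probability (ties -> oldest)."""
        return int(self.cal_bp[int(np.argmax(self.prob))])

    def mean_year(self) -> float:
        return float(np.sum(self.cal_bp * self.prob))


def _density_row(c14_age, sigma_lab, mu, sg):
    """Unnormalized per-year weights for one measurement (may raise)."""
    var = sigma_lab**2 + sg**2
    zero = var == 0.0
    if zero.any():
        hits = zero & (mu == c14_age)
        if hits.any():
            w = np.zeros_like(mu)
            w[hits] = 1.0
            return w
        if zero.all():
            raise DegenerateDensityError(
                f"zero-error measurement {c14_age} matches no grid year exactly"
            )
        var = np.where(zero, np.inf, var)  # exclude exact-zero years
    z2 = (c14_age - mu) ** 2 / var
    if z2.min() > _SUPPORT_NSIGMA**2:
        raise OutOfRangeError(
            f"14C age {c14_age} lies outside the curve support "
            f"(> {_SUPPORT_NSIGMA} sigma from every grid year)"
        )
    logw = -0.5 * z2 - 0.5 * np.log(var)
    return np.exp(logw - logw.max())


def calibrate_date(
    c14_age: float,
    sigma_lab: float,
    curve: CalibrationCurve,
    window=None,
    date_ref: str = "",
) -> CalibratedDensity:
    """Calibrate one measurement to a normalized calendar-year density.

    The likelihood combines lab and curve variance in quadrature.  With
    ``window`` (an (older, younger) cal BP pair) the density is computed and
    normalized on that sub-grid; otherwise on the full curve grid.
    """
    if sigma_lab < 0:
        raise ArgumentError("sigma_lab must be >= 0")
    sl = slice(None) if window is None else curve.subgrid(window)
    grid = curve.cal_bp[sl]
    w = _density_row(float(c14_age), float(sigma_lab), curve.c14_age[sl], curve.sigma[sl])
    return CalibratedDensity(cal_bp=grid, prob=w / w.sum(), date_ref=date_ref)


def calibrate_many(
    c14_ages, sigma_labs, curve: CalibrationCurve, window=None
) -> np.ndarray:
    """Vectorized calibration: one normalized density row per measurement.

    Returns an (n_dates, n_grid_years) array whose rows each sum to one.
    Used on the hot path of the Monte-Carlo test; identical numerics to
    :func:`calibrate_date` for strictly positive combined variance.
    """
    c14 = np.asarray(c14_ages, dtype=float)[:, None]
    sl = np.asarray(sigma_labs, dtype=float)[:, None]
    if np.any(sl < 0):
        raise ArgumentError("sigma_lab must be >= 0")
    gsl = slice(None) if window is None else curve.subgrid(window)
    mu = curve.c14_age[gsl][None, :]
    var = sl**2 + curve.sigma[gsl][None, :] ** 2
    if np.any(var == 0):
        raise ArgumentError("calibrate_many requires positive combined variance; "
                            "use calibrate_date for degenerate measurements")
    z2 = (c14 - mu) ** 2 / var
    if np.any(z2.min(axis=1) > _SUPPORT_NSIGMA**2):
        raise OutOfRangeError("one or more 14C ages lie outside the curve support")
    logw = -0.5 * z2 - 0.5 * np.log(var)
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    return w / w.sum(axis=1, keepdims=True)


def back_calibrate_sample(
    theta: int,
    curve: CalibrationCurve,
    sigma_pool,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Simulate the measurement a lab would report for calendar year ``theta``.

    The 14C age is drawn from N(mu(theta), s_c(theta)); the lab error is
    resampled uniformly with replacement from ``sigma_pool``.
    """
    pool = np.asarray(sigma_pool, dtype=float)
    if pool.size == 0:
        raise ArgumentError("sigma_pool must be non-empty")
    mu, sg = curve.mu_sigma(theta)
    c14 = float(rng.normal(mu, sg))
    sigma_lab = float(pool[rng.integers(pool.size)])
    return c14, sigma_lab


def back_calibrate_many(
    thetas, curve: CalibrationCurve, sigma_pool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`back_calibrate_sample` over many calendar years."""
    pool = np.asarray(sigma_pool, dtype=float)
    if pool.size == 0:
        raise ArgumentError("sigma_pool must be non-empty")
    mu, sg = curve.mu_sigma(np.asarray(thetas))
    c14 = rng.normal(mu, sg)
    sigma_lab = pool[rng.integers(pool.size, size=len(c14))]
    return c14, sigma_lab
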