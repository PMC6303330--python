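"""Null demographic models fitted to the pre-decline portion of an SPD.

The null model represents the trajectory a population proxy would have
followed had it never declined.  It is built in two stages:

1.  A segmented (two-piece) log-link quasi-Poisson regression locates the
    breakpoint — the calendar year where the SPD switches from rising to
    falling trend.  Quasi-Poisson point estimates coincide with Poisson
    maximum-likelihood estimates (dispersion rescales standard errors only),
    so each segment is fitted by Poisson iteratively reweighted least squares
    on the continuous SPD values, and the breakpoint is chosen by exhaustive
    deviance profiling over candidate years on the annual grid (coarse
    10-year pass, then 1-year refinement).
2.  A single log-link GLM fitted from the start of the analysis window to the
    breakpoint, then extrapolated over the whole grid, gives the exponential
    null.  Alternatively a five-parameter Richards (generalized logistic)
    curve is fitted by Gaussian maximum likelihood with multi-start
    optimization, giving a carrying-capacity-style null.

The internal time axis is years elapsed since the oldest grid year, so a
positive slope means growth toward the present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ArgumentError, FitError
from .spd import SPDSeries

__all__ = [
    "BreakpointFit",
    "ExponentialNull",
    "LogisticNull",
    "poisson_loglink_fit",
    "fit_breakpoint",
    "fit_exponential_null",
    "fit_logistic_null",
]


def poisson_loglink_fit(t, y, tol: float = 1e-10, max_iter: int = 100):
    """Poisson log-link IRLS for the two-parameter model log mu = b0 + b1*t.

    Accepts continuous nonnegative responses (quasi-likelihood point
    estimates).  Returns (b0, b1, deviance).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ArgumentError("responses must be nonnegative")
    ybar = y.mean()
    if ybar <= 0:
        raise ArgumentError("responses are all zero")
    tm = t.mean()
    tc = t - tm  # center for conditioning
    eta = np.log(np.clip(y, ybar * 1e-6, None))
    dev = np.inf
    for _ in range(max_iter):
        mu = np.exp(eta)
        w = mu
        z = eta + (y - mu) / mu
        sw = w.sum()
        swt = (w * tc).sum()
        swtt = (w * tc * tc).sum()
        swz = (w * z).sum()
        swtz = (w * tc * z).sum()
        det = sw * swtt - swt * swt
        if det <= 0 or not np.isfinite(det):
            raise FitError("singular IRLS system")
        b1 = (sw * swtz - swt * swz) / det
        b0c = (swz - swt * b1) / sw
        eta_new = b0c + b1 * tc
        mu_new = np.exp(eta_new)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu_new), 0.0)
        dev_new = 2.0 * np.sum(term - (y - mu_new))
        if abs(dev_new - dev) <= tol * (abs(dev_new) + tol):
            dev = dev_new
            eta = eta_new
            break
        dev = dev_new
        eta = eta_new
    return float(b0c - b1 * tm), float(b1), float(dev)


@dataclass(frozen=True)
class BreakpointFit:
    """Two-segment log-linear fit joined at the deviance-minimizing year."""

    breakpoint_cal_bp: int
    slope_pre: float            # per elapsed year, older segment
    slope_post: float           # per elapsed year, younger segment
    deviance: float
    no_interior_optimum: bool = False
    profile_cal_bp: np.ndarray | None = field(default=None, repr=False)
    profile_deviance: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class ExponentialNull:
    """Log-linear null extrapolated over the full grid.

    log(fitted) = beta0 + beta1 * t_elapsed; beta1 > 0 is growth toward the
    present.
    """

    beta0: float
    beta1: float
    cal_bp: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    fit_window: tuple[int, int] = (0, 0)

    @property
    def growth_rate(self) -> float:
        """Per-calendar-year growth rate toward the present."""
        return self.beta1


@dataclass(frozen=True)
class LogisticNull:
    """Richards (generalized logistic) null.

    y(t) = A + (K - A) / (1 + exp(-B*(t - M)))**(1/nu) on the elapsed-year
    axis; K is the upper asymptote (carrying-capacity analogue), M locates
    the inflection region, nu controls the asymmetry.
    """

    A: float
    K: float
    B: float
    M: float
    nu: float
    resid_sd: float
    converged: bool
    cal_bp: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    fit_window: tuple[int, int] = (0, 0)


def _segment_deviance(t, y, i_break):
    """Total deviance of two log-linear segments split at index i_break."""
    _, b1a, da = poisson_loglink_fit(t[: i_break + 1], y[: i_break + 1])
    _, b1b, db = poisson_loglink_fit(t[i_break:], y[i_break:])
    return da + db, b1a, b1b


def fit_breakpoint(
    spd: SPDSeries,
    search,
    coarse_step: int = 10,
    min_margin: int = 500,
) -> BreakpointFit:
    """Locate the rising-to-falling breakpoint by deviance profiling.

    ``search`` is an (older, younger) cal BP interval of candidate years; it
    must leave at least ``min_margin`` years of series on each side.  A flat
    profile or a minimum pinned to the search boundary is reported as
    ``no_interior_optimum`` (a single-slope series has no breakpoint).
    """
    old, young = max(search), min(search)
    if old > spd.oldest - min_margin or young < spd.youngest + min_margin:
        raise ArgumentError(
            f"search interval ({old}, {young}) must leave >= {min_margin} "
            f"years on each side of [{spd.oldest}, {spd.youngest}]"
        )
    y = spd.values
    if np.all(y == 0):
        raise ArgumentError("SPD is identically zero in the window")
    t = spd.t_elapsed()

    def dev_at(cal_year):
        return _segment_deviance(t, y, spd.oldest - int(cal_year))

    coarse = np.arange(old, young - 1, -coarse_step)
    devs = np.array([dev_at(c)[0] for c in coarse])
    i_best = int(np.argmin(devs))
    # refine +/- coarse_step at annual resolution
    lo = max(young, int(coarse[i_best]) - coarse_step)
    hi = min(old, int(coarse[i_best]) + coarse_step)
    fine = np.arange(hi, lo - 1, -1)
    fdevs = np.array([dev_at(c)[0] for c in fine])
    j = int(np.argmin(fdevs))
    best_year = int(fine[j])
    dev_best, b1a, b1b = dev_at(best_year)

    span = float(devs.max() - devs.min())
    flat = span <= 1e-9 * max(1.0, abs(float(devs.min())))
    on_boundary = best_year in (old, young)
    return BreakpointFit(
        breakpoint_cal_bp=best_year,
        slope_pre=b1a,
        slope_post=b1b,
        deviance=float(dev_best),
        no_interior_optimum=bool(flat or on_boundary),
        profile_cal_bp=coarse,
        profile_deviance=devs,
    )


def _fit_slice(spd: SPDSeries, fit_from: int, breakpoint: int):
    if fit_from <= breakpoint:
        raise ArgumentError("fit_from must be older than the breakpoint")
    i0 = spd.oldest - min(fit_from, spd.oldest)
    i1 = spd.oldest - breakpoint + 1
    if i1 - i0 < 10:
        raise ArgumentError("fewer than 10 grid years in the fit window")
    return i0, i1


def fit_exponential_null(spd: SPDSeries, fit_from: int, breakpoint: int) -> ExponentialNull:
    """Log-link GLM on [fit_from, breakpoint], extrapolated over the grid."""
    i0, i1 = _fit_slice(spd, fit_from, breakpoint)
    t = spd.t_elapsed()
    b0, b1, _ = poisson_loglink_fit(t[i0:i1], spd.values[i0:i1])
    fitted = np.exp(b0 + b1 * t)
    return ExponentialNull(
        beta0=b0, beta1=b1, cal_bp=spd.cal_bp, fitted=fitted,
        fit_window=(int(min(fit_from, spd.oldest)), int(breakpoint)),
    )


def _richards(t, A, K, B, M, nu):
    # exponent clipped to keep exp() finite far from the inflection
    z = np.clip(-B * (t - M), -700.0, 700.0)
    return A + (K - A) / (1.0 + np.exp(z)) ** (1.0 / nu)


def fit_logistic_null(
    spd: SPDSeries,
    fit_from: int,
    breakpoint: int,
    starts: int = 25,
    rng: np.random.Generator | None = None,
    fix_A_zero: bool = False,
) -> LogisticNull:
    """Richards-curve null by Gaussian maximum likelihood, multi-start.

    The residual variance is profiled out, so maximizing the likelihood
    reduces to nonlinear least squares; ``starts`` jittered initializations
    derived from data quantiles guard against local optima.  On exponential-
    phase data the upper asymptote is typically driven far above the series —
    the expected behaviour when no saturation is visible in the fit window.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    i0, i1 = _fit_slice(spd, fit_from, breakpoint)
    t = spd.t_elapsed()[i0:i1]
    y = spd.values[i0:i1]
    ymin, ymax = float(y.min()), float(y.max())
    yspan = max(ymax - ymin, 1e-12)
    tspan = float(t[-1] - t[0])

    def residuals(p):
        A, dK, logB, M, lognu = p
        return _richards(t, A, A + dK, np.exp(logB), M, np.exp(lognu)) - y

    bounds = (
        [0.0, 1e-12, np.log(1e-5), t[0] - 5 * tspan, np.log(1e-2)],
        [max(ymax, 1e-12), 1e6 * max(yspan, ymax, 1e-12), np.log(1.0), t[-1] + 5 * tspan, np.log(1e2)],
    )
    if fix_A_zero:
        bounds[1][0] = 1e-12

    best = None
    for k in range(starts):
        jit = rng.uniform(0.5, 2.0, size=5)
        p0 = np.array([
            0.0 if fix_A_zero else ymin * rng.uniform(0.0, 1.0),
            (ymax - 0.0) * jit[1] * rng.uniform(1.0, 5.0),
            np.log(np.clip(4.0 / max(tspan, 1.0) * jit[2], 1e-5, 1.0)),
            t[0] + tspan * rng.uniform(0.3, 1.5),
            np.log(np.clip(jit[4], 1e-2, 1e2)),
        ])
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            sol = least_squares(residuals, p0, bounds=bounds, method="trf",
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError(
            "all Richards starts failed; fall back to the exponential null"
        )
    A, dK, logB, M, lognu = best.x
    K, B, nu = A + dK, float(np.exp(logB)), float(np.exp(lognu))
    fitted = _richards(spd.t_elapsed(), A, K, B, M, nu)
    resid_sd = float(np.sqrt(2.0 * best.cost / y.size))
    return LogisticNull(
        A=float(A), K=float(K), B=B, M=float(M), nu=nu,
        resid_sd=resid_sd, converged=bool(best.success),
        cal_bp=spd.cal_bp, fitted=fitted,
        fit_window=(int(min(fit_from, spd.oldest)), int(breakpoint)),
    )
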