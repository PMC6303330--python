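"""Synthetic calibration curves, demographic scenarios, and date sets.

Every stage of the pipeline is testable without downloads: a scenario
specifies a known demographic history (exponential growth, growth with an
imposed bust, or a Richards logistic), calendar years are drawn in
proportion to it, and each year is pushed back through a calibration curve
with per-year curve error and lab errors resampled from an empirical pool —
the same forward model the Monte-Carlo test assumes.  Ground truth
(growth rate, bust interval, Richards parameters) is returned alongside
every generated date set so recovery can be asserted.

Default conditions mirror the study design this emulates: dates on a
20.0–10.0 ka cal BP window, lab errors of a few tens of 14C years, and date
densities of roughly 0.002–0.158 dates/yr (tens to hundreds of dates per
taxon over ten millennia).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calcurve import CalibrationCurve, _normalize_interval
from .calibrate import back_calibrate_many
from .dates import DateSet, RadiocarbonDate
from .errors import ArgumentError

__all__ = [
    "Scenario",
    "DEFAULT_SIGMA_POOL",
    "make_synthetic_curve",
    "population_curve",
    "draw_scenario_dates",
]

# Plausible late-Pleistocene lab-error spread (14C yr); resampled with
# replacement when a scenario does not supply its own pool.
DEFAULT_SIGMA_POOL = (30.0, 40.0, 50.0, 60.0, 80.0, 100.0)


@dataclass(frozen=True)
class Scenario:
    """A demographic history with known ground truth.

    kind:
        ``exponential`` — N(t) ∝ exp(r * t_elapsed);
        ``exponential_with_bust`` — same, multiplied by (1 - depth) inside
        ``bust_interval`` with linear ramps of ``ramp_years`` just outside
        each edge;
        ``richards`` — the five-parameter logistic (A, K, B, M, nu) on the
        elapsed-year axis.
    """

    kind: str = "exponential"
    window: tuple[int, int] = (20000, 10000)
    n_dates: int = 100
    seed: int = 0
    growth_rate: float = 0.0003
    bust_interval: tuple[int, int] | None = None
    bust_depth: float = 0.0
    ramp_years: int = 50
    richards: tuple[float, float, float, float, float] | None = None
    sigma_pool: tuple = DEFAULT_SIGMA_POOL
    label: str = "synthetic"

    def __post_init__(self):
        if self.kind not in ("exponential", "exponential_with_bust", "richards"):
            raise ArgumentError(f"unknown scenario kind {self.kind!r}")
        if self.n_dates < 1:
            raise ArgumentError("n_dates must be >= 1")
        if self.kind == "exponential_with_bust":
            if self.bust_interval is None or not (0.0 < self.bust_depth < 1.0):
                raise ArgumentError("bust scenarios need bust_interval and depth in (0,1)")
        if self.kind == "richards" and self.richards is None:
            raise ArgumentError("richards scenarios need (A, K, B, M, nu)")

    def ground_truth(self) -> dict:
        gt = {"kind": self.kind, "window": list(self.window), "n_dates": self.n_dates,
              "seed": self.seed}
        if self.kind.startswith("exponential"):
            gt["growth_rate"] = self.growth_rate
        if self.kind == "exponential_with_bust":
            gt["bust_interval"] = list(self.bust_interval)
            gt["bust_depth"] = self.bust_depth
            gt["breakpoint_cal_bp"] = int(max(self.bust_interval))
        if self.kind == "richards":
            gt["richards"] = list(self.richards)
        return gt


def make_synthetic_curve(
    kind: str = "identity",
    window=(21000, 9000),
    sigma: float = 10.0,
    wiggle_amp: float = 0.0,
    wiggle_period: float = 500.0,
    name: str | None = None,
) -> CalibrationCurve:
    """Identity or wiggly calibration curve with constant error ``sigma``.

    ``wiggly`` adds wiggle_amp * sin(2*pi*theta / wiggle_period) to the
    identity mean, mimicking the decadal-to-centennial structure of real
    curves.  A wiggle strong enough to make the mean non-monotone is allowed
    (real curves have reversals) but reported via a warning.
    """
    if sigma <= 0:
        raise ArgumentError("curve error sigma must be > 0")
    if kind not in ("identity", "wiggly"):
        raise ArgumentError(f"unknown curve kind {kind!r}")
    old, young = _normalize_interval(window)
    grid = np.arange(old, young - 1, -1, dtype=np.int64)
    mu = grid.astype(float)
    if kind == "wiggly":
        mu = mu + wiggle_amp * np.sin(2.0 * np.pi * grid / wiggle_period)
        if np.any(np.diff(mu[::-1]) <= 0):
            warnings.warn("synthetic curve mean is non-monotone (curve reversal)",
                          stacklevel=2)
    knots = pd.DataFrame({"cal_bp": grid[::-1].astype(float),
                          "c14_age": mu[::-1], "sigma": float(sigma)})
    return CalibrationCurve(cal_bp=grid, c14_age=mu,
                            sigma=np.full(grid.size, float(sigma)),
                            knots=knots, name=name or f"synthetic-{kind}")


def _bust_multiplier(grid, interval, depth, ramp):
    """1 outside the bust, (1-depth) inside, linear ramps just outside."""
    old, young = _normalize_interval(interval)
    m = np.ones(grid.size)
    inside = (grid <= old) & (grid >= young)
    m[inside] = 1.0 - depth
    if ramp > 0:
        older_ramp = (grid > old) & (grid <= old + ramp)
        m[older_ramp] = 1.0 - depth * (1.0 - (grid[older_ramp] - old) / ramp)
        younger_ramp = (grid < young) & (grid >= young - ramp)
        m[younger_ramp] = 1.0 - depth * (1.0 - (young - grid[younger_ramp]) / ramp)
    return m


def population_curve(scenario: Scenario, grid: np.ndarray) -> np.ndarray:
    """Relative population size per grid year under the scenario."""
    t = (grid[0] - grid).astype(float)
    if scenario.kind == "richards":
        A, K, B, M, nu = scenario.richards
        z = np.clip(-B * (t - M), -700.0, 700.0)
        return A + (K - A) / (1.0 + np.exp(z)) ** (1.0 / nu)
    pop = np.exp(scenario.growth_rate * t)
    if scenario.kind == "exponential_with_bust":
        pop = pop * _bust_multiplier(grid, scenario.bust_interval,
                                     scenario.bust_depth, scenario.ramp_years)
    return pop


def draw_scenario_dates(
    scenario: Scenario, curve: CalibrationCurve
) -> tuple[DateSet, dict]:
    """Generate a reproducible synthetic date set plus its ground truth.

    Calendar years are drawn with probability proportional to the scenario's
    population curve over its window, then back-calibrated through ``curve``
    with lab errors resampled from the scenario's sigma pool.
    """
    pool = np.asarray(scenario.sigma_pool, dtype=float)
    if pool.size == 0:
        raise ArgumentError("sigma_pool must be non-empty")
    sl = curve.subgrid(scenario.window)
    grid = curve.cal_bp[sl]
    pop = population_curve(scenario, grid)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed]))
    thetas = grid[rng.choice(grid.size, size=scenario.n_dates, p=pop / pop.sum())]
    c14, slab = back_calibrate_many(thetas, curve, pool, rng)
    dates = [
        RadiocarbonDate(
            lab_id=f"SYN-{i:05d}",
            c14_age=float(c14[i]),
            sigma_lab=float(slab[i]),
            taxon=scenario.label,
            context="paleontological",
        )
        for i in range(scenario.n_dates)
    ]
    ds = DateSet(dates=dates, label=scenario.label,
                 provenance=f"synthetic scenario kind={scenario.kind} seed={scenario.seed}")
    truth = scenario.ground_truth()
    truth["true_calendar_years"] = thetas.astype(int).tolist()
    return ds, truth
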