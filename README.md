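# paleospd

Radiocarbon summed probability distributions (SPDs) as population proxies,
with Monte-Carlo null-model tests for demographic booms and busts.

`paleospd` is for archaeologists and paleoecologists who use the *frequency*
of radiocarbon dates through time as a relative population signal — for
example, to ask whether late-Pleistocene megafauna populations in North
America collapsed before, during, or after human population growth. It
implements the full pipeline:

1. **Calibration.** A lab measurement (¹⁴C age ± σ_lab) becomes a calendar
   probability mass function on an annual grid: for calendar year θ with
   curve mean μ(θ) and curve error σ_c(θ),
   p(θ) ∝ N(c14_age | μ(θ), σ_lab² + σ_c(θ)²), normalized to 1.
   Curves are read from the standard IntCal-style `.14c` column format.
2. **Date vetting.** Duplicate lab numbers, anomalous-flagged entries,
   non-target depositional contexts, kill/scavenging-site associations, and
   multiple dates per individual are removed with a per-rule audit, plus
   regional (Southwest, Great Lakes, contiguous-US latitude cut) and
   per-taxon (> *n* dates in window) filters.
3. **SPD construction.** Normalized calibrated densities are summed per year
   and smoothed with a centered 200-year moving average over 10–20 ka.
4. **Null models.** A two-segment log-link quasi-Poisson regression finds the
   breakpoint where the SPD turns from rising to falling; a single log-link
   GLM fitted from 20 ka to the breakpoint and extrapolated over the grid is
   the exponential null (“the trend had the population never declined”).
   A five-parameter Richards (generalized logistic) null is available as an
   alternative.
5. **Monte-Carlo test.** The observed number of dates is redistributed under
   the null, back-calibrated, recalibrated, summed and smoothed (default 500
   simulations); per-year Z-scores against the simulated ensemble yield a 95%
   envelope. Years above/below it are booms/busts; a global p-value is the
   proportion of simulations whose area outside the envelope is at least the
   observed one.
6. **Taphonomic correction and SPD correlation.** Power-law survival
   correction s(t) = a·(t + c)^b and Spearman rank correlation between two
   SPDs (with an exact permutation p for tiny windows).
7. **Synthetic data.** Scenario generators (exponential growth, growth with
   an imposed bust, Richards) with known ground truth, so calibration,
   breakpoint, growth-rate and bust recovery are all testable end to end.

## Worked example

Detect an imposed 60% population bust (12.9–12.0 ka) from 100 synthetic
dates:

```python
from paleospd import (Scenario, draw_scenario_dates, make_synthetic_curve,
                      build_spd, fit_breakpoint, fit_exponential_null,
                      run_model_test, terminal_bust_onset)

curve = make_synthetic_curve("wiggly", (21000, 9000), sigma=15.0,
                             wiggle_amp=20.0, wiggle_period=400.0)
scenario = Scenario(kind="exponential_with_bust", window=(20000, 10000),
                    n_dates=100, seed=42, growth_rate=0.0003,
                    bust_interval=(12900, 12000), bust_depth=0.6)
dates, truth = draw_scenario_dates(scenario, curve)
spd = build_spd(dates, curve, window=(20000, 10000), smoothing=200)
bp = fit_breakpoint(spd, search=(19000, 11000))
null = fit_exponential_null(spd, fit_from=20000, breakpoint=bp.breakpoint_cal_bp)
result = run_model_test(spd, null, curve, n=spd.n_dates,
                        sigma_pool=dates.sigma_pool(), nsim=500,
                        reporting_window=(15000, 10000), seed=11)
print(f"breakpoint: {bp.breakpoint_cal_bp} cal BP")
print(f"pre-breakpoint growth rate: {null.beta1:.2e} per year")
print(f"global p: {result.global_p:.4f}")
print(f"bust intervals: {result.bust_intervals}")
print(f"terminal bust onset: {terminal_bust_onset(result)} cal BP")
```

prints

```
breakpoint: 11203 cal BP
pre-breakpoint growth rate: 2.55e-04 per year
global p: 0.0619
bust intervals: [(14427, 14225), (12881, 12847), (12844, 12837), (11977, 11903), (11880, 11878), (11863, 11854)]
terminal bust onset: 11863 cal BP
```

The imposed bust is recovered: a significant bust interval opens at 12,881
cal BP, 19 years after the true onset at 12,900, and the recovered
pre-breakpoint growth rate (2.55 × 10⁻⁴/yr) approximates the true 3 × 10⁻⁴/yr.
Intervals are (older, younger) cal BP pairs; the "terminal bust onset" is the
oldest year of the youngest significant bust interval. Because the scenario's
population *recovers* after 12.0 ka, the breakpoint and the post-12 ka
intervals reflect late-window sampling noise rather than the imposed bust —
exactly the kind of reading the per-year Z-score table is for.

The same pipeline is scriptable from the shell:

```sh
paleospd simulate --kind exponential_with_bust --n-dates 100 --seed 42 \
    --out-dates dates.csv --out-curve curve.14c --out-truth truth.json
paleospd modeltest config.yaml --out-json result.json --out-csv result.csv
paleospd correlate spd_a.csv spd_b.csv --window 15000 11700 --out corr.json
```

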