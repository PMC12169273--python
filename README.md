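# lstdyn

Temporal dynamics of land-surface-temperature (LST) responses to forest
loss: time-series change detection, paired-pixel contrast against
stable-forest backgrounds, abrupt/gradual/seasonal response metrics, and
surface-energy-balance attribution — with a seeded synthetic-scene
generator so the whole chain is testable against known truth without any
satellite downloads.

## The problem

Clearing or burning a forest changes the radiometric skin temperature of
the land surface through biophysical pathways (albedo, evapotranspiration,
roughness).  Static before/after comparisons conflate the *immediate*
response with the *gradual* response of whatever the land becomes next —
regrowing forest, cropland, pavement — so studies disagree on sign and
magnitude.  `lstdyn` separates the two, and additionally tracks how the
*seasonal cycle* (amplitude and phase) shifts after loss.  It is written
for researchers in land-surface biophysics and ecological remote sensing
working with 10-day composite series (36 steps per year) at ~1-km
resolution.

## The method

1. **Decomposition + change detection.**  Each pixel series is modelled as
   `y_t = T_t + S_t + e_t` with a piecewise-linear trend `T` (≤ 3
   breakpoints) and a segmented second-order harmonic seasonal component
   `S` (period 36, ≤ 3 breakpoints).  Fitting is deterministic segmented
   least squares: exact dynamic programming per component, BIC for the
   number of breaks, alternation between components, and a joint OLS
   refinement.  Break-date confidence intervals come from a residual
   bootstrap.
2. **Pairing.**  A loss event is analysed only if a detected break matches
   it (loss year inside the break's CI, ≤ 2 years apart).  Controls are
   stable-forest pixels 25–50 km away at similar elevation; their shared
   climate signal is differenced away (mean or inverse-distance weights).
3. **Response metrics.**  With annual trend means relative to the year
   before the loss window: ΔT(y) per year, the abrupt change ΔT₁ (one year
   after the window), the gradual change ΔT_slope (K per decade), monthly
   seasonal changes ΔS, amplitude change ΔS_A (max − min of the seasonal
   cycle) and phase change ΔS_ϕ (days, negative = earlier).  The signs of
   (ΔT₁, ΔT_slope) against margins (0.001 K, 0.002 K/decade) label each
   event: enhanced/abrupt/attenuated warming or cooling, or insignificant.
4. **Attribution.**  Albedo and latent-heat changes convert to equivalent
   LST changes via the Taylor sensitivity `1/(4εσ·LST³)`:
   `ΔT_α = −sens·SW↓·Δα`, `ΔT_LE = −sens·ΔLE` (ΔET converted at
   λ_v = 2.45×10⁶ J kg⁻¹); sensible heat is the exact residual
   `ΔT_H = ΔT − ΔT_α − ΔT_LE`.
5. **Reporting.**  Zonal means (climate regions SM/LL/NM/boreal and 5°
   latitude bins) with Student-t 95% CIs and t tests against zero.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Detect an abrupt change in a single noisy series with a +0.8 K step
injected in 2006:

```python
import numpy as np
from lstdyn import make_pixel_series, fit_decomposition

series = make_pixel_series(
    trend_spec=[(0, 290.0, 0.0), (180, 290.8, -0.02)],   # +0.8 K step in 2006
    harmonic_spec=(8.0, 0.5, 0.6, 0.1),                  # annual cycle ~16 K
    noise_sd=0.5, missing_fraction=0.05, seed=42, n_years=12)

result = fit_decomposition(series, bootstrap_reps=100, seed=0)
for b in result.breakpoints:
    lo, hi = b.ci_years(series.start_year)
    print(f"{b.component} break in {b.year(series.start_year)} "
          f"(95% CI {lo}-{hi}), magnitude {b.magnitude:+.2f} K")
atm = result.annual_trend_means()
print("annual trend means 2005-2008:",
      np.round(atm.loc[2005:2008].to_numpy(), 2))
```

prints

```
trend break in 2006 (95% CI 2005-2006), magnitude +0.81 K
annual trend means 2005-2008: [289.92 290.71 290.68 290.65]
```

— the detector localizes the 2006 step, estimates its size (+0.81 K vs
+0.8 K injected), and the annual trend means show the jump between 2005
and 2006 followed by the slight imposed cooling drift.

The full chain on a synthetic scene, from the shell:

```bash
lstdyn run-all --seed 11 --out results/demo
```

writes `pairs.csv` (event/background bookkeeping and exclusions),
`metrics.csv` (per-event ΔT₁, ΔT_slope, ΔS_A, ΔS_ϕ, pattern label, and the
ΔT series), `attribution.csv` (yearly ΔT_α/ΔT_LE/ΔT_H and monthly seasonal
analogues), `zonal_summary.csv`, `trajectories.csv`, and a `run.json` log.
`lstdyn simulate|decompose|pair|quantify|attribute|report` expose the
individual stages; scene configurations are YAML (see
`lstdyn.SceneConfig`).

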