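"""Trend/seasonal decomposition of 10-day series with abrupt-change detection.

The observation model is additive::

    y_t = T_t + S_t + e_t

where the trend ``T`` is piecewise linear with up to ``m`` breakpoints, the
seasonal component ``S`` is a piecewise second-order harmonic (period 36
steps = 1 year) with up to ``q`` breakpoints, and ``e`` is the remainder.
Both components may change abruptly at (different) break dates — the model
family used by BEAST-style change detection on satellite land-surface
temperature records.

Fitting is a deterministic surrogate for the Bayesian samplers usually
attached to this model family: alternating conditional optimization between
the two components, each step solved exactly by dynamic programming over a
grid of admissible break dates with the number of breaks chosen by BIC (see
:mod:`lstdyn._segment`).  Break-date confidence intervals come from a
residual bootstrap with the break counts held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._segment import Segmenter, design_harmonic, design_trend
from .timeseries import STEPS_PER_YEAR, TimeSeries10d

__all__ = [
    "TrendSegment",
    "SeasonalSegment",
    "Breakpoint",
    "DecompositionResult",
    "fit_decomposition",
    "fit_windowed_decomposition",
    "evaluate_components",
    "annual_trend_means",
]


@dataclass
class TrendSegment:
    """Linear trend piece: value(t) = intercept + slope * t_years.

    ``t_years`` is decimal years since the series start (step midpoints);
    ``slope`` is therefore in K per year.
    """

    start_step: int
    end_step: int          # exclusive
    intercept: float
    slope: float

    @property
    def slope_per_step(self) -> float:
        return self.slope / STEPS_PER_YEAR


@dataclass
class SeasonalSegment:
    """Second-order harmonic piece with a global phase origin.

    ``coeffs`` are (γ₁, δ₁, γ₂, δ₂) for sin/cos at the annual and
    semi-annual frequencies.
    """

    start_step: int
    end_step: int
    coeffs: np.ndarray


@dataclass
class Breakpoint:
    """An abrupt change in one component, with a bootstrap confidence interval."""

    component: str         # "trend" | "seasonal"
    step: int              # first step of the new regime
    ci_low: int
    ci_high: int
    magnitude: float       # component value just after minus just before (K)

    def year(self, start_year: int, steps_per_year: int = STEPS_PER_YEAR) -> int:
        return start_year + self.step // steps_per_year

    def ci_years(self, start_year: int, steps_per_year: int = STEPS_PER_YEAR) -> tuple[int, int]:
        return (start_year + self.ci_low // steps_per_year,
                start_year + self.ci_high // steps_per_year)


@dataclass
class DecompositionResult:
    """Fitted decomposition of one pixel's series."""

    start_year: int
    n_steps: int
    trend_segments: list[TrendSegment]
    seasonal_segments: list[SeasonalSegment]
    breakpoints: list[Breakpoint]
    residuals: np.ndarray      # NaN at missing steps
    rss: float
    bic: float
    steps_per_year: int = STEPS_PER_YEAR
    windowed: bool = False     # True for forced-window refits (no detection)

    # -- evaluation ----------------------------------------------------
    def trend_values(self, steps: np.ndarray | None = None) -> np.ndarray:
        """Trend component at integer steps (model-defined everywhere)."""
        steps = self._check_steps(steps)
        starts = np.array([s.start_step for s in self.trend_segments])
        idx = np.clip(np.searchsorted(starts, steps, side="right") - 1, 0, None)
        t = (steps + 0.5) / self.steps_per_year
        a = np.array([s.intercept for s in self.trend_segments])[idx]
        b = np.array([s.slope for s in self.trend_segments])[idx]
        return a + b * t

    def seasonal_values(self, steps: np.ndarray | None = None) -> np.ndarray:
        """Seasonal component at (possibly fractional) steps."""
        steps = self._check_steps(steps, allow_fractional=True)
        starts = np.array([s.start_step for s in self.seasonal_segments])
        idx = np.clip(np.searchsorted(starts, steps, side="right") - 1, 0, None)
        u = 2.0 * np.pi * np.asarray(steps, dtype=float) / self.steps_per_year
        C = np.vstack([s.coeffs for s in self.seasonal_segments])[idx]
        basis = np.column_stack([np.sin(u), np.cos(u), np.sin(2 * u), np.cos(2 * u)])
        return np.einsum("np,np->n", C, basis)

    def _check_steps(self, steps, allow_fractional: bool = False) -> np.ndarray:
        if steps is None:
            return np.arange(self.n_steps)
        steps = np.atleast_1d(np.asarray(steps, dtype=float if allow_fractional else int))
        if steps.min() < 0 or steps.max() > self.n_steps:
            raise ValueError("steps outside the fitted span")
        return steps

    def annual_trend_means(self) -> pd.Series:
        """Mean of the trend component over each calendar year's 36 steps."""
        tv = self.trend_values()
        n_years = self.n_steps // self.steps_per_year
        means = tv[: n_years * self.steps_per_year].reshape(n_years, -1).mean(axis=1)
        years = self.start_year + np.arange(n_years)
        return pd.Series(means, index=years, name="trend_mean")

    def breaks_for(self, component: str) -> list[Breakpoint]:
        return [b for b in self.breakpoints if b.component == component]


def evaluate_components(result: DecompositionResult,
                        steps: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Trend and seasonal component values over ``steps`` (default: full span)."""
    return result.trend_values(steps), result.seasonal_values(steps)


def annual_trend_means(result: DecompositionResult) -> pd.Series:
    return result.annual_trend_means()


# ---------------------------------------------------------------------------
def _trend_segments_from(fit, steps_per_year: int) -> list[TrendSegment]:
    return [
        TrendSegment(int(i), int(j), float(b[0]), float(b[1]))
        for i, j, b in zip(fit.bounds[:-1], fit.bounds[1:], fit.betas)
    ]


def _seasonal_segments_from(fit) -> list[SeasonalSegment]:
    return [
        SeasonalSegment(int(i), int(j), np.asarray(b, dtype=float))
        for i, j, b in zip(fit.bounds[:-1], fit.bounds[1:], fit.betas)
    ]


def _harmonic_amplitude(coeffs: np.ndarray, steps_per_year: int = STEPS_PER_YEAR) -> float:
    """Max − min of the harmonic over one cycle (dense evaluation)."""
    u = 2.0 * np.pi * np.linspace(0.0, 1.0, 721)
    s = (coeffs[0] * np.sin(u) + coeffs[1] * np.cos(u)
         + coeffs[2] * np.sin(2 * u) + coeffs[3] * np.cos(2 * u))
    return float(s.max() - s.min())


def _make_breakpoints(tfit, sfit, steps_per_year: int) -> list[Breakpoint]:
    out: list[Breakpoint] = []
    tsegs = _trend_segments_from(tfit, steps_per_year)
    for k, step in enumerate(tfit.break_steps):
        tb = step / steps_per_year
        before, after = tsegs[k], tsegs[k + 1]
        mag = (after.intercept + after.slope * tb) - (before.intercept + before.slope * tb)
        out.append(Breakpoint("trend", int(step), int(step), int(step), float(mag)))
    ssegs = _seasonal_segments_from(sfit)
    for k, step in enumerate(sfit.break_steps):
        mag = (_harmonic_amplitude(ssegs[k + 1].coeffs)
               - _harmonic_amplitude(ssegs[k].coeffs))
        out.append(Breakpoint("seasonal", int(step), int(step), int(step), float(mag)))
    return out


def fit_decomposition(series: TimeSeries10d,
                      max_trend_breaks: int = 3,
                      max_seasonal_breaks: int = 3,
                      min_trend_seg: int = 72,
                      min_seasonal_seg: int = 36,
                      break_stride: int = 3,
                      ci_level: float = 0.95,
                      bootstrap_reps: int = 100,
                      seed: int | None = None,
                      max_iter: int = 5,
                      tol: float = 1e-8) -> DecompositionResult:
    """Fit the segmented trend + harmonic model and detect abrupt changes.

    Parameters
    ----------
    series : TimeSeries10d
        Observations; NaN marks missing composites.
    max_trend_breaks, max_seasonal_breaks : int
        Upper bounds on the number of abrupt changes per component (the
        number actually used is chosen by BIC).
    min_trend_seg, min_seasonal_seg : int
        Minimum segment lengths in steps (defaults: 2 years for the trend so
        a slope is identifiable, 1 year for the four harmonic coefficients).
    break_stride : int
        Candidate break dates are multiples of this step count (~monthly by
        default); disturbance dates are interpreted at annual resolution
        downstream, so sub-monthly placement buys nothing.
    bootstrap_reps : int
        Residual-bootstrap replicates for break-date confidence intervals;
        0 skips the bootstrap (point CIs), useful for background pixels
        whose breaks are never matched against loss events.
    seed : int, optional
        Seed for the bootstrap resampling.

    Notes
    -----
    Alternating conditional optimization: the series is first detrended by a
    global linear fit, then the seasonal segmentation is fitted to the
    detrended series and the trend segmentation to the deseasonalized
    series, repeating until the joint RSS stabilizes (≤ ``max_iter`` outer
    iterations).  Each conditional step is an exact dynamic program; ties in
    RSS resolve to the earliest break date, so the fit is deterministic.
    """
    series.require_coverage(2.0)
    y = series.values
    valid = np.isfinite(y)
    n = series.n_steps
    spy = series.steps_per_year

    Xt, Xs = design_trend(n, spy), design_harmonic(n, spy)
    seg_t = Segmenter(Xt, valid, min_trend_seg, break_stride)
    seg_s = Segmenter(Xs, valid, min_seasonal_seg, break_stride)

    # Alternation is order-sensitive when one component alone carries the
    # abrupt change (the other's segmentation can soak up the mismatch on
    # the first pass), so run both schedules and keep the lower joint BIC.
    fits = [
        _alternate(y, valid, seg_t, seg_s, max_trend_breaks,
                   max_seasonal_breaks, first, max_iter, tol)
        for first in ("trend", "seasonal")
    ]
    tfit, sfit, rss = min(
        fits, key=lambda f: _joint_bic(f[2], f[0].n_breaks, f[1].n_breaks,
                                       seg_t.n_eff))
    tfit, sfit, rss = _joint_refine(y, valid, Xt, Xs, tfit, sfit)

    breakpoints = _make_breakpoints(tfit, sfit, spy)
    if bootstrap_reps > 0 and breakpoints:
        _bootstrap_cis(breakpoints, y, valid, tfit, sfit, seg_t, seg_s,
                       max_trend_breaks, max_seasonal_breaks,
                       ci_level, bootstrap_reps, seed)

    residuals = np.where(valid, y - tfit.values - sfit.values, np.nan)
    return DecompositionResult(
        start_year=series.start_year,
        n_steps=n,
        trend_segments=_trend_segments_from(tfit, spy),
        seasonal_segments=_seasonal_segments_from(sfit),
        breakpoints=breakpoints,
        residuals=residuals,
        rss=rss,
        bic=tfit.bic + sfit.bic,
        steps_per_year=spy,
    )


def _joint_bic(rss: float, m: int, q: int, n_eff: float) -> float:
    from ._segment import SIGMA_FLOOR

    k = 2 * (m + 1) + m + 4 * (q + 1) + q
    n = max(n_eff, 1.0)
    return n * np.log(max(rss / n, SIGMA_FLOOR**2)) + k * np.log(n)


def _alternate(y, valid, seg_t, seg_s, max_tb, max_sb, first, max_iter, tol):
    """Alternating conditional optimization, seeding one component first."""
    tfit = seg_t.fit(y, max_breaks=0)             # global line
    if first == "trend":
        sfit = seg_s.fit(y - tfit.values, max_breaks=0)
        tfit = seg_t.fit(y - sfit.values, max_tb)
    else:
        sfit = seg_s.fit(y - tfit.values, max_sb)
        tfit = seg_t.fit(y - sfit.values, max_tb)
    prev_rss, rss = np.inf, np.inf
    for _ in range(max_iter):
        sfit = seg_s.fit(y - tfit.values, max_sb)
        tfit = seg_t.fit(y - sfit.values, max_tb)
        resid = np.where(valid, y - tfit.values - sfit.values, 0.0)
        rss = float(resid @ resid)
        if abs(prev_rss - rss) < tol:
            break
        prev_rss = rss
    return tfit, sfit, rss


def _joint_refine(y, valid, Xt, Xs, tfit, sfit):
    """Exact joint OLS given both segmentations (one lstsq over all pieces).

    The alternation fixes the break dates; re-solving all segment
    coefficients jointly removes the residual coupling between trend and
    harmonics that the conditional steps leave behind.
    """
    n = y.size
    cols, owners = [], []
    for k, (i, j) in enumerate(zip(tfit.bounds[:-1], tfit.bounds[1:])):
        block = np.zeros((n, Xt.shape[1]))
        block[i:j] = Xt[i:j]
        cols.append(block)
        owners.append(("t", k))
    for k, (i, j) in enumerate(zip(sfit.bounds[:-1], sfit.bounds[1:])):
        block = np.zeros((n, Xs.shape[1]))
        block[i:j] = Xs[i:j]
        cols.append(block)
        owners.append(("s", k))
    X = np.concatenate(cols, axis=1)
    yz = np.where(valid, y, 0.0)
    coef, _, _, _ = np.linalg.lstsq(X[valid], yz[valid], rcond=None)

    pos = 0
    for comp, k in owners:
        if comp == "t":
            tfit.betas[k] = coef[pos:pos + Xt.shape[1]]
            i, j = tfit.bounds[k], tfit.bounds[k + 1]
            tfit.values[i:j] = Xt[i:j] @ tfit.betas[k]
            pos += Xt.shape[1]
        else:
            sfit.betas[k] = coef[pos:pos + Xs.shape[1]]
            i, j = sfit.bounds[k], sfit.bounds[k + 1]
            sfit.values[i:j] = Xs[i:j] @ sfit.betas[k]
            pos += Xs.shape[1]
    resid = np.where(valid, y - tfit.values - sfit.values, 0.0)
    return tfit, sfit, float(resid @ resid)


def _bootstrap_cis(breakpoints, y, valid, tfit, sfit, seg_t, seg_s,
                   max_tb, max_sb, ci_level, reps, seed) -> None:
    """Residual-bootstrap confidence intervals for break dates (in place).

    Break counts are held at the selected values; each replicate re-estimates
    break *positions* for one component with the other component fixed.
    """
    rng = np.random.default_rng(seed)
    fitted = tfit.values + sfit.values
    resid = (y - fitted)[valid]
    n = y.size
    alpha = (1.0 - ci_level) / 2.0

    t_steps = np.empty((reps, tfit.n_breaks), dtype=int)
    s_steps = np.empty((reps, sfit.n_breaks), dtype=int)
    for r in range(reps):
        ystar = fitted + rng.choice(resid, size=n, replace=True)
        if tfit.n_breaks:
            rt = seg_t.fit(ystar - sfit.values, max_tb, n_breaks=tfit.n_breaks)
            t_steps[r] = np.sort(rt.break_steps)
        if sfit.n_breaks:
            rs = seg_s.fit(ystar - tfit.values, max_sb, n_breaks=sfit.n_breaks)
            s_steps[r] = np.sort(rs.break_steps)

    for comp, steps in (("trend", t_steps), ("seasonal", s_steps)):
        bps = [b for b in breakpoints if b.component == comp]
        for k, bp in enumerate(bps):
            lo, hi = np.percentile(steps[:, k], [100 * alpha, 100 * (1 - alpha)])
            bp.ci_low = int(min(np.floor(lo), bp.step))
            bp.ci_high = int(max(np.ceil(hi), bp.step))


# ---------------------------------------------------------------------------
def fit_windowed_decomposition(series: TimeSeries10d,
                               window: tuple[int, int],
                               period: tuple[int, int]) -> DecompositionResult:
    """Before/after component fit with a forced break at the loss window.

    Once a loss window is fixed, the response metrics contrast components
    *before* the window with components *after* it.  This fit estimates a
    single line plus second-order harmonics jointly by OLS on the pre-window
    span of the study period, and again on the post-window span, rather than
    relying on the detection fit having segmented exactly at the window.

    Parameters
    ----------
    window : (start_year, end_year)
        Loss window (inclusive years).
    period : (start_year, end_year)
        Study period (inclusive years); must contain the window, with
        ≥ 2 pre-window years and ≥ 1 post-window year.

    Returns
    -------
    DecompositionResult
        Two trend segments and two seasonal segments splitting at the window
        start; the pre-window model is extended back to the series start and
        the post-window model forward to the series end, so evaluation is
        defined everywhere (only the study period is meaningful).
    """
    ws, we = window
    ps, pe = period
    if not (ps <= ws <= we <= pe):
        raise ValueError("study period must contain the loss window")
    if ws - ps < 2:
        raise ValueError("need at least two pre-window years in the study period")
    if pe - we < 1:
        raise ValueError("need at least one post-window year in the study period")
    if ps < series.start_year or pe > series.end_year:
        raise ValueError("study period outside the series span")

    y = series.values
    valid = np.isfinite(y)
    n, spy = series.n_steps, series.steps_per_year
    X = np.column_stack([design_trend(n, spy), design_harmonic(n, spy)])

    def span_fit(y0: int, y1: int) -> np.ndarray:
        """OLS coefficients on calendar years [y0, y1] inclusive."""
        i = (y0 - series.start_year) * spy
        j = (y1 - series.start_year + 1) * spy
        m = valid[i:j]
        if m.sum() < X.shape[1] + 2:
            raise ValueError("insufficient non-missing data in span")
        coef, _, _, _ = np.linalg.lstsq(X[i:j][m], y[i:j][m], rcond=None)
        return coef

    pre = span_fit(ps, ws - 1)
    post = span_fit(we + 1, pe)
    split = (ws - series.start_year) * spy

    trend_segments = [
        TrendSegment(0, split, float(pre[0]), float(pre[1])),
        TrendSegment(split, n, float(post[0]), float(post[1])),
    ]
    seasonal_segments = [
        SeasonalSegment(0, split, pre[2:].copy()),
        SeasonalSegment(split, n, post[2:].copy()),
    ]
    result = DecompositionResult(
        start_year=series.start_year, n_steps=n,
        trend_segments=trend_segments, seasonal_segments=seasonal_segments,
        breakpoints=[], residuals=np.full(n, np.nan),
        rss=np.nan, bic=np.nan, steps_per_year=spy, windowed=True,
    )
    tv, sv = evaluate_components(result)
    result.residuals = np.where(valid, y - tv - sv, np.nan)
    result.rss = float(np.nansum(result.residuals[valid] ** 2))
    return result
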