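"""Dynamic LST response metrics for a paired sample.

All metrics contrast the forest-loss pixel with the combined signal of its
background controls (simple mean or inverse-distance weighting), relative to
a baseline one year before the loss window:

* ΔT(y): background-corrected change in the annual mean of the trend
  component, per post-baseline year;
* ΔT₁: ΔT one year after the loss window — the abrupt response;
* ΔT_slope: OLS slope of the post-loss ΔT trajectory, in K per decade — the
  gradual response;
* ΔS(month): background-corrected change in the seasonal component per
  calendar month (three composite steps each);
* ΔS_A, ΔS_ϕ: changes in seasonal-cycle amplitude (max − min of the
  seasonal component) and phase (day of year of the fitted first-harmonic
  maximum; negative = advance);
* a temporal-pattern label from the signs of (ΔT₁, ΔT_slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import DecompositionResult
from .pairing import LossWindow
from .timeseries import DAYS_PER_STEP, STEPS_PER_MONTH, STEPS_PER_YEAR

__all__ = [
    "ResponseMetrics", "PatternLabel", "delta_trend_series", "abrupt_change",
    "gradual_slope", "delta_seasonal", "seasonal_cycle_changes",
    "classify_pattern", "compute_response_metrics",
]

DEFAULT_DT1_MARGIN_K = 0.001
DEFAULT_SLOPE_MARGIN_K_PER_DECADE = 0.002


@dataclass
class PatternLabel:
    """Temporal pattern of ΔT: sign of the abrupt change × sign of the slope."""

    label: str
    sign_dt1: str              # "+", "-", "~"
    sign_slope: str
    dt1_margin: float
    slope_margin: float


@dataclass
class ResponseMetrics:
    dT: pd.Series              # by calendar year over the study period
    dt1: float                 # K
    dt_slope: float            # K per decade (NaN if post span < 3 years)
    dS: pd.Series              # by month 1..12, K
    rel_dS: pd.Series          # month-wise ΔS / |S_before| diagnostics, %
    dS_A: float                # K
    rel_dS_A: float            # %
    dS_phi_days: float         # negative = advance
    phase_ok: bool
    pattern: PatternLabel | None


# ---------------------------------------------------------------------------
def _weights(n: int, distances_m: np.ndarray | None, weighting: str) -> np.ndarray:
    if weighting == "mean":
        return np.full(n, 1.0 / n)
    if weighting == "idw":
        if distances_m is None or len(distances_m) != n:
            raise ValueError("IDW weighting needs one distance per background")
        w = 1.0 / np.asarray(distances_m, dtype=float)
        return w / w.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def _delta_annual(result: DecompositionResult, window: LossWindow,
                  period: tuple[int, int]) -> pd.Series:
    """Annual trend means relative to the year before the window."""
    atm = result.annual_trend_means()
    base = atm.loc[window.start - 1]
    years = np.arange(period[0], period[1] + 1)
    return atm.loc[years] - base


def delta_trend_series(target: DecompositionResult,
                       backgrounds: list[DecompositionResult],
                       window: LossWindow, period: tuple[int, int],
                       weighting: str = "mean",
                       distances_m: np.ndarray | None = None) -> pd.Series:
    """ΔT by year: target minus combined-background annual trend change."""
    if not backgrounds:
        raise ValueError("no valid background pixels")
    d_o = _delta_annual(target, window, period)
    w = _weights(len(backgrounds), distances_m, weighting)
    d_bg = sum(wi * _delta_annual(bg, window, period)
               for wi, bg in zip(w, backgrounds))
    out = d_o - d_bg
    out.name = "dT"
    return out


def abrupt_change(dT: pd.Series, window: LossWindow) -> float:
    """ΔT₁: the ΔT value one year after the loss window ends."""
    year = window.end + 1
    if year not in dT.index:
        raise ValueError("post-loss span shorter than one year")
    return float(dT.loc[year])


def gradual_slope(dT: pd.Series, window: LossWindow,
                  min_years: int = 3) -> float:
    """ΔT_slope: OLS slope of the post-loss ΔT trajectory, K per decade.

    Because the baseline is a constant, the slope of ΔT equals the
    difference between the target's and the combined background's post-loss
    annual trend slopes.
    """
    post = dT.loc[dT.index >= window.end + 1]
    if len(post) < min_years:
        raise ValueError(f"need at least {min_years} post-loss years")
    res = stats.linregress(post.index.to_numpy(dtype=float), post.to_numpy())
    return float(res.slope * 10.0)


# ---------------------------------------------------------------------------
def _span_years(window: LossWindow, period: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    pre = np.arange(period[0], window.start)
    post = np.arange(window.end + 1, period[1] + 1)
    return pre, post


def _monthly_seasonal(result: DecompositionResult, years: np.ndarray) -> np.ndarray:
    """Mean seasonal component per calendar month over the given years."""
    spy = result.steps_per_year
    steps = np.concatenate([
        np.arange((y - result.start_year) * spy, (y - result.start_year + 1) * spy)
        for y in years])
    vals = result.seasonal_values(steps).reshape(len(years), spy).mean(axis=0)
    return vals.reshape(12, STEPS_PER_MONTH).mean(axis=1)


def _annual_amplitude(result: DecompositionResult, years: np.ndarray) -> float:
    """Mean over years of (max − min) of the seasonal component (dense)."""
    spy = result.steps_per_year
    amps = []
    for y in years:
        i0 = (y - result.start_year) * spy
        t = np.linspace(i0, i0 + spy, 361)
        s = result.seasonal_values(t)
        amps.append(s.max() - s.min())
    return float(np.mean(amps))


def _phase_day(result: DecompositionResult, years: np.ndarray,
               min_amp: float = 1e-6) -> tuple[float, bool]:
    """Day of year of the first-harmonic maximum, averaged over years.

    The seasonal component over each year is projected onto the annual
    sin/cos pair (an exact discrete Fourier coefficient at 36 samples); the
    mean coefficient vector across years gives the phase.  Returns
    (day, ok); ok is False when the first harmonic is degenerate.
    """
    spy = result.steps_per_year
    a1 = b1 = 0.0
    for y in years:
        i0 = (y - result.start_year) * spy
        steps = np.arange(i0, i0 + spy)
        s = result.seasonal_values(steps)
        u = 2.0 * np.pi * steps / spy
        a1 += 2.0 / spy * float(s @ np.sin(u))
        b1 += 2.0 / spy * float(s @ np.cos(u))
    a1, b1 = a1 / len(years), b1 / len(years)
    if np.hypot(a1, b1) < min_amp:
        return np.nan, False
    t_max = (np.pi / 2.0 - np.arctan2(b1, a1)) / (2.0 * np.pi) * spy
    return float((t_max % spy) * DAYS_PER_STEP), True


def _wrap_days(d: float, period: float = 365.0) -> float:
    """Wrap a day difference to (−period/2, period/2]."""
    return float(-((period / 2.0 - d) % period) + period / 2.0)


def delta_seasonal(target: DecompositionResult,
                   backgrounds: list[DecompositionResult],
                   window: LossWindow, period: tuple[int, int],
                   weighting: str = "mean",
                   distances_m: np.ndarray | None = None) -> pd.Series:
    """ΔS by calendar month: post-window minus pre-window seasonal component,
    background-corrected.  Mean-zero across the 12 months by construction."""
    if not backgrounds:
        raise ValueError("no valid background pixels")
    pre, post = _span_years(window, period)
    w = _weights(len(backgrounds), distances_m, weighting)

    def delta(res: DecompositionResult) -> np.ndarray:
        return _monthly_seasonal(res, post) - _monthly_seasonal(res, pre)

    d = delta(target) - sum(wi * delta(bg) for wi, bg in zip(w, backgrounds))
    return pd.Series(d, index=pd.RangeIndex(1, 13, name="month"), name="dS")


@dataclass
class SeasonalCycleChange:
    dS_A: float
    rel_dS_A: float            # % of the target's pre-loss amplitude
    dS_phi_days: float
    phase_ok: bool


def seasonal_cycle_changes(target: DecompositionResult,
                           backgrounds: list[DecompositionResult],
                           window: LossWindow, period: tuple[int, int],
                           weighting: str = "mean",
                           distances_m: np.ndarray | None = None
                           ) -> SeasonalCycleChange:
    """Background-corrected amplitude and phase changes of the seasonal cycle."""
    if not backgrounds:
        raise ValueError("no valid background pixels")
    pre, post = _span_years(window, period)
    w = _weights(len(backgrounds), distances_m, weighting)

    def amp_change(res: DecompositionResult) -> float:
        return _annual_amplitude(res, post) - _annual_amplitude(res, pre)

    def phase_change(res: DecompositionResult) -> tuple[float, bool]:
        p0, ok0 = _phase_day(res, pre)
        p1, ok1 = _phase_day(res, post)
        if not (ok0 and ok1):
            return np.nan, False
        return _wrap_days(p1 - p0), True

    dA_o = amp_change(target)
    dA = dA_o - sum(wi * amp_change(bg) for wi, bg in zip(w, backgrounds))

    dphi_o, ok = phase_change(target)
    dphi_bg, oks = 0.0, True
    for wi, bg in zip(w, backgrounds):
        v, vok = phase_change(bg)
        oks = oks and vok
        if vok:
            dphi_bg += wi * v
    phase_ok = bool(ok and oks)
    dphi = _wrap_days(dphi_o - dphi_bg) if phase_ok else np.nan

    amp_before = _annual_amplitude(target, pre)
    rel = dA / amp_before * 100.0 if amp_before > 0 else np.nan
    return SeasonalCycleChange(float(dA), float(rel), dphi, phase_ok)


# ---------------------------------------------------------------------------
def classify_pattern(dt1: float, dt_slope: float,
                     dt1_margin: float = DEFAULT_DT1_MARGIN_K,
                     slope_margin: float = DEFAULT_SLOPE_MARGIN_K_PER_DECADE
                     ) -> PatternLabel:
    """Temporal-pattern taxonomy from the signs of ΔT₁ and ΔT_slope.

    |ΔT₁| within its margin collapses to "insignificant" regardless of the
    slope; otherwise warming/cooling is qualified as enhanced, abrupt (slope
    within its margin), or attenuated.
    """
    if not (np.isfinite(dt1) and np.isfinite(dt_slope)):
        raise ValueError("pattern classification needs finite inputs")
    s1 = "+" if dt1 > dt1_margin else ("-" if dt1 < -dt1_margin else "~")
    s2 = "+" if dt_slope > slope_margin else ("-" if dt_slope < -slope_margin else "~")
    table = {
        ("+", "+"): "enhanced warming",
        ("+", "~"): "abrupt warming",
        ("+", "-"): "attenuated warming",
        ("-", "+"): "attenuated cooling",
        ("-", "~"): "abrupt cooling",
        ("-", "-"): "enhanced cooling",
    }
    label = "insignificant" if s1 == "~" else table[(s1, s2)]
    return PatternLabel(label, s1, s2, dt1_margin, slope_margin)


def compute_response_metrics(target: DecompositionResult,
                             backgrounds: list[DecompositionResult],
                             window: LossWindow, period: tuple[int, int],
                             weighting: str = "mean",
                             distances_m: np.ndarray | None = None,
                             rel_ds_floor_k: float = 0.5) -> ResponseMetrics:
    """All response metrics for one paired sample."""
    dT = delta_trend_series(target, backgrounds, window, period,
                            weighting, distances_m)
    dt1 = abrupt_change(dT, window)
    try:
        slope = gradual_slope(dT, window)
    except ValueError:
        slope = np.nan
    dS = delta_seasonal(target, backgrounds, window, period,
                        weighting, distances_m)
    pre, _ = _span_years(window, period)
    s_before = _monthly_seasonal(target, pre)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(np.abs(s_before) >= rel_ds_floor_k,
                       dS.to_numpy() / np.abs(s_before) * 100.0, np.nan)
    rel_dS = pd.Series(rel, index=dS.index, name="rel_dS_pct")
    cyc = seasonal_cycle_changes(target, backgrounds, window, period,
                                 weighting, distances_m)
    pattern = classify_pattern(dt1, slope) if np.isfinite(slope) else None
    return ResponseMetrics(dT=dT, dt1=dt1, dt_slope=slope, dS=dS, rel_dS=rel_dS,
                           dS_A=cyc.dS_A, rel_dS_A=cyc.rel_dS_A,
                           dS_phi_days=cyc.dS_phi_days, phase_ok=cyc.phase_ok,
                           pattern=pattern)
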