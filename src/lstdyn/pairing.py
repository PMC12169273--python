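"""Paired-pixel extraction: loss/break matching, windows, and backgrounds.

A forest-loss event enters the analysis only if the change detector found an
abrupt LST change consistent with it; the loss window then unites the loss
year with the matched break years, and the study period runs from two years
before the window to the next detected abrupt change (or the series end).
Background control pixels — stable forest in a 25–50 km annulus at similar
elevation — provide the shared climate signal that is differenced away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decompose import Breakpoint, DecompositionResult
from .synthetic import DRIVERS, LC_FOREST

__all__ = [
    "PixelGeo", "LossEvent", "LossWindow", "PairedSample",
    "aggregate_forest_maps", "match_loss_to_breaks", "loss_window",
    "study_period", "select_background",
]


@dataclass
class PixelGeo:
    """Static attributes of one 1-km pixel."""

    row: int
    col: int
    x: float                   # projected metres
    y: float
    latitude: float
    elevation: float
    landcover: int
    forest_cover_pct: float
    forest_change_pct: float   # loss + gain over the record


@dataclass
class LossEvent:
    pixel: PixelGeo
    loss_year: int
    loss_pct: float
    driver: str

    def __post_init__(self) -> None:
        if not 0.0 < self.loss_pct <= 100.0:
            raise ValueError("loss percentage must be in (0, 100]")
        if self.driver not in DRIVERS and self.driver != "other":
            raise ValueError(f"unknown driver {self.driver!r}")


@dataclass
class LossWindow:
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start after end")

    def __contains__(self, year: int) -> bool:
        return self.start <= year <= self.end


@dataclass
class PairedSample:
    """A loss event with its window, study period and validated backgrounds."""

    event: LossEvent
    window: LossWindow | None
    period: tuple[int, int] | None
    backgrounds: list[PixelGeo]
    distances_m: np.ndarray
    n_candidates: int
    n_valid: int
    exclusion: str | None = None       # reason code if the sample is unusable

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / self.n_candidates if self.n_candidates else 0.0


# ---------------------------------------------------------------------------
def aggregate_forest_maps(loss_mask: np.ndarray, cover2000: np.ndarray,
                          driver_map: np.ndarray, block: int
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate high-resolution forest maps to the analysis grid.

    Parameters
    ----------
    loss_mask : ndarray (H, W)
        1 where a high-res (e.g. 30 m) pixel was lost during the record.
    cover2000 : ndarray (H, W)
        Initial forest-cover fraction in [0, 1].
    driver_map : ndarray (H, W) of int
        Loss-driver codes (0 = none) on the high-res grid.
    block : int
        Aggregation factor; must tile both dimensions exactly.

    Returns
    -------
    loss_pct, cover_pct, driver
        Coarse-grid loss percentage (block mean of loss × cover, ×100),
        cover percentage, and modal driver over lost subpixels (0 where no
        subpixel was lost; ties broken toward the smallest driver code).
    """
    H, W = loss_mask.shape
    if H % block or W % block:
        raise ValueError("block size does not tile the high-resolution grid")
    if cover2000.shape != (H, W) or driver_map.shape != (H, W):
        raise ValueError("input grids must share a shape")

    def blocks(a: np.ndarray) -> np.ndarray:
        return a.reshape(H // block, block, W // block, block).swapaxes(1, 2)

    lossb = blocks(np.asarray(loss_mask, dtype=float))
    coverb = blocks(np.asarray(cover2000, dtype=float))
    loss_pct = (lossb * coverb).mean(axis=(2, 3)) * 100.0
    cover_pct = coverb.mean(axis=(2, 3)) * 100.0

    drvb = blocks(np.asarray(driver_map, dtype=int))
    lost = blocks(np.asarray(loss_mask, dtype=bool))
    n_codes = int(drvb.max(initial=0)) + 1
    driver = np.zeros(loss_pct.shape, dtype=np.int16)
    for i in range(driver.shape[0]):
        for j in range(driver.shape[1]):
            codes = drvb[i, j][lost[i, j]]
            codes = codes[codes > 0]
            if codes.size:
                counts = np.bincount(codes, minlength=n_codes)
                driver[i, j] = int(np.argmax(counts))   # first max = smallest code
    return loss_pct, cover_pct, driver


# ---------------------------------------------------------------------------
def match_loss_to_breaks(event: LossEvent, result: DecompositionResult,
                         max_gap_years: int = 2) -> list[Breakpoint]:
    """Breaks consistent with the loss: loss year inside the break's CI and
    within ``max_gap_years`` of the break date.  Returns all matches (trend
    and/or seasonal); empty list if none."""
    matches = []
    for bp in result.breakpoints:
        lo, hi = bp.ci_years(result.start_year, result.steps_per_year)
        byear = bp.year(result.start_year, result.steps_per_year)
        if lo <= event.loss_year <= hi and abs(byear - event.loss_year) <= max_gap_years:
            matches.append(bp)
    return matches


def loss_window(event: LossEvent, matched: list[Breakpoint],
                start_year: int, steps_per_year: int = 36) -> LossWindow:
    """Union of the loss year and the matched break years."""
    if not matched:
        raise ValueError("loss_window requires at least one matched break")
    years = [event.loss_year] + [b.year(start_year, steps_per_year) for b in matched]
    return LossWindow(min(years), max(years))


def study_period(window: LossWindow, breakpoints: list[Breakpoint],
                 start_year: int, series_end_year: int,
                 pre_years: int = 2,
                 steps_per_year: int = 36) -> tuple[int, int]:
    """Analysis span for one paired sample.

    Starts ``pre_years`` before the window (default 2, guaranteeing two full
    pre-loss years); ends the year before the confidence interval of the
    next detected abrupt change begins, or at the series end if no later
    break exists.
    """
    start = window.start - pre_years
    if start < start_year:
        raise ValueError("study period would start before the series")
    later = [b for b in breakpoints
             if b.year(start_year, steps_per_year) > window.end]
    if later:
        next_ci_start = min(b.ci_years(start_year, steps_per_year)[0] for b in later)
        end = min(series_end_year, next_ci_start - 1)
    else:
        end = series_end_year
    if end < window.end + 1:
        raise ValueError("degenerate post-loss span (next break too close)")
    return start, end


# ---------------------------------------------------------------------------
def select_background(event: LossEvent, candidates: list[PixelGeo],
                      inner_m: float = 25_000.0, outer_m: float = 50_000.0,
                      max_elev_diff_m: float = 100.0,
                      change_cap_pct: float = 2.0,
                      min_valid_fraction: float = 0.05) -> PairedSample:
    """Validate background control pixels for one loss event.

    A candidate is valid iff it lies in the [inner, outer] annulus
    (inclusive), keeps stable forest cover with a forest-change percentage
    below min(``change_cap_pct``, the event's loss percentage), and differs
    in elevation by less than ``max_elev_diff_m``.  The sample is excluded
    when the annulus is empty or valid candidates do not exceed
    ``min_valid_fraction`` of all annulus candidates.
    """
    tgt = event.pixel
    annulus, dists = [], []
    for cand in candidates:
        d = float(np.hypot(cand.x - tgt.x, cand.y - tgt.y))
        if inner_m <= d <= outer_m:
            annulus.append(cand)
            dists.append(d)
    n_cand = len(annulus)
    if n_cand == 0:
        return PairedSample(event, None, None, [], np.empty(0), 0, 0,
                            exclusion="empty_annulus")

    change_limit = min(change_cap_pct, event.loss_pct)
    valid, vdists = [], []
    for cand, d in zip(annulus, dists):
        if (cand.landcover == LC_FOREST
                and cand.forest_change_pct < change_limit
                and abs(cand.elevation - tgt.elevation) < max_elev_diff_m):
            valid.append(cand)
            vdists.append(d)
    n_valid = len(valid)
    exclusion = None
    if n_valid <= min_valid_fraction * n_cand:
        exclusion = "too_few_valid_backgrounds"
        valid, vdists = [], []
    return PairedSample(event, None, None, valid, np.asarray(vdists),
                        n_cand, n_valid, exclusion=exclusion)
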