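"""Seeded synthetic scenes with known ground truth.

Generates gridded 10-day LST / albedo / ET stacks plus the static rasters
(elevation, land cover, forest cover and change, loss year/percentage/driver,
latitude) that the paired-pixel analysis consumes, with forest-loss events
injected into known pixels.  Every injected quantity — the abrupt step, the
post-loss slope change, seasonal amplitude and phase shifts, and the albedo
and ET steps — is recorded in a truth table so recovery can be tested end to
end.

Statistical structure emulated:

* per-pixel series = piecewise-linear trend + second-order harmonic
  seasonality (period 36 steps) + i.i.d. Gaussian noise (optional AR(1)),
* a regional interannual anomaly shared by *all* pixels (constant within a
  year), which background differencing must cancel,
* missing observations at a configurable rate,
* spatial layout with stable-forest background candidates in the 25–50 km
  annulus around each loss pixel, plus invalid candidates (non-forest
  cover, elevation offenders, secondary forest change).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .attribution import DEFAULT_LAMBDA_V, et_to_le, taylor_sensitivity
from .timeseries import STEPS_PER_YEAR, TimeSeries10d

DRIVERS = ("cCRO", "URB", "shiftAG", "forestry", "fire")
DRIVER_CODES = {name: i + 1 for i, name in enumerate(DRIVERS)}   # 0 = none
DRIVER_NAMES = {v: k for k, v in DRIVER_CODES.items()}

# land-cover codes (reclassified scheme: 7 broad classes)
LC_CROPLAND, LC_FOREST, LC_NATURAL, LC_URBAN, LC_BARE, LC_WATER, LC_ICE = range(1, 8)

METERS_PER_DEG_LAT = 111_320.0


# ---------------------------------------------------------------------------
@dataclass
class SceneConfig:
    """Configuration of a synthetic scene.

    Defaults describe the analysis conditions the package is designed
    around: 1-km pixels, 36 composite steps per year, forest loss confined
    to 2005–2015 with at least two pre-loss years, 0.5 K observation noise,
    and per-event effect distributions centred on globally representative
    response magnitudes (abrupt step ≈ +0.3 K, post-loss slope ≈ −0.14
    K/decade, amplitude ≈ +0.21 K, phase ≈ −0.6 days).
    """

    rows: int = 120
    cols: int = 120
    pixel_size_m: float = 1000.0
    start_year: int = 2001
    end_year: int = 2020
    steps_per_year: int = STEPS_PER_YEAR

    noise_sd: float = 0.5              # K, per 10-day composite
    anomaly_sd: float = 0.3            # K, shared interannual anomaly
    ar1: float = 0.0                   # optional AR(1) noise coefficient
    missing_fraction: float = 0.05

    n_events: int = 20
    loss_year_min: int = 2005
    loss_year_max: int = 2015
    loss_pct_min: float = 10.0
    loss_pct_max: float = 100.0
    driver_mix: dict = field(default_factory=lambda: {
        "cCRO": 0.27, "forestry": 0.26, "shiftAG": 0.24, "fire": 0.23, "URB": 0.0,
    })

    # per-event truth distributions (Gaussian)
    step_mean: float = 0.30            # K
    step_sd: float = 0.05
    slope_change_mean: float = -0.14   # K per decade
    slope_change_sd: float = 0.05
    amp_change_mean: float = 0.21      # K
    amp_change_sd: float = 0.05
    phase_change_mean: float = -0.6    # days (negative = advance)
    phase_change_sd: float = 0.5
    albedo_step_mean: float = 0.02
    albedo_step_sd: float = 0.005
    et_step_mean: float = -1.0         # mm per 10 days
    et_step_sd: float = 0.3

    # if True, the LST step becomes (drawn step) + closed-form equivalents
    # of the albedo/ET steps, so attribution recovery is testable
    couple_attribution: bool = False

    # energy-balance constants carried with the scene
    sw_down: float = 200.0             # W m^-2
    emissivity: float = 0.97
    lambda_v: float = DEFAULT_LAMBDA_V

    # climatology
    base_lst: float = 290.0            # K
    lst_seasonal_amp: float = 16.0     # K, max-minus-min scale
    base_albedo: float = 0.13
    albedo_seasonal_amp: float = 0.04
    albedo_noise_sd: float = 0.005
    base_et: float = 25.0              # mm per 10 days
    et_seasonal_amp: float = 20.0
    et_noise_sd: float = 0.3

    lat0: float = 45.0                 # latitude of the southernmost row
    boreal_lat: float = 50.0           # latitude proxy for the boreal flag

    background_inner_km: float = 25.0
    background_outer_km: float = 50.0
    min_candidates: int = 50           # stable-forest candidates per event ring
    max_backgrounds: int = 20

    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps_per_year != STEPS_PER_YEAR:
            raise ValueError("the composite period is fixed at 36 steps per year")
        if self.n_years < 4:
            raise ValueError("years span must be at least 4")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing fraction must be in [0, 1)")
        if not (self.start_year + 2 <= self.loss_year_min
                and self.loss_year_max <= self.end_year - 1):
            raise ValueError("loss years must leave >=2 pre-loss and >=1 post-loss years")
        for k in self.driver_mix:
            if k not in DRIVERS:
                raise ValueError(f"unknown driver {k!r}")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def n_steps(self) -> int:
        return self.n_years * self.steps_per_year

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class TruthRecord:
    """Injected changes for one forest-loss event."""

    row: int
    col: int
    loss_year: int
    loss_pct: float
    driver: str
    step_k: float                      # total abrupt LST trend step
    slope_change_k_per_decade: float
    amp_change_k: float
    phase_change_days: float
    albedo_step: float
    et_step: float                     # mm per 10 days
    dt_alpha_true: float = 0.0         # closed-form equivalents (coupled scenes)
    dt_le_true: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.loss_pct <= 100.0:
            raise ValueError("loss percentage must be in (0, 100]")
        if self.driver not in DRIVERS:
            raise ValueError(f"unknown driver {self.driver!r}")


# ---------------------------------------------------------------------------
def _harmonic_values(coeffs: Sequence[float], n: int,
                     steps_per_year: int = STEPS_PER_YEAR) -> np.ndarray:
    u = 2.0 * np.pi * np.arange(n) / steps_per_year
    g1, d1, g2, d2 = coeffs
    return g1 * np.sin(u) + d1 * np.cos(u) + g2 * np.sin(2 * u) + d2 * np.cos(2 * u)


def _harmonic_amplitude(coeffs: Sequence[float]) -> float:
    u = 2.0 * np.pi * np.linspace(0.0, 1.0, 721)
    g1, d1, g2, d2 = coeffs
    s = g1 * np.sin(u) + d1 * np.cos(u) + g2 * np.sin(2 * u) + d2 * np.cos(2 * u)
    return float(s.max() - s.min())


def _shift_scale_harmonic(coeffs: Sequence[float], shift_steps: float,
                          scale: float,
                          steps_per_year: int = STEPS_PER_YEAR) -> np.ndarray:
    """Coefficients of scale · S(t − shift) for a second-order harmonic."""
    g1, d1, g2, d2 = coeffs
    out = []
    for h, (g, d) in ((1, (g1, d1)), (2, (g2, d2))):
        a = 2.0 * np.pi * h * shift_steps / steps_per_year
        c, s = np.cos(a), np.sin(a)
        out.extend([scale * (g * c + d * s), scale * (d * c - g * s)])
    return np.asarray(out)


def make_pixel_series(trend_spec: Sequence[tuple[int, float, float]],
                      harmonic_spec: Sequence[float],
                      noise_sd: float = 0.0,
                      missing_fraction: float = 0.0,
                      seed: int | None = None,
                      start_year: int = 2001,
                      n_years: int = 10,
                      ar1: float = 0.0,
                      return_truth: bool = False):
    """Synthesize one pixel's series: piecewise trend + harmonics + noise.

    Parameters
    ----------
    trend_spec : sequence of (start_step, intercept, slope_per_year)
        Linear segments; the first must start at step 0.  Each segment's
        value at step t is intercept + slope·(t + 0.5)/36 (years since
        series start, midpoint convention).
    harmonic_spec : (γ₁, δ₁, γ₂, δ₂)
        Second-order harmonic coefficients (period 36 steps).
    return_truth : bool
        If True, also return the noiseless (trend, seasonal) components.
    """
    spec = [(int(s), float(a), float(b)) for s, a, b in trend_spec]
    if not spec or spec[0][0] != 0:
        raise ValueError("trend spec must start at step 0")
    coeffs = np.asarray(harmonic_spec, dtype=float)
    if coeffs.shape != (4,):
        raise ValueError("harmonic spec must give (γ₁, δ₁, γ₂, δ₂)")
    if not (np.all(np.isfinite(coeffs))
            and all(np.isfinite(v) for seg in spec for v in seg)
            and np.isfinite(noise_sd) and noise_sd >= 0):
        raise ValueError("non-finite generator parameters")

    n = n_years * STEPS_PER_YEAR
    t_years = (np.arange(n) + 0.5) / STEPS_PER_YEAR
    trend = np.empty(n)
    starts = [s for s, _, _ in spec] + [n]
    for (s0, a, b), s1 in zip(spec, starts[1:]):
        trend[s0:s1] = a + b * t_years[s0:s1]
    seasonal = _harmonic_values(coeffs, n)

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    if ar1:
        for t in range(1, n):
            noise[t] += ar1 * noise[t - 1]
    values = trend + seasonal + noise
    if missing_fraction > 0:
        values = values.copy()
        values[rng.random(n) < missing_fraction] = np.nan

    series = TimeSeries10d(start_year=start_year, values=values)
    if return_truth:
        return series, trend, seasonal
    return series


# ---------------------------------------------------------------------------
@dataclass
class PixelSeriesBundle:
    """Noiseless truth components for one pixel (LST, albedo, ET)."""

    start_year: int
    lst_trend: np.ndarray
    lst_harm: np.ndarray               # current harmonic coefficients
    alb_trend: np.ndarray
    alb_harm: np.ndarray
    et_trend: np.ndarray
    et_harm: np.ndarray
    # post-loss harmonic coefficients (set by injection; None = unchanged)
    lst_harm_post: np.ndarray | None = None
    split_step: int | None = None

    @property
    def n_steps(self) -> int:
        return self.lst_trend.size

    def seasonal(self, var: str = "lst") -> np.ndarray:
        pre = {"lst": self.lst_harm, "albedo": self.alb_harm, "et": self.et_harm}[var]
        vals = _harmonic_values(pre, self.n_steps)
        if var == "lst" and self.lst_harm_post is not None:
            post = _harmonic_values(self.lst_harm_post, self.n_steps)
            vals = np.where(np.arange(self.n_steps) >= self.split_step, post, vals)
        return vals

    def trend(self, var: str = "lst") -> np.ndarray:
        return {"lst": self.lst_trend, "albedo": self.alb_trend,
                "et": self.et_trend}[var]


def inject_loss_event(bundle: PixelSeriesBundle, truth: TruthRecord,
                      min_pre_years: int = 2) -> PixelSeriesBundle:
    """Apply a loss event's changes to a pixel's truth components, in place.

    From the loss year onward: the LST trend gains the abrupt step plus the
    slope change; the seasonal harmonic is scaled so its amplitude grows by
    the stated amount and shifted by the stated phase change; the albedo and
    ET trends gain their steps.
    """
    spy = STEPS_PER_YEAR
    n = bundle.n_steps
    t0 = (truth.loss_year - bundle.start_year) * spy
    if t0 < min_pre_years * spy or t0 >= n - spy:
        raise ValueError("loss year too close to the series edges")

    post = np.arange(n) >= t0
    years_since = (np.arange(n) + 0.5 - t0) / spy
    bundle.lst_trend[post] += (truth.step_k
                               + truth.slope_change_k_per_decade / 10.0
                               * years_since[post])
    bundle.alb_trend[post] += truth.albedo_step
    bundle.et_trend[post] += truth.et_step

    if truth.amp_change_k or truth.phase_change_days:
        amp_pre = _harmonic_amplitude(bundle.lst_harm)
        if amp_pre <= 0 and truth.amp_change_k:
            raise ValueError("cannot scale a zero-amplitude seasonal cycle")
        scale = (amp_pre + truth.amp_change_k) / amp_pre if amp_pre > 0 else 1.0
        shift = truth.phase_change_days * spy / 365.0
        bundle.lst_harm_post = _shift_scale_harmonic(bundle.lst_harm, shift, scale)
        bundle.split_step = t0
    return bundle


# ---------------------------------------------------------------------------
@dataclass
class SceneBundle:
    """A full synthetic scene: stacks (time, row, col), static rasters, truth."""

    config: SceneConfig
    lst: np.ndarray
    albedo: np.ndarray
    et: np.ndarray
    elevation: np.ndarray
    landcover: np.ndarray
    forest_cover_pct: np.ndarray
    forest_change_pct: np.ndarray      # loss + gain over the record, %
    loss_year: np.ndarray              # 0 = no loss
    loss_pct: np.ndarray
    driver: np.ndarray                 # DRIVER_CODES, 0 = none
    latitude: np.ndarray
    boreal: np.ndarray
    truth: list[TruthRecord]
    lst_truth_trend: np.ndarray | None = None
    lst_truth_seasonal: np.ndarray | None = None

    @property
    def start_year(self) -> int:
        return self.config.start_year

    def pixel_series(self, row: int, col: int, var: str = "lst") -> TimeSeries10d:
        stack = {"lst": self.lst, "albedo": self.albedo, "et": self.et}[var]
        return TimeSeries10d(self.start_year, stack[:, row, col].copy())

    def pixel_xy(self, row: int, col: int) -> tuple[float, float]:
        """Projected planar coordinates (m) of a pixel centre."""
        p = self.config.pixel_size_m
        return col * p, row * p


def _smooth_field(rng: np.random.Generator, rows: int, cols: int,
                  amplitude: float, n_waves: int = 4) -> np.ndarray:
    """Low-frequency random surface: a sum of planar cosines."""
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    out = np.zeros((rows, cols))
    for _ in range(n_waves):
        fr, fc = rng.uniform(-1.0, 1.0, 2) / max(rows, cols) * 2 * np.pi * rng.uniform(1, 3)
        phase = rng.uniform(0, 2 * np.pi)
        out += rng.uniform(0.3, 1.0) * np.cos(fr * r + fc * c + phase)
    return amplitude * out / n_waves


def _ring_offsets(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dr, dc, distance_m) for all pixels in the background annulus."""
    max_px = int(np.ceil(cfg.background_outer_km * 1000.0 / cfg.pixel_size_m))
    dr, dc = np.mgrid[-max_px:max_px + 1, -max_px:max_px + 1]
    d = np.hypot(dr, dc) * cfg.pixel_size_m
    keep = (d >= cfg.background_inner_km * 1000.0) & (d <= cfg.background_outer_km * 1000.0)
    return dr[keep], dc[keep], d[keep]


def make_scene(cfg: SceneConfig) -> SceneBundle:
    """Generate a deterministic scene from its configuration.

    All pixels share one regional interannual anomaly (constant within each
    year) added to the trend; loss pixels are placed so their 25–50 km
    annulus holds at least ``cfg.min_candidates`` stable-forest candidates.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols, n = cfg.rows, cfg.cols, cfg.n_steps
    spy = cfg.steps_per_year

    dr, dc, _ = _ring_offsets(cfg)
    if dr.size == 0:
        raise ValueError("grid/pixel size cannot host the 25–50 km annulus")

    # --- static rasters ----------------------------------------------------
    elevation = 300.0 + _smooth_field(rng, rows, cols, 150.0) \
        + rng.normal(0.0, 10.0, (rows, cols))
    latitude = cfg.lat0 + np.arange(rows)[:, None] * cfg.pixel_size_m \
        / METERS_PER_DEG_LAT * np.ones((1, cols))
    boreal = latitude >= cfg.boreal_lat

    landcover = np.full((rows, cols), LC_FOREST, dtype=np.int16)
    crop_field = _smooth_field(rng, rows, cols, 1.0)
    landcover[crop_field > np.quantile(crop_field, 0.92)] = LC_CROPLAND
    forest = landcover == LC_FOREST

    forest_cover = np.where(forest, rng.uniform(80.0, 100.0, (rows, cols)),
                            rng.uniform(0.0, 10.0, (rows, cols)))
    # sprinkle small secondary change (loss+gain) on ~2% of stable pixels
    gain = np.zeros((rows, cols))
    churn = rng.random((rows, cols)) < 0.02
    gain[churn] = rng.uniform(2.0, 10.0, int(churn.sum()))
    loss_pct = np.zeros((rows, cols))
    loss_year = np.zeros((rows, cols), dtype=np.int32)
    driver = np.zeros((rows, cols), dtype=np.int16)

    # --- event placement ---------------------------------------------------
    names = list(cfg.driver_mix)
    weights = np.array([cfg.driver_mix[k] for k in names], dtype=float)
    weights = weights / weights.sum()
    truth_records: list[TruthRecord] = []
    occupied = np.zeros((rows, cols), dtype=bool)
    tries = 0
    while len(truth_records) < cfg.n_events:
        tries += 1
        if tries > 200 * max(cfg.n_events, 1):
            raise ValueError("could not place the requested events "
                             "(grid too small for the annulus rules)")
        r = int(rng.integers(0, rows))
        c = int(rng.integers(0, cols))
        if occupied[r, c] or not forest[r, c] or gain[r, c] > 0:
            continue
        rr, cc = r + dr, c + dc
        ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        if ok.sum() < cfg.min_candidates:
            continue
        stable = forest[rr[ok], cc[ok]] & (gain[rr[ok], cc[ok]] < 2.0) \
            & (np.abs(elevation[rr[ok], cc[ok]] - elevation[r, c]) < 100.0)
        n_valid = int(stable.sum())
        if n_valid < cfg.min_candidates or n_valid <= 0.05 * int(ok.sum()):
            continue
        occupied[r, c] = True
        ly = int(rng.integers(cfg.loss_year_min, cfg.loss_year_max + 1))
        p = float(rng.uniform(cfg.loss_pct_min, cfg.loss_pct_max))
        drv = names[int(rng.choice(len(names), p=weights))]
        truth_records.append(TruthRecord(
            row=r, col=c, loss_year=ly, loss_pct=p, driver=drv,
            step_k=float(rng.normal(cfg.step_mean, cfg.step_sd)),
            slope_change_k_per_decade=float(
                rng.normal(cfg.slope_change_mean, cfg.slope_change_sd)),
            amp_change_k=float(rng.normal(cfg.amp_change_mean, cfg.amp_change_sd)),
            phase_change_days=float(
                rng.normal(cfg.phase_change_mean, cfg.phase_change_sd)),
            albedo_step=float(rng.normal(cfg.albedo_step_mean, cfg.albedo_step_sd)),
            et_step=float(rng.normal(cfg.et_step_mean, cfg.et_step_sd)),
        ))

    # --- per-pixel climatological parameters -------------------------------
    base = (cfg.base_lst - 0.0065 * elevation
            - 0.3 * (latitude - latitude.mean())
            + rng.normal(0.0, 0.5, (rows, cols)))
    slope = 0.01 + rng.normal(0.0, 0.002, (rows, cols))        # K per year
    g1 = cfg.lst_seasonal_amp / 2.0 * (1.0 + rng.normal(0.0, 0.03, (rows, cols)))
    d1 = rng.normal(0.0, 0.3, (rows, cols))
    g2 = 0.08 * g1 + rng.normal(0.0, 0.05, (rows, cols))
    d2 = rng.normal(0.0, 0.05, (rows, cols))

    alb_base = cfg.base_albedo + rng.normal(0.0, 0.01, (rows, cols))
    alb_g1 = cfg.albedo_seasonal_amp / 2.0 * (1.0 + rng.normal(0.0, 0.05, (rows, cols)))
    et_base = cfg.base_et + rng.normal(0.0, 1.0, (rows, cols))
    et_g1 = cfg.et_seasonal_amp / 2.0 * (1.0 + rng.normal(0.0, 0.05, (rows, cols)))

    anomaly = np.repeat(rng.normal(0.0, cfg.anomaly_sd, cfg.n_years), spy)

    t_years = (np.arange(n) + 0.5) / spy
    u = 2.0 * np.pi * np.arange(n) / spy
    sin1, cos1, sin2, cos2 = np.sin(u), np.cos(u), np.sin(2 * u), np.cos(2 * u)

    trend_stack = base[None] + slope[None] * t_years[:, None, None]
    seas_stack = (g1[None] * sin1[:, None, None] + d1[None] * cos1[:, None, None]
                  + g2[None] * sin2[:, None, None] + d2[None] * cos2[:, None, None])
    alb_trend = np.broadcast_to(alb_base[None], (n, rows, cols)).copy()
    alb_seas = alb_g1[None] * sin1[:, None, None]
    et_trend = np.broadcast_to(et_base[None], (n, rows, cols)).copy()
    et_seas = et_g1[None] * sin1[:, None, None]

    # --- inject events ------------------------------------------------------
    for rec in truth_records:
        r, c = rec.row, rec.col
        if cfg.couple_attribution:
            ref_lst = float(trend_stack[:spy, r, c].mean())
            sens = taylor_sensitivity(cfg.emissivity, ref_lst)
            rec.dt_alpha_true = sens * (-cfg.sw_down * rec.albedo_step)
            rec.dt_le_true = sens * (-float(et_to_le(rec.et_step, cfg.lambda_v)))
            rec.step_k = rec.step_k + rec.dt_alpha_true + rec.dt_le_true
        bundle = PixelSeriesBundle(
            start_year=cfg.start_year,
            lst_trend=trend_stack[:, r, c].copy(),
            lst_harm=np.array([g1[r, c], d1[r, c], g2[r, c], d2[r, c]]),
            alb_trend=alb_trend[:, r, c].copy(),
            alb_harm=np.array([alb_g1[r, c], 0.0, 0.0, 0.0]),
            et_trend=et_trend[:, r, c].copy(),
            et_harm=np.array([et_g1[r, c], 0.0, 0.0, 0.0]),
        )
        inject_loss_event(bundle, rec)
        trend_stack[:, r, c] = bundle.lst_trend
        seas_stack[:, r, c] = bundle.seasonal("lst")
        alb_trend[:, r, c] = bundle.alb_trend
        et_trend[:, r, c] = bundle.et_trend
        loss_year[r, c] = rec.loss_year
        loss_pct[r, c] = rec.loss_pct
        driver[r, c] = DRIVER_CODES[rec.driver]
        landcover[r, c] = LC_FOREST   # loss pixels were forest in 2000

    forest_change = loss_pct + gain

    # --- observation stacks -------------------------------------------------
    def observe(truth: np.ndarray, sd: float, add_anomaly: bool = False) -> np.ndarray:
        out = truth.copy()
        if add_anomaly:
            out += anomaly[:, None, None]
        if sd > 0:
            noise = rng.normal(0.0, sd, truth.shape)
            if cfg.ar1:
                for t in range(1, n):
                    noise[t] += cfg.ar1 * noise[t - 1]
            out += noise
        if cfg.missing_fraction > 0:
            out[rng.random(truth.shape) < cfg.missing_fraction] = np.nan
        return out

    lst = observe(trend_stack + seas_stack, cfg.noise_sd, add_anomaly=True)
    albedo = observe(alb_trend + alb_seas, cfg.albedo_noise_sd)
    et = observe(et_trend + et_seas, cfg.et_noise_sd)

    return SceneBundle(
        config=cfg, lst=lst, albedo=albedo, et=et,
        elevation=elevation, landcover=landcover,
        forest_cover_pct=forest_cover, forest_change_pct=forest_change,
        loss_year=loss_year, loss_pct=loss_pct, driver=driver,
        latitude=latitude, boreal=boreal, truth=truth_records,
        lst_truth_trend=trend_stack, lst_truth_seasonal=seas_stack,
    )


# ---------------------------------------------------------------------------
@dataclass
class CohortEvent:
    """One loss event with its background control series (no spatial grid)."""

    truth: TruthRecord
    lst_target: TimeSeries10d
    alb_target: TimeSeries10d
    et_target: TimeSeries10d
    lst_backgrounds: list[TimeSeries10d]
    alb_backgrounds: list[TimeSeries10d]
    et_backgrounds: list[TimeSeries10d]
    distances_m: np.ndarray
    ref_lst_true: float                # noiseless baseline-year LST mean


def make_event_cohort(n_events: int, n_backgrounds: int = 20,
                      cfg: SceneConfig | None = None,
                      seed: int | None = None) -> list[CohortEvent]:
    """Simulate paired samples directly: target + backgrounds per event.

    A light-weight alternative to :func:`make_scene` for Monte-Carlo studies
    of metric recovery: each event gets its own regional anomaly shared by
    its target and background pixels, independent observation noise per
    pixel, and background distances drawn uniformly over the 25–50 km
    annulus.
    """
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_steps
    spy = cfg.steps_per_year
    t_years = (np.arange(n) + 0.5) / spy
    events: list[CohortEvent] = []

    for _ in range(n_events):
        anomaly = np.repeat(rng.normal(0.0, cfg.anomaly_sd, cfg.n_years), spy)
        shared_slope = 0.01 + rng.normal(0.0, 0.002)

        def draw_params():
            base = cfg.base_lst + rng.normal(0.0, 0.5)
            slope = shared_slope + rng.normal(0.0, 0.002)
            harm = np.array([
                cfg.lst_seasonal_amp / 2.0 * (1.0 + rng.normal(0.0, 0.03)),
                rng.normal(0.0, 0.3),
                0.08 * cfg.lst_seasonal_amp / 2.0 + rng.normal(0.0, 0.05),
                rng.normal(0.0, 0.05),
            ])
            return base, slope, harm

        def make_bundle():
            base, slope, harm = draw_params()
            return PixelSeriesBundle(
                start_year=cfg.start_year,
                lst_trend=base + slope * t_years,
                lst_harm=harm,
                alb_trend=np.full(n, cfg.base_albedo + rng.normal(0.0, 0.01)),
                alb_harm=np.array([cfg.albedo_seasonal_amp / 2.0, 0.0, 0.0, 0.0]),
                et_trend=np.full(n, cfg.base_et + rng.normal(0.0, 1.0)),
                et_harm=np.array([cfg.et_seasonal_amp / 2.0, 0.0, 0.0, 0.0]),
            )

        target = make_bundle()
        rec = TruthRecord(
            row=0, col=0,
            loss_year=int(rng.integers(cfg.loss_year_min, cfg.loss_year_max + 1)),
            loss_pct=float(rng.uniform(cfg.loss_pct_min, cfg.loss_pct_max)),
            driver=str(rng.choice(DRIVERS)),
            step_k=float(rng.normal(cfg.step_mean, cfg.step_sd)),
            slope_change_k_per_decade=float(
                rng.normal(cfg.slope_change_mean, cfg.slope_change_sd)),
            amp_change_k=float(rng.normal(cfg.amp_change_mean, cfg.amp_change_sd)),
            phase_change_days=float(
                rng.normal(cfg.phase_change_mean, cfg.phase_change_sd)),
            albedo_step=float(rng.normal(cfg.albedo_step_mean, cfg.albedo_step_sd)),
            et_step=float(rng.normal(cfg.et_step_mean, cfg.et_step_sd)),
        )
        ref_lst_true = float(target.lst_trend[:spy].mean())
        if cfg.couple_attribution:
            sens = taylor_sensitivity(cfg.emissivity, ref_lst_true)
            rec.dt_alpha_true = sens * (-cfg.sw_down * rec.albedo_step)
            rec.dt_le_true = sens * (-float(et_to_le(rec.et_step, cfg.lambda_v)))
            rec.step_k = rec.step_k + rec.dt_alpha_true + rec.dt_le_true
        inject_loss_event(target, rec)

        def realize(bundle: PixelSeriesBundle, var: str, sd: float,
                    with_anomaly: bool) -> TimeSeries10d:
            vals = bundle.trend(var) + bundle.seasonal(var)
            if with_anomaly:
                vals = vals + anomaly
            if sd > 0:
                vals = vals + rng.normal(0.0, sd, n)
            if cfg.missing_fraction > 0:
                vals = np.where(rng.random(n) < cfg.missing_fraction, np.nan, vals)
            return TimeSeries10d(cfg.start_year, vals)

        bgs = [make_bundle() for _ in range(n_backgrounds)]
        events.append(CohortEvent(
            truth=rec,
            lst_target=realize(target, "lst", cfg.noise_sd, True),
            alb_target=realize(target, "albedo", cfg.albedo_noise_sd, False),
            et_target=realize(target, "et", cfg.et_noise_sd, False),
            lst_backgrounds=[realize(b, "lst", cfg.noise_sd, True) for b in bgs],
            alb_backgrounds=[realize(b, "albedo", cfg.albedo_noise_sd, False) for b in bgs],
            et_backgrounds=[realize(b, "et", cfg.et_noise_sd, False) for b in bgs],
            distances_m=rng.uniform(cfg.background_inner_km * 1000.0,
                                    cfg.background_outer_km * 1000.0,
                                    n_backgrounds),
            ref_lst_true=ref_lst_true,
        ))
    return events
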