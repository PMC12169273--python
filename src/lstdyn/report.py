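"""Climate regions, zonal statistics, and the end-to-end pipeline.

Events are grouped into four latitudinal/climatic regions — southern
mid-latitudes (SM, 60°S–20°S), low latitudes (LL, 20°S–20°N), and, above
20°N, the boreal climate zone versus the northern mid-latitudes (NM) — and
into 5° latitude bins.  Zonal means carry Student-t 95% confidence intervals
and one-sample t tests against zero.

``run_all`` drives the full chain on a synthetic scene: simulate →
decompose → pair → quantify → attribute → report, writing CSV artifacts and
a JSON run log.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .attribution import EnergyBalanceInputs, attribute
from .decompose import fit_decomposition, fit_windowed_decomposition
from .pairing import (LossEvent, PairedSample, PixelGeo, loss_window,
                      match_loss_to_breaks, select_background, study_period)
from .response import compute_response_metrics, delta_seasonal, delta_trend_series
from .synthetic import DRIVER_NAMES, SceneBundle, SceneConfig, make_scene

__all__ = ["assign_region", "latitude_bin", "ZonalSummary", "zonal_summary",
           "analyze_scene", "run_all"]

REGIONS = ("SM", "LL", "NM", "boreal")


def assign_region(latitude: float, boreal_flag: bool) -> str:
    """Region label: SM (60°S–20°S), LL (20°S–20°N), boreal/NM above 20°N.

    Latitudes south of 60°S fall outside the study domain ("outside").
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude out of range")
    if latitude < -60.0:
        return "outside"
    if latitude < -20.0:
        return "SM"
    if latitude <= 20.0:
        return "LL"
    return "boreal" if boreal_flag else "NM"


def latitude_bin(latitude: float, width: float = 5.0,
                 lo: float = -60.0, hi: float = 80.0) -> float:
    """Lower edge of the half-open [edge, edge+width) latitude bin."""
    if not lo <= latitude < hi:
        return np.nan
    return lo + width * np.floor((latitude - lo) / width)


@dataclass
class ZonalSummary:
    group: str
    metric: str
    n: int
    mean: float
    ci_half_width: float       # 95% Student-t half width (NaN for n < 2)
    t_stat: float
    p_value: float
    significant: bool          # p < 0.05


def zonal_summary(df: pd.DataFrame, metric: str, by: str,
                  alpha: float = 0.05) -> list[ZonalSummary]:
    """Per-group mean, 95% CI, and one-sample t test against zero."""
    out: list[ZonalSummary] = []
    sub = df[[by, metric]].dropna()
    for group, vals in sub.groupby(by, observed=True)[metric]:
        x = vals.to_numpy(dtype=float)
        n = x.size
        mean = float(x.mean())
        if n < 2:
            out.append(ZonalSummary(str(group), metric, n, mean,
                                    np.nan, np.nan, np.nan, False))
            continue
        sd = x.std(ddof=1)
        if sd == 0.0:
            t_stat = np.inf if mean != 0 else 0.0
            p = 0.0 if mean != 0 else 1.0
            half = 0.0
        else:
            t_stat, p = stats.ttest_1samp(x, 0.0)
            half = float(stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n))
        out.append(ZonalSummary(str(group), metric, n, mean, half,
                                float(t_stat), float(p), bool(p < alpha)))
    return out


# ---------------------------------------------------------------------------
def _pixel_geo(scene: SceneBundle, row: int, col: int) -> PixelGeo:
    x, y = scene.pixel_xy(row, col)
    return PixelGeo(
        row=row, col=col, x=x, y=y,
        latitude=float(scene.latitude[row, col]),
        elevation=float(scene.elevation[row, col]),
        landcover=int(scene.landcover[row, col]),
        forest_cover_pct=float(scene.forest_cover_pct[row, col]),
        forest_change_pct=float(scene.forest_change_pct[row, col]),
    )


def _annulus_candidates(scene: SceneBundle, row: int, col: int,
                        outer_m: float) -> list[PixelGeo]:
    p = scene.config.pixel_size_m
    reach = int(np.ceil(outer_m / p)) + 1
    r0, r1 = max(0, row - reach), min(scene.config.rows, row + reach + 1)
    c0, c1 = max(0, col - reach), min(scene.config.cols, col + reach + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - row, cc - col) * p
    keep = d <= outer_m
    return [_pixel_geo(scene, int(r), int(c))
            for r, c in zip(rr[keep], cc[keep]) if (r, c) != (row, col)]


def analyze_scene(scene: SceneBundle, seed: int = 0, weighting: str = "mean",
                  bootstrap_reps: int = 100, max_backgrounds: int | None = None,
                  pre_years: int = 2) -> dict:
    """Run pairing, quantification, and attribution on every loss pixel.

    Returns a dict of DataFrames: ``pairs``, ``metrics``, ``attribution``,
    ``zonal``, ``trajectories``.
    """
    cfg = scene.config
    max_bg = max_backgrounds or cfg.max_backgrounds
    ss = np.random.SeedSequence([seed, 1713])
    event_rc = np.argwhere(scene.loss_pct > 0)

    pair_rows, metric_rows, attr_rows = [], [], []
    per_event_dT: list[tuple[int, pd.Series, LossEvent]] = []

    for eid, (row, col) in enumerate(map(tuple, event_rc)):
        child = np.random.default_rng(ss.spawn(1)[0])
        geo = _pixel_geo(scene, row, col)
        event = LossEvent(pixel=geo, loss_year=int(scene.loss_year[row, col]),
                          loss_pct=float(scene.loss_pct[row, col]),
                          driver=DRIVER_NAMES.get(int(scene.driver[row, col]), "other"))
        region = assign_region(geo.latitude, bool(scene.boreal[row, col]))
        base_row = dict(event_id=eid, row=row, col=col, latitude=geo.latitude,
                        region=region, lat_bin=latitude_bin(geo.latitude),
                        driver=event.driver, loss_year=event.loss_year,
                        loss_pct=event.loss_pct)

        candidates = _annulus_candidates(scene, row, col,
                                         cfg.background_outer_km * 1000.0)
        sample = select_background(
            event, candidates,
            inner_m=cfg.background_inner_km * 1000.0,
            outer_m=cfg.background_outer_km * 1000.0)

        def record(sample: PairedSample, window=None, period=None):
            pair_rows.append(dict(
                base_row,
                n_candidates=sample.n_candidates, n_valid=sample.n_valid,
                valid_fraction=sample.valid_fraction,
                window_start=window.start if window else np.nan,
                window_end=window.end if window else np.nan,
                period_start=period[0] if period else np.nan,
                period_end=period[1] if period else np.nan,
                exclusion=sample.exclusion or ""))

        if sample.exclusion:
            record(sample)
            metric_rows.append(dict(base_row, exclusion=sample.exclusion))
            continue

        # detection on the target pixel decides matching and the windows
        lst_t = scene.pixel_series(row, col, "lst")
        det = fit_decomposition(lst_t, bootstrap_reps=bootstrap_reps,
                                seed=int(child.integers(2**31)))
        matches = match_loss_to_breaks(event, det)
        if not matches:
            sample.exclusion = "no_matched_break"
            record(sample)
            metric_rows.append(dict(base_row, exclusion=sample.exclusion))
            continue
        window = loss_window(event, matches, det.start_year)
        try:
            period = study_period(window, det.breakpoints, det.start_year,
                                  lst_t.end_year, pre_years=pre_years)
        except ValueError as err:
            sample.exclusion = str(err)
            record(sample, window)
            metric_rows.append(dict(base_row, exclusion=sample.exclusion))
            continue
        sample.window, sample.period = window, period
        record(sample, window, period)

        # subsample backgrounds and fit windowed components everywhere
        idx = np.arange(len(sample.backgrounds))
        if idx.size > max_bg:
            idx = np.sort(child.choice(idx, size=max_bg, replace=False))
        bgs = [sample.backgrounds[i] for i in idx]
        dists = sample.distances_m[idx]

        def wfit(r: int, c: int, var: str):
            return fit_windowed_decomposition(
                scene.pixel_series(r, c, var), (window.start, window.end), period)

        try:
            tgt = {v: wfit(row, col, v) for v in ("lst", "albedo", "et")}
            bg = {v: [wfit(b.row, b.col, v) for b in bgs]
                  for v in ("lst", "albedo", "et")}
        except ValueError as err:
            metric_rows.append(dict(base_row, exclusion=f"windowed_fit: {err}"))
            continue

        m = compute_response_metrics(tgt["lst"], bg["lst"], window, period,
                                     weighting=weighting, distances_m=dists)
        per_event_dT.append((eid, m.dT, event))
        metric_rows.append(dict(
            base_row, exclusion="",
            n_backgrounds=len(bgs),
            dt1_k=m.dt1, dt_slope_k_per_decade=m.dt_slope,
            ds_a_k=m.dS_A, rel_ds_a_pct=m.rel_dS_A,
            ds_phi_days=m.dS_phi_days, phase_ok=m.phase_ok,
            pattern=m.pattern.label if m.pattern else "",
            dT_json=json.dumps({int(k): round(float(v), 6)
                                for k, v in m.dT.items()}),
        ))

        # energy-balance attribution
        baseline_year = cfg.start_year
        sl = scene.pixel_series(row, col, "lst").year_slice(baseline_year)
        ref_lst = float(np.nanmean(scene.lst[sl, row, col]))
        eb = EnergyBalanceInputs(ref_lst=ref_lst, sw_down=cfg.sw_down,
                                 emissivity=cfg.emissivity, lambda_v=cfg.lambda_v)
        d_alpha = delta_trend_series(tgt["albedo"], bg["albedo"], window, period,
                                     weighting, dists)
        d_et = delta_trend_series(tgt["et"], bg["et"], window, period,
                                  weighting, dists)
        ds_alpha = delta_seasonal(tgt["albedo"], bg["albedo"], window, period,
                                  weighting, dists)
        ds_et = delta_seasonal(tgt["et"], bg["et"], window, period,
                               weighting, dists)
        att = attribute(m.dT, m.dS, d_alpha, d_et, ds_alpha, ds_et, eb)
        for year in att.dT.index:
            attr_rows.append(dict(event_id=eid, component="trend", index=int(year),
                                  dT=att.dT[year], dT_alpha=att.dT_alpha[year],
                                  dT_le=att.dT_le[year], dT_h=att.dT_h[year]))
        for month in att.dS.index:
            attr_rows.append(dict(event_id=eid, component="seasonal",
                                  index=int(month),
                                  dT=att.dS[month], dT_alpha=att.dS_alpha[month],
                                  dT_le=att.dS_le[month], dT_h=att.dS_h[month]))

    pairs = pd.DataFrame(pair_rows)
    metrics = pd.DataFrame(metric_rows)
    attribution_df = pd.DataFrame(attr_rows)

    # zonal summaries over analyzed events
    zonal_rows: list[ZonalSummary] = []
    ok = metrics[metrics["exclusion"] == ""] \
        if "exclusion" in metrics.columns else metrics.iloc[:0]
    metric_cols = ["dt1_k", "dt_slope_k_per_decade", "ds_a_k", "ds_phi_days"]
    if len(ok):
        for p_floor, tag in ((0.0, "P>0"), (50.0, "P>50")):
            cohort = ok[ok.loss_pct > p_floor].copy()
            if not len(cohort):
                continue
            cohort["global"] = "global"
            for mcol in metric_cols:
                if mcol not in cohort:
                    continue
                for by in ("global", "region", "driver", "lat_bin"):
                    for z in zonal_summary(cohort, mcol, by):
                        zonal_rows.append(dict(asdict(z), grouping=by, cohort=tag))
    zonal = pd.DataFrame(zonal_rows)

    # cohort trajectory: mean ΔT by years since the loss window
    traj_rows = []
    rel: dict[int, list[float]] = {}
    for eid, dT, event in per_event_dT:
        for year, val in dT.items():
            rel.setdefault(int(year) - event.loss_year, []).append(float(val))
    for k in sorted(rel):
        x = np.asarray(rel[k])
        half = (stats.t.ppf(0.975, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
                if x.size > 1 else np.nan)
        traj_rows.append(dict(years_since_loss=k, n=x.size,
                              mean_dT=float(x.mean()), ci95_half=half))
    trajectories = pd.DataFrame(traj_rows)

    return dict(pairs=pairs, metrics=metrics, attribution=attribution_df,
                zonal=zonal, trajectories=trajectories)


# ---------------------------------------------------------------------------
def run_all(scene_cfg: SceneConfig | str | Path, out_dir: str | Path,
            seed: int = 0, weighting: str = "mean",
            bootstrap_reps: int = 100) -> dict:
    """simulate → decompose → pair → quantify → attribute → report.

    ``scene_cfg`` is a :class:`SceneConfig` (its own ``seed`` is replaced by
    ``seed``), a path to a scene-config YAML, or a path to a directory
    written by :func:`lstdyn.io.write_scene`.  Writes ``pairs.csv``,
    ``metrics.csv``, ``attribution.csv``, ``zonal_summary.csv``,
    ``trajectories.csv`` and ``run.json`` into ``out_dir``.
    """
    from .io import read_scene

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if isinstance(scene_cfg, SceneConfig):
        cfg = SceneConfig(**{**asdict(scene_cfg), "seed": seed})
        scene = make_scene(cfg)
    else:
        p = Path(scene_cfg)
        if p.is_dir():
            scene = read_scene(p)
        else:
            cfg = SceneConfig(**{**asdict(SceneConfig.from_yaml(p)), "seed": seed})
            scene = make_scene(cfg)

    tables = analyze_scene(scene, seed=seed, weighting=weighting,
                           bootstrap_reps=bootstrap_reps)
    files = {}
    for name, df in tables.items():
        fname = "zonal_summary.csv" if name == "zonal" else f"{name}.csv"
        df.to_csv(out / fname, index=False)
        files[name] = str(out / fname)

    n_ok = int((tables["metrics"]["exclusion"] == "").sum()) \
        if len(tables["metrics"]) else 0
    log = dict(package="lstdyn", version=__version__, seed=seed,
               weighting=weighting, bootstrap_reps=bootstrap_reps,
               scene_config=asdict(scene.config),
               n_events=int(len(scene.truth)), n_analyzed=n_ok, outputs=files)
    with open(out / "run.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return dict(tables=tables, log=log, scene=scene)
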