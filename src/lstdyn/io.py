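"""Scene and result I/O.

A scene is persisted as one directory: ``scene.nc`` (NetCDF-3 classic via
xarray's scipy backend — stacks with dimension order time × y × x, a CF-style
time coordinate, and the static rasters as 2-D variables), ``truth.csv``,
and ``config.yaml``.  Single-pixel series round-trip through two-column CSV
(decimal-year time, value), and decompositions serialize to JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .decompose import DecompositionResult
from .synthetic import SceneBundle, SceneConfig, TruthRecord
from .timeseries import STEPS_PER_YEAR, TimeSeries10d

_EPOCH = "days since 2000-01-01"


def _time_days(cfg: SceneConfig) -> np.ndarray:
    t = np.arange(cfg.n_steps, dtype=float)
    return ((cfg.start_year - 2000) * 365.0
            + (t + 0.5) * 365.0 / cfg.steps_per_year)


def write_scene(scene: SceneBundle, out_dir: str | Path) -> Path:
    """Write a scene directory (scene.nc + truth.csv + config.yaml)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = scene.config

    time = xr.DataArray(_time_days(cfg), dims="time",
                        attrs={"units": _EPOCH, "calendar": "365_day"})
    dims3 = ("time", "y", "x")
    ds = xr.Dataset(
        {
            "lst": (dims3, scene.lst, {"units": "K"}),
            "albedo": (dims3, scene.albedo, {"units": "1"}),
            "et": (dims3, scene.et, {"units": "mm/10d"}),
            "elevation": (("y", "x"), scene.elevation, {"units": "m"}),
            "landcover": (("y", "x"), scene.landcover.astype(np.int32)),
            "forest_cover_pct": (("y", "x"), scene.forest_cover_pct),
            "forest_change_pct": (("y", "x"), scene.forest_change_pct),
            "loss_year": (("y", "x"), scene.loss_year.astype(np.int32)),
            "loss_pct": (("y", "x"), scene.loss_pct),
            "driver": (("y", "x"), scene.driver.astype(np.int32)),
            "latitude": (("y", "x"), scene.latitude, {"units": "degrees_north"}),
            "boreal": (("y", "x"), scene.boreal.astype(np.int8)),
        },
        coords={"time": time,
                "y": np.arange(cfg.rows) * cfg.pixel_size_m,
                "x": np.arange(cfg.cols) * cfg.pixel_size_m},
        attrs={"start_year": cfg.start_year, "pixel_size_m": cfg.pixel_size_m},
    )
    ds.to_netcdf(out / "scene.nc", engine="scipy")
    pd.DataFrame([asdict(t) for t in scene.truth]).to_csv(
        out / "truth.csv", index=False)
    cfg.to_yaml(out / "config.yaml")
    return out


def read_scene(scene_dir: str | Path) -> SceneBundle:
    """Load a scene directory written by :func:`write_scene`."""
    p = Path(scene_dir)
    cfg = SceneConfig.from_yaml(p / "config.yaml")
    with xr.open_dataset(p / "scene.nc", engine="scipy", decode_times=False) as ds:
        ds = ds.load()
    truth_df = pd.read_csv(p / "truth.csv") if (p / "truth.csv").stat().st_size > 1 \
        else pd.DataFrame()
    truth = [TruthRecord(**{k: row[k] for k in TruthRecord.__dataclass_fields__})
             for _, row in truth_df.iterrows()] if len(truth_df) else []
    for t in truth:
        t.row, t.col, t.loss_year = int(t.row), int(t.col), int(t.loss_year)
    return SceneBundle(
        config=cfg,
        lst=ds["lst"].values, albedo=ds["albedo"].values, et=ds["et"].values,
        elevation=ds["elevation"].values,
        landcover=ds["landcover"].values.astype(np.int16),
        forest_cover_pct=ds["forest_cover_pct"].values,
        forest_change_pct=ds["forest_change_pct"].values,
        loss_year=ds["loss_year"].values.astype(np.int32),
        loss_pct=ds["loss_pct"].values,
        driver=ds["driver"].values.astype(np.int16),
        latitude=ds["latitude"].values,
        boreal=ds["boreal"].values.astype(bool),
        truth=truth,
    )


# ---------------------------------------------------------------------------
def series_to_csv(series: TimeSeries10d, path: str | Path) -> None:
    pd.DataFrame({"time": series.time_years, "value": series.values}).to_csv(
        path, index=False)


def read_series_csv(path: str | Path) -> TimeSeries10d:
    """Read a 2-column (decimal-year time, value) CSV as a 10-day series."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected columns: time (decimal year), value")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    start_year = int(np.floor(time.min()))
    n_years = int(np.ceil(time.max() - start_year))
    values = np.full(n_years * STEPS_PER_YEAR, np.nan)
    steps = np.round((time - start_year) * STEPS_PER_YEAR - 0.5).astype(int)
    values[steps] = df.iloc[:, 1].to_numpy(dtype=float)
    return TimeSeries10d(start_year, values)


def decomposition_to_dict(result: DecompositionResult) -> dict:
    """JSON-serializable view of a decomposition (segments, breaks, CIs)."""
    return {
        "start_year": result.start_year,
        "n_steps": result.n_steps,
        "rss": None if not np.isfinite(result.rss) else result.rss,
        "trend_segments": [
            {"start_step": s.start_step, "end_step": s.end_step,
             "intercept_k": s.intercept, "slope_k_per_year": s.slope}
            for s in result.trend_segments],
        "seasonal_segments": [
            {"start_step": s.start_step, "end_step": s.end_step,
             "coeffs": [float(c) for c in s.coeffs]}
            for s in result.seasonal_segments],
        "breakpoints": [
            {"component": b.component, "step": b.step,
             "year": b.year(result.start_year, result.steps_per_year),
             "ci_low_step": b.ci_low, "ci_high_step": b.ci_high,
             "ci_years": list(b.ci_years(result.start_year,
                                         result.steps_per_year)),
             "magnitude_k": b.magnitude}
            for b in result.breakpoints],
    }


def write_decomposition_json(result: DecompositionResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(decomposition_to_dict(result), fh, indent=2)
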