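import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lstdyn import SceneConfig, make_scene
from lstdyn.decompose import (DecompositionResult, SeasonalSegment,
                              TrendSegment)

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


SMALL_SCENE_KW = dict(rows=46, cols=46, pixel_size_m=2500.0,
                      start_year=2003, end_year=2017,
                      n_events=8, min_candidates=30, seed=5)


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene: 2.5-km pixels so the 25–50 km annulus fits a 46² grid."""
    return make_scene(SceneConfig(**SMALL_SCENE_KW))


@pytest.fixture(scope="session")
def noiseless_scene():
    cfg = SceneConfig(**{**SMALL_SCENE_KW, "noise_sd": 0.0, "anomaly_sd": 0.0,
                         "missing_fraction": 0.0, "albedo_noise_sd": 0.0,
                         "et_noise_sd": 0.0, "n_events": 4, "seed": 9})
    return make_scene(cfg)


def make_result(start_year, n_years, trend_pieces, seasonal_pieces,
                steps_per_year=36):
    """Hand-built DecompositionResult for metric tests.

    trend_pieces: list of (start_step, intercept, slope_per_year);
    seasonal_pieces: list of (start_step, (γ1, δ1, γ2, δ2)).
    """
    n = n_years * steps_per_year
    tstarts = [p[0] for p in trend_pieces] + [n]
    tsegs = [TrendSegment(s0, s1, a, b)
             for (s0, a, b), s1 in zip(trend_pieces, tstarts[1:])]
    sstarts = [p[0] for p in seasonal_pieces] + [n]
    ssegs = [SeasonalSegment(s0, s1, np.asarray(c, dtype=float))
             for (s0, c), s1 in zip(seasonal_pieces, sstarts[1:])]
    return DecompositionResult(
        start_year=start_year, n_steps=n, trend_segments=tsegs,
        seasonal_segments=ssegs, breakpoints=[],
        residuals=np.zeros(n), rss=0.0, bic=0.0,
        steps_per_year=steps_per_year)
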