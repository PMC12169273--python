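"""Generator contracts: pixel series, event injection, scene construction."""

import numpy as np
import pytest

from lstdyn import SceneConfig, TimeSeries10d, make_event_cohort, make_pixel_series, make_scene
from lstdyn.synthetic import (PixelSeriesBundle, TruthRecord,
                              _harmonic_amplitude, inject_loss_event)

SPY = 36


class TestMakePixelSeries:
    def test_flat_trend_identity(self):
        s = make_pixel_series([(0, 290.0, 0.0)], (0, 0, 0, 0), n_years=4)
        assert np.all(s.values == 290.0)

    def test_sinusoid_amplitude(self):
        s = make_pixel_series([(0, 0.0, 0.0)], (5.0, 0, 0, 0), n_years=4)
        year = s.values[:SPY]
        assert year.max() - year.min() == pytest.approx(10.0, abs=1e-12)

    def test_noise_sd_recovered(self):
        s, trend, seas = make_pixel_series(
            [(0, 290.0, 0.0)], (8, 0.3, 0.6, 0.1), noise_sd=0.5,
            seed=42, n_years=10, return_truth=True)
        resid = s.values - trend - seas
        assert 0.45 <= resid.std(ddof=1) <= 0.55

    def test_missing_fraction_masks(self):
        s = make_pixel_series([(0, 290.0, 0.0)], (5, 0, 0, 0),
                              missing_fraction=0.2, seed=3, n_years=10)
        frac = np.isnan(s.values).mean()
        assert 0.1 < frac < 0.3

    @pytest.mark.parametrize("bad", [
        dict(trend_spec=[(0, np.nan, 0.0)], harmonic_spec=(0, 0, 0, 0)),
        dict(trend_spec=[(0, 290.0, 0.0)], harmonic_spec=(np.inf, 0, 0, 0)),
        dict(trend_spec=[(5, 290.0, 0.0)], harmonic_spec=(0, 0, 0, 0)),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            make_pixel_series(**bad, n_years=4)


def _bundle(n_years=12, base=290.0, harm=(8.0, 0.3, 0.6, 0.1)):
    n = n_years * SPY
    return PixelSeriesBundle(
        start_year=2001,
        lst_trend=np.full(n, base), lst_harm=np.asarray(harm, dtype=float),
        alb_trend=np.full(n, 0.13), alb_harm=np.array([0.02, 0, 0, 0.0]),
        et_trend=np.full(n, 25.0), et_harm=np.array([10.0, 0, 0, 0.0]))


def _truth(**kw):
    base = dict(row=0, col=0, loss_year=2006, loss_pct=50.0, driver="fire",
                step_k=0.0, slope_change_k_per_decade=0.0, amp_change_k=0.0,
                phase_change_days=0.0, albedo_step=0.0, et_step=0.0)
    base.update(kw)
    return TruthRecord(**base)


class TestInjectLossEvent:
    def test_pure_step_shifts_annual_trend_means(self):
        b = inject_loss_event(_bundle(), _truth(step_k=0.4))
        t0 = (2006 - 2001) * SPY
        annual = b.lst_trend.reshape(-1, SPY).mean(axis=1)
        pre, post = annual[: t0 // SPY], annual[t0 // SPY:]
        assert post.mean() - pre.mean() == pytest.approx(0.4, abs=1e-12)
        assert np.ptp(pre) == 0 and np.ptp(post) == 0

    def test_slope_change_linear_extrapolation(self):
        b = inject_loss_event(_bundle(), _truth(slope_change_k_per_decade=-0.14))
        t0 = (2006 - 2001) * SPY
        k = t0 + 6 * SPY   # 6 years past the loss
        expected = -0.14 / 10.0 * (k + 0.5 - t0) / SPY
        assert b.lst_trend[k] - 290.0 == pytest.approx(expected, abs=1e-12)

    def test_phase_shift_moves_seasonal_argmax_one_step(self):
        b = _bundle(harm=(8.0, 0.0, 0.0, 0.0))
        days_per_step = 365.0 / SPY
        inject_loss_event(b, _truth(phase_change_days=days_per_step))
        pre = b.seasonal("lst")[:SPY]
        post = b.seasonal("lst")[-SPY:]
        assert np.argmax(post) == np.argmax(pre) + 1

    def test_amplitude_change_scales_max_minus_min(self):
        b = inject_loss_event(_bundle(), _truth(amp_change_k=2.0))
        assert (_harmonic_amplitude(b.lst_harm_post)
                - _harmonic_amplitude(b.lst_harm)) == pytest.approx(2.0, abs=1e-9)

    def test_albedo_and_et_steps(self):
        b = inject_loss_event(_bundle(), _truth(albedo_step=0.05, et_step=-2.0))
        t0 = (2006 - 2001) * SPY
        assert b.alb_trend[t0] - b.alb_trend[t0 - 1] == pytest.approx(0.05)
        assert b.et_trend[t0] - b.et_trend[t0 - 1] == pytest.approx(-2.0)

    def test_loss_too_close_to_edges_rejected(self):
        with pytest.raises(ValueError):
            inject_loss_event(_bundle(), _truth(loss_year=2002))
        with pytest.raises(ValueError):
            inject_loss_event(_bundle(n_years=12), _truth(loss_year=2012))


class TestMakeScene:
    def test_deterministic_under_seed(self):
        cfg = SceneConfig(rows=44, cols=44, pixel_size_m=2500.0,
                          start_year=2003, end_year=2010, loss_year_max=2009,
                          n_events=3, min_candidates=20, seed=21)
        a, b = make_scene(cfg), make_scene(cfg)
        assert np.array_equal(a.lst, b.lst, equal_nan=True)
        assert np.array_equal(a.loss_year, b.loss_year)
        assert [t.step_k for t in a.truth] == [t.step_k for t in b.truth]

    def test_different_seeds_differ(self):
        kw = dict(rows=44, cols=44, pixel_size_m=2500.0, start_year=2003,
                  end_year=2010, loss_year_max=2009, n_events=0)
        a = make_scene(SceneConfig(**kw, seed=1))
        b = make_scene(SceneConfig(**kw, seed=2))
        assert not np.array_equal(a.lst, b.lst, equal_nan=True)

    def test_zero_events_all_stable(self, small_scene):
        cfg = SceneConfig(rows=44, cols=44, pixel_size_m=2500.0,
                          start_year=2003, end_year=2010, loss_year_max=2009,
                          n_events=0, seed=4)
        scene = make_scene(cfg)
        assert scene.truth == []
        assert not scene.loss_pct.any()

    def test_requested_events_are_placed_with_candidates(self, small_scene):
        scene = small_scene
        assert len(scene.truth) == scene.config.n_events
        for t in scene.truth:
            assert scene.loss_year[t.row, t.col] == t.loss_year
            assert 0 < t.loss_pct <= 100
            assert scene.config.loss_year_min <= t.loss_year <= scene.config.loss_year_max

    def test_grid_too_small_for_annulus(self):
        cfg = SceneConfig(rows=10, cols=10, pixel_size_m=1000.0,
                          start_year=2003, end_year=2010, loss_year_max=2009,
                          n_events=1, seed=0)
        with pytest.raises(ValueError):
            make_scene(cfg)

    def test_anomaly_cancels_between_stable_pixels(self):
        """The shared interannual anomaly cancels in pixel differences.

        With zero observation noise, the difference of two stable pixels'
        annual means is exactly linear in time (only their slopes differ),
        while each pixel's own annual means deviate from a line by the
        anomaly.
        """
        cfg = SceneConfig(rows=44, cols=44, pixel_size_m=2500.0,
                          start_year=2003, end_year=2012, loss_year_max=2011,
                          n_events=0, noise_sd=0.0, missing_fraction=0.0,
                          anomaly_sd=0.5, seed=13)
        scene = make_scene(cfg)
        years = np.arange(cfg.n_years, dtype=float)

        def annual(r, c):
            return scene.lst[:, r, c].reshape(-1, SPY).mean(axis=1)

        def resid_from_line(v):
            coef = np.polyfit(years, v, 1)
            return v - np.polyval(coef, years)

        diff = annual(5, 5) - annual(30, 30)
        assert np.abs(resid_from_line(diff)).max() < 1e-9
        assert np.abs(resid_from_line(annual(5, 5))).max() > 0.05

    def test_truth_components_reconstruct_observations(self):
        cfg = SceneConfig(rows=44, cols=44, pixel_size_m=2500.0,
                          start_year=2003, end_year=2012, loss_year_max=2011,
                          n_events=2, min_candidates=20, noise_sd=0.0,
                          missing_fraction=0.0, anomaly_sd=0.0, seed=8)
        scene = make_scene(cfg)
        total = scene.lst_truth_trend + scene.lst_truth_seasonal
        assert np.allclose(scene.lst, total, atol=1e-12)


class TestEventCohort:
    def test_shapes_and_determinism(self):
        cfg = SceneConfig()
        a = make_event_cohort(3, 5, cfg, seed=2)
        b = make_event_cohort(3, 5, cfg, seed=2)
        assert len(a) == 3 and len(a[0].lst_backgrounds) == 5
        assert np.array_equal(a[1].lst_target.values, b[1].lst_target.values,
                              equal_nan=True)
        assert np.all((a[0].distances_m >= 25_000) & (a[0].distances_m <= 50_000))
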