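"""Response metrics: ΔT, ΔT₁, ΔT_slope, ΔS, amplitude/phase, patterns."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lstdyn import (LossWindow, abrupt_change, classify_pattern,
                    compute_response_metrics, delta_seasonal,
                    delta_trend_series, gradual_slope, seasonal_cycle_changes)
from lstdyn.timeseries import DAYS_PER_STEP

from conftest import make_result

WINDOW = LossWindow(2006, 2006)
PERIOD = (2004, 2012)
SPLIT = (2006 - 2001) * 36          # results start in 2001


def flat(level=290.0, post_offset=0.0, post_slope_extra=0.0, harm=(10.0, 0, 0, 0),
         post_harm=None):
    """Target/background stub: flat pre, optional post step/slope, harmonics."""
    return make_result(
        2001, 12,
        [(0, level, 0.0), (SPLIT, level + post_offset, post_slope_extra)],
        [(0, harm)] if post_harm is None else [(0, harm), (SPLIT, post_harm)])


class TestDeltaTrend:
    def test_identical_series_zero(self):
        dT = delta_trend_series(flat(), [flat(), flat()], WINDOW, PERIOD)
        assert np.allclose(dT.to_numpy(), 0.0, atol=1e-12)
        assert list(dT.index) == list(range(2004, 2013))

    def test_constant_target_offset(self):
        dT = delta_trend_series(flat(post_offset=1.0), [flat()], WINDOW, PERIOD)
        post = dT.loc[2007:]
        assert np.allclose(post.to_numpy(), 1.0, atol=1e-12)

    def test_idw_hand_example(self):
        # backgrounds with post-loss offsets 1 K and 3 K at 25 and 50 km:
        # δT_bg = (1/25·1 + 1/50·3)/(1/25 + 1/50) = 5/3
        dT = delta_trend_series(flat(), [flat(post_offset=1.0), flat(post_offset=3.0)],
                                WINDOW, PERIOD, weighting="idw",
                                distances_m=np.array([25_000.0, 50_000.0]))
        assert dT.loc[2008] == pytest.approx(-5.0 / 3.0, abs=1e-12)

    def test_shared_constant_cancels(self):
        # adding the same level to target and backgrounds changes nothing
        a = delta_trend_series(flat(post_offset=0.5), [flat()], WINDOW, PERIOD)
        b = delta_trend_series(flat(level=295.0, post_offset=0.5),
                               [flat(level=295.0)], WINDOW, PERIOD)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_no_backgrounds_rejected(self):
        with pytest.raises(ValueError):
            delta_trend_series(flat(), [], WINDOW, PERIOD)


class TestAbruptAndGradual:
    def test_dt1_is_value_one_year_after_window(self):
        dT = delta_trend_series(flat(post_offset=0.4), [flat()], WINDOW, PERIOD)
        assert abrupt_change(dT, WINDOW) == pytest.approx(dT.loc[2007])
        assert abrupt_change(dT, WINDOW) == pytest.approx(0.4, abs=1e-12)

    def test_dt1_requires_post_year(self):
        dT = delta_trend_series(flat(), [flat()], WINDOW, (2004, 2006))
        with pytest.raises(ValueError):
            abrupt_change(dT, WINDOW)

    def test_slope_difference_in_k_per_decade(self):
        # target post slope +0.03 K/yr vs background +0.01 K/yr → +0.2 K/decade
        tgt = flat(post_slope_extra=0.03)
        bg = flat(post_slope_extra=0.01)
        dT = delta_trend_series(tgt, [bg], WINDOW, PERIOD)
        assert gradual_slope(dT, WINDOW) == pytest.approx(0.2, abs=1e-9)

    def test_identical_series_zero_slope(self):
        dT = delta_trend_series(flat(), [flat()], WINDOW, PERIOD)
        assert gradual_slope(dT, WINDOW) == pytest.approx(0.0, abs=1e-12)

    def test_short_post_span_rejected(self):
        dT = delta_trend_series(flat(), [flat()], WINDOW, (2004, 2008))
        with pytest.raises(ValueError):
            gradual_slope(dT, WINDOW)


class TestDeltaSeasonal:
    def test_no_change_anywhere_zero(self):
        dS = delta_seasonal(flat(), [flat()], WINDOW, PERIOD)
        assert np.allclose(dS.to_numpy(), 0.0, atol=1e-12)

    def test_amplitude_scaling_signs_and_zero_mean(self):
        tgt = flat(harm=(10.0, 0, 0, 0), post_harm=(12.0, 0, 0, 0))
        dS = delta_seasonal(tgt, [flat()], WINDOW, PERIOD)
        # warm months (γ₁ sin peaks at month ~4) gain, cold months lose
        assert dS.loc[4] > 0 and dS.loc[10] < 0
        assert abs(dS.mean()) <= 1e-9

    def test_matches_analytic_harmonic_difference(self):
        pre = np.array([10.0, 1.0, 0.5, 0.2])
        post = 1.2 * pre
        tgt = flat(harm=tuple(pre), post_harm=tuple(post))
        dS = delta_seasonal(tgt, [flat()], WINDOW, PERIOD)
        t = np.arange(36)
        u = 2 * np.pi * t / 36
        basis = np.column_stack([np.sin(u), np.cos(u), np.sin(2 * u), np.cos(2 * u)])
        expected = (basis @ (post - pre)).reshape(12, 3).mean(axis=1)
        assert np.allclose(dS.to_numpy(), expected, atol=1e-9)


class TestSeasonalCycle:
    def test_amplitude_change_and_relative(self):
        tgt = flat(harm=(5.0, 0, 0, 0), post_harm=(6.0, 0, 0, 0))  # 10 → 12 K
        c = seasonal_cycle_changes(tgt, [flat(harm=(5.0, 0, 0, 0))], WINDOW, PERIOD)
        assert c.dS_A == pytest.approx(2.0, abs=1e-6)
        assert c.rel_dS_A == pytest.approx(20.0, abs=1e-4)

    def test_one_step_delay_in_days(self):
        shift = 2 * np.pi / 36
        tgt = flat(harm=(5.0, 0.0, 0, 0),
                   post_harm=(5.0 * np.cos(shift), -5.0 * np.sin(shift), 0, 0))
        c = seasonal_cycle_changes(tgt, [flat(harm=(5.0, 0, 0, 0))], WINDOW, PERIOD)
        assert c.dS_phi_days == pytest.approx(DAYS_PER_STEP, abs=1e-6)

    def test_pure_second_order_harmonic_flagged(self):
        tgt = flat(harm=(0, 0, 4.0, 1.0))
        c = seasonal_cycle_changes(tgt, [flat(harm=(0, 0, 4.0, 1.0))],
                                   WINDOW, PERIOD)
        assert not c.phase_ok and np.isnan(c.dS_phi_days)


class TestPatternTaxonomy:
    @pytest.mark.parametrize("dt1,slope,label", [
        (0.12, -0.14, "attenuated warming"),
        (0.0005, 0.05, "insignificant"),
        (-0.05, -0.16, "enhanced cooling"),
        (0.08, 0.03, "enhanced warming"),
        (0.30, 0.001, "abrupt warming"),
        (-0.05, 0.08, "attenuated cooling"),
        (-0.30, -0.001, "abrupt cooling"),
    ])
    def test_known_classifications(self, dt1, slope, label):
        assert classify_pattern(dt1, slope).label == label

    @given(st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False))
    def test_every_pair_gets_exactly_one_consistent_label(self, dt1, slope):
        p = classify_pattern(dt1, slope)
        expect1 = "+" if dt1 > 0.001 else ("-" if dt1 < -0.001 else "~")
        expect2 = "+" if slope > 0.002 else ("-" if slope < -0.002 else "~")
        assert (p.sign_dt1, p.sign_slope) == (expect1, expect2)
        if expect1 == "~":
            assert p.label == "insignificant"
        else:
            side = "warming" if expect1 == "+" else "cooling"
            assert p.label.endswith(side)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern(np.nan, 0.1)


class TestCombinedMetrics:
    def test_consistency_between_fields(self):
        tgt = flat(post_offset=0.4, post_slope_extra=-0.02,
                   harm=(5.0, 0, 0, 0), post_harm=(6.0, 0, 0, 0))
        m = compute_response_metrics(tgt, [flat(harm=(5.0, 0, 0, 0))],
                                     WINDOW, PERIOD)
        assert m.dt1 == pytest.approx(m.dT.loc[2007])
        assert m.pattern is not None
        assert m.pattern.label == "attenuated warming"
        assert m.dS_A == pytest.approx(2.0, abs=1e-6)

    def test_recovery_from_noisy_cohort(self):
        """Small-sample version of the parameter-recovery property."""
        from lstdyn import SceneConfig, fit_windowed_decomposition, make_event_cohort

        cfg = SceneConfig()
        events = make_event_cohort(40, 12, cfg, seed=31)
        bias = {"dt1": [], "slope": [], "amp": [], "phi": []}
        for ev in events:
            ly = ev.truth.loss_year
            window, period = LossWindow(ly, ly), (ly - 2, cfg.end_year)
            tgt = fit_windowed_decomposition(ev.lst_target, (ly, ly), period)
            bgs = [fit_windowed_decomposition(s, (ly, ly), period)
                   for s in ev.lst_backgrounds]
            m = compute_response_metrics(tgt, bgs, window, period)
            truth = ev.truth
            bias["dt1"].append(
                m.dt1 - truth.step_k - truth.slope_change_k_per_decade / 10 * 1.5)
            bias["slope"].append(m.dt_slope - truth.slope_change_k_per_decade)
            bias["amp"].append(m.dS_A - truth.amp_change_k)
            bias["phi"].append(m.dS_phi_days - truth.phase_change_days)
        assert abs(np.mean(bias["dt1"])) < 0.1
        assert abs(np.mean(bias["slope"])) < 0.1
        assert abs(np.mean(bias["amp"])) < 0.12
        assert abs(np.mean(bias["phi"])) < 0.6
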