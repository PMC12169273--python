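"""Forest-map aggregation, loss/break matching, windows, background rules."""

import numpy as np
import pytest

from lstdyn import (LossEvent, LossWindow, PixelGeo, aggregate_forest_maps,
                    loss_window, match_loss_to_breaks, select_background,
                    study_period)
from lstdyn.decompose import Breakpoint
from lstdyn.synthetic import DRIVER_CODES, LC_CROPLAND, LC_FOREST

from conftest import make_result


def geo(row=0, col=0, x=0.0, y=0.0, lat=45.0, elev=300.0,
        lc=LC_FOREST, cover=95.0, change=0.0):
    return PixelGeo(row, col, x, y, lat, elev, lc, cover, change)


def event(loss_year=2005, P=40.0, driver="cCRO", pixel=None):
    return LossEvent(pixel or geo(), loss_year, P, driver)


def bp(component, year, ci_lo, ci_hi, start_year=2001, spy=36):
    step = (year - start_year) * spy + 12
    return Breakpoint(component, step, (ci_lo - start_year) * spy,
                      (ci_hi - start_year) * spy + spy - 1, 1.0)


class TestAggregateForestMaps:
    def test_half_lost_full_cover(self):
        loss = np.zeros((4, 4)); loss[:2] = 1
        cover = np.ones((4, 4))
        drv = np.where(loss > 0, DRIVER_CODES["fire"], 0)
        lp, cp, dv = aggregate_forest_maps(loss, cover, drv, 4)
        assert lp[0, 0] == pytest.approx(50.0)
        assert cp[0, 0] == pytest.approx(100.0)
        assert dv[0, 0] == DRIVER_CODES["fire"]

    def test_no_loss_driver_undefined(self):
        lp, cp, dv = aggregate_forest_maps(np.zeros((2, 2)), np.ones((2, 2)),
                                           np.zeros((2, 2), int), 2)
        assert lp[0, 0] == 0.0 and dv[0, 0] == 0

    def test_driver_mode_majority(self):
        loss = np.ones((1, 8))
        cover = np.ones((1, 8))
        drv = np.array([[5, 5, 5, 5, 5, 4, 4, 4]])   # fire×5, forestry×3
        _, _, dv = aggregate_forest_maps(loss, cover, drv, 1)
        # aggregate 1×8 with block 1 → per-cell; redo with one 8-wide block
        loss = loss.reshape(8, 1).T
        _, _, dv = aggregate_forest_maps(np.ones((8, 8)), np.ones((8, 8)),
                                         np.tile([5, 5, 5, 5, 5, 4, 4, 4], (8, 1)), 8)
        assert dv[0, 0] == DRIVER_CODES["fire"]

    def test_driver_tie_breaks_to_smallest_code(self):
        drv = np.tile([1, 5], (2, 1))               # cCRO×2, fire×2
        _, _, dv = aggregate_forest_maps(np.ones((2, 2)), np.ones((2, 2)), drv, 2)
        assert dv[0, 0] == DRIVER_CODES["cCRO"]

    def test_loss_weighted_by_cover(self):
        loss = np.array([[1, 1], [0, 0]], float)
        cover = np.array([[0.5, 1.0], [1.0, 1.0]])
        lp, _, _ = aggregate_forest_maps(loss, cover, np.ones((2, 2), int), 2)
        assert lp[0, 0] == pytest.approx((0.5 + 1.0) / 4 * 100)

    def test_non_tiling_block_rejected(self):
        with pytest.raises(ValueError):
            aggregate_forest_maps(np.zeros((3, 3)), np.ones((3, 3)),
                                  np.zeros((3, 3), int), 2)


class TestMatching:
    def test_both_components_match(self):
        # loss 2005; trend break 2005 (CI 2004–2006), seasonal 2006 (CI 2005–2007)
        res = make_result(2001, 10, [(0, 290, 0)], [(0, (5, 0, 0, 0))])
        res.breakpoints = [bp("trend", 2005, 2004, 2006),
                           bp("seasonal", 2006, 2005, 2007)]
        matched = match_loss_to_breaks(event(2005), res)
        assert [b.component for b in matched] == ["trend", "seasonal"]

    def test_loss_outside_ci_no_match(self):
        res = make_result(2001, 20, [(0, 290, 0)], [(0, (5, 0, 0, 0))])
        res.breakpoints = [bp("trend", 2014, 2013, 2015)]
        assert match_loss_to_breaks(event(2010), res) == []

    def test_boundary_gap_exactly_two_years_matches(self):
        res = make_result(2001, 12, [(0, 290, 0)], [(0, (5, 0, 0, 0))])
        res.breakpoints = [bp("trend", 2010, 2007, 2011)]
        assert len(match_loss_to_breaks(event(2008), res)) == 1

    def test_inside_ci_but_gap_over_two_years_no_match(self):
        res = make_result(2001, 14, [(0, 290, 0)], [(0, (5, 0, 0, 0))])
        res.breakpoints = [bp("trend", 2011, 2007, 2012)]
        assert match_loss_to_breaks(event(2008), res) == []


class TestWindowsAndPeriods:
    def test_window_unites_loss_and_break_years(self):
        matched = [bp("trend", 2005, 2004, 2006), bp("seasonal", 2006, 2005, 2007)]
        w = loss_window(event(2005), matched, 2001)
        assert (w.start, w.end) == (2005, 2006)

    def test_single_break_same_year(self):
        w = loss_window(event(2009), [bp("trend", 2009, 2008, 2010)], 2001)
        assert (w.start, w.end) == (2009, 2009)

    def test_break_before_loss_extends_window_back(self):
        w = loss_window(event(2010), [bp("trend", 2008, 2007, 2009)], 2001)
        assert (w.start, w.end) == (2008, 2010)

    def test_no_match_raises(self):
        with pytest.raises(ValueError):
            loss_window(event(2005), [], 2001)

    def test_period_ends_before_next_break_ci(self):
        # window 2005–2006; next break CI starts 2015; series ends 2020
        later = [bp("trend", 2016, 2015, 2017)]
        assert study_period(LossWindow(2005, 2006), later, 2001, 2020) == (2003, 2014)

    def test_period_runs_to_series_end_without_later_break(self):
        assert study_period(LossWindow(2009, 2009), [], 2001, 2020) == (2007, 2020)

    def test_degenerate_post_span_rejected(self):
        later = [bp("trend", 2008, 2007, 2009)]
        with pytest.raises(ValueError):
            study_period(LossWindow(2005, 2006), later, 2001, 2020)

    def test_period_start_before_series_rejected(self):
        with pytest.raises(ValueError):
            study_period(LossWindow(2002, 2002), [], 2001, 2020)


class TestBackgroundSelection:
    def test_valid_candidate_passes_all_rules(self):
        cands = [geo(x=30_000.0, elev=350.0, change=1.0)]
        s = select_background(event(P=40.0), cands)
        assert s.exclusion is None and s.n_valid == 1
        assert s.distances_m[0] == pytest.approx(30_000.0)

    @pytest.mark.parametrize("cand", [
        geo(x=10_000.0),                       # inside inner radius
        geo(x=60_000.0),                       # beyond outer radius
        geo(x=30_000.0, elev=450.0),           # elevation differs by >100 m
        geo(x=30_000.0, change=3.0),           # forest change above 2%
        geo(x=30_000.0, lc=LC_CROPLAND),       # not forest cover
    ])
    def test_invalid_candidates_rejected(self, cand):
        s = select_background(event(P=40.0), [cand, geo(x=40_000.0)])
        assert s.n_valid == 1   # only the always-valid companion survives

    def test_change_cap_uses_min_of_two_percent_and_loss_pct(self):
        # P = 1.5% → cap is 1.5, so a 1.8% change candidate is invalid
        cands = [geo(x=30_000.0, change=1.8), geo(x=40_000.0, change=1.0)]
        s = select_background(event(P=1.5), cands)
        assert s.n_valid == 1

    def test_five_percent_rule_excludes_sample(self):
        good = [geo(x=26_000.0 + i, elev=300.0) for i in range(12)]
        bad = [geo(x=30_000.0, y=float(i), elev=900.0) for i in range(388)]
        s = select_background(event(P=40.0), good + bad)
        assert s.exclusion == "too_few_valid_backgrounds"
        assert s.n_candidates == 400 and s.n_valid == 12

    def test_empty_annulus_excluded_with_reason(self):
        s = select_background(event(), [geo(x=1_000.0)])
        assert s.exclusion == "empty_annulus"

    def test_annulus_bounds_inclusive(self):
        cands = [geo(x=25_000.0), geo(x=50_000.0, y=0.0)]
        s = select_background(event(), cands)
        assert s.n_valid == 2

    def test_selection_idempotent(self):
        rng = np.random.default_rng(3)
        cands = [geo(x=float(x), y=float(y), elev=300 + float(e), change=float(c))
                 for x, y, e, c in zip(rng.uniform(-60e3, 60e3, 200),
                                       rng.uniform(-60e3, 60e3, 200),
                                       rng.normal(0, 80, 200),
                                       rng.uniform(0, 3, 200))]
        s1 = select_background(event(P=40.0), cands)
        s2 = select_background(event(P=40.0), s1.backgrounds)
        assert [(g.x, g.y) for g in s2.backgrounds] == \
               [(g.x, g.y) for g in s1.backgrounds]
        assert np.all((s1.distances_m >= 25_000) & (s1.distances_m <= 50_000))


def test_event_pixels_never_valid_backgrounds(small_scene):
    """Injected loss pixels carry forest change ≥ P ≥ cap, so the stability
    rule excludes them from every other event's background set."""
    scene = small_scene
    for t in scene.truth:
        change = scene.forest_change_pct[t.row, t.col]
        assert change >= t.loss_pct
        assert change >= 2.0   # ≥ min(2, P) for any target's cap
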