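"""Stage segmentation, flight bouts, KDE occupancy, top-quartile overlap."""

import numpy as np
import pandas as pd
import pytest

from shearwater.migration import (
    AnalysisConfig,
    Stage,
    detect_flight_bouts,
    kde_occupancy,
    segment_stages,
    split_substages,
    top_quartile_overlap,
)


class TestSegmentStages:
    def test_recovers_simulated_boundaries(self, annual_bird, annual_daily, sim_config):
        stages = segment_stages(annual_daily, sim_config.colony)
        truth = annual_bird.stage_truth
        by_kind = {s.kind: s for s in stages if s.kind != "breeding"}
        for kind in ("migration_south", "winter", "migration_north"):
            t = truth[truth["kind"] == kind].iloc[0]
            est = by_kind[kind]
            assert abs((pd.Timestamp(est.start) - pd.Timestamp(t["start"])).days) <= 2
            assert abs((pd.Timestamp(est.end) - pd.Timestamp(t["end"])).days) <= 2

    def test_stages_tile_without_overlap(self, annual_daily, sim_config):
        stages = segment_stages(annual_daily, sim_config.colony)
        for a, b in zip(stages[:-1], stages[1:]):
            assert pd.Timestamp(b.start) == pd.Timestamp(a.end) + pd.Timedelta(days=1)
        assert stages[0].start == annual_daily["date"].iloc[0]
        assert stages[-1].end == annual_daily["date"].iloc[-1]

    def test_all_at_colony_single_breeding_stage(self, sim_config):
        dates = pd.date_range("2008-01-01", periods=90).date
        daily = pd.DataFrame(
            {"date": dates, "lat": sim_config.colony[0], "lon": sim_config.colony[1]}
        )
        stages = segment_stages(daily, sim_config.colony)
        assert [s.kind for s in stages] == ["breeding"]

    def test_no_southern_positions_rejected(self, sim_config):
        dates = pd.date_range("2008-01-01", periods=90).date
        daily = pd.DataFrame({"date": dates, "lat": 30.0, "lon": -20.0})
        with pytest.raises(ValueError):
            segment_stages(daily, sim_config.colony)

    def test_zero_radius_degenerate(self, annual_daily, sim_config):
        cfg = AnalysisConfig(proximity_radius_km=0.0)
        # continuous jitter means no day sits exactly on either centre
        with pytest.raises(ValueError):
            segment_stages(annual_daily, sim_config.colony, cfg)


class TestSubstages:
    def test_hundred_day_stage(self):
        st = Stage("winter", pd.Timestamp("2008-01-01").date(), pd.Timestamp("2008-04-09").date())
        assert st.n_days == 100
        subs = split_substages(st)
        assert [s.n_days for s in subs] == [30, 40, 30]
        assert subs[0].start == st.start
        assert subs[-1].end == st.end

    def test_sixty_one_day_stage(self):
        st = Stage("winter", pd.Timestamp("2008-01-01").date(), pd.Timestamp("2008-03-01").date())
        assert st.n_days == 61
        subs = split_substages(st)
        assert [s.n_days for s in subs] == [30, 1, 30]

    def test_sixty_day_stage_empty_middle_warns(self):
        st = Stage("winter", pd.Timestamp("2008-01-01").date(), pd.Timestamp("2008-02-29").date())
        assert st.n_days == 60
        with pytest.warns(UserWarning):
            subs = split_substages(st)
        assert [s.n_days for s in subs] == [30, 30]


class TestFlightBouts:
    @staticmethod
    def _daily(wets, start="2008-03-01"):
        dates = pd.date_range(start, periods=len(wets)).date
        return pd.DataFrame({"date": dates, "wet": wets})

    @staticmethod
    def _stage(n, start="2008-03-01"):
        dates = pd.date_range(start, periods=n)
        return [Stage("migration_south", dates[0].date(), dates[-1].date())]

    def test_threshold_scan_finds_run(self):
        bouts = detect_flight_bouts(self._daily([0.9, 0.2, 0.1, 0.8]), self._stage(4))
        assert len(bouts) == 1
        assert bouts[0].start == pd.Timestamp("2008-03-02").date()
        assert bouts[0].end == pd.Timestamp("2008-03-03").date()

    def test_departure_and_arrival_runs(self):
        wets = [0.1, 0.1, 0.8, 0.7, 0.9, 0.2, 0.15]
        bouts = detect_flight_bouts(self._daily(wets), self._stage(7))
        assert [b.position for b in bouts] == ["departure", "arrival"]
        assert bouts[0].end == pd.Timestamp("2008-03-02").date()
        assert bouts[1].start == pd.Timestamp("2008-03-06").date()

    def test_no_days_below_threshold(self):
        bouts = detect_flight_bouts(self._daily([0.9, 0.5, 0.3]), self._stage(3))
        assert bouts == []

    def test_degenerate_threshold_covers_everything(self):
        cfg = AnalysisConfig(flight_bout_threshold=1.0)
        bouts = detect_flight_bouts(self._daily([0.9, 0.5, 0.3]), self._stage(3), cfg)
        assert len(bouts) == 1
        assert bouts[0].start == pd.Timestamp("2008-03-01").date()
        assert bouts[0].end == pd.Timestamp("2008-03-03").date()


KDE_CFG = AnalysisConfig(kde_cell=0.05, kde_bandwidth=0.2)


@pytest.fixture(scope="module")
def normal_sample_grid():
    rng = np.random.default_rng(0)
    pts = pd.DataFrame({"lon": rng.normal(0, 1, 5000), "lat": rng.normal(0, 1, 5000)})
    return kde_occupancy(pts, KDE_CFG)


class TestKdeOccupancy:
    CFG = KDE_CFG

    def test_density_integrates_to_one(self, normal_sample_grid):
        g = normal_sample_grid
        assert g.density.sum() * g.cell**2 == pytest.approx(1.0, abs=1e-6)

    def test_isopleth_containment_and_area_monotone(self, normal_sample_grid):
        g = normal_sample_grid
        assert g.contours[0.95].area >= g.contours[0.5].area
        # the 95% region must contain the 50% region
        assert g.contours[0.95].density_threshold <= g.contours[0.5].density_threshold
        for p50 in g.contours[0.5].polygons:
            c = p50.representative_point()
            assert g.contours[0.95].contains(c.x, c.y)

    def test_half_mass_contour_matches_analytic_area(self, normal_sample_grid):
        # KDE of N(0,1) with bandwidth h is ~ N(0, 1 + h^2); its 50% highest
        # density region is a disc of area pi * (1+h^2) * 2 ln 2
        s2 = 1.0 + self.CFG.kde_bandwidth**2
        analytic = np.pi * s2 * 2 * np.log(2)
        assert normal_sample_grid.contours[0.5].area == pytest.approx(analytic, rel=0.10)

    def test_distant_clusters_give_disjoint_polygons(self):
        rng = np.random.default_rng(1)
        pts = pd.DataFrame(
            {
                "lon": np.r_[rng.normal(0, 1, 2000), rng.normal(30, 1, 2000)],
                "lat": np.r_[rng.normal(0, 1, 2000), rng.normal(0, 1, 2000)],
            }
        )
        g = kde_occupancy(pts, AnalysisConfig(kde_cell=0.1, kde_bandwidth=0.5))
        polys = g.contours[0.5].polygons
        assert len(polys) == 2
        assert not polys[0].intersects(polys[1])

    def test_identical_locations_warn(self):
        pts = pd.DataFrame({"lon": np.zeros(20), "lat": np.zeros(20)})
        with pytest.warns(UserWarning):
            g = kde_occupancy(pts, AnalysisConfig(kde_cell=0.1, kde_bandwidth=0.5))
        assert g.density.sum() * g.cell**2 == pytest.approx(1.0, abs=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kde_occupancy(pd.DataFrame({"lon": [], "lat": []}), self.CFG)


class TestTopQuartileOverlap:
    @staticmethod
    def _days(p, start="2008-03-01"):
        dates = pd.date_range(start, periods=len(p)).date
        df = pd.DataFrame(p, columns=["p_rest", "p_flight", "p_forage"])
        df.insert(0, "date", dates)
        df["lat"] = 0.0
        df["lon"] = np.arange(len(p), dtype=float)
        return df

    def test_orthogonal_days_no_overlap(self):
        p = [(1, 0, 0), (1, 0, 0), (0, 1, 0), (0, 1, 0), (0, 0, 1), (0, 0, 1), (0.4, 0.3, 0.3), (0.3, 0.4, 0.3)]
        out = top_quartile_overlap(self._days(p))
        assert out["percent"]["two"] == 0.0
        assert out["percent"]["three"] == 0.0

    def test_percentages_partition(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet([2, 2, 2], size=40)
        out = top_quartile_overlap(self._days(p))
        total = sum(out["percent"].values())
        assert total == pytest.approx(100.0)

    def test_tied_proportions_break_by_date(self):
        p = [(1 / 3, 1 / 3, 1 / 3)] * 8
        out = top_quartile_overlap(self._days(p))
        assert out["set_size"] == 2
        # all behaviours pick the earliest two days
        assert out["top_sets"]["rest"] == {0, 1}
        assert out["top_sets"]["flight"] == {0, 1}

    def test_covarying_flight_forage_overlap_composition(self):
        # flight and forage rise together on "travel" days
        p = []
        for i in range(16):
            if i % 4 == 0:
                p.append((0.2, 0.45, 0.35))
            else:
                p.append((0.9, 0.05, 0.05))
        out = top_quartile_overlap(self._days(p))
        assert out["percent"]["two"] > 0.0
        assert out["two_set_composition"]["flight+forage"] == 100.0
        assert out["two_set_composition"]["rest+flight"] == 0.0

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            top_quartile_overlap(self._days([(1, 0, 0)] * 3))
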