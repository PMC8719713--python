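import numpy as np
import pandas as pd
import pytest

from conftest import make_fix, make_track
from whimtrack import segmentation as seg
from whimtrack.geodesy import destination_point, great_circle_km
from whimtrack.io import Fix, Track

UTC = "UTC"


class TestTerritoryModel:
    def test_identical_fixes_give_zero_dispersion(self):
        fixes = [make_fix(t=f"2020-06-01T0{i}:00:00") for i in range(4)]
        m = seg.fit_territory_model(fixes)
        assert (m.centroid_lat, m.centroid_lon) == (60.0, -90.0)
        assert m.mean_disp_km == 0.0 and m.sd_disp_km == 0.0

    def test_square_corners_symmetric_displacements(self):
        corners = [(60.0, -90.0), (60.0, -89.9), (60.1, -90.0), (60.1, -89.9)]
        fixes = [make_fix(t=f"2020-06-01T0{i}:00:00", lat=la, lon=lo)
                 for i, (la, lo) in enumerate(corners)]
        m = seg.fit_territory_model(fixes)
        assert m.centroid_lat == pytest.approx(60.05)
        assert m.centroid_lon == pytest.approx(-89.95)
        assert m.sd_disp_km < 0.01 * m.mean_disp_km   # near-equal by symmetry

    def test_antimeridian_centroid(self):
        fixes = [make_fix(t=f"2020-06-01T0{i}:00:00", lat=0.0, lon=lo)
                 for i, lo in enumerate([179.9, -179.9, 179.9])]
        m = seg.fit_territory_model(fixes)
        # circular unwrap: (179.9 + 180.1 + 179.9)/3, not a naive mean near 60
        assert abs(abs(m.centroid_lon) - 179.9667) < 0.01

    def test_too_few_fixes(self):
        with pytest.raises(ValueError):
            seg.fit_territory_model([make_fix(), make_fix(t="2020-06-01T01:00:00")])


def _territory_then_flight(n_home=20, jitter=0.001, bearing=90.0, speed_kmh=53.0,
                           step_h=1.0):
    """Fixes at a territory, then ballistic flight away at constant speed."""
    rng = np.random.default_rng(0)
    home = (60.0, -90.0)
    pos = [(home[0] + rng.normal(0, jitter), home[1] + rng.normal(0, jitter))
           for _ in range(n_home)]
    for k in range(1, 15):
        la, lo = destination_point(*home, bearing, speed_kmh * k * step_h)
        pos.append((la, lo))
    return make_track(pos, step_h=step_h), n_home


class TestBreakout:
    def test_no_movement_means_no_event(self):
        track, n_home = _territory_then_flight()
        model = seg.fit_territory_model(track.fixes[:n_home])
        stay = Track("a", track.fixes[:n_home])
        assert seg.detect_breakout(stay, model) is None

    def test_departure_is_first_post_breakout_fix(self):
        track, n_home = _territory_then_flight()
        model = seg.fit_territory_model(track.fixes[:n_home])
        ev = seg.detect_breakout(track, model)
        assert ev is not None and ev.kind == "departure"
        assert ev.observed_fix.timestamp == track.fixes[n_home].timestamp

    def test_single_outlier_with_return_is_not_an_event(self):
        """A lone spike beyond threshold followed by return: no false start."""
        rng = np.random.default_rng(1)
        home = (60.0, -90.0)
        pos = [(home[0] + rng.normal(0, 0.001), home[1] + rng.normal(0, 0.001))
               for _ in range(10)]
        pos.insert(5, destination_point(*home, 45.0, 30.0))   # 30 km excursion fix
        track = make_track(pos)
        model = seg.fit_territory_model(track.fixes[:4])
        assert seg.detect_breakout(track, model) is None

    def test_translation_invariance_away_from_antimeridian(self):
        track, n_home = _territory_then_flight()
        model = seg.fit_territory_model(track.fixes[:n_home])
        t_ev = seg.detect_breakout(track, model).observed_fix.timestamp
        shifted = Track("a", [Fix("a", f.timestamp, f.lat, f.lon + 30.0,
                                  f.location_class) for f in track.fixes])
        model2 = seg.fit_territory_model(shifted.fixes[:n_home])
        ev2 = seg.detect_breakout(shifted, model2)
        assert ev2.observed_fix.timestamp == t_ev


class TestEventInterpolation:
    def _event(self, kind, obs_t, lat, lon):
        fix = make_fix(t=obs_t, lat=lat, lon=lon)
        return seg.TransitionEvent(kind=kind, season="autumn", observed_fix=fix,
                                   event_time=fix.timestamp, interpolated=False)

    def test_slow_apparent_speed_interpolates_with_mean_flight_speed(self):
        """264.6 km across a gap at apparent 5 m/s → offset 264.6/52.92 = 5 h."""
        la, lo = destination_point(60.0, -90.0, 180.0, 264.6)
        dt_h = 264.6 / (5.0 * 3.6)   # gap giving apparent speed 5 m/s
        obs_t = pd.Timestamp("2020-07-10T00:00:00", tz=UTC)
        ev = self._event("departure", obs_t, la, lo)
        neighbor = make_fix(t=str(obs_t - pd.Timedelta(hours=dt_h)))
        out = seg.interpolate_event_time(ev, neighbor)
        assert out.interpolated
        offset_h = (obs_t - out.event_time).total_seconds() / 3600.0
        assert offset_h == pytest.approx(5.0, abs=1e-3)

    def test_fast_apparent_speed_keeps_observed_time(self):
        la, lo = destination_point(60.0, -90.0, 180.0, 100.0)
        dt_h = 100.0 / (14.0 * 3.6)   # apparent 14 m/s >= 10.68 threshold
        obs_t = pd.Timestamp("2020-07-10T00:00:00", tz=UTC)
        ev = self._event("departure", obs_t, la, lo)
        neighbor = make_fix(t=str(obs_t - pd.Timedelta(hours=dt_h)))
        out = seg.interpolate_event_time(ev, neighbor)
        assert not out.interpolated and out.event_time == obs_t

    def test_arrival_adds_flight_time_to_previous_fix(self):
        la, lo = destination_point(60.0, -90.0, 180.0, 264.6)
        obs_t = pd.Timestamp("2020-07-12T00:00:00", tz=UTC)
        ev = self._event("arrival", obs_t, 60.0, -90.0)
        neighbor = make_fix(t=str(obs_t - pd.Timedelta(hours=48)), lat=la, lon=lo)
        out = seg.interpolate_event_time(ev, neighbor)
        assert out.interpolated
        got_h = (out.event_time - neighbor.timestamp).total_seconds() / 3600.0
        assert got_h == pytest.approx(5.0, abs=1e-3)

    def test_zero_distance_and_zero_dt(self):
        obs_t = "2020-07-10T00:00:00"
        ev = self._event("arrival", obs_t, 60.0, -90.0)
        neighbor = make_fix(t="2020-07-09T00:00:00")
        out = seg.interpolate_event_time(ev, neighbor)
        assert out.event_time == neighbor.timestamp   # zero distance: no flight time
        bad = make_fix(t=obs_t, lat=61.0)
        with pytest.raises(ValueError):
            seg.interpolate_event_time(self._event("arrival", obs_t, 60.0, -90.0), bad)


class TestStationaryPeriods:
    def test_ballistic_track_has_no_periods(self):
        pos = [destination_point(40.0, -70.0, 90.0, 53.0 * k) for k in range(30)]
        assert seg.detect_stationary_periods(make_track(pos)) == []

    def test_single_stop_recovered(self):
        pos = [destination_point(40.0, -70.0, 90.0, 53.0 * k) for k in range(5)]
        stop = pos[-1]
        pos += [stop] * 72                     # 3-day stop at hourly cadence
        pos += [destination_point(*stop, 90.0, 53.0 * k) for k in range(1, 5)]
        periods = seg.detect_stationary_periods(make_track(pos))
        assert len(periods) == 1
        assert periods[0].duration_d == pytest.approx(72 / 24.0, abs=0.05)

    def test_two_stops_split_by_flight(self):
        a = (40.0, -70.0)
        b = destination_point(*a, 90.0, 110.0)   # 110 km apart, ~2 h flight
        pos = [a] * 12
        pos += [destination_point(*a, 90.0, 55.0)]   # one in-flight fix
        pos += [b] * 12
        periods = seg.detect_stationary_periods(make_track(pos))
        assert len(periods) == 2
        assert great_circle_km(periods[0].centroid_lat, periods[0].centroid_lon,
                               periods[1].centroid_lat, periods[1].centroid_lon) > 100


class TestSeasons:
    def _ev(self, kind, t):
        return seg.TransitionEvent(kind=kind, season="", observed_fix=make_fix(t=t),
                                   event_time=pd.Timestamp(t, tz=UTC), interpolated=False)

    def test_durations_are_calendar_differences_and_partition(self):
        cyc = seg.delineate_seasons(
            self._ev("departure", "2015-07-07"), self._ev("arrival", "2015-08-30"),
            self._ev("departure", "2016-04-06"), self._ev("arrival", "2016-05-31"),
            next_breeding_departure=self._ev("departure", "2016-07-07"))
        d = cyc.durations_d
        assert d["autumn_migration"] == pytest.approx(54.0)
        assert d["winter"] == pytest.approx(220.0)
        assert d["spring_migration"] == pytest.approx(55.0)
        assert d["breeding"] == pytest.approx(37.0)
        total = sum(d.values())
        span = (pd.Timestamp("2016-07-07", tz=UTC)
                - pd.Timestamp("2015-07-07", tz=UTC)).total_seconds() / 86400.0
        assert total == pytest.approx(span)

    def test_out_of_order_events_raise_naming_the_pair(self):
        with pytest.raises(ValueError, match="winter_departure"):
            seg.delineate_seasons(
                self._ev("departure", "2015-07-07"), self._ev("arrival", "2015-08-30"),
                self._ev("departure", "2015-08-01"), self._ev("arrival", "2016-05-31"))
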