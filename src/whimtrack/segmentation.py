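"""Annual-cycle delineation from quality-filtered tracks.

The season boundaries follow the breakout convention used in satellite
tracking studies of territorial migrants:

* a *territory model* is a centroid of residency fixes with the mean and SD
  of great-circle displacements from it;
* *departure* is the first fix whose displacement exceeds mean + 2·SD
  (confirmed by the next fix, or by a net displacement > 100 km, so a single
  noisy fix cannot trigger a false start);
* *arrival* is the first fix that settles within the destination territory's
  threshold, with the same confirmation;
* when the transition happened inside a transmitter off-period, the event
  time is interpolated from the mean flight speed (14.7 m/s) and the
  great-circle distance across the gap, provided the apparent speed over the
  gap is less than 2 SD below the mean flight speed (14.7 − 2·2.01 m/s);
* the four seasons partition each tracked year: autumn migration
  [breeding departure, winter arrival), winter, spring migration, breeding.

Stationary periods along migration (staging and stopover visits) are maximal
runs of slow, spatially compact fixes lasting at least ``min_duration_h``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geodesy import circular_mean_lon, great_circle_km, normalize_lon
from .io import Fix, Track

MEAN_FLIGHT_SPEED_MPS = 14.7
FLIGHT_SPEED_SD_MPS = 2.01          # published ±0.3 m/s (n=45) read as an SE


@dataclass(frozen=True)
class TerritoryModel:
    centroid_lat: float
    centroid_lon: float
    mean_disp_km: float
    sd_disp_km: float
    n_fixes: int

    @property
    def threshold_km(self) -> float:
        """Breakout displacement threshold: mean + 2 SD."""
        return self.mean_disp_km + 2.0 * self.sd_disp_km

    def displacement_km(self, lat, lon):
        return great_circle_km(self.centroid_lat, self.centroid_lon, lat, lon)


@dataclass
class TransitionEvent:
    kind: str                 # departure | arrival
    season: str               # autumn | winter | spring | breeding
    observed_fix: Fix
    event_time: pd.Timestamp
    interpolated: bool


@dataclass
class StationaryPeriod:
    animal_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    centroid_lat: float
    centroid_lon: float
    n_fixes: int
    season: str | None = None      # autumn | spring once assigned to a migration

    @property
    def duration_d(self) -> float:
        return (self.end - self.start).total_seconds() / 86400.0


@dataclass
class AnnualCycle:
    """Initiation dates and durations of the four seasons for one animal-year."""

    animal_id: str
    year: int
    initiation: dict          # season -> Timestamp (initiation instant)
    durations_d: dict         # season -> float days (NaN where open-ended)
    population: str | None = None


@dataclass(frozen=True)
class StationaryConfig:
    max_speed_kmh: float = 5.0
    max_radius_km: float = 25.0
    min_duration_h: float = 6.0
    error_allowance_km: float = 3.0   # tolerated ARGOS scatter between near-simultaneous fixes


def fit_territory_model(fixes) -> TerritoryModel:
    """Centroid (arithmetic mean lat, circular-unwrapped mean lon) and
    great-circle displacement statistics of residency fixes."""
    fixes = list(fixes)
    if len(fixes) < 3:
        raise ValueError(f"need at least 3 fixes to fit a territory, got {len(fixes)}")
    lats = np.array([f.lat for f in fixes])
    lons = np.array([f.lon for f in fixes])
    ref = circular_mean_lon(lons)
    unwrapped = ref + (lons - ref + 180.0) % 360.0 - 180.0
    c_lat = float(np.mean(lats))
    c_lon = float(normalize_lon(np.mean(unwrapped)))
    d = great_circle_km(c_lat, c_lon, lats, lons)
    d = np.atleast_1d(d)
    return TerritoryModel(centroid_lat=c_lat, centroid_lon=c_lon,
                          mean_disp_km=float(np.mean(d)),
                          sd_disp_km=float(np.std(d, ddof=0)),
                          n_fixes=len(fixes))


def detect_breakout(track: Track, model: TerritoryModel, from_time=None,
                    season: str = "", confirm_km: float = 100.0,
                    confirm_margin_km: float = 5.0,
                    confirm_min_dt_h: float = 2.0) -> TransitionEvent | None:
    """First confirmed fix beyond the territory's mean + 2·SD displacement.

    Confirmation guards against measurement scatter and territory wander: a
    candidate is an event if it is already a net displacement > ``confirm_km``
    (an abrupt long jump needs no second witness), or if the first fix at
    least ``confirm_min_dt_h`` later exceeds the threshold by
    ``confirm_margin_km`` (a genuine migrant is far out by then; wander plus
    positional error cannot be).  Returns ``None`` when the animal never
    leaves.
    """
    fixes = _fixes_after(track, from_time)
    for i, f in enumerate(fixes):
        d = model.displacement_km(f.lat, f.lon)
        if d <= model.threshold_km:
            continue
        if d > confirm_km:
            confirmed = True
        else:
            later = [g for g in fixes[i + 1:]
                     if (g.timestamp - f.timestamp).total_seconds() >= confirm_min_dt_h * 3600.0]
            confirmed = bool(later) and (
                model.displacement_km(later[0].lat, later[0].lon)
                > model.threshold_km + confirm_margin_km)
        if confirmed:
            return TransitionEvent(kind="departure", season=season, observed_fix=f,
                                   event_time=f.timestamp, interpolated=False)
    return None


def detect_arrival(track: Track, model: TerritoryModel, from_time=None,
                   season: str = "", min_arrival_radius_km: float = 30.0) -> TransitionEvent | None:
    """First confirmed fix settling within the destination territory.

    The settling radius is the breakout threshold, floored at
    ``min_arrival_radius_km`` so a tight territory model still captures an
    arrival fix perturbed by measurement error.
    """
    radius = max(model.threshold_km, min_arrival_radius_km)
    fixes = _fixes_after(track, from_time)
    for i, f in enumerate(fixes):
        if model.displacement_km(f.lat, f.lon) > radius:
            continue
        if i + 1 < len(fixes):
            nxt = fixes[i + 1]
            if model.displacement_km(nxt.lat, nxt.lon) > radius:
                continue
        return TransitionEvent(kind="arrival", season=season, observed_fix=f,
                               event_time=f.timestamp, interpolated=False)
    return None


def interpolate_event_time(event: TransitionEvent, neighbor_fix: Fix,
                           mean_speed_mps: float = MEAN_FLIGHT_SPEED_MPS,
                           sd_speed_mps: float = FLIGHT_SPEED_SD_MPS) -> TransitionEvent:
    """Refine an event time across a duty-cycle gap using the mean flight speed.

    ``neighbor_fix`` is the fix on the other side of the gap from the event
    fix: the last territory fix for a departure, the last in-flight fix for
    an arrival.  If the apparent speed over the gap is below
    mean − 2·SD (default 14.7 − 4.02 m/s = 10.68 m/s ⇒ part of the gap was
    spent stationary), the event time is set from the great-circle distance
    flown at the mean speed; otherwise the observed fix time stands.
    """
    obs = event.observed_fix
    d_km = great_circle_km(neighbor_fix.lat, neighbor_fix.lon, obs.lat, obs.lon)
    dt_s = abs((obs.timestamp - neighbor_fix.timestamp).total_seconds())
    if dt_s == 0:
        if d_km > 0:
            raise ValueError("zero time between fixes with nonzero separation")
        return replace(event, interpolated=False)
    apparent_mps = d_km * 1000.0 / dt_s
    threshold = mean_speed_mps - 2.0 * sd_speed_mps
    if apparent_mps >= threshold:
        return replace(event, event_time=obs.timestamp, interpolated=False)
    flight = pd.Timedelta(seconds=d_km * 1000.0 / mean_speed_mps)
    if event.kind == "departure":
        t = max(obs.timestamp - flight, neighbor_fix.timestamp)
    else:
        t = min(neighbor_fix.timestamp + flight, obs.timestamp)
    return replace(event, event_time=t, interpolated=True)


def detect_stationary_periods(track: Track, cfg: StationaryConfig | None = None):
    """Maximal runs of slow, compact fixes: the animal's staging/stopover visits.

    Consecutive fixes join a run while the segment displacement stays below
    ``max_speed_kmh``·Δt plus a positional-error allowance (so two fixes
    minutes apart do not register an apparent flight from measurement
    scatter alone) and the fix lies within ``max_radius_km`` of the run's
    running centroid; runs shorter than ``min_duration_h`` are discarded.
    """
    cfg = cfg or StationaryConfig()
    out = []
    run: list[Fix] = []
    run_sum = [0.0, 0.0]    # running (lat, lon) sums for the centroid test

    def close():
        if len(run) >= 2:
            dur_h = (run[-1].timestamp - run[0].timestamp).total_seconds() / 3600.0
            if dur_h >= cfg.min_duration_h:
                lats = np.array([f.lat for f in run])
                lons = np.array([f.lon for f in run])
                ref = circular_mean_lon(lons)
                unwrapped = ref + (lons - ref + 180.0) % 360.0 - 180.0
                out.append(StationaryPeriod(
                    animal_id=track.animal_id, start=run[0].timestamp,
                    end=run[-1].timestamp, centroid_lat=float(np.mean(lats)),
                    centroid_lon=float(normalize_lon(np.mean(unwrapped))),
                    n_fixes=len(run)))
        run.clear()

    for f in track.fixes:
        if not run:
            run.append(f)
            run_sum[:] = [f.lat, f.lon]
            continue
        prev = run[-1]
        dt_h = (f.timestamp - prev.timestamp).total_seconds() / 3600.0
        d_km = great_circle_km(prev.lat, prev.lon, f.lat, f.lon)
        slow = d_km < cfg.max_speed_kmh * dt_h + cfg.error_allowance_km
        c_lat = run_sum[0] / len(run)
        c_lon = run_sum[1] / len(run)
        if slow and great_circle_km(c_lat, c_lon, f.lat, f.lon) <= cfg.max_radius_km:
            run.append(f)
            run_sum[0] += f.lat
            run_sum[1] += f.lon
        else:
            close()
            run.append(f)
            run_sum[:] = [f.lat, f.lon]
    close()
    return out


def delineate_seasons(breeding_departure: TransitionEvent, winter_arrival: TransitionEvent,
                      winter_departure: TransitionEvent, breeding_arrival: TransitionEvent,
                      animal_id: str = "", year: int = 0,
                      next_breeding_departure: TransitionEvent | None = None,
                      population: str | None = None) -> AnnualCycle:
    """Partition one tracked year into the four seasons.

    autumn = [breeding departure, winter arrival); winter = [winter arrival,
    winter departure); spring = [winter departure, breeding arrival);
    breeding runs from breeding arrival to the next breeding departure (open
    when the next departure is untracked → duration NaN).
    """
    order = [("breeding_departure", breeding_departure),
             ("winter_arrival", winter_arrival),
             ("winter_departure", winter_departure),
             ("breeding_arrival", breeding_arrival)]
    for (n1, e1), (n2, e2) in zip(order, order[1:]):
        if e2.event_time <= e1.event_time:
            raise ValueError(f"events out of order: {n2} not after {n1}")
    t = {k: e.event_time for k, e in order}

    def days(a, b):
        return (b - a).total_seconds() / 86400.0

    initiation = {
        "autumn_migration": t["breeding_departure"],
        "winter": t["winter_arrival"],
        "spring_migration": t["winter_departure"],
        "breeding": t["breeding_arrival"],
    }
    durations = {
        "autumn_migration": days(t["breeding_departure"], t["winter_arrival"]),
        "winter": days(t["winter_arrival"], t["winter_departure"]),
        "spring_migration": days(t["winter_departure"], t["breeding_arrival"]),
        "breeding": (days(t["breeding_arrival"], next_breeding_departure.event_time)
                     if next_breeding_departure is not None else float("nan")),
    }
    return AnnualCycle(animal_id=animal_id, year=year, initiation=initiation,
                       durations_d=durations, population=population)


# --- per-animal driver -----------------------------------------------------

@dataclass(frozen=True)
class SegmentationConfig:
    territory_window_d: float = 14.0
    min_winter_d: float = 45.0
    stationary: StationaryConfig = StationaryConfig()
    mean_speed_mps: float = MEAN_FLIGHT_SPEED_MPS
    sd_speed_mps: float = FLIGHT_SPEED_SD_MPS


def segment_annual_cycles(track: Track, cfg: SegmentationConfig | None = None,
                          population: str | None = None):
    """Delineate every tracked annual cycle of one quality-filtered track.

    Assumes tracking begins on the breeding territory (the deployment
    convention).  Returns (events, cycles, stationary_periods); events are
    time-ordered with interpolated times where the speed rule fired.
    """
    cfg = cfg or SegmentationConfig()
    if len(track.fixes) < 10:
        return [], [], []
    periods = detect_stationary_periods(track, cfg.stationary)
    events: list[TransitionEvent] = []
    cycles: list[AnnualCycle] = []

    t0 = track.times[0]
    breeding_model = fit_territory_model(
        track.between(end=t0 + pd.Timedelta(days=cfg.territory_window_d)).fixes)

    cursor = t0
    pending = []   # (dep, w_arr, w_dep, b_arr) per cycle, to chain next-year departures
    while True:
        dep = detect_breakout(track, breeding_model, from_time=cursor, season="autumn")
        if dep is None:
            break
        dep = _refine(track, dep, cfg)
        winter_period = _winter_period(periods, dep.event_time, cfg.min_winter_d)
        if winter_period is None:
            events.append(dep)
            break
        winter_model = fit_territory_model(
            track.between(start=winter_period.start,
                          end=winter_period.start + pd.Timedelta(days=cfg.territory_window_d)).fixes)
        w_arr = detect_arrival(track, winter_model, from_time=dep.event_time, season="winter")
        w_arr = _refine(track, w_arr, cfg)
        w_dep = detect_breakout(track, winter_model, from_time=winter_period.end
                                if winter_period.end > w_arr.observed_fix.timestamp
                                else w_arr.observed_fix.timestamp, season="spring")
        if w_dep is None:
            events.extend([dep, w_arr])
            break
        w_dep = _refine(track, w_dep, cfg)
        b_arr = detect_arrival(track, breeding_model, from_time=w_dep.event_time,
                               season="breeding")
        if b_arr is None:
            events.extend([dep, w_arr, w_dep])
            break
        b_arr = _refine(track, b_arr, cfg)
        events.extend([dep, w_arr, w_dep, b_arr])
        pending.append((dep, w_arr, w_dep, b_arr))
        cursor = b_arr.observed_fix.timestamp + pd.Timedelta(days=7)

    for i, (dep, w_arr, w_dep, b_arr) in enumerate(pending):
        nxt = pending[i + 1][0] if i + 1 < len(pending) else None
        cycles.append(delineate_seasons(dep, w_arr, w_dep, b_arr,
                                        animal_id=track.animal_id,
                                        year=dep.event_time.year,
                                        next_breeding_departure=nxt,
                                        population=population))
    return events, cycles, periods


def _fixes_after(track: Track, from_time):
    if from_time is None:
        return track.fixes
    t = pd.Timestamp(from_time)
    t = t.tz_localize("UTC") if t.tzinfo is None else t.tz_convert("UTC")
    return [f for f in track.fixes if f.timestamp > t]


def _winter_period(periods, after, min_winter_d):
    """First sufficiently long residency after the departure: that year's winter."""
    cands = [p for p in periods if p.start >= after and p.duration_d >= min_winter_d]
    if not cands:
        return None
    return min(cands, key=lambda p: p.start.value)


def _refine(track: Track, event: TransitionEvent, cfg: SegmentationConfig):
    """Apply the flight-speed interpolation rule across the adjacent gap."""
    if event is None:
        return None
    obs_t = event.observed_fix.timestamp
    idx = int(np.searchsorted(track.times.asi8, obs_t.value))
    if idx == 0:
        return event
    neighbor = track.fixes[idx - 1]
    return interpolate_event_time(event, neighbor, cfg.mean_speed_mps, cfg.sd_speed_mps)
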