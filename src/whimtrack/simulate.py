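"""Synthetic annual-cycle telemetry with known ground truth.

The field data behind multi-year shorebird tracking studies are rarely
deposited, so every pipeline stage here is validated against simulated
cohorts whose true departure/arrival instants, path lengths and site visits
are recorded in a :class:`TruthLog`.

The generative model walks one animal through its annual cycle:

* bounded wander around the breeding territory centroid (hourly offsets,
  radius ``territory_radius_km``);
* migration legs flown along great-circle routes (with per-leg shaping
  waypoints from the population preset) at a per-animal flight speed drawn
  around 14.7 m/s (SD 2.01 — the published ±0.3 with n = 45 is a standard
  error, so the individual SD is 0.3·√45);
* scheduled staging stays (mean ± SD from the population preset) and
  Poisson-sampled unplanned stopovers placed on the route;
* winter residency, then the spring itinerary back to the territory.

The continuous true path is then observed through the transmitter duty
cycle (default 48 h off / 10 h on, 1–34 fixes per on-period with mean 5.48),
perturbed with location-class-dependent circular error and labelled with a
location class.  Everything is deterministic given the seed.

Population presets (``mackenzie_delta``, ``hudson_bay``) encode the two
study populations' mean initiation dates, staging itineraries and routes.
"""

from __future__ import annotations

import importlib.resources
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .geodesy import aeq_inverse, gc_interpolate, great_circle_km
from .io import Fix, Track

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class ItineraryStop:
    """A scheduled staging visit plus the stopover regime on the leg leaving it."""

    name: str
    lat: float
    lon: float
    mean_stay_d: float
    se_stay_d: float = 0.0
    n_stays: int = 1
    post_stopover_rate: float = 0.0       # expected unplanned stops on the next leg
    post_stopover_stay_d: float = 0.0     # mean stay per unplanned stop

    @property
    def sd_stay_d(self) -> float:
        """Between-visit SD, treating the printed ± as an SE of the mean."""
        return self.se_stay_d * np.sqrt(self.n_stays)


@dataclass
class PopulationSchedule:
    name: str
    breeding_centroid: tuple[float, float]
    winter_centroid: tuple[float, float]
    autumn_itinerary: list[ItineraryStop]
    spring_itinerary: list[ItineraryStop]
    mean_dates: dict            # day-of-year: breeding_arrival, autumn_departure,
                                # winter_arrival, spring_departure
    date_se_d: dict
    date_n_seasons: dict
    autumn_waypoints: list = field(default_factory=list)   # per-leg [(lat, lon), ...]
    spring_waypoints: list = field(default_factory=list)

    def date_sd(self, key: str) -> float:
        return float(self.date_se_d[key]) * np.sqrt(float(self.date_n_seasons[key]))

    def validate(self, mean_speed_kmh: float = 52.92) -> None:
        for season, itinerary, dep, arr in (
                ("autumn", self.autumn_itinerary, "autumn_departure", "winter_arrival"),
                ("spring", self.spring_itinerary, "spring_departure", "breeding_arrival")):
            span = (self.mean_dates[arr] - self.mean_dates[dep]) % 365.0
            stays = sum(s.mean_stay_d for s in itinerary)
            if stays > span + 15.0:
                raise ValueError(
                    f"{self.name}: {season} staging stays ({stays:.1f} d) exceed the "
                    f"{season} season length ({span:.1f} d)")


@dataclass(frozen=True)
class MovementConfig:
    flight_speed_mean_mps: float = 14.7
    flight_speed_sd_mps: float = 2.01
    territory_radius_km: float = 5.0
    lc_mix: dict = field(default_factory=lambda: {
        "LC3": 0.12, "LC2": 0.18, "LC1": 0.25, "LC0": 0.15, "LCA": 0.18, "LCB": 0.12})
    lc_error_m: dict = field(default_factory=lambda: {
        "LC3": 100.0, "LC2": 250.0, "LC1": 700.0, "LC0": 1500.0,
        "LCA": 3000.0, "LCB": 5000.0})
    duty_cycle: tuple[float, float] | None = (48.0, 10.0)   # (off_h, on_h)
    fixes_per_on_mean: float = 5.48
    fixes_per_on_range: tuple[int, int] = (1, 34)
    sampling_interval_h: float = 1.0      # used when duty_cycle is None (always on)

    def __post_init__(self):
        total = sum(self.lc_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"lc_mix probabilities sum to {total}, not 1")
        if any(v < 0 for v in self.lc_error_m.values()):
            raise ValueError("error scales must be non-negative")


@dataclass(frozen=True)
class TruthEvent:
    kind: str        # autumn_departure | winter_arrival | spring_departure | breeding_arrival
    time: pd.Timestamp
    year: int


@dataclass(frozen=True)
class TruthLeg:
    season: str      # autumn | spring
    year: int
    departure: pd.Timestamp
    arrival: pd.Timestamp
    length_km: float


@dataclass(frozen=True)
class SiteVisit:
    site: str
    lat: float
    lon: float
    start: pd.Timestamp
    end: pd.Timestamp
    season: str
    year: int
    is_staging: bool


@dataclass
class TruthLog:
    animal_id: str
    population: str
    events: list[TruthEvent]
    legs: list[TruthLeg]
    visits: list[SiteVisit]

    def event_time(self, kind: str, year: int) -> pd.Timestamp:
        for e in self.events:
            if e.kind == kind and e.year == year:
                return e.time
        raise KeyError((kind, year))


# --- continuous true-path timeline ----------------------------------------

class _Stationary:
    """Residency at a site with bounded hourly wander (piecewise linear)."""

    #: hour-to-hour autocorrelation of the wander (correlation time ~6 h,
    #: matching slow foraging commutes rather than ballistic jumps)
    RHO = float(np.exp(-1.0 / 6.0))

    def __init__(self, lat, lon, t0_h, t1_h, radius_km, rng):
        self.lat, self.lon = lat, lon
        self.t0, self.t1 = t0_h, t1_h
        n = max(int(np.ceil(t1_h - t0_h)) + 2, 2)
        if radius_km > 0:
            sd = radius_km / 2.0
            innov = rng.normal(0.0, sd, size=(n, 2))
            off = np.empty((n, 2))
            off[0] = innov[0]
            scale = np.sqrt(1.0 - self.RHO ** 2)
            for k in range(1, n):     # AR(1) with stationary SD = radius/2
                off[k] = self.RHO * off[k - 1] + scale * innov[k]
            r = np.hypot(off[:, 0], off[:, 1])
            over = r > radius_km
            off[over] *= (radius_km / r[over])[:, None]
        else:
            off = np.zeros((n, 2))
        self.off = off

    def position(self, t_h):
        u = t_h - self.t0
        i = int(np.floor(u))
        i = min(max(i, 0), len(self.off) - 2)
        w = u - i
        dx, dy = (1 - w) * self.off[i] + w * self.off[i + 1]
        return aeq_inverse(dx, dy, self.lat, self.lon)


class _Flight:
    """Great-circle polyline flown at constant speed."""

    def __init__(self, points, t0_h, speed_kmh):
        self.pts = points                      # [(lat, lon), ...]
        self.t0 = t0_h
        seg = [great_circle_km(*points[i], *points[i + 1])
               for i in range(len(points) - 1)]
        self.cum = np.concatenate([[0.0], np.cumsum(seg)])
        self.length_km = float(self.cum[-1])
        self.speed = speed_kmh
        self.t1 = t0_h + self.length_km / speed_kmh

    def position(self, t_h):
        d = min(max((t_h - self.t0) * self.speed, 0.0), self.length_km)
        j = min(int(np.searchsorted(self.cum, d, side="right")) - 1, len(self.pts) - 2)
        seg_len = self.cum[j + 1] - self.cum[j]
        f = 0.0 if seg_len <= 0 else (d - self.cum[j]) / seg_len
        lats, lons = gc_interpolate(*self.pts[j], *self.pts[j + 1], [f])
        return float(lats[0]), float(lons[0])


class Timeline:
    """Piecewise true path: position(t) for any instant in the tracked span."""

    def __init__(self):
        self.segments = []
        self.starts = []

    def append(self, seg):
        self.segments.append(seg)
        self.starts.append(seg.t0)

    @property
    def t_end(self):
        return self.segments[-1].t1

    def position(self, t_h):
        i = bisect_right(self.starts, t_h) - 1
        i = min(max(i, 0), len(self.segments) - 1)
        return self.segments[i].position(t_h)


# --- generation ------------------------------------------------------------

def _doy_to_hours(year: int, doy: float, base: pd.Timestamp) -> float:
    t = pd.Timestamp(year=year, month=1, day=1, tz="UTC") + pd.Timedelta(days=doy - 1.0)
    return (t - base).total_seconds() / 3600.0


def generate_annual_track(schedule: PopulationSchedule, move: MovementConfig,
                          seed, n_years: int = 1, start_year: int = 2015,
                          animal_id: str | None = None) -> tuple[Track, TruthLog]:
    """Simulate one animal for ``n_years`` annual cycles.

    Returns the observed :class:`Track` (duty-cycled, error-perturbed,
    class-labelled fixes) and the :class:`TruthLog` of true transition
    instants, per-leg path lengths and site visits.  Deterministic per seed.
    """
    schedule.validate()
    rng = np.random.default_rng(seed)
    base = pd.Timestamp(year=start_year, month=1, day=1, tz="UTC")
    aid = animal_id or f"{schedule.name}_{_seed_tag(seed)}"
    speed_kmh = max(rng.normal(move.flight_speed_mean_mps, move.flight_speed_sd_mps),
                    8.0) * 3.6

    timeline = Timeline()
    events: list[TruthEvent] = []
    legs: list[TruthLeg] = []
    visits: list[SiteVisit] = []

    pre_residency_d = 21.0
    first_dep_doy = rng.normal(schedule.mean_dates["autumn_departure"],
                               schedule.date_sd("autumn_departure"))
    t_cursor = _doy_to_hours(start_year, first_dep_doy, base) - pre_residency_d * 24.0
    t_track_start = t_cursor
    dep_h = t_cursor + pre_residency_d * 24.0

    for y in range(n_years):
        year = start_year + y
        # breeding residency ends at the (already drawn) autumn departure
        timeline.append(_Stationary(*schedule.breeding_centroid, t_cursor, dep_h,
                                    move.territory_radius_km, rng))
        events.append(TruthEvent("autumn_departure", _h2ts(dep_h, base), year))

        arr_h, length = _fly_season(timeline, visits, rng, move, schedule, "autumn",
                                    year, dep_h, speed_kmh,
                                    origin=schedule.breeding_centroid,
                                    itinerary=schedule.autumn_itinerary,
                                    waypoints=schedule.autumn_waypoints,
                                    dest=schedule.winter_centroid, base=base)
        events.append(TruthEvent("winter_arrival", _h2ts(arr_h, base), year))
        legs.append(TruthLeg("autumn", year, _h2ts(dep_h, base), _h2ts(arr_h, base), length))

        spring_doy = rng.normal(schedule.mean_dates["spring_departure"],
                                schedule.date_sd("spring_departure"))
        sdep_h = _doy_to_hours(year + 1, spring_doy, base)
        if sdep_h < arr_h + 240.0:
            sdep_h = arr_h + 240.0      # at least 10 d on the winter grounds
        timeline.append(_Stationary(*schedule.winter_centroid, arr_h, sdep_h,
                                    move.territory_radius_km, rng))
        events.append(TruthEvent("spring_departure", _h2ts(sdep_h, base), year + 1))

        barr_h, length = _fly_season(timeline, visits, rng, move, schedule, "spring",
                                     year + 1, sdep_h, speed_kmh,
                                     origin=schedule.winter_centroid,
                                     itinerary=schedule.spring_itinerary,
                                     waypoints=schedule.spring_waypoints,
                                     dest=schedule.breeding_centroid, base=base)
        events.append(TruthEvent("breeding_arrival", _h2ts(barr_h, base), year + 1))
        legs.append(TruthLeg("spring", year + 1, _h2ts(sdep_h, base), _h2ts(barr_h, base), length))

        t_cursor = barr_h
        if y + 1 < n_years:
            dep_doy = rng.normal(schedule.mean_dates["autumn_departure"],
                                 schedule.date_sd("autumn_departure"))
            dep_h = max(_doy_to_hours(year + 1, dep_doy, base), barr_h + 240.0)
        else:
            dep_h = barr_h + 21.0 * 24.0   # post-arrival residency, then tracking ends
            timeline.append(_Stationary(*schedule.breeding_centroid, t_cursor, dep_h,
                                        move.territory_radius_km, rng))

    track = _observe(timeline, move, rng, t_track_start, timeline.t_end, aid, base)
    truth = TruthLog(animal_id=aid, population=schedule.name, events=events,
                     legs=legs, visits=visits)
    return track, truth


def _fly_season(timeline, visits, rng, move, schedule, season, year, t_dep_h,
                speed_kmh, origin, itinerary, waypoints, dest, base):
    """Append flight + staging segments for one migration; return (arrival_h, km)."""
    nodes = [origin] + [(s.lat, s.lon) for s in itinerary] + [dest]
    total_km = 0.0
    t = t_dep_h
    for i in range(len(nodes) - 1):
        via = list(waypoints[i]) if i < len(waypoints) else []
        pts = [tuple(nodes[i])] + [tuple(p) for p in via] + [tuple(nodes[i + 1])]
        origin_stop = itinerary[i - 1] if i >= 1 else None
        rate = origin_stop.post_stopover_rate if origin_stop else 0.0
        stay_mean = origin_stop.post_stopover_stay_d if origin_stop else 0.0
        n_stop = int(rng.poisson(rate)) if rate > 0 else 0

        flight = _Flight(pts, t, speed_kmh)
        if n_stop == 0:
            timeline.append(flight)
            total_km += flight.length_km
            t = flight.t1
        else:
            # split the leg at stopover points placed on the route
            fracs = np.sort(rng.uniform(0.15, 0.85, size=n_stop))
            cut_pts, cut_ds = _polyline_cuts(flight, fracs)
            prev = pts[0]
            prev_d = 0.0
            for k, (cp, cd) in enumerate(zip(cut_pts, cut_ds)):
                sub = _sub_polyline(flight, prev_d, cd)
                fseg = _Flight(sub, t, speed_kmh)
                timeline.append(fseg)
                total_km += fseg.length_km
                t = fseg.t1
                stay_h = max(rng.exponential(stay_mean), 0.25) * 24.0
                timeline.append(_Stationary(cp[0], cp[1], t, t + stay_h, 2.0, rng))
                visits.append(SiteVisit(f"{season}_stopover_{year}_{k}", cp[0], cp[1],
                                        _h2ts(t, base), _h2ts(t + stay_h, base),
                                        season, year, is_staging=False))
                t += stay_h
                prev, prev_d = cp, cd
            sub = _sub_polyline(flight, prev_d, flight.length_km)
            fseg = _Flight(sub, t, speed_kmh)
            timeline.append(fseg)
            total_km += fseg.length_km
            t = fseg.t1

        if i < len(nodes) - 2:   # staging stay at itinerary[i]
            stop = itinerary[i]
            stay_h = max(rng.normal(stop.mean_stay_d, stop.sd_stay_d), 1.0) * 24.0
            timeline.append(_Stationary(stop.lat, stop.lon, t, t + stay_h,
                                        move.territory_radius_km, rng))
            visits.append(SiteVisit(stop.name, stop.lat, stop.lon,
                                    _h2ts(t, base), _h2ts(t + stay_h, base),
                                    season, year, is_staging=True))
            t += stay_h
    return t, total_km


def _polyline_cuts(flight: _Flight, fracs):
    pts, ds = [], []
    for f in fracs:
        d = f * flight.length_km
        lat, lon = flight.position(flight.t0 + d / flight.speed)
        pts.append((lat, lon))
        ds.append(d)
    return pts, ds


def _sub_polyline(flight: _Flight, d0: float, d1: float):
    """Vertices of the flight polyline between route distances d0 and d1."""
    p0 = flight.position(flight.t0 + d0 / flight.speed)
    p1 = flight.position(flight.t0 + d1 / flight.speed)
    inner = [tuple(flight.pts[j]) for j in range(1, len(flight.pts) - 1)
             if d0 < flight.cum[j] < d1]
    return [p0] + inner + [p1]


def _observe(timeline, move, rng, t0_h, t1_h, animal_id, base) -> Track:
    """Sample the true path through the duty cycle and perturb per class."""
    classes = sorted(move.lc_mix)
    probs = np.array([move.lc_mix[c] for c in classes])
    fix_times = []
    if move.duty_cycle is None:
        fix_times = list(np.arange(t0_h, t1_h, move.sampling_interval_h))
    else:
        off_h, on_h = move.duty_cycle
        cycle = off_h + on_h
        lo, hi = move.fixes_per_on_range
        w = t0_h + rng.uniform(0.0, cycle)
        while w < t1_h:
            k = int(np.clip(1 + rng.poisson(move.fixes_per_on_mean - 1.0), lo, hi))
            ts = np.sort(rng.uniform(w, min(w + on_h, t1_h), size=k))
            fix_times.extend(ts.tolist())
            w += cycle
    fixes = []
    last_s = None
    for t in fix_times:
        lat, lon = timeline.position(t)
        lc = classes[rng.choice(len(classes), p=probs)]
        err = move.lc_error_m.get(lc, 0.0)
        if err > 0:
            dx, dy = rng.normal(0.0, err / 1000.0, size=2)
            lat, lon = aeq_inverse(dx, dy, lat, lon)
        ts = _h2ts(t, base).floor("s")
        s = ts.value
        if last_s is not None and s <= last_s:   # collapse sub-second collisions
            continue
        last_s = s
        fixes.append(Fix(animal_id=animal_id, timestamp=ts, lat=lat, lon=lon,
                         location_class=lc, error_radius_m=err or None))
    return Track(animal_id=animal_id, fixes=fixes, duty_cycle=move.duty_cycle)


def generate_cohort(n: int, schedule: PopulationSchedule, move: MovementConfig,
                    seed, n_years: int = 1, start_year: int = 2015):
    """n independent animals with dates drawn around the schedule means."""
    if n < 0:
        raise ValueError("n must be non-negative")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n)
    tracks, truths = [], []
    for i, child in enumerate(children):
        tr, tl = generate_annual_track(schedule, move, child, n_years=n_years,
                                       start_year=start_year,
                                       animal_id=f"{schedule.name}_{i:02d}")
        tracks.append(tr)
        truths.append(tl)
    return tracks, truths


def _h2ts(t_h: float, base: pd.Timestamp) -> pd.Timestamp:
    return base + pd.Timedelta(seconds=t_h * 3600.0)


def _seed_tag(seed) -> str:
    if isinstance(seed, np.random.SeedSequence):
        return str(seed.entropy)[-6:]
    return str(seed)


def load_preset(name: str) -> PopulationSchedule:
    """Load a shipped population preset (``mackenzie_delta`` or ``hudson_bay``)
    or a path to a preset YAML file."""
    if name.endswith((".yaml", ".yml")):
        with open(name) as fh:
            raw = yaml.safe_load(fh)
    else:
        ref = importlib.resources.files("whimtrack") / "presets" / f"{name}.yaml"
        raw = yaml.safe_load(ref.read_text())
    return PopulationSchedule(
        name=raw["name"],
        breeding_centroid=tuple(raw["breeding_centroid"]),
        winter_centroid=tuple(raw["winter_centroid"]),
        autumn_itinerary=[ItineraryStop(**s) for s in raw["autumn_itinerary"]],
        spring_itinerary=[ItineraryStop(**s) for s in raw["spring_itinerary"]],
        mean_dates=raw["mean_dates"],
        date_se_d=raw["date_se_d"],
        date_n_seasons=raw["date_n_seasons"],
        autumn_waypoints=raw.get("autumn_waypoints", []),
        spring_waypoints=raw.get("spring_waypoints", []),
    )
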