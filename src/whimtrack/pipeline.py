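"""End-to-end orchestration: simulate → filter → segment → interpolate →
metrics → classify → tables.

Each stage is importable on its own; :func:`run_pipeline` chains them for a
two-population simulated cohort (or tracks read from disk), writes the
standard artifact set (events.csv, stationary_periods.csv, annual_cycle.csv,
migration.csv, sites.csv, comparisons.csv, paths.geojson, run_manifest.json)
and is byte-reproducible from its config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ctcrw, io, segmentation, simulate, sites, stats
from .geodesy import great_circle_km


@dataclass
class RunConfig:
    presets: tuple[str, ...] = ("mackenzie_delta", "hudson_bay")
    input_csv: str | None = None          # read tracks instead of simulating
    n_per_population: int = 6
    n_years: int = 1
    seed: int = 1
    out_dir: str = "results/pipeline"
    duty_cycle: tuple[float, float] | None = (48.0, 10.0)
    dt_minutes: float = 15.0
    link_km: float = 250.0

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["presets"] = list(self.presets)
        return d


def measure_leg(track, dep_event, arr_event, periods, dt_minutes: float = 15.0,
                min_ctcrw_fixes: int = 8):
    """Migration distance along the interpolated pathway, excluding local
    movements within stationary periods.

    The leg is split at its stationary periods; each flight segment (bounded
    by the adjacent stationary-edge fixes) is interpolated with the CTCRW
    smoother when it has enough fixes, else measured as a piecewise
    great-circle polyline over its fixes.  Returns (distance_km, paths) with
    ``paths`` the list of interpolated segments for export.
    """
    t_dep = dep_event.observed_fix.timestamp
    t_arr = arr_event.observed_fix.timestamp
    inside = [p for p in periods
              if p.start > t_dep and p.end < t_arr and p.animal_id == track.animal_id]
    inside.sort(key=lambda p: p.start.value)
    bounds = [(t_dep, t_dep)] + [(p.start, p.end) for p in inside] + [(t_arr, t_arr)]
    total = 0.0
    paths = []
    for (s0, e0), (s1, e1) in zip(bounds, bounds[1:]):
        seg = track.between(start=e0, end=s1)
        if len(seg.fixes) < 2:
            continue
        if len(seg.fixes) >= min_ctcrw_fixes:
            try:
                fit = ctcrw.fit_ctcrw(seg)
                path = ctcrw.predict_path(seg, fit.params, dt_minutes=dt_minutes)
                total += stats.path_length_km(path)
                paths.append(path)
                continue
            except (ValueError, np.linalg.LinAlgError):
                pass
        total += stats.path_length_km((seg.lats, seg.lons))
    return total, paths


def process_population(tracks, population: str, seg_cfg=None,
                       dt_minutes: float = 15.0):
    """Segment and measure every track of one population.

    Returns (events_rows, cycles, legs, all_periods, paths).
    """
    seg_cfg = seg_cfg or segmentation.SegmentationConfig()
    all_events, cycles, legs, all_periods, paths = [], [], [], [], []
    for tr in tracks:
        filtered = io.filter_quality(tr)
        events, cyc, periods = segmentation.segment_annual_cycles(
            filtered, seg_cfg, population=population)
        all_events.extend((tr.animal_id, e) for e in events)
        cycles.extend(cyc)
        all_periods.extend(periods)
        # pair departure/arrival events into migration legs
        deps = [e for e in events if e.kind == "departure"]
        arrs = [e for e in events if e.kind == "arrival"]
        for dep in deps:
            after = [a for a in arrs if a.event_time > dep.event_time]
            if not after:
                continue
            arr = min(after, key=lambda a: a.event_time.value)
            season = "autumn" if dep.season == "autumn" else "spring"
            dist, p = measure_leg(filtered, dep, arr, periods, dt_minutes)
            if dist <= 0:
                continue
            paths.extend(p)
            legs.append(stats.summarize_leg(
                dep.event_time, arr.event_time, dist,
                animal_id=tr.animal_id, season=season, population=population,
                year=dep.event_time.year))
    return all_events, cycles, legs, all_periods, paths


def migration_periods(periods, cycles):
    """Stationary periods that fall inside a migration season of their animal."""
    windows = {}
    for c in cycles:
        windows.setdefault(c.animal_id, []).append(
            (c.initiation["autumn_migration"], c.initiation["winter"], "autumn"))
        windows.setdefault(c.animal_id, []).append(
            (c.initiation["spring_migration"], c.initiation["breeding"], "spring"))
    out = []
    for p in periods:
        for (a, b, season) in windows.get(p.animal_id, []):
            if p.start >= a and p.end <= b:
                p.season = season
                out.append(p)
                break
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    move = simulate.MovementConfig(duty_cycle=config.duty_cycle)

    population_tracks: dict[str, list] = {}
    if config.input_csv is not None:
        src = Path(config.input_csv)
        if not src.exists():
            raise FileNotFoundError(f"missing input: {src}")
        tracks = io.read_tracks(str(src))
        population_tracks["unknown"] = tracks
    else:
        ss = np.random.SeedSequence(config.seed).spawn(len(config.presets))
        for preset_name, child in zip(config.presets, ss):
            schedule = simulate.load_preset(preset_name)
            tracks, _ = simulate.generate_cohort(
                config.n_per_population, schedule, move, child,
                n_years=config.n_years)
            population_tracks[schedule.name] = tracks

    events_rows, cycles, legs, periods, paths = [], [], [], [], []
    for pop, tracks in population_tracks.items():
        ev, cy, lg, pe, pa = process_population(tracks, pop, dt_minutes=config.dt_minutes)
        events_rows.extend(ev)
        cycles.extend(cy)
        legs.extend(lg)
        periods.extend(pe)
        paths.extend(pa)

    artifacts = {}

    ev_df = pd.DataFrame([{
        "animal_id": a, "kind": e.kind, "season": e.season,
        "event_time": e.event_time.strftime("%Y-%m-%dT%H:%M:%SZ"),
        "interpolated": e.interpolated,
    } for a, e in events_rows])
    artifacts["events"] = _write(ev_df, out / "events.csv")

    sp_df = pd.DataFrame([{
        "animal_id": p.animal_id,
        "start": p.start.strftime("%Y-%m-%dT%H:%M:%SZ"),
        "end": p.end.strftime("%Y-%m-%dT%H:%M:%SZ"),
        "centroid_lat": round(p.centroid_lat, 5), "centroid_lon": round(p.centroid_lon, 5),
        "n_fixes": p.n_fixes, "duration_d": round(p.duration_d, 3),
    } for p in periods])
    artifacts["stationary_periods"] = _write(sp_df, out / "stationary_periods.csv")

    artifacts["annual_cycle"] = _write(stats.build_phenology_table(cycles),
                                       out / "annual_cycle.csv")
    artifacts["migration"] = _write(stats.build_migration_table(legs),
                                    out / "migration.csv")

    mig_p = migration_periods(periods, cycles)
    if mig_p:
        # terminal destinations (winter/breeding arrivals) close each season's
        # itinerary so terminal staging areas get their true onward leg
        terminals: dict[str, list] = {t.animal_id: []
                                      for v in population_tracks.values() for t in v}
        for a, e in events_rows:
            if e.kind == "arrival":
                terminals.setdefault(a, []).append(
                    (e.event_time, (e.observed_fix.lat, e.observed_fix.lon)))
        for seq in terminals.values():
            seq.sort(key=lambda x: x[0].value)
        clusters = sites.cluster_visits(mig_p, link_km=config.link_km)
        sites.classify_sites(clusters, itineraries=terminals)
        sites.associate_stopovers(clusters)
        sites_df = sites.build_sites_table(clusters)
    else:
        sites_df = pd.DataFrame()
    artifacts["sites"] = _write(sites_df, out / "sites.csv")

    comp_df = _comparisons(cycles, legs)
    artifacts["comparisons"] = _write(comp_df, out / "comparisons.csv")

    io.write_paths_geojson(paths, str(out / "paths.geojson"))
    artifacts["paths"] = "paths.geojson"

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "artifacts": artifacts,
        "n_tracks": sum(len(v) for v in population_tracks.values()),
        "n_cycles": len(cycles),
        "n_legs": len(legs),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _comparisons(cycles, legs) -> pd.DataFrame:
    """Between-population season-initiation tests plus season speed tests."""
    pops = sorted({c.population for c in cycles if c.population})
    pairs = []
    if len(pops) == 2:
        p1, p2 = pops
        for season in ("breeding", "autumn_migration", "winter", "spring_migration"):
            g = {}
            for pop in pops:
                vals = [c.initiation[season] for c in cycles
                        if c.population == pop and season in c.initiation]
                ids = [c.animal_id for c in cycles
                       if c.population == pop and season in c.initiation]
                if len(vals) >= 2:
                    g[pop] = stats.date_stats(vals, ids)
            if len(g) == 2:
                pairs.append((f"{season}_initiation:{p1}_vs_{p2}", g[p1], g[p2]))
    spring = [l.speed_kmd for l in legs if l.season == "spring"]
    autumn = [l.speed_kmd for l in legs if l.season == "autumn"]
    if len(spring) >= 2 and len(autumn) >= 2:
        pairs.append(("migration_speed:spring_vs_autumn", spring, autumn))
    if not pairs:
        return pd.DataFrame(columns=["comparison", "t", "df", "p", "p_bonferroni"])
    return stats.build_comparisons_table(pairs)


def _write(df: pd.DataFrame, path: Path) -> str:
    io.write_table(df, str(path))
    return path.name
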