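#!/usr/bin/env python
"""Quality-filter, segment and measure the simulated cohorts.

Reads the telemetry written by 02_simulate_cohorts.py, keeps location
classes 1–3, delineates each animal's annual cycles (2-SD breakout rule
with flight-speed event interpolation), measures every migration leg along
its CTCRW-interpolated pathway, and writes per-event, per-cycle, per-leg
and per-stationary-period tables plus the interpolated paths GeoJSON.
"""

from pathlib import Path

import pandas as pd

from whimtrack import io, pipeline, stats

root = Path(__file__).resolve().parents[1] / "results"
cohorts = root / "cohorts"
out = root
ISO = "%Y-%m-%dT%H:%M:%SZ"

events_rows, cycles, legs, periods, paths = [], [], [], [], []
for preset in ("mackenzie_delta", "hudson_bay"):
    tracks = io.read_tracks(str(cohorts / f"{preset}.csv"))
    ev, cy, lg, pe, pa = pipeline.process_population(tracks, preset)
    events_rows += ev
    cycles += cy
    legs += lg
    periods += pe
    paths += pa
    print(f"{preset}: {len(cy)} annual cycles, {len(lg)} migration legs, "
          f"{len(pe)} stationary periods")

pd.DataFrame([{"animal_id": a, "kind": e.kind, "season": e.season,
               "event_time": e.event_time.strftime(ISO),
               "interpolated": e.interpolated} for a, e in events_rows]
             ).to_csv(out / "events.csv", index=False)

pd.DataFrame([{"animal_id": c.animal_id, "population": c.population,
               "year": c.year,
               **{f"init_{k}": v.strftime(ISO) for k, v in c.initiation.items()},
               **{f"dur_{k}_d": round(v, 2) for k, v in c.durations_d.items()}}
              for c in cycles]).to_csv(out / "cycles.csv", index=False)

pd.DataFrame([{"animal_id": l.animal_id, "population": l.population,
               "season": l.season, "year": l.year,
               "departure": l.departure_time.strftime(ISO),
               "arrival": l.arrival_time.strftime(ISO),
               "distance_km": round(l.distance_km, 1),
               "duration_d": round(l.duration_d, 2),
               "speed_kmd": round(l.speed_kmd, 1)}
              for l in legs]).to_csv(out / "legs.csv", index=False)

mig_periods = pipeline.migration_periods(periods, cycles)
pd.DataFrame([{"animal_id": p.animal_id, "start": p.start.strftime(ISO),
               "end": p.end.strftime(ISO), "centroid_lat": round(p.centroid_lat, 5),
               "centroid_lon": round(p.centroid_lon, 5), "n_fixes": p.n_fixes,
               "season": p.season}
              for p in mig_periods]).to_csv(out / "stationary_periods.csv", index=False)

stats.build_phenology_table(cycles).to_csv(out / "phenology.csv", index=False)
stats.build_migration_table(legs).to_csv(out / "migration.csv", index=False)
io.write_paths_geojson(paths, str(out / "paths.geojson"))

print(stats.build_phenology_table(cycles).to_string(index=False))
print(stats.build_migration_table(legs).to_string(index=False))
print("Wrote events/cycles/legs/stationary_periods/phenology/migration tables to", out)
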