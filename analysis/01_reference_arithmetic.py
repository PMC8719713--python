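#!/usr/bin/env python
"""Arithmetic identities from the published summary tables.

The raw telemetry behind the study is not deposited, but its printed
per-population summaries are shipped with the package as inputs.  This
driver recomputes every headline contrast from them: season-initiation
offsets between the two breeding populations, breeding→winter spans, the
migration distance/speed contrasts, the pooled season-speed t-test and the
staging-fidelity percentage.  Writes results/reference_identities.json.
"""

import json
from pathlib import Path

from whimtrack import reference

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

diffs = reference.season_initiation_differences()
spans = reference.breeding_to_winter_spans()
speed = reference.spring_vs_autumn_speed_differences_kmd()
t = reference.overall_speed_comparison()
fid = reference.fidelity_counts()

results = {
    "initiation_differences_d (HB minus MD)": diffs,
    "breeding_to_winter_span_d": spans,
    "spring_distance_difference_km": reference.spring_distance_difference_km(),
    "spring_minus_autumn_speed_kmd": speed,
    "season_speed_pooled_t": {"t": round(t.t_statistic, 2), "df": t.df,
                              "p": round(t.p_two_tailed, 3)},
    "staging_fidelity": {"consistent": fid.consistent, "total": fid.total,
                         "percent": round(100 * fid.proportion, 1)},
}

with open(out_dir / "reference_identities.json", "w") as fh:
    json.dump(results, fh, indent=2)

print("Season-initiation offsets (Hudson Bay minus Mackenzie Delta, days):", diffs)
print("The western population transitions earlier at every boundary; the")
print("breeding→winter span is", spans, "— 16 days longer for Hudson Bay.")
print("Spring distance gap:", results["spring_distance_difference_km"], "km;")
print("spring is faster than autumn by", speed, "km/d within population.")
print("Pooled season-speed test:", results["season_speed_pooled_t"])
print("Staging fidelity:", results["staging_fidelity"])
print("Wrote", out_dir / "reference_identities.json")
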