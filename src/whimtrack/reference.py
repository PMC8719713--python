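"""Published summary tables shipped as inputs, and the arithmetic on them.

The underlying raw telemetry of the source study is not deposited; what the
study prints are per-population season-initiation dates, migration
distance/duration/speed summaries (mean ± SE with "n (x)" sample sizes) and
staging-fidelity counts.  These are first-class *inputs* here: the
phenology calculators, t-test and fidelity machinery run on them exactly as
they would on summaries computed from raw tracks.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .sites import FidelityResult, fidelity_from_counts
from .stats import ComparisonResult, GroupSummary, date_diff, two_sample_t


def _load(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("whimtrack") / "data" / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def phenology_table() -> pd.DataFrame:
    return _load("phenology_reference.csv")


def migration_table() -> pd.DataFrame:
    return _load("migration_reference.csv")


def overall_speed_table() -> pd.DataFrame:
    return _load("speed_overall_reference.csv")


def fidelity_counts() -> FidelityResult:
    row = _load("fidelity_reference.csv").iloc[0]
    return fidelity_from_counts(int(row.repeat_events), int(row.exceptions))


def _mean_date(df: pd.DataFrame, population: str, season: str) -> str:
    sel = df[(df.population == population) & (df.season == season)]
    return str(sel.iloc[0].mean_date)


def season_initiation_differences() -> dict[str, int]:
    """Hudson Bay minus Mackenzie Delta initiation dates, in days.

    Positive = Mackenzie Delta earlier.
    """
    df = phenology_table()
    out = {}
    for season in ("breeding", "autumn_migration", "winter", "spring_migration"):
        md = _mean_date(df, "mackenzie_delta", season)
        hb = _mean_date(df, "hudson_bay", season)
        out[season] = date_diff(md, hb)
    return out


def breeding_to_winter_spans() -> dict[str, int]:
    """Days from breeding-ground arrival to winter-ground arrival, per population."""
    df = phenology_table()
    return {pop: date_diff(_mean_date(df, pop, "breeding"), _mean_date(df, pop, "winter"))
            for pop in ("mackenzie_delta", "hudson_bay")}


def _mig(pop: str, season: str) -> pd.Series:
    df = migration_table()
    return df[(df.population == pop) & (df.season == season)].iloc[0]


def spring_distance_difference_km() -> float:
    """Between-population difference in mean spring migration distance."""
    return float(_mig("mackenzie_delta", "spring").distance_km
                 - _mig("hudson_bay", "spring").distance_km)


def spring_vs_autumn_speed_differences_kmd() -> dict[str, float]:
    """Within-population spring − autumn mean migration speed, km/d."""
    return {pop: float(_mig(pop, "spring").speed_kmd - _mig(pop, "autumn").speed_kmd)
            for pop in ("mackenzie_delta", "hudson_bay")}


def overall_speed_comparison() -> ComparisonResult:
    """Pooled two-tailed t between spring and autumn migration speed, both
    populations combined, from the printed summaries."""
    df = overall_speed_table().set_index("season")

    def grp(season):
        r = df.loc[season]
        return GroupSummary(n_individuals=int(r.n_seasons), n_seasons=int(r.n_seasons),
                            mean=float(r.mean_kmd), se=float(r.se))

    return two_sample_t(grp("spring"), grp("autumn"), method="pooled")
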