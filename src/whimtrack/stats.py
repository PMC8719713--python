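"""Migration metrics, phenology summaries and the statistical comparisons.

Conventions match standard practice for multi-year tracking studies:

* distances are great-circle km on the 6371.0088 km sphere;
* migration speed is total path length / elapsed time in km/d, elapsed time
  *including* stops en route;
* group summaries report mean ± SE with sample sizes "n (x)" = number of
  individuals (total number of seasons), repeated seasons from one animal
  treated as independent samples (per-animal averaging available via
  ``per_animal=True`` for sensitivity analysis);
* comparisons are two-tailed t-tests, pooled-variance Student's t by default
  (df = n1 + n2 − 2), with Bonferroni correction applied per output table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geodesy import great_circle_km as _gc_km
from .geodesy import path_length_km as _polyline_km


def great_circle_km(a, b) -> float:
    """Haversine distance in km between two (lat, lon) pairs."""
    return _gc_km(a[0], a[1], b[0], b[1])


def path_length_km(path) -> float:
    """Length along an interpolated path (sum of great-circle segments), km.

    Accepts anything with ``lats``/``lons`` or a (lats, lons) pair.  A
    single-point path has length 0.
    """
    if hasattr(path, "lats"):
        lats, lons = np.asarray(path.lats), np.asarray(path.lons)
    else:
        lats, lons = (np.asarray(x, dtype=float) for x in path)
    return _polyline_km(lats, lons)


@dataclass
class MigrationLeg:
    """One migration (autumn or spring) for one animal-year."""

    animal_id: str
    season: str                      # "autumn" | "spring"
    departure_time: pd.Timestamp
    arrival_time: pd.Timestamp
    distance_km: float
    duration_d: float
    speed_kmd: float
    population: str | None = None
    year: int | None = None


def summarize_leg(departure_time, arrival_time, path, animal_id: str = "",
                  season: str = "", **kw) -> MigrationLeg:
    """Build a :class:`MigrationLeg` from transition events and a path.

    ``path`` may be an interpolated path object, a (lats, lons) pair, or a
    precomputed length in km.  Duration is elapsed days including stops.
    """
    dep = pd.Timestamp(departure_time)
    arr = pd.Timestamp(arrival_time)
    if arr <= dep:
        raise ValueError(f"arrival {arr} not after departure {dep}")
    dist = float(path) if np.isscalar(path) else path_length_km(path)
    dur = (arr - dep).total_seconds() / 86400.0
    return MigrationLeg(animal_id=animal_id, season=season,
                        departure_time=dep, arrival_time=arr,
                        distance_km=dist, duration_d=dur,
                        speed_kmd=dist / dur, **kw)


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SE with 'n (x)' sample sizes: individuals (seasons)."""

    n_individuals: int
    n_seasons: int
    mean: float
    se: float

    def __post_init__(self):
        if not (self.n_seasons >= self.n_individuals >= 1):
            raise ValueError("need n_seasons >= n_individuals >= 1")
        if self.se < 0:
            raise ValueError("se must be non-negative")


def summarize_group(values: Sequence[float], animal_ids: Sequence[str] | None = None,
                    per_animal: bool = False) -> GroupSummary:
    """Summarize per-season values into mean ± SE.

    With ``per_animal=True`` values are first averaged within animal and the
    SE is computed across animal means (sensitivity mode).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarize")
    ids = list(animal_ids) if animal_ids is not None else [str(i) for i in range(v.size)]
    n_ind = len(set(ids))
    n_seas = v.size
    if per_animal:
        df = pd.DataFrame({"id": ids, "v": v}).groupby("id")["v"].mean()
        v = df.to_numpy()
    se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return GroupSummary(n_individuals=n_ind, n_seasons=n_seas,
                        mean=float(np.mean(v)), se=se)


@dataclass(frozen=True)
class ComparisonResult:
    t_statistic: float
    df: float
    p_two_tailed: float
    p_bonferroni: float
    method: str


def two_sample_t(g1, g2, method: str = "pooled", family_size: int = 1) -> ComparisonResult:
    """Two-tailed two-sample t-test between groups.

    Groups are either :class:`GroupSummary` objects or raw value sequences.
    ``pooled`` is Student's t with df = n1 + n2 − 2 (SDs back-computed from
    SEs when given summaries); ``welch`` uses unpooled variances with
    Satterthwaite df.  Antisymmetric in its arguments: swapping groups flips
    the sign of t and leaves p unchanged.
    """
    m1, s1, n1 = _moments(g1)
    m2, s2, n2 = _moments(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    var1, var2 = s1 ** 2, s2 ** 2
    if method == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / df
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif method == "welch":
        se2 = var1 / n1 + var2 / n2
        denom = np.sqrt(se2)
        if var1 == var2 == 0:
            df = n1 + n2 - 2
        else:
            df = se2 ** 2 / ((var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    diff = m1 - m2
    if denom == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / denom
        p = float(2.0 * sps.t.sf(abs(t), df))
    return ComparisonResult(t_statistic=float(t), df=float(df), p_two_tailed=p,
                            p_bonferroni=bonferroni([p], family_size)[0],
                            method=method)


def _moments(g) -> tuple[float, float, int]:
    """(mean, sd, n) from a GroupSummary (SE → SD) or raw values."""
    if isinstance(g, GroupSummary):
        n = g.n_seasons
        return g.mean, g.se * np.sqrt(n), n
    v = np.asarray(g, dtype=float)
    return float(np.mean(v)), float(np.std(v, ddof=1)) if v.size > 1 else 0.0, v.size


def bonferroni(p_values: Iterable[float], family_size: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, p * m)."""
    ps = list(p_values)
    m = family_size if family_size is not None else len(ps)
    if m < len(ps):
        raise ValueError("family_size smaller than number of p-values")
    return [min(1.0, p * m) for p in ps]


# --- calendar-date arithmetic (phenology) ---------------------------------

_NOMINAL_YEAR = 2001  # non-leap reference year for month-day arithmetic


def _to_doy(d) -> float:
    """Day-of-year on the nominal (non-leap) calendar axis."""
    if isinstance(d, (int, float, np.integer, np.floating)):
        return float(d)
    ts = pd.Timestamp(d)
    base = pd.Timestamp(year=_NOMINAL_YEAR, month=ts.month, day=ts.day,
                        hour=ts.hour, minute=ts.minute)
    return float(base.dayofyear) + (ts.hour * 3600 + ts.minute * 60 + ts.second) / 86400.0


def date_diff(d1, d2) -> int:
    """Whole days from d1 to d2 on the month-day calendar (d2 − d1).

    Works on dates or day-of-year numbers; the year is ignored so that
    multi-year phenology means can be compared.  Differences wrap into
    (−182.5, 182.5] so seasonal offsets keep their natural sign.
    """
    delta = _to_doy(d2) - _to_doy(d1)
    delta = (delta + 182.5) % 365.0 - 182.5
    return int(round(delta))


def date_stats(dates: Sequence, animal_ids: Sequence[str] | None = None) -> GroupSummary:
    """Mean ± SE of calendar dates as day-of-year.

    All dates must fall within a 180-day window (one season); otherwise the
    circular mean is ambiguous and an error is raised.
    """
    doys = np.array([_to_doy(d) for d in dates], dtype=float)
    if doys.size == 0:
        raise ValueError("no dates")
    # unwrap about the first date so a season straddling New Year is linear
    ref = doys[0]
    unwrapped = ref + (doys - ref + 182.5) % 365.0 - 182.5
    if unwrapped.max() - unwrapped.min() > 180.0:
        raise ValueError("dates span more than 180 days: mean is ambiguous")
    return summarize_group(unwrapped, animal_ids)


def doy_to_date_str(doy: float) -> str:
    """Day-of-year (nominal non-leap year) → '04 Jul' style label."""
    d = pd.Timestamp(year=_NOMINAL_YEAR, month=1, day=1) + pd.Timedelta(days=float(doy) - 1)
    return d.strftime("%d %b")


# --- output tables mirroring the study's summary structure -----------------

def build_phenology_table(cycles) -> pd.DataFrame:
    """Season-initiation summary: one row per population × season.

    ``cycles`` is an iterable of annual cycles (``population``, ``animal_id``
    and per-season initiation times, see ``whimtrack.segmentation``).
    """
    rows = []
    recs = [c for c in cycles]
    pops = sorted({c.population for c in recs})
    for pop in pops:
        sub = [c for c in recs if c.population == pop]
        for season in ("breeding", "autumn_migration", "winter", "spring_migration"):
            vals, ids = [], []
            for c in sub:
                t = c.initiation.get(season)
                if t is not None:
                    vals.append(t)
                    ids.append(c.animal_id)
            if not vals:
                continue
            g = date_stats(vals, ids)
            rows.append({
                "population": pop, "season": season,
                "n_individuals": g.n_individuals, "n_seasons": g.n_seasons,
                "mean_doy": round(g.mean, 2), "mean_date": doy_to_date_str(g.mean),
                "se_d": round(g.se, 2),
            })
    return pd.DataFrame(rows, columns=["population", "season", "n_individuals",
                                       "n_seasons", "mean_doy", "mean_date", "se_d"])


def build_migration_table(legs: Iterable[MigrationLeg]) -> pd.DataFrame:
    """Distance/duration/speed summary: one row per population × season."""
    legs = list(legs)
    rows = []
    for pop in sorted({l.population for l in legs}):
        for season in ("autumn", "spring"):
            sub = [l for l in legs if l.population == pop and l.season == season]
            if not sub:
                continue
            ids = [l.animal_id for l in sub]
            row = {"population": pop, "season": season,
                   "n_individuals": len(set(ids)), "n_seasons": len(sub)}
            for fieldname, key in (("distance_km", "distance_km"),
                                   ("duration_d", "duration_d"),
                                   ("speed_kmd", "speed_kmd")):
                g = summarize_group([getattr(l, key) for l in sub], ids)
                row[f"{fieldname}_mean"] = round(g.mean, 1)
                row[f"{fieldname}_se"] = round(g.se, 2)
            rows.append(row)
    return pd.DataFrame(rows)


def build_comparisons_table(named_pairs, family_size: int | None = None) -> pd.DataFrame:
    """Run a family of two-sample tests: [(label, g1, g2), ...] → table."""
    named_pairs = list(named_pairs)
    m = family_size if family_size is not None else len(named_pairs)
    rows = []
    for label, g1, g2 in named_pairs:
        r = two_sample_t(g1, g2, family_size=m)
        rows.append({"comparison": label, "t": round(r.t_statistic, 3),
                     "df": r.df, "p": round(r.p_two_tailed, 4),
                     "p_bonferroni": round(r.p_bonferroni, 4)})
    return pd.DataFrame(rows, columns=["comparison", "t", "df", "p", "p_bonferroni"])
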