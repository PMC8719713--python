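"""Site-level analysis: clustering visits, staging vs stopover, fidelity.

*Staging areas* are annually used refueling destinations: long stays
(weeks), long onward flights (> 1,000 km) and use by a substantial part of
the population across years.  *Stopovers* are short, opportunistic en-route
stops, each associated with the staging area most recently departed
upstream.  Resource density — part of the field definition of staging — is
unobservable from telemetry and deliberately not a criterion here.

Visits (stationary periods along migration) are clustered into sites by
single-linkage agglomeration over great-circle distance with a regional
linkage radius (default 250 km; published staging areas span whole coastal
regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geodesy import great_circle_km
from .segmentation import StationaryPeriod


@dataclass(frozen=True)
class ClassificationCriteria:
    min_staging_stay_d: float = 7.0       # "weeks" floor; smallest published staging mean is 7.6 d
    min_next_leg_km: float = 1000.0
    min_population_fraction: float = 0.2
    min_reuse_years: int = 2
    max_stopover_stay_d: float = 7.0

    def __post_init__(self):
        if min(self.min_staging_stay_d, self.min_next_leg_km,
               self.min_population_fraction, self.min_reuse_years,
               self.max_stopover_stay_d) <= 0:
            raise ValueError("criteria thresholds must be positive")


@dataclass
class SiteCluster:
    site_id: int
    centroid_lat: float
    centroid_lon: float
    visits: list[StationaryPeriod] = field(default_factory=list)
    label: str = "unclassified"           # staging | stopover | unclassified
    next_leg_km: float = float("nan")
    upstream_site: int | None = None
    origin_associated: bool = False

    @property
    def n_individuals(self) -> int:
        return len({v.animal_id for v in self.visits})

    @property
    def n_years(self) -> int:
        return len({v.start.year for v in self.visits})

    @property
    def median_stay_d(self) -> float:
        return float(np.median([v.duration_d for v in self.visits]))


def cluster_visits(periods, link_km: float = 250.0) -> list[SiteCluster]:
    """Single-linkage agglomeration of visit centroids cut at ``link_km``.

    Input-order independent: visits are canonically sorted by coordinates
    before linkage and clusters are numbered by (lat, lon) of their centroid.
    """
    periods = list(periods)
    if not periods:
        raise ValueError("no stationary periods to cluster")
    periods = sorted(periods, key=lambda p: (round(p.centroid_lat, 9),
                                             round(p.centroid_lon, 9),
                                             p.animal_id, p.start.value))
    lats = np.array([p.centroid_lat for p in periods])
    lons = np.array([p.centroid_lon for p in periods])
    if len(periods) == 1:
        labels = np.array([1])
    else:
        n = len(periods)
        dm = np.zeros((n, n))
        for i in range(n):
            dm[i, i + 1:] = great_circle_km(lats[i], lons[i], lats[i + 1:], lons[i + 1:])
        dm = dm + dm.T
        Z = linkage(squareform(dm, checks=False), method="single")
        labels = fcluster(Z, t=link_km, criterion="distance")
    clusters = {}
    for p, lab in zip(periods, labels):
        clusters.setdefault(int(lab), []).append(p)
    out = []
    for visits in clusters.values():
        out.append(SiteCluster(
            site_id=0,
            centroid_lat=float(np.mean([v.centroid_lat for v in visits])),
            centroid_lon=float(np.mean([v.centroid_lon for v in visits])),
            visits=visits))
    out.sort(key=lambda c: (round(-c.centroid_lat, 9), round(c.centroid_lon, 9)))
    for i, c in enumerate(out):
        c.site_id = i + 1
    return out


def _build_itinerary_index(clusters):
    """animal -> time-ordered [(start, cluster), ...] across all its visits."""
    itin = {}
    for c in clusters:
        for v in c.visits:
            itin.setdefault(v.animal_id, []).append((v.start, c))
    for k in itin:
        itin[k].sort(key=lambda x: x[0].value)
    return itin


def classify_sites(clusters, itineraries=None, criteria: ClassificationCriteria | None = None,
                   n_population: int | None = None) -> list[SiteCluster]:
    """Label each cluster staging / stopover / unclassified.

    The onward-flight distance of a visit is measured to the next *major*
    destination in that animal's itinerary: the next visited cluster whose
    median stay reaches the staging floor, or the next entry of
    ``itineraries`` (animal_id → time-ordered [(time, (lat, lon)), ...]),
    which callers use to supply the terminal territory arrivals.  Short
    en-route stops never count as a destination, so a staging area followed
    by a nearby stopover still shows its full onward leg.  When
    ``itineraries`` is given it must cover every visiting animal.

    staging ⇔ median stay ≥ min_staging_stay_d AND next leg > min_next_leg_km
              AND (reused across ≥ min_reuse_years years OR visited by
              ≥ min_population_fraction of the population);
    otherwise stopover if median stay ≤ max_stopover_stay_d, else unclassified.
    """
    criteria = criteria or ClassificationCriteria()
    clusters = list(clusters)
    itin = _build_itinerary_index(clusters)
    if n_population is None:
        n_population = len(itin) if itin else 1
    if itineraries is not None:
        missing = [a for c in clusters for v in c.visits
                   if (a := v.animal_id) not in itineraries]
        if missing:
            raise KeyError(f"no itinerary for animal {missing[0]!r}")

    for c in clusters:
        dists = []
        for v in c.visits:
            nxt = _next_destination(v, itin, itineraries,
                                    criteria.min_staging_stay_d)
            if nxt is not None:
                dists.append(great_circle_km(c.centroid_lat, c.centroid_lon, *nxt))
        c.next_leg_km = float(np.median(dists)) if dists else 0.0
        pop_frac = c.n_individuals / max(n_population, 1)
        is_staging = (c.median_stay_d >= criteria.min_staging_stay_d
                      and c.next_leg_km > criteria.min_next_leg_km
                      and (c.n_years >= criteria.min_reuse_years
                           or pop_frac >= criteria.min_population_fraction))
        if is_staging:
            c.label = "staging"
        elif c.median_stay_d <= criteria.max_stopover_stay_d:
            c.label = "stopover"
        else:
            c.label = "unclassified"
    return clusters


def _next_destination(visit, itin, itineraries, min_major_stay_d):
    candidates = []
    seq = itin[visit.animal_id]
    for t, cc in seq:
        if t > visit.end and cc.median_stay_d >= min_major_stay_d:
            candidates.append((t, (cc.centroid_lat, cc.centroid_lon)))
            break
    if itineraries is not None:
        for t, pos in itineraries[visit.animal_id]:
            if t > visit.end:
                candidates.append((t, tuple(pos)))
                break
    if not candidates:
        return None
    return min(candidates, key=lambda x: x[0].value)[1]


def associate_stopovers(clusters) -> dict[int, int | None]:
    """Map each stopover site to its upstream staging site.

    For every stopover visit, the most recent staging-site visit preceding it
    in that animal's itinerary casts a vote; majority wins, ties going to the
    earliest (lowest-id) staging site.  A stopover with no upstream staging
    visit in any itinerary maps to the origin territory (None) and is flagged.
    """
    clusters = list(clusters)
    itin = _build_itinerary_index(clusters)
    mapping: dict[int, int | None] = {}
    for c in clusters:
        if c.label != "stopover":
            continue
        votes: dict[int, int] = {}
        orphan = 0
        for v in c.visits:
            seq = itin[v.animal_id]
            upstream = [cc for t, cc in seq
                        if t < v.start and cc.label == "staging"]
            if upstream:
                sid = upstream[-1].site_id
                votes[sid] = votes.get(sid, 0) + 1
            else:
                orphan += 1
        if votes:
            best = max(votes.values())
            winner = min(s for s, n in votes.items() if n == best)
            c.upstream_site = winner
            mapping[c.site_id] = winner
        else:
            c.upstream_site = None
            c.origin_associated = True
            mapping[c.site_id] = None
    return mapping


@dataclass(frozen=True)
class FidelityResult:
    consistent: int
    total: int

    @property
    def proportion(self) -> float:
        if self.total == 0:
            raise ValueError("fidelity undefined: no repeat-year events")
        return self.consistent / self.total


def site_fidelity(clusters, tracked_seasons: dict[str, set] | None = None) -> FidelityResult:
    """Between-year staging fidelity.

    Over all (animal, staging site, year, season) events where the animal
    was also tracked through the same season the following year: the event
    is consistent if the animal revisited the site that next year,
    inconsistent if it overflew it (tracked through the season, but no
    visit).  ``tracked_seasons`` maps animal → set of (year, season) with
    tracking coverage; by default an animal counts as tracked in a
    (year, season) iff it has any staging visit there, so deliberate
    overflights can only be charged when coverage is supplied explicitly.
    """
    clusters = [c for c in clusters if c.label == "staging"]
    visits = {}
    for c in clusters:
        for v in c.visits:
            key = (v.animal_id, v.start.year, getattr(v, "season", None))
            visits.setdefault(key, set()).add(c.site_id)
    if tracked_seasons is None:
        tracked_seasons = {}
        for (a, y, s) in visits:
            tracked_seasons.setdefault(a, set()).add((y, s))
    consistent = total = 0
    for (a, y, s), sids in sorted(visits.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))):
        if (y + 1, s) not in tracked_seasons.get(a, set()):
            continue
        nxt = visits.get((a, y + 1, s), set())
        for sid in sorted(sids):
            total += 1
            if sid in nxt:
                consistent += 1
    return FidelityResult(consistent=consistent, total=total)


def fidelity_from_counts(repeat_events: int, exceptions: int) -> FidelityResult:
    """Fidelity from printed counts (N repeat events, k switches/overflights)."""
    if exceptions > repeat_events:
        raise ValueError("more exceptions than events")
    return FidelityResult(consistent=repeat_events - exceptions, total=repeat_events)


def build_sites_table(clusters) -> pd.DataFrame:
    """One row per site: centroid, label, use and stay summaries."""
    rows = []
    for c in sorted(clusters, key=lambda c: c.site_id):
        stays = [v.duration_d for v in c.visits]
        rows.append({
            "site_id": c.site_id,
            "centroid_lat": round(c.centroid_lat, 4),
            "centroid_lon": round(c.centroid_lon, 4),
            "label": c.label,
            "n_individuals": c.n_individuals,
            "n_visits": len(c.visits),
            "n_years": c.n_years,
            "median_stay_d": round(float(np.median(stays)), 2),
            "mean_stay_d": round(float(np.mean(stays)), 2),
            "next_leg_km": round(c.next_leg_km, 1),
            "upstream_site": c.upstream_site,
        })
    return pd.DataFrame(rows)
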