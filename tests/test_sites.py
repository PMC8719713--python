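import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_single_linkage
from whimtrack import sites
from whimtrack.geodesy import destination_point, great_circle_km
from whimtrack.segmentation import StationaryPeriod

UTC = "UTC"


def make_period(animal="a", start="2015-08-01", days=10.0, lat=45.0, lon=-64.0,
                season=None):
    t0 = pd.Timestamp(start, tz=UTC)
    return StationaryPeriod(animal_id=animal, start=t0,
                            end=t0 + pd.Timedelta(days=days),
                            centroid_lat=lat, centroid_lon=lon, n_fixes=10,
                            season=season)


class TestClustering:
    def test_single_visit_single_cluster(self):
        (c,) = sites.cluster_visits([make_period()])
        assert len(c.visits) == 1
        assert c.centroid_lat == 45.0

    def test_linkage_against_brute_force(self):
        # distances {100, 100, 200-ish} with link 250 → one chain cluster;
        # a fourth point 600 km away stays alone
        a = (45.0, -64.0)
        b = destination_point(*a, 90.0, 100.0)
        c = destination_point(*b, 90.0, 100.0)
        d = destination_point(*a, 180.0, 600.0)
        pts = [a, b, c, d]
        periods = [make_period(animal=f"x{i}", lat=p[0], lon=p[1])
                   for i, p in enumerate(pts)]
        clusters = sites.cluster_visits(periods, link_km=250.0)
        n = len(pts)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                dm[i, j] = great_circle_km(*pts[i], *pts[j])
        expected = brute_force_single_linkage(dm, 250.0)
        got = sorted((len(c.visits) for c in clusters), reverse=True)
        assert got == sorted((len(s) for s in expected), reverse=True) == [3, 1]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        periods = [make_period(animal=f"x{i}", lat=40 + rng.uniform(-8, 8),
                               lon=-70 + rng.uniform(-8, 8)) for i in range(12)]
        ref = sites.cluster_visits(periods)
        perm = [periods[i] for i in rng.permutation(12)]
        other = sites.cluster_visits(perm)
        key = lambda cl: sorted((round(c.centroid_lat, 6), len(c.visits)) for c in cl)
        assert key(ref) == key(other)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sites.cluster_visits([])


def _two_site_itinerary():
    """Two animals, staging at A (19 d) then a stopover B, then far terminal."""
    A = (45.0, -64.0)
    B = destination_point(*A, 200.0, 400.0)
    terminal = (6.0, -55.0)
    periods, terminals = [], {}
    for i, animal in enumerate(["a", "b"]):
        periods.append(make_period(animal, "2015-08-01", 19.3, *A, season="autumn"))
        periods.append(make_period(animal, "2015-08-25", 1.0, *B, season="autumn"))
        terminals[animal] = [(pd.Timestamp("2015-09-05", tz=UTC), terminal)]
    return periods, terminals


class TestClassification:
    def test_long_stay_long_leg_multi_individual_is_staging(self):
        periods, terminals = _two_site_itinerary()
        clusters = sites.cluster_visits(periods)
        sites.classify_sites(clusters, itineraries=terminals)
        by_stay = {round(c.median_stay_d): c for c in clusters}
        assert by_stay[19].label == "staging"
        assert by_stay[19].next_leg_km > 1000
        assert by_stay[1].label == "stopover"

    def test_short_next_leg_blocks_staging(self):
        A = (45.0, -64.0)
        near_terminal = destination_point(*A, 90.0, 400.0)
        periods = [make_period(a, "2015-08-01", 10.0, *A) for a in "ab"]
        terminals = {a: [(pd.Timestamp("2015-09-01", tz=UTC), near_terminal)]
                     for a in "ab"}
        (c,) = sites.cluster_visits(periods)
        sites.classify_sites([c], itineraries=terminals)
        assert c.label == "unclassified"    # long stay but short onward leg

    def test_missing_itinerary_names_the_animal(self):
        periods, terminals = _two_site_itinerary()
        del terminals["b"]
        clusters = sites.cluster_visits(periods)
        with pytest.raises(KeyError, match="b"):
            sites.classify_sites(clusters, itineraries=terminals)

    def test_raising_distance_threshold_never_creates_staging(self):
        periods, terminals = _two_site_itinerary()
        prev = None
        for thresh in (500.0, 1000.0, 5000.0, 10000.0):
            clusters = sites.cluster_visits(periods)
            crit = sites.ClassificationCriteria(min_next_leg_km=thresh)
            sites.classify_sites(clusters, itineraries=terminals, criteria=crit)
            n_staging = sum(c.label == "staging" for c in clusters)
            if thresh == 500.0:
                assert n_staging == 1
            if thresh >= 5000.0:    # onward leg to the terminal is ~4,400 km
                assert n_staging == 0
            if prev is not None:
                assert n_staging <= prev   # monotone: higher bar, never more staging
            prev = n_staging

    def test_labels_partition(self):
        periods, terminals = _two_site_itinerary()
        clusters = sites.cluster_visits(periods)
        sites.classify_sites(clusters, itineraries=terminals)
        assert all(c.label in {"staging", "stopover", "unclassified"} for c in clusters)


class TestAssociation:
    def test_stopover_maps_to_most_recent_staging(self):
        periods, terminals = _two_site_itinerary()
        clusters = sites.cluster_visits(periods)
        sites.classify_sites(clusters, itineraries=terminals)
        mapping = sites.associate_stopovers(clusters)
        staging = next(c for c in clusters if c.label == "staging")
        stopover = next(c for c in clusters if c.label == "stopover")
        assert mapping[stopover.site_id] == staging.site_id

    def test_majority_vote_and_orphan_flag(self):
        A, B = (45.0, -64.0), (35.0, -80.0)
        S = destination_point(40.0, -70.0, 150.0, 300.0)
        terminal = (6.0, -55.0)
        periods = []
        terminals = {}
        # two birds stage at A then stop at S; one stages at B then stops at S
        for animal, stage in [("a", A), ("b", A), ("c", B)]:
            periods.append(make_period(animal, "2015-08-01", 15.0, *stage))
            periods.append(make_period(animal, "2015-08-20", 1.0, *S))
            terminals[animal] = [(pd.Timestamp("2015-09-05", tz=UTC), terminal)]
        # an early stopover before any staging: flagged origin association
        periods.append(make_period("d", "2015-07-01", 1.0, 55.0, -70.0))
        terminals["d"] = [(pd.Timestamp("2015-09-05", tz=UTC), terminal)]
        clusters = sites.cluster_visits(periods)
        sites.classify_sites(clusters, itineraries=terminals)
        sites.associate_stopovers(clusters)
        stop_s = next(c for c in clusters
                      if c.label == "stopover" and len(c.visits) == 3)
        winner = next(c for c in clusters
                      if c.label == "staging" and abs(c.centroid_lat - A[0]) < 1)
        assert stop_s.upstream_site == winner.site_id
        orphan = next(c for c in clusters
                      if c.label == "stopover" and c.visits[0].animal_id == "d")
        assert orphan.origin_associated and orphan.upstream_site is None


class TestFidelity:
    def test_printed_counts(self):
        f = sites.fidelity_from_counts(52, 1)
        assert round(100 * f.proportion) == 98

    def test_direct_counts(self):
        assert sites.fidelity_from_counts(10, 3).proportion == pytest.approx(0.7)
        assert sites.fidelity_from_counts(8, 0).proportion == 1.0

    def test_reuse_and_overflight_counting(self):
        A = (45.0, -64.0)
        periods = [
            make_period("a", "2015-08-01", 15.0, *A, season="autumn"),
            make_period("a", "2016-08-01", 15.0, *A, season="autumn"),
            make_period("b", "2015-08-01", 15.0, *A, season="autumn"),
        ]
        terminals = {x: [(pd.Timestamp(f"{y}-09-05", tz=UTC), (6.0, -55.0))
                         for y in (2015, 2016)] for x in "ab"}
        clusters = sites.cluster_visits(periods)
        sites.classify_sites(clusters, itineraries=terminals)
        # default coverage: only animal a is known-tracked in autumn 2016
        f = sites.site_fidelity(clusters)
        assert (f.consistent, f.total) == (1, 1)
        # explicit coverage says b was tracked through autumn 2016 → overflight
        tracked = {"a": {(2015, "autumn"), (2016, "autumn")},
                   "b": {(2015, "autumn"), (2016, "autumn")}}
        f2 = sites.site_fidelity(clusters, tracked_seasons=tracked)
        assert (f2.consistent, f2.total) == (1, 2)
        assert 0.0 <= f2.proportion <= 1.0

    def test_undefined_without_repeat_years(self):
        periods = [make_period("a", "2015-08-01", 15.0, season="autumn"),
                   make_period("b", "2015-08-05", 15.0, season="autumn")]
        clusters = sites.cluster_visits(periods)
        sites.classify_sites(clusters)
        f = sites.site_fidelity(clusters)
        assert f.total == 0
        with pytest.raises(ValueError):
            f.proportion
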