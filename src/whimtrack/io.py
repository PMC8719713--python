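"""Reading, validating, filtering and writing ARGOS-style telemetry tables.

An ARGOS (Doppler) fix carries a *location class* (LC) describing its
positional accuracy: LC3 (< 150 m) best, then LC2 (150–350 m), LC1
(350–1000 m), LC0 (> 1 km), LCA/LCB (no accuracy estimate) and LCZ (failed).
The standard quality filter retains classes 1–3 only.

Input is any delimited table with a header whose columns can be mapped onto
(animal id, timestamp, lat, lon, location class); the default dialect expects
columns ``animal_id, timestamp, lat, lon, lc`` with ISO-8601 UTC timestamps.
Canonical form: one :class:`Track` per animal, fixes strictly increasing in
time, duplicate (animal, timestamp) rows collapsed keeping the best class.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geodesy import great_circle_km, normalize_lon

#: Location classes from best to worst Doppler quality.
LOCATION_CLASSES = ("LC3", "LC2", "LC1", "LC0", "LCA", "LCB", "LCZ")
_LC_RANK = {lc: i for i, lc in enumerate(LOCATION_CLASSES)}

#: Accepted spellings in input files, normalized to canonical tokens.
_LC_ALIASES = {
    "3": "LC3", "2": "LC2", "1": "LC1", "0": "LC0",
    "A": "LCA", "B": "LCB", "Z": "LCZ",
    "LC3": "LC3", "LC2": "LC2", "LC1": "LC1", "LC0": "LC0",
    "LCA": "LCA", "LCB": "LCB", "LCZ": "LCZ",
}


class TelemetryFormatError(ValueError):
    """Raised for unparseable rows or unknown location-class tokens."""


def parse_location_class(token) -> str:
    lc = _LC_ALIASES.get(str(token).strip().upper())
    if lc is None:
        raise TelemetryFormatError(f"unknown location-class token: {token!r}")
    return lc


@dataclass(frozen=True)
class Fix:
    """One satellite location estimate."""

    animal_id: str
    timestamp: pd.Timestamp          # tz-aware UTC
    lat: float                       # decimal degrees, [-90, 90]
    lon: float                       # decimal degrees, normalized to (-180, 180]
    location_class: str              # member of LOCATION_CLASSES
    error_radius_m: float | None = None

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of bounds: {self.lat}")
        object.__setattr__(self, "lon", float(normalize_lon(self.lon)))
        if self.location_class not in _LC_RANK:
            raise ValueError(f"unknown location class {self.location_class!r}")
        ts = pd.Timestamp(self.timestamp)
        ts = ts.tz_localize("UTC") if ts.tzinfo is None else ts.tz_convert("UTC")
        object.__setattr__(self, "timestamp", ts)
        if self.error_radius_m is not None and self.error_radius_m < 0:
            raise ValueError("error_radius_m must be non-negative")


@dataclass
class Track:
    """Time-ordered fixes for one animal plus transmitter metadata."""

    animal_id: str
    fixes: list[Fix]
    duty_cycle: tuple[float, float] | None = None   # (off_hours, on_hours)
    transmitter_mass_g: float | None = None

    def __post_init__(self):
        for f in self.fixes:
            if f.animal_id != self.animal_id:
                raise ValueError(
                    f"fix animal_id {f.animal_id!r} != track {self.animal_id!r}")
        times = self.times
        if len(times) > 1 and not (np.diff(times.asi8) > 0).all():
            raise ValueError("fixes must be strictly increasing in time")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex([f.timestamp for f in self.fixes], tz="UTC")

    @property
    def lats(self) -> np.ndarray:
        return np.array([f.lat for f in self.fixes], dtype=float)

    @property
    def lons(self) -> np.ndarray:
        return np.array([f.lon for f in self.fixes], dtype=float)

    @property
    def location_classes(self) -> list[str]:
        return [f.location_class for f in self.fixes]

    def between(self, start=None, end=None) -> "Track":
        """Sub-track with fixes in [start, end] (either bound optional)."""
        fx = self.fixes
        if start is not None:
            start = _as_utc(start)
            fx = [f for f in fx if f.timestamp >= start]
        if end is not None:
            end = _as_utc(end)
            fx = [f for f in fx if f.timestamp <= end]
        return dataclasses.replace(self, fixes=list(fx))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal_id": [f.animal_id for f in self.fixes],
            "timestamp": self.times,
            "lat": self.lats,
            "lon": self.lons,
            "lc": self.location_classes,
        })


@dataclass(frozen=True)
class QualityFilterConfig:
    """ARGOS quality filter: which classes survive, optional speed-spike cap.

    The speed cap is off by default; when set, a fix whose implied segment
    speed to *both* neighbours exceeds ``max_speed_mps`` is treated as a
    positional spike and dropped.
    """

    allowed_classes: frozenset[str] = frozenset({"LC1", "LC2", "LC3"})
    max_speed_mps: float | None = None

    def __post_init__(self):
        allowed = frozenset(self.allowed_classes)
        if not allowed:
            raise ValueError("allowed_classes must be non-empty")
        unknown = allowed - set(LOCATION_CLASSES)
        if unknown:
            raise ValueError(f"unknown location classes: {sorted(unknown)}")
        object.__setattr__(self, "allowed_classes", allowed)


#: Default column mapping for delimited input (CLS exports vary).
DEFAULT_DIALECT: Mapping[str, str] = {
    "animal_id": "animal_id",
    "timestamp": "timestamp",
    "lat": "lat",
    "lon": "lon",
    "location_class": "lc",
    "error_radius_m": "error_radius_m",   # optional column
}


def read_tracks(source: IO | str, dialect: Mapping[str, str] | None = None,
                sep: str = ",") -> list[Track]:
    """Read a delimited telemetry table into canonical per-animal tracks.

    Fixes are sorted by time per animal; duplicate (animal, timestamp) rows
    collapse to the best location class (LC3 best), then first occurrence.
    An empty table yields an empty list.  Unparseable rows raise
    :class:`TelemetryFormatError` naming the offending row.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    try:
        df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    required = ["animal_id", "timestamp", "lat", "lon", "location_class"]
    missing = [dialect[k] for k in required if dialect[k] not in df.columns]
    if missing:
        raise TelemetryFormatError(f"missing columns: {missing}")

    fixes: list[Fix] = []
    err_col = dialect.get("error_radius_m")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        rec = dict(zip(df.columns, row))
        try:
            err = None
            if err_col in df.columns and rec[err_col] != "":
                err = float(rec[err_col])
            ts = pd.Timestamp(rec[dialect["timestamp"]])
            fixes.append(Fix(
                animal_id=str(rec[dialect["animal_id"]]),
                timestamp=ts,
                lat=float(rec[dialect["lat"]]),
                lon=float(rec[dialect["lon"]]),
                location_class=parse_location_class(rec[dialect["location_class"]]),
                error_radius_m=err,
            ))
        except TelemetryFormatError:
            raise
        except (ValueError, TypeError) as exc:
            raise TelemetryFormatError(f"unparseable row {i}: {exc}") from exc
    return assemble_tracks(fixes)


def assemble_tracks(fixes: Iterable[Fix]) -> list[Track]:
    """Group fixes into canonical tracks (sorted, deduplicated, per animal)."""
    by_animal: dict[str, list[Fix]] = {}
    for f in fixes:
        by_animal.setdefault(f.animal_id, []).append(f)
    tracks = []
    for animal_id in sorted(by_animal):
        fx = sorted(by_animal[animal_id],
                    key=lambda f: (f.timestamp, _LC_RANK[f.location_class]))
        dedup: list[Fix] = []
        for f in fx:
            if dedup and f.timestamp == dedup[-1].timestamp:
                continue  # earlier sort key ⇒ better class, keep first
            dedup.append(f)
        tracks.append(Track(animal_id=animal_id, fixes=dedup))
    return tracks


def filter_quality(track: Track, cfg: QualityFilterConfig | None = None) -> Track:
    """Apply the location-class filter (and optional speed-spike filter).

    Idempotent, order-preserving; may return an empty track.
    """
    cfg = cfg or QualityFilterConfig()
    fixes = [f for f in track.fixes if f.location_class in cfg.allowed_classes]
    if cfg.max_speed_mps is not None and len(fixes) > 2:
        fixes = _drop_speed_spikes(fixes, cfg.max_speed_mps)
    return dataclasses.replace(track, fixes=fixes)


def _drop_speed_spikes(fixes: Sequence[Fix], cap_mps: float) -> list[Fix]:
    def seg_speed(a: Fix, b: Fix) -> float:
        dt = (b.timestamp - a.timestamp).total_seconds()
        if dt <= 0:
            return np.inf
        return great_circle_km(a.lat, a.lon, b.lat, b.lon) * 1000.0 / dt

    keep = [fixes[0]]
    for i in range(1, len(fixes) - 1):
        if seg_speed(keep[-1], fixes[i]) > cap_mps and seg_speed(fixes[i], fixes[i + 1]) > cap_mps:
            continue
        keep.append(fixes[i])
    keep.append(fixes[-1])
    return keep


def write_tracks(tracks: Iterable[Track], sink: IO | str, sep: str = ",") -> None:
    """Write tracks as one delimited table (default dialect columns)."""
    frames = [t.to_frame() for t in tracks]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["animal_id", "timestamp", "lat", "lon", "lc"])
    df = df.copy()
    if len(df):
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(sink, sep=sep, index=False)


def write_table(rows: pd.DataFrame, sink: IO | str, float_format: str = "%.6g") -> None:
    """Write a derived output table as CSV with header (bit-stable)."""
    rows.to_csv(sink, index=False, float_format=float_format)


def write_paths_geojson(paths, sink: IO | str) -> None:
    """Write interpolated paths as an RFC 7946 FeatureCollection of LineStrings.

    ``paths`` is an iterable of objects with ``animal_id``, ``lats``, ``lons``
    (e.g. :class:`whimtrack.ctcrw.InterpolatedPath`).  Positions are in
    GeoJSON [lon, lat] order.
    """
    features = []
    for p in paths:
        coords = [[round(float(lo), 6), round(float(la), 6)]
                  for la, lo in zip(p.lats, p.lons)]
        features.append({
            "type": "Feature",
            "properties": {"animal_id": p.animal_id},
            "geometry": {"type": "LineString", "coordinates": coords},
        })
    doc = {"type": "FeatureCollection", "features": features}
    if hasattr(sink, "write"):
        json.dump(doc, sink, separators=(",", ":"))
    else:
        with open(sink, "w") as fh:
            json.dump(doc, fh, separators=(",", ":"))


def _as_utc(t) -> pd.Timestamp:
    ts = pd.Timestamp(t)
    return ts.tz_localize("UTC") if ts.tzinfo is None else ts.tz_convert("UTC")
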