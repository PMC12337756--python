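"""Domain types and readers for tracks, stop logs and transects.

Tracks are second-resolution point sequences recorded by an observer
following an individual butterfly; stops come from a field event log
(the recording protocol notes the second at which the animal lands and
what it does there), not from positional clustering. Inputs arrive as
CSV (``t,x,y`` or ``t,lon,lat``) or GeoJSON point collections;
geographic coordinates are projected to a local metric tangent plane.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .projection import LocalTangentProjection

#: Longest permitted recording, seconds. Tracking stopped after 12 min
#: in the field protocol; longer inputs draw a warning, not an error.
MAX_TRACK_DURATION_S = 720

#: An inter-fix interval of at least this many seconds counts as a data
#: gap at the nominal 1-s sampling rate.
DEFAULT_GAP_THRESHOLD_S = 3


class Species(str, enum.Enum):
    """Study species: small heath (CP) and small white (PR)."""

    CP = "CP"  # Coenonympha pamphilus
    PR = "PR"  # Pieris rapae


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Activity(str, enum.Enum):
    NECTARING = "nectaring"
    RESTING = "resting"
    BASKING = "basking"
    OVIPOSITION = "oviposition"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class TrackPoint:
    """One GPS fix: seconds since track start, planar metres."""

    t: int
    x: float
    y: float

    def __post_init__(self):
        if self.t < 0:
            raise ValueError(f"negative fix time t={self.t}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates at t={self.t}")


class TrackValidationError(ValueError):
    pass


class TrackParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass
class Trajectory:
    """Ordered, strictly time-increasing fixes for one individual."""

    individual_id: str
    species: Species
    sex: Sex
    site_id: str
    t: np.ndarray  # int seconds since start
    x: np.ndarray  # easting, m
    y: np.ndarray  # northing, m
    crs: str = "planar"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise TrackValidationError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise TrackValidationError("a trajectory needs at least 2 points")
        if np.any(np.diff(self.t) <= 0):
            raise TrackValidationError("fix times must be strictly increasing")
        if self.t[0] < 0:
            raise TrackValidationError("fix times must be nonnegative")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
            raise TrackValidationError("coordinates must be finite")
        if self.duration > MAX_TRACK_DURATION_S:
            warnings.warn(
                f"track {self.individual_id!r} lasts {self.duration} s, "
                f"longer than the {MAX_TRACK_DURATION_S} s protocol maximum",
                stacklevel=2,
            )
        if self.sex is Sex.UNKNOWN:
            warnings.warn(
                f"track {self.individual_id!r} has unknown sex; the inference "
                "stage omits unknown-sex individuals for PR",
                stacklevel=2,
            )

    @property
    def n_points(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> int:
        """Seconds from first to last fix."""
        return int(self.t[-1] - self.t[0])

    @property
    def points(self) -> list[TrackPoint]:
        return [TrackPoint(int(t), float(x), float(y)) for t, x, y in zip(self.t, self.x, self.y)]

    def with_coords(self, x: np.ndarray, y: np.ndarray) -> "Trajectory":
        return replace(self, x=np.asarray(x, float), y=np.asarray(y, float))


@dataclass(frozen=True)
class StopEvent:
    """One annotated landing: closed interval [start_s, end_s]."""

    start_s: int
    end_s: int
    activity: Activity = Activity.UNKNOWN

    def __post_init__(self):
        object.__setattr__(self, "activity", Activity(self.activity))
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(f"need 0 <= start < end, got [{self.start_s}, {self.end_s}]")

    @property
    def duration(self) -> int:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Gap:
    """A hole in the fix sequence: ``missing_duration`` absent seconds
    after the fix at time ``after_t``."""

    after_t: int
    missing_duration: int


@dataclass(frozen=True)
class TransectRecord:
    """Visually estimated flowering nectar-plant cover of one 1-m
    transect segment, percent."""

    segment_index: int
    np_cover: float

    def __post_init__(self):
        if not 0.0 <= self.np_cover <= 100.0:
            raise ValueError(f"cover {self.np_cover} outside [0, 100]")
        if self.segment_index < 1:
            raise ValueError("segment indices are 1-based")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _looks_geographic(cols: list[str]) -> bool:
    return "lon" in cols and "lat" in cols


def read_track(
    path: str | Path,
    individual_id: str = "",
    species: Species | str = Species.CP,
    sex: Sex | str = Sex.UNKNOWN,
    site_id: str = "",
) -> Trajectory:
    """Read a track from CSV (``t,x,y`` or ``t,lon,lat``) or GeoJSON.

    Rows are sorted by ``t``; duplicate timestamps are rejected;
    geographic coordinates are projected to a local tangent plane
    centred on the track centroid (recorded in ``crs``).
    """
    path = Path(path)
    individual_id = individual_id or path.stem
    species = Species(species)
    sex = Sex(sex)

    if path.suffix.lower() in {".geojson", ".json"}:
        t, x, y, geographic = _read_track_geojson(path)
    else:
        t, x, y, geographic = _read_track_csv(path)

    order = np.argsort(t, kind="stable")
    t, x, y = t[order], x[order], y[order]
    if np.any(np.diff(t) == 0):
        dup = int(t[np.where(np.diff(t) == 0)[0][0]])
        raise TrackValidationError(f"duplicate timestamp t={dup}")

    crs = "planar"
    if geographic:
        proj = LocalTangentProjection.for_points(x, y)
        x, y = proj.forward(x, y)
        crs = proj.describe()

    return Trajectory(individual_id, species, sex, site_id, t, x, y, crs=crs)


def _read_track_csv(path: Path):
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV body
        raise TrackParseError(str(exc)) from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "t" not in cols:
        raise TrackParseError(f"missing 't' column; found {cols}")
    geographic = _looks_geographic(cols)
    cx, cy = ("lon", "lat") if geographic else ("x", "y")
    if cx not in cols or cy not in cols:
        raise TrackParseError(f"need columns t,{cx},{cy}; found {cols}")
    for col in ("t", cx, cy):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            # +2: header line plus 1-based numbering
            row = int(np.where(bad | df[col].isna())[0][0])
            raise TrackParseError(f"non-numeric or missing {col!r}", line=row + 2)
    t = df["t"].to_numpy(dtype=float)
    if np.any(t != np.round(t)):
        raise TrackParseError("timestamps must be whole seconds")
    return t.astype(np.int64), df[cx].to_numpy(float), df[cy].to_numpy(float), geographic


def _read_track_geojson(path: Path):
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features")
    if feats is None:
        raise TrackParseError("GeoJSON input must be a FeatureCollection of Points")
    t, xs, ys = [], [], []
    for i, feat in enumerate(feats):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise TrackParseError(f"feature {i} is not a Point")
        props = feat.get("properties") or {}
        if "t" not in props:
            raise TrackParseError(f"feature {i} lacks a 't' property")
        lon, lat = geom["coordinates"][:2]
        t.append(int(props["t"]))
        xs.append(float(lon))
        ys.append(float(lat))
    # GeoJSON coordinates are lon/lat by definition
    return np.asarray(t, np.int64), np.asarray(xs), np.asarray(ys), True


def write_track(traj: Trajectory, path: str | Path) -> None:
    """Write the planar view back to a ``t,x,y`` CSV (round-trips to
    1e-6 m; timestamps exactly)."""
    df = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y})
    df.to_csv(path, index=False, float_format="%.6f")


def read_events(path: str | Path) -> list[StopEvent]:
    """Read a stop log CSV with columns ``start_s,end_s,activity``."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    needed = {"start_s", "end_s", "activity"}
    if not needed.issubset(df.columns):
        raise TrackParseError(f"event log needs columns {sorted(needed)}")
    events = []
    for i, row in df.iterrows():
        try:
            events.append(
                StopEvent(int(row["start_s"]), int(row["end_s"]),
                          Activity(str(row["activity"]).strip().lower()))
            )
        except ValueError as exc:
            raise TrackParseError(str(exc), line=int(i) + 2) from exc
    return sorted(events, key=lambda e: e.start_s)


def write_events(events: list[StopEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_s": [e.start_s for e in events],
            "end_s": [e.end_s for e in events],
            "activity": [e.activity.value for e in events],
        }
    ).to_csv(path, index=False)


def read_transect(path: str | Path) -> list[TransectRecord]:
    """Read a transect CSV with columns ``segment,np_cover_pct``."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "segment" not in df.columns or "np_cover_pct" not in df.columns:
        raise TrackParseError("transect CSV needs columns segment,np_cover_pct")
    recs = [
        TransectRecord(int(s), float(c))
        for s, c in zip(df["segment"], df["np_cover_pct"])
    ]
    recs.sort(key=lambda r: r.segment_index)
    idx = [r.segment_index for r in recs]
    if idx != list(range(idx[0], idx[0] + len(idx))):
        raise TrackValidationError("transect segment indices must be contiguous")
    return recs


def write_transect(records: list[TransectRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"segment": [r.segment_index for r in records],
         "np_cover_pct": [r.np_cover for r in records]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gaps
# ---------------------------------------------------------------------------

def detect_gaps(traj: Trajectory, threshold_s: int = DEFAULT_GAP_THRESHOLD_S) -> list[Gap]:
    """Find inter-fix intervals of at least ``threshold_s`` seconds.

    At nominal 1-s sampling an interval of Δt seconds hides Δt − 1
    missing fixes, reported as ``missing_duration = Δt − 1``.
    """
    if threshold_s < 2:
        raise ValueError("gap threshold must be >= 2 s")
    dt = np.diff(traj.t)
    out = []
    for i in np.where(dt >= threshold_s)[0]:
        out.append(Gap(after_t=int(traj.t[i]), missing_duration=int(dt[i]) - 1))
    return out


def split_on_gaps(traj: Trajectory, gaps: list[Gap]) -> list[range]:
    """Partition point indices into contiguous segments at each gap.

    Returns k+1 ranges for k gaps; their concatenation enumerates
    0..n-1 in order.
    """
    cuts = sorted(g.after_t for g in gaps)
    bounds = [0]
    for c in cuts:
        idx = int(np.searchsorted(traj.t, c, side="right"))
        bounds.append(idx)
    bounds.append(traj.n_points)
    return [range(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
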