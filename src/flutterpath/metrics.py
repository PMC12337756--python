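"""Per-individual movement metrics: speed, time budgets, tortuosity.

Tortuosity is Benhamou's corrected sinuosity

    Sin = 2 * [ p * ( (1 + c) / (1 - c) + b**2 ) ] ** (-1/2)

with p the mean step length (m), c the mean cosine of turning angles
and b the coefficient of variation of step length. Sin is ~0 for a
straight path and grows as the path convolutes; its unit is m^(-1/2).
Where a track is split by data gaps, each piece gets its own sinuosity
and the track value is the mean weighted by relative segment length.

Flight speed divides the path length travelled while flying by the
seconds spent flying: after stop consolidation the displacement inside
a stop is exactly zero, and counting those seconds would conflate speed
with stopping share, which is modelled separately. A ``gross`` switch
divides by total retained duration instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stops import ProcessedTrack
from .trajectory import Activity

#: Fewest fixes in a segment for turning angles to exist.
MIN_SEGMENT_POINTS = 3


class DegenerateSegmentError(ValueError):
    pass


class UndefinedSinuosityError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentGeometry:
    """Step/turn summary of one gap-free path segment."""

    step_lengths: np.ndarray
    turning_angles: np.ndarray
    p: float  # mean step length, m
    c: float  # mean cosine of turning angles
    b: float  # CV of step length (population SD / mean)

    @property
    def path_length(self) -> float:
        return float(self.step_lengths.sum())


def segment_geometry(points: np.ndarray) -> SegmentGeometry:
    """Steps, signed turning angles and the (p, c, b) triple.

    Zero-length steps (consecutive duplicate fixes) are merged before
    heading computation — a heading is undefined across a zero step.
    Needs at least 2 distinct fixes for steps and 3 for angles.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) >= 2:
        dup = np.all(np.isclose(np.diff(pts, axis=0), 0.0, atol=0.0), axis=1)
        pts = pts[np.concatenate([[True], ~dup])]
    if len(pts) < 2:
        raise DegenerateSegmentError(f"need >= 2 distinct fixes, got {len(pts)}")

    d = np.diff(pts, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    headings = np.arctan2(d[:, 1], d[:, 0])
    turns = np.diff(headings)
    turns = (turns + np.pi) % (2.0 * np.pi) - np.pi  # wrap to (-pi, pi]

    p = float(steps.mean())
    c = float(np.cos(turns).mean()) if len(turns) else float("nan")
    b = float(steps.std() / p) if p > 0 else float("nan")  # population SD
    return SegmentGeometry(steps, turns, p=p, c=c, b=b)


def sinuosity(seg: SegmentGeometry) -> float:
    """Corrected sinuosity of one segment, m^(-1/2).

    Returns 0 at c = 1 (straight-path continuity limit); raises when
    the bracket p*((1+c)/(1-c) + b^2) is not positive (extreme
    anti-correlation of headings) or when angles are unavailable.
    """
    if len(seg.turning_angles) < 1 or not np.isfinite(seg.c):
        raise DegenerateSegmentError("sinuosity needs at least one turning angle")
    if seg.c >= 1.0 - 1e-12:
        return 0.0
    bracket = seg.p * ((1.0 + seg.c) / (1.0 - seg.c) + seg.b**2)
    if bracket <= 0.0:
        raise UndefinedSinuosityError(
            f"p((1+c)/(1-c)+b^2) = {bracket:.3g} <= 0 (p={seg.p}, c={seg.c}, b={seg.b})"
        )
    return float(2.0 * bracket**-0.5)


def weighted_sinuosity(segments: list[tuple[SegmentGeometry, float]]) -> float:
    """Length-weighted mean sinuosity across track segments.

    ``segments`` pairs each geometry with its weight (path length, m).
    Segments whose sinuosity is not computable are dropped from both
    numerator and denominator with a warning.
    """
    vals, weights = [], []
    for seg, w in segments:
        if w <= 0:
            raise ValueError("segment weights must be positive")
        try:
            vals.append(sinuosity(seg))
            weights.append(w)
        except (DegenerateSegmentError, UndefinedSinuosityError) as exc:
            warnings.warn(f"segment dropped from weighted sinuosity: {exc}", stacklevel=2)
    if not vals:
        raise DegenerateSegmentError("no segment admits a sinuosity value")
    v = np.asarray(vals)
    w = np.asarray(weights)
    return float((v * w).sum() / w.sum())


# ---------------------------------------------------------------------------
# per-second occupancy of the retained track span
# ---------------------------------------------------------------------------

def _second_masks(pt: ProcessedTrack):
    """Boolean masks over the seconds [t0, t1) of the retained span:
    (stopping, nectaring, resting, missing-in-gap)."""
    t0, t1 = int(pt.t[0]), int(pt.t[-1])
    n = t1 - t0
    stopping = np.zeros(n, dtype=bool)
    nectaring = np.zeros(n, dtype=bool)
    resting = np.zeros(n, dtype=bool)
    missing = np.zeros(n, dtype=bool)
    for stop in pt.stops:
        a = max(stop.event.start_s, t0) - t0
        b = min(stop.event.end_s, t1) - t0
        if b > a:
            stopping[a:b] = True
            if stop.event.activity is Activity.NECTARING:
                nectaring[a:b] = True
            elif stop.event.activity is Activity.RESTING:
                resting[a:b] = True
    for gap in pt.gaps():
        a = gap.after_t + 1 - t0
        b = a + gap.missing_duration
        missing[max(a, 0):min(b, n)] = True
    return stopping, nectaring, resting, missing


def flight_speed(pt: ProcessedTrack, gross: bool = False) -> float:
    """Mean flight speed, m/s.

    Path length accumulates within gap-free segments of the mobility
    view (zero inside stops by construction); the denominator is the
    number of seconds spent flying — retained seconds that are neither
    inside a stop nor lost to a data gap — or the full retained
    duration when ``gross``.
    """
    dist = 0.0
    for seg in pt.mobility_segments():
        dx = np.diff(pt.x[seg])
        dy = np.diff(pt.y[seg])
        dist += float(np.hypot(dx, dy).sum())
    stopping, _, _, missing = _second_masks(pt)
    if gross:
        denom = pt.analyzed_duration
    else:
        denom = int((~stopping & ~missing).sum())
    if denom <= 0:
        raise ValueError("no flying time: the whole span is stops or gaps")
    return dist / denom


def time_budget(pt: ProcessedTrack) -> tuple[float, float, float]:
    """Shares of the retained duration spent stopping / nectaring /
    resting. Stopping covers every stop activity (basking and
    oviposition are folded into stopping, not reported separately);
    nectaring and resting are subsets of stopping.
    """
    if pt.analyzed_duration <= 0:
        raise ValueError("zero analyzed duration")
    stopping, nectaring, resting, _ = _second_masks(pt)
    n = float(pt.analyzed_duration)
    return (
        float(stopping.sum()) / n,
        float(nectaring.sum()) / n,
        float(resting.sum()) / n,
    )


@dataclass(frozen=True)
class MovementSummary:
    """One individual's response variables for the inference stage."""

    individual_id: str
    species: str
    sex: str
    site_id: str
    duration_s: int
    path_m: float
    flight_speed: float
    stopping: float
    nectaring: float
    resting: float
    sinuosity: float
    n_stops: int
    n_segments: int

    def __post_init__(self):
        # 1-ulp slack: the shares are ratios of exact second counts
        assert 0.0 <= self.nectaring + self.resting <= self.stopping + 1e-9
        assert self.stopping <= 1.0 + 1e-12
        assert self.sinuosity >= 0.0


def summarize_track(pt: ProcessedTrack, weight: str = "length", gross_speed: bool = False) -> MovementSummary:
    """All response variables for one processed track.

    ``weight`` selects the sinuosity weighting: segment path ``length``
    (default) or segment ``duration``.
    """
    if weight not in {"length", "duration"}:
        raise ValueError("weight must be 'length' or 'duration'")
    tt = pt.t[pt.tortuosity_mask]
    segments = []
    for seg in pt.tortuosity_segments():
        if len(seg) < MIN_SEGMENT_POINTS:
            warnings.warn(f"segment of {len(seg)} fixes too short for sinuosity; dropped", stacklevel=2)
            continue
        geom = segment_geometry(pt.tortuosity_points[list(seg)])
        w = geom.path_length if weight == "length" else float(tt[seg[-1]] - tt[seg[0]])
        if w > 0:
            segments.append((geom, w))
    sin = weighted_sinuosity(segments)

    path = 0.0
    for seg in pt.mobility_segments():
        path += float(np.hypot(np.diff(pt.x[seg]), np.diff(pt.y[seg])).sum())
    stopping, nectaring, resting = time_budget(pt)
    return MovementSummary(
        individual_id=pt.trajectory.individual_id,
        species=pt.trajectory.species.value,
        sex=pt.trajectory.sex.value,
        site_id=pt.trajectory.site_id,
        duration_s=pt.analyzed_duration,
        path_m=path,
        flight_speed=flight_speed(pt, gross=gross_speed),
        stopping=stopping,
        nectaring=nectaring,
        resting=resting,
        sinuosity=sin,
        n_stops=len(pt.stops),
        n_segments=len(pt.tortuosity_segments()),
    )
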