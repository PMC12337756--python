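"""Stop consolidation: turning landing point-clouds into single fixes.

While a butterfly sits, the observer wearing the GPS backpack still
drifts, so a landing is recorded as a small point cloud. Each annotated
stop interval is collapsed onto the geometric median of its member
fixes (the "median center" of GIS tooling), which is robust against
the occasional large observer excursion. Two processed views result:

* the *mobility* view keeps every retained fix but pins stop members to
  the stop centre (within-stop displacement becomes exactly zero);
* the *tortuosity* view additionally keeps only the first fix of each
  stop, so that zero-length steps do not corrupt turning angles.

Stops overlapping the start or end of logging are dropped from both
views: those intervals mix tracking with the observer walking up to or
away from the animal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory import DEFAULT_GAP_THRESHOLD_S, Gap, StopEvent, Trajectory


class MedianConvergenceError(RuntimeError):
    def __init__(self, best: tuple[float, float], n_iter: int):
        self.best = best
        super().__init__(f"geometric median did not converge in {n_iter} iterations")


def geometric_median(
    points: list[tuple[float, float]] | np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> tuple[float, float]:
    """Point minimising the sum of Euclidean distances to ``points``.

    Weiszfeld iteration started at the centroid, with the Vardi-Zhang
    correction when an iterate lands on an input point (the subgradient
    condition decides whether that vertex is optimal). ``tol`` is the
    movement per iteration, metres, at which iteration stops.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("geometric median of an empty set")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if len(pts) == 1:
        return float(pts[0, 0]), float(pts[0, 1])

    y = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.hypot(pts[:, 0] - y[0], pts[:, 1] - y[1])
        at_vertex = d < 1e-12
        if at_vertex.any():
            # multiplicity of the coincident vertex vs. pull of the rest
            m = int(at_vertex.sum())
            rest = pts[~at_vertex]
            dr = d[~at_vertex]
            if len(rest) == 0:
                return float(y[0]), float(y[1])
            r_vec = ((rest - y) / dr[:, None]).sum(axis=0)
            r = np.hypot(*r_vec)
            if r <= m:  # subgradient optimality at the vertex
                return float(y[0]), float(y[1])
            t_new = (rest / dr[:, None]).sum(axis=0) / (1.0 / dr).sum()
            step = max(0.0, 1.0 - m / r)
            y_new = y + step * (t_new - y)
        else:
            w = 1.0 / d
            y_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.hypot(*(y_new - y)) < tol:
            return float(y_new[0]), float(y_new[1])
        y = y_new
    raise MedianConvergenceError((float(y[0]), float(y[1])), max_iter)


@dataclass(frozen=True)
class ConsolidatedStop:
    event: StopEvent
    center: tuple[float, float]
    member_point_count: int

    def __post_init__(self):
        if self.member_point_count < 1:
            raise ValueError("a consolidated stop needs at least one member fix")


@dataclass
class ProcessedTrack:
    """A trajectory with consolidated stops and the two analysis views.

    ``view_*`` arrays carry retained fixes only (terminal stops
    removed); ``stop_id`` is the index into ``stops`` (-1 = in flight).
    ``tortuosity_mask`` selects, within the mobility view, the fixes
    retained for turning-angle work (first fix of each stop only).
    """

    trajectory: Trajectory
    stops: list[ConsolidatedStop]
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stop_id: np.ndarray
    tortuosity_mask: np.ndarray
    gap_threshold_s: int = DEFAULT_GAP_THRESHOLD_S
    dropped_terminal_events: list[StopEvent] = field(default_factory=list)

    @property
    def mobility_points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def tortuosity_points(self) -> np.ndarray:
        return np.column_stack([self.x[self.tortuosity_mask], self.y[self.tortuosity_mask]])

    @property
    def analyzed_duration(self) -> int:
        """Seconds spanned by the retained fixes."""
        return int(self.t[-1] - self.t[0])

    def gaps(self) -> list[Gap]:
        dt = np.diff(self.t)
        return [
            Gap(after_t=int(self.t[i]), missing_duration=int(dt[i]) - 1)
            for i in np.where(dt >= self.gap_threshold_s)[0]
        ]

    def _segments(self, t: np.ndarray) -> list[range]:
        dt = np.diff(t)
        cut = np.where(dt >= self.gap_threshold_s)[0] + 1
        bounds = [0, *cut.tolist(), len(t)]
        return [range(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]

    def mobility_segments(self) -> list[range]:
        return self._segments(self.t)

    def tortuosity_segments(self) -> list[range]:
        return self._segments(self.t[self.tortuosity_mask])

    def to_frame(self):
        import pandas as pd

        tt = self.t[self.tortuosity_mask]
        rows = []
        for view, (t, x, y, sid) in {
            "mobility": (self.t, self.x, self.y, self.stop_id),
            "tortuosity": (tt, self.x[self.tortuosity_mask],
                           self.y[self.tortuosity_mask], self.stop_id[self.tortuosity_mask]),
        }.items():
            rows.append(pd.DataFrame({"view": view, "t": t, "x": x, "y": y, "stop_id": sid}))
        return pd.concat(rows, ignore_index=True)


def match_stops(
    traj: Trajectory, events: list[StopEvent]
) -> dict[StopEvent, np.ndarray]:
    """Assign fixes to stop events: fix ``i`` belongs to an event iff
    ``start_s <= t_i <= end_s``. Overlapping events are rejected;
    events reaching outside the track span are clipped with a warning.
    """
    evs = sorted(events, key=lambda e: e.start_s)
    for a, b in zip(evs[:-1], evs[1:]):
        if b.start_s <= a.end_s:
            raise ValueError(f"overlapping stop events [{a.start_s},{a.end_s}] and [{b.start_s},{b.end_s}]")
    t0, t1 = int(traj.t[0]), int(traj.t[-1])
    out: dict[StopEvent, np.ndarray] = {}
    for ev in evs:
        if ev.start_s < t0 or ev.end_s > t1:
            warnings.warn(
                f"stop [{ev.start_s},{ev.end_s}] reaches outside track span [{t0},{t1}]; clipped",
                stacklevel=2,
            )
        members = np.where((traj.t >= ev.start_s) & (traj.t <= ev.end_s))[0]
        if len(members) == 0:
            warnings.warn(f"stop [{ev.start_s},{ev.end_s}] has no member fixes", stacklevel=2)
        out[ev] = members
    return out


def consolidate(
    traj: Trajectory,
    events: list[StopEvent],
    gap_threshold_s: int = DEFAULT_GAP_THRESHOLD_S,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> ProcessedTrack:
    """Build the processed views of a track.

    Every member fix of a stop takes the stop's geometric-median
    coordinate; stops touching the first or last retained fix are
    removed from the analysis entirely; the tortuosity view keeps only
    the first fix of each remaining stop.
    """
    membership = match_stops(traj, events)

    x = traj.x.copy()
    y = traj.y.copy()
    n = traj.n_points
    stop_id = np.full(n, -1, dtype=int)
    t0, t1 = int(traj.t[0]), int(traj.t[-1])

    keep = np.ones(n, dtype=bool)
    dropped: list[StopEvent] = []
    interior: list[tuple[StopEvent, np.ndarray]] = []
    for ev, members in membership.items():
        if len(members) == 0:
            continue
        if ev.start_s <= t0 or ev.end_s >= t1:
            keep[members] = False  # logging started or ended inside this stop
            dropped.append(ev)
        else:
            interior.append((ev, members))

    stops: list[ConsolidatedStop] = []
    tortuosity_keep = np.ones(n, dtype=bool)
    for sid, (ev, members) in enumerate(sorted(interior, key=lambda em: em[0].start_s)):
        center = geometric_median(
            np.column_stack([x[members], y[members]]), tol=tol, max_iter=max_iter
        )
        x[members] = center[0]
        y[members] = center[1]
        stop_id[members] = sid
        tortuosity_keep[members[1:]] = False
        stops.append(ConsolidatedStop(ev, center, len(members)))

    t = traj.t[keep]
    return ProcessedTrack(
        trajectory=traj,
        stops=stops,
        t=t,
        x=x[keep],
        y=y[keep],
        stop_id=stop_id[keep],
        tortuosity_mask=tortuosity_keep[keep],
        gap_threshold_s=gap_threshold_s,
        dropped_terminal_events=dropped,
    )
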