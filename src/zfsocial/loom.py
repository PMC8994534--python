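"""Looming-stimulus (predator-avoidance) assay: schedules, escape detection, response curves.

A loom is a dark dot projected 10 mm to the animal's left or right that
expands linearly in diameter over 0.5 s (15 frames at 30 Hz) to a final size
of 0-12 mm, evoking a fast escape maneuver.  Looms of randomized size and
side are presented once per minute; a 20 s centering grating ends 10 s before
each loom.  Escapes are scored from trajectory speed within a response
window after loom onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .io import TrajectoryTable

MAX_FINAL_DIAM = 12.0  # mm


@dataclass
class LoomEvent:
    """One looming presentation and (after scoring) its outcome."""

    t_onset: float                 # s from session start
    side: str                      # "left" (dot on -x side) or "right"
    final_diam: float              # mm, in [0, 12]
    offset_mm: float = 10.0        # lateral dot placement
    expand_s: float = 0.5          # linear expansion duration
    expand_frames: int = 15
    escaped: bool | None = None    # filled by detector (or simulator truth)
    latency: float = math.nan      # s from onset to threshold crossing
    direction_away: bool | None = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not 0.0 <= self.final_diam <= MAX_FINAL_DIAM:
            raise ValueError(f"final_diam {self.final_diam} outside [0, {MAX_FINAL_DIAM}] mm")

    def diameter_at(self, t: float) -> float:
        """Dot diameter at absolute time t (linear ramp, then hold at final)."""
        if t < self.t_onset:
            return 0.0
        if t < self.t_onset + self.expand_s:
            return self.final_diam * (t - self.t_onset) / self.expand_s
        return self.final_diam


@dataclass
class LoomSchedule:
    """Ordered loom presentations with fixed once-per-minute spacing."""

    events: list[LoomEvent] = field(default_factory=list)
    inter_event: float = 60.0      # s between consecutive onsets
    grating_s: float = 20.0        # centering grating duration
    grating_gap_s: float = 10.0    # gap between grating end and next loom

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.t_onset)
        onsets = [e.t_onset for e in self.events]
        for a, b in zip(onsets, onsets[1:]):
            if not math.isclose(b - a, self.inter_event, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError("loom events must be spaced by inter_event seconds")

    @property
    def duration(self) -> float:
        """Total session length: one inter-event block per loom."""
        return self.inter_event * len(self.events)


def build_schedule(
    final_sizes: list[float],
    reps: int = 1,
    seed: int | None = None,
    *,
    inter_event: float = 60.0,
    first_onset: float = 30.0,
) -> LoomSchedule:
    """Randomized size x side loom schedule, one event per minute.

    Each final size is paired with both sides, ``reps`` times; the order is
    shuffled with the given seed.  The centering grating occupies the 20 s
    ending 10 s before each onset.  ``reps = 0`` gives an empty schedule.
    """
    sizes = [float(s) for s in final_sizes]
    bad = [s for s in sizes if not 0.0 <= s <= MAX_FINAL_DIAM]
    if bad:
        raise ValueError(f"final sizes outside [0, {MAX_FINAL_DIAM}] mm: {bad}")
    combos = [(s, side) for s in sizes for side in ("left", "right")] * reps
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    events = [
        LoomEvent(t_onset=first_onset + i * inter_event, side=combos[j][1], final_diam=combos[j][0])
        for i, j in enumerate(order)
    ]
    return LoomSchedule(events=events, inter_event=inter_event)


class UnscorableEventError(ValueError):
    """The response window has no tracked frames."""


def default_speed_threshold(table: TrajectoryTable, factor: float = 5.0) -> float:
    """Adaptive escape-speed threshold: ``factor`` x the median per-frame
    speed over frames in which the animal actually moved.

    Bout-and-glide swimmers are stationary in most frames, so the median is
    taken over positive-displacement frames; this keeps the threshold scaled
    to the individual's routine bout speed rather than to dwell time.
    """
    xy = table.xy
    d = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    dt = np.diff(table.t)
    speeds = d / dt
    moving = speeds[np.isfinite(speeds) & (speeds > 0)]
    if moving.size == 0:
        return math.inf
    return factor * float(np.median(moving))


def detect_escape(
    table: TrajectoryTable,
    event: LoomEvent,
    window: float = 1.0,
    speed_thresh: float | None = None,
) -> LoomEvent:
    """Score one loom: did the animal produce a fast escape within the window?

    ``escaped`` is True iff the peak inter-frame speed in
    ``[t_onset, t_onset + window]`` exceeds ``speed_thresh`` (adaptive
    default, see :func:`default_speed_threshold`).  ``latency`` is the time
    from onset to the first threshold crossing; ``direction_away`` is whether
    the lateral displacement over the window points away from the loom side.
    Returns a copy of the event with the outcome fields filled.
    """
    if window < event.expand_s:
        raise ValueError("response window must cover the expansion")
    if speed_thresh is None:
        speed_thresh = default_speed_threshold(table)
    t = table.t
    xy = table.xy
    in_win = (t >= event.t_onset) & (t <= event.t_onset + window)
    idx = np.flatnonzero(in_win)
    if idx.size < 2 or not np.any(np.isfinite(xy[idx, 0])):
        raise UnscorableEventError(f"loom at t={event.t_onset}s has no tracked frames in window")
    seg = idx[:-1]
    d = np.hypot(xy[seg + 1, 0] - xy[seg, 0], xy[seg + 1, 1] - xy[seg, 1])
    dt = t[seg + 1] - t[seg]
    speeds = d / dt
    crossing = np.flatnonzero(np.isfinite(speeds) & (speeds > speed_thresh))
    if crossing.size == 0:
        return replace(event, escaped=False, latency=math.nan, direction_away=None)
    first = seg[crossing[0]]
    latency = float(t[first] - event.t_onset)
    # lateral displacement over the escape: from crossing to end of window
    dx = float(xy[idx[-1], 0] - xy[first, 0])
    away = dx > 0 if event.side == "left" else dx < 0
    return replace(event, escaped=True, latency=latency, direction_away=bool(away))


def score_session(
    table: TrajectoryTable,
    schedule: LoomSchedule,
    window: float = 1.0,
    speed_thresh: float | None = None,
) -> list[LoomEvent]:
    """Score every loom of a session; unscorable events keep ``escaped=None``."""
    if speed_thresh is None:
        speed_thresh = default_speed_threshold(table)
    out = []
    for ev in schedule.events:
        try:
            out.append(detect_escape(table, ev, window=window, speed_thresh=speed_thresh))
        except UnscorableEventError:
            out.append(replace(ev, escaped=None))
    return out


def response_curve(events: list[LoomEvent], ci_alpha: float = 0.05) -> pd.DataFrame:
    """Escape fraction per final dot size, with binomial confidence intervals.

    Unscorable events (``escaped is None``) are excluded from denominators.
    Returns a frame with columns ``final_diam, n, n_escaped, fraction,
    ci_low, ci_high``.
    """
    rows = []
    scored = [e for e in events if e.escaped is not None]
    for size in sorted({e.final_diam for e in scored}):
        grp = [e for e in scored if e.final_diam == size]
        n = len(grp)
        k = sum(e.escaped for e in grp)
        lo, hi = proportion_confint(k, n, alpha=ci_alpha, method="wilson")
        rows.append(dict(final_diam=size, n=n, n_escaped=k, fraction=k / n, ci_low=lo, ci_high=hi))
    return pd.DataFrame(rows)
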