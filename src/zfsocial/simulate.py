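"""Seeded simulators for every assay in the pipeline.

Larval zebrafish swim in discrete bouts: brief propulsive events, each with
an associated turn, separated by glides and dwell.  The agent model here is a
bout-and-turn random walk: inter-bout intervals are exponential, per-bout
turns are wrapped-normal around a bias term, and per-bout displacements are
gamma distributed and executed as a short linear glide.  Social drive enters
through a single signed gain on the turn bias: a positive gain steers bouts
toward the stimulus (or toward the mirrored dyad partner), a negative gain
steers away, and zero gain makes the trajectory statistically independent of
the stimulus — the null that the social index is calibrated against.

Everything is driven by one `numpy` Generator per call, so equal seeds give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ArenaGeometry, TrajectoryTable
from .loom import LoomEvent, LoomSchedule


@dataclass(frozen=True)
class AgentParams:
    """Bout-kinematics and drive parameters of a simulated larva.

    Defaults describe a plausible 14 dpf larva in a 20 mm-radius watch glass:
    about one bout per second, 1.5 mm per bout, moderate turn noise.

    attraction_gain is signed: 0 = asocial null, > 0 = attraction (turn bias
    toward the stimulus, saturating as gain grows), < 0 = avoidance.
    """

    bout_rate: float = 1.0           # Hz, mean bouts per second
    bout_disp_mean: float = 1.5      # mm, mean per-bout displacement
    bout_disp_shape: float = 2.0     # gamma shape of per-bout displacement
    bout_disp_max: float = 5.0       # mm, hard cap (bounds per-frame speed)
    turn_sd: float = 0.6             # rad, wrapped-normal turn noise per bout
    attraction_gain: float = 0.0     # signed social drive k
    flight_zone: float = math.inf    # mm; negative gain only acts inside this range
    flight_vigor: float = 2.0        # displacement multiplier of an avoidance bout
    body_length: float = 5.0         # mm
    glide_s: float = 0.15            # s over which a bout's displacement plays out
    escape_speed: float = 100.0      # mm/s during a loom escape
    escape_p50: float = 6.0          # mm, loom final size at 50% escape probability
    escape_slope: float = 1.0        # 1/mm, steepness of the escape psychometric

    def __post_init__(self) -> None:
        for name in ("bout_rate", "bout_disp_mean", "bout_disp_shape", "bout_disp_max",
                     "turn_sd", "body_length", "glide_s", "escape_speed"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class KnotPathParams:
    """Closed Lissajous ("synthetic knot") path of the dot stimulus.

    x = amplitude_x * sin(p*w*t), y = amplitude_y * sin(q*w*t + phase) with
    w = 2*pi/period; p != q makes the path self-crossing.  In boutlike mode
    the dot advances along this path in discrete steps at ``bout_rate``,
    dwelling in between — the larva-like kinetics that drive following.
    """

    amplitude_x: float = 14.0        # mm
    amplitude_y: float = 14.0        # mm
    freq_p: int = 2
    freq_q: int = 3
    period: float = 120.0            # s for one closed traversal
    phase: float = 0.0               # rad
    step_mode: str = "boutlike"      # "boutlike" | "smooth"
    bout_rate: float = 1.0           # Hz, dot steps per second in boutlike mode

    def __post_init__(self) -> None:
        if self.freq_p == self.freq_q:
            raise ValueError("freq ratio p:q must have p != q")
        if self.step_mode not in ("boutlike", "smooth"):
            raise ValueError("step_mode must be 'boutlike' or 'smooth'")

    def point(self, tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = 2.0 * math.pi / self.period
        return (self.amplitude_x * np.sin(self.freq_p * w * tau),
                self.amplitude_y * np.sin(self.freq_q * w * tau + self.phase))


@dataclass(frozen=True)
class StimulusProgram:
    """Dot presentation epochs: (diameter mm, start s, duration s) each.

    The default presentation length is 300 s (a 5-min period per dot size).
    """

    epochs: tuple[tuple[float, float, float], ...] = ((4.0, 0.0, 300.0),)
    tail_s: float = 0.0              # extra stimulus-off time after the last epoch

    def __post_init__(self) -> None:
        eps = sorted(self.epochs, key=lambda e: e[1])
        for (d1, s1, u1), (_, s2, _) in zip(eps, eps[1:]):
            if s1 + u1 > s2:
                raise ValueError("stimulus epochs must not overlap")

    @property
    def duration(self) -> float:
        if not self.epochs:
            return self.tail_s
        return max(s + u for _, s, u in self.epochs) + self.tail_s

    @classmethod
    def single(cls, dot_diam: float = 4.0, duration: float = 300.0) -> "StimulusProgram":
        return cls(epochs=((float(dot_diam), 0.0, float(duration)),))


def simulate_knot_stimulus(
    params: KnotPathParams,
    program: StimulusProgram,
    fps: float = 30.0,
    seed: int | None = None,
    arena: ArenaGeometry | None = None,
) -> pd.DataFrame:
    """Per-frame stimulus track (t, stim_x, stim_y, stim_diam, epoch_id).

    Within each program epoch the dot traverses the closed knot path; in
    boutlike mode it advances in discrete steps at the dot's bout rate and
    dwells in between.  Outside epochs stim_diam is 0 and the position NaN.
    """
    n = int(round(program.duration * fps))
    t = np.arange(n) / fps
    sx = np.full(n, np.nan)
    sy = np.full(n, np.nan)
    diam = np.zeros(n)
    eid = np.full(n, -1, dtype=int)
    rng = np.random.default_rng(seed)
    for k, (d, start, dur) in enumerate(program.epochs):
        sel = (t >= start) & (t < start + dur)
        tau = t[sel] - start
        if params.step_mode == "smooth":
            px, py = params.point(tau)
        else:
            # dot advances at Poisson bout times; zero-order hold in between
            steps = [0.0]
            while steps[-1] < dur:
                steps.append(steps[-1] + rng.exponential(1.0 / params.bout_rate))
            steps = np.asarray(steps)
            hold = steps[np.searchsorted(steps, tau, side="right") - 1]
            px, py = params.point(hold)
        sx[sel], sy[sel] = px, py
        diam[sel] = d
        eid[sel] = k
    if arena is not None:
        on = diam > 0
        if not np.all(arena.contains(sx[on], sy[on])):
            raise ValueError("knot path leaves the arena; reduce amplitudes")
    return pd.DataFrame({"t": t, "stim_x": sx, "stim_y": sy, "stim_diam": diam, "epoch_id": eid})


def _wrap_angle(a):
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def _reflect_into(arena: ArenaGeometry, p: np.ndarray) -> np.ndarray:
    """Mirror a point back into the arena (specular reflection at the wall)."""
    x, y = float(p[0]), float(p[1])
    if arena.shape == "circle":
        cx, cy = arena.center
        r = math.hypot(x - cx, y - cy)
        R = arena.radius
        if r > R:
            s = (2.0 * R - r) / r
            s = max(s, 0.0)
            x, y = cx + (x - cx) * s, cy + (y - cy) * s
    else:
        def fold(v, hi):
            v = v % (2.0 * hi)
            return 2.0 * hi - v if v > hi else v
        x = fold(x, arena.width)
        y = fold(y, arena.length)
    return np.array([x, y])


class _BoutWalker:
    """Incremental bout-and-glide integrator over a fixed frame grid."""

    def __init__(self, agent: AgentParams, arena: ArenaGeometry, fps: float,
                 rng: np.random.Generator, pos: np.ndarray, heading: float):
        self.agent = agent
        self.arena = arena
        self.fps = fps
        self.rng = rng
        self.pos = np.asarray(pos, dtype=float)
        self.heading = float(heading)
        self.glide_frames = max(1, int(round(agent.glide_s * fps)))

    def next_bout_gap(self) -> int:
        """Frames until the next bout.

        Exponential waiting time at the bout rate, floored at the glide
        duration: a new bout cannot interrupt the propulsive phase of the
        previous one (the behavioral refractory period).
        """
        gap = int(round(self.rng.exponential(1.0 / self.agent.bout_rate) * self.fps))
        return max(self.glide_frames, gap, 1)

    def _refuge(self, threat: np.ndarray) -> np.ndarray:
        """Point of the arena farthest from a threat (slightly off the wall)."""
        a = self.arena
        if a.shape == "circle":
            c = np.asarray(a.center)
            v = c - threat
            nv = np.hypot(*v)
            u = v / nv if nv > 1e-9 else np.array([1.0, 0.0])
            return c + 0.9 * a.radius * u
        corners = np.array([[0.0, 0.0], [a.width, 0.0], [0.0, a.length], [a.width, a.length]])
        far = corners[np.argmax(np.hypot(*(corners - threat).T))]
        return far + 0.1 * (np.array([a.width, a.length]) / 2.0 - far)

    def turn_bias(self, target: np.ndarray | None) -> tuple[float, float]:
        """(turn-bias angle, displacement multiplier) for the next bout.

        Positive gain: saturating bias of the turn toward the target.
        Negative gain: a flight response — the bout is more vigorous and its
        turn is biased toward the refuge, the arena point farthest from the
        stimulus (steering directly "away" pins the animal against the wall;
        fleeing toward the far side is what escapes actually achieve).  A
        stimulus beyond the flight zone is ignored.
        """
        k = self.agent.attraction_gain
        if target is None or k == 0.0 or not np.all(np.isfinite(target)):
            return 0.0, 1.0
        w = abs(k) / (1.0 + abs(k))
        if k > 0:
            bearing = math.atan2(target[1] - self.pos[1], target[0] - self.pos[0])
            return w * _wrap_angle(bearing - self.heading), 1.0
        if math.hypot(target[0] - self.pos[0], target[1] - self.pos[1]) > self.agent.flight_zone:
            return 0.0, 1.0
        refuge = self._refuge(target)
        bearing = math.atan2(refuge[1] - self.pos[1], refuge[0] - self.pos[0])
        return w * _wrap_angle(bearing - self.heading), self.agent.flight_vigor

    def bout(self, out_xy: np.ndarray, out_h: np.ndarray, f: int, n_glide: int,
             target: np.ndarray | None) -> None:
        """Execute one bout starting at frame f, writing glide frames f+1..f+n_glide.

        The displacement plays out at constant speed over the glide; if the
        next bout (or the segment end) interrupts the glide after g of
        glide_frames frames, only the fraction g/glide_frames of the sampled
        displacement is covered.  This bounds per-frame speed by
        bout_disp_max / glide_s for every bout spacing.
        """
        a = self.agent
        bias, vigor = self.turn_bias(target)
        self.heading = _wrap_angle(self.heading + bias + self.rng.normal(0.0, a.turn_sd))
        disp = min(vigor * self.rng.gamma(a.bout_disp_shape, a.bout_disp_mean / a.bout_disp_shape),
                   a.bout_disp_max)
        g = min(n_glide, self.glide_frames)
        disp *= g / self.glide_frames
        end = self.pos + disp * np.array([math.cos(self.heading), math.sin(self.heading)])
        end = _reflect_into(self.arena, end)
        actual = end - self.pos
        if np.hypot(*actual) > 1e-12:
            self.heading = math.atan2(actual[1], actual[0])
        if g > 0:
            frac = np.arange(1, g + 1)[:, None] / g
            out_xy[f + 1 : f + 1 + g] = self.pos + frac * actual
        if n_glide > g:
            out_xy[f + 1 + g : f + 1 + n_glide] = end
        out_h[f + 1 : f + 1 + n_glide] = self.heading
        self.pos = end


def _random_start(arena: ArenaGeometry, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    if arena.shape == "circle":
        cx, cy = arena.center
        r = arena.radius * 0.8 * math.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * math.pi)
        pos = np.array([cx + r * math.cos(th), cy + r * math.sin(th)])
    else:
        pos = np.array([rng.uniform(0.1, 0.9) * arena.width,
                        rng.uniform(0.1, 0.9) * arena.length])
    return pos, rng.uniform(-math.pi, math.pi)


def _run_segment(walker: _BoutWalker, n: int, target_fn) -> tuple[np.ndarray, np.ndarray]:
    """Simulate n frames; target_fn(frame_index) -> target point or None."""
    xy = np.empty((n, 2))
    h = np.empty(n)
    xy[:] = walker.pos
    h[:] = walker.heading
    f = walker.next_bout_gap() - 1
    while f < n - 1:
        gap = walker.next_bout_gap()
        walker.bout(xy, h, f, min(gap, n - 1 - f), target_fn(f))
        f += gap
    return xy, h


def simulate_agent(
    agent: AgentParams,
    stimulus: pd.DataFrame | None,
    arena: ArenaGeometry,
    fps: float = 30.0,
    seed: int | None = None,
    duration: float | None = None,
    animal_id: str = "sim",
    genotype: str | None = None,
) -> TrajectoryTable:
    """Simulate one larva in a circular dish, optionally tracking a dot.

    ``stimulus`` is a track from :func:`simulate_knot_stimulus` (or None for
    an open-field session of ``duration`` seconds).  At each bout the turn is
    wrapped-normal around the gain-weighted bearing error to the dot when a
    dot is shown, around 0 otherwise; with zero gain the trajectory is
    independent of the stimulus by construction.
    """
    if arena.shape != "circle":
        raise ValueError("the virtual biological-motion assay uses a circular dish")
    rng = np.random.default_rng(seed)
    if stimulus is None:
        if duration is None:
            raise ValueError("duration required when no stimulus track is given")
        n = int(round(duration * fps))
        t = np.arange(n) / fps
        stim = pd.DataFrame({"t": t, "stim_x": np.nan, "stim_y": np.nan,
                             "stim_diam": 0.0, "epoch_id": -1}, index=range(n))
    else:
        stim = stimulus.reset_index(drop=True)
        t = stim["t"].to_numpy()
        n = len(stim)
    sxy = stim[["stim_x", "stim_y"]].to_numpy()
    on = stim["stim_diam"].to_numpy() > 0
    pos, heading = _random_start(arena, rng)
    walker = _BoutWalker(agent, arena, fps, rng, pos, heading)

    def target(f: int):
        return sxy[f] if on[f] else None

    xy, h = _run_segment(walker, n, target)
    frames = pd.DataFrame({
        "t": t, "x": xy[:, 0], "y": xy[:, 1], "heading": h,
        "stim_x": sxy[:, 0], "stim_y": sxy[:, 1],
        "stim_diam": stim["stim_diam"].to_numpy(),
        "epoch_id": stim["epoch_id"].to_numpy(),
    })
    return TrajectoryTable(frames=frames, fps=fps, arena=arena, animal_id=animal_id,
                           body_length=agent.body_length, genotype=genotype,
                           meta={"seed": seed, "attraction_gain": agent.attraction_gain})


def simulate_dyad(
    agent_a: AgentParams,
    agent_b: AgentParams,
    arena: ArenaGeometry | None = None,
    phase_duration: float = 300.0,
    fps: float = 10.0,
    seed: int | None = None,
    ids: tuple[str, str] = ("A", "B"),
    genotypes: tuple[str | None, str | None] = (None, None),
) -> tuple[TrajectoryTable, TrajectoryTable]:
    """Split-dyad session: presocial (opaque divider) then social (divider out).

    Both animals sit in mirrored rectangular tanks whose dividers coincide at
    y = 0.  During the presocial phase each behaves as an asocial walker;
    once the divider is removed, each animal's bouts are biased toward the
    partner's mirrored position with its own attraction gain, which drags its
    place preference toward the divider.  Frames carry epoch_id 0 (presocial)
    and 1 (social); each phase has ``phase_duration * fps`` frames.
    """
    if arena is None:
        arena = ArenaGeometry.dyad_tank()
    if arena.shape != "rectangle":
        raise ValueError("dyad assay uses rectangular tanks with a divider")
    rng = np.random.default_rng(seed)
    n = int(round(phase_duration * fps))
    t = np.arange(2 * n) / fps

    walkers = []
    for ag in (agent_a, agent_b):
        pos, heading = _random_start(arena, rng)
        walkers.append(_BoutWalker(ag, arena, fps, rng, pos, heading))
    xy = [np.empty((2 * n, 2)), np.empty((2 * n, 2))]
    hh = [np.empty(2 * n), np.empty(2 * n)]
    for w, arr, ha in zip(walkers, xy, hh):
        arr[:] = w.pos
        ha[:] = w.heading

    # the partner's tank is the mirror image across the shared divider wall
    if arena.divider_at == 0.0:
        def mirrored(p: np.ndarray) -> np.ndarray:
            return np.array([p[0], -p[1]])
    else:
        L = arena.length
        def mirrored(p: np.ndarray) -> np.ndarray:
            return np.array([p[0], 2.0 * L - p[1]])

    # event-driven joint simulation so each bout sees the partner's current frame
    pending = [w.next_bout_gap() - 1 for w in walkers]
    while min(pending) < 2 * n - 1:
        i = 0 if pending[0] <= pending[1] else 1
        f = pending[i]
        gap = walkers[i].next_bout_gap()
        social = f >= n  # divider removed in the second phase
        target = mirrored(xy[1 - i][f]) if social else None
        walkers[i].bout(xy[i], hh[i], f, min(gap, 2 * n - 1 - f), target)
        pending[i] = f + gap

    out = []
    eid = np.where(np.arange(2 * n) < n, 0, 1)
    for i, (ag, aid, gt) in enumerate(zip((agent_a, agent_b), ids, genotypes)):
        frames = pd.DataFrame({
            "t": t, "x": xy[i][:, 0], "y": xy[i][:, 1], "heading": hh[i],
            "stim_x": np.nan, "stim_y": np.nan, "stim_diam": 0.0, "epoch_id": eid,
        })
        out.append(TrajectoryTable(frames=frames, fps=fps, arena=arena, animal_id=aid,
                                   body_length=ag.body_length, genotype=gt,
                                   meta={"seed": seed, "phase_duration": phase_duration,
                                         "partner": ids[1 - i]}))
    return out[0], out[1]


def simulate_loom_session(
    agent: AgentParams,
    looms: LoomSchedule,
    arena: ArenaGeometry | None = None,
    fps: float = 30.0,
    seed: int | None = None,
    animal_id: str = "sim",
) -> tuple[TrajectoryTable, LoomSchedule]:
    """Predator-avoidance session with planted, ground-truthed escapes.

    Baseline swimming is the asocial bout walk.  The centering grating before
    each loom re-centers the animal at the dish center (its only modeled
    effect).  At each loom the agent escapes with probability
    ``logistic(escape_slope * (final_diam - escape_p50))``; an escape is a
    high-speed glide (``escape_speed``) directed away from the loom side,
    starting within the expansion window.  The returned schedule carries the
    ground-truth ``escaped`` flags and planted latencies.
    """
    if arena is None:
        arena = ArenaGeometry.circle(20.0)
    rng = np.random.default_rng(seed)
    block = int(round(looms.inter_event * fps))
    n = block * len(looms.events)
    t = np.arange(n) / fps
    xy = np.empty((n, 2))
    hh = np.empty(n)
    truth_events = []
    esc_dur = 0.08  # s of high-speed escape dart (~8 mm at the default speed)
    no_target = lambda f: None

    pos0, head0 = _random_start(arena, rng)
    walker = _BoutWalker(agent, arena, fps, rng, pos0, head0)
    cursor = 0  # next frame to fill

    def advance(until: int) -> None:
        """Baseline bout swimming from `cursor` up to (excluding) frame `until`."""
        nonlocal cursor
        m = until - cursor
        if m <= 0:
            return
        seg_xy, seg_h = _run_segment(walker, m + 1, no_target)
        xy[cursor:until] = seg_xy[:m]
        hh[cursor:until] = seg_h[:m]
        walker.pos = xy[until - 1].copy()
        walker.heading = hh[until - 1]
        cursor = until

    for b, ev in enumerate(looms.events):
        f0 = b * block
        onset_f = f0 + int(round((ev.t_onset - b * looms.inter_event) * fps))
        center_f = max(f0, onset_f - int(round(looms.grating_gap_s * fps)))
        # the grating herds the animal back to the dish center by its end,
        # 10 s before the loom; modeled as a re-center at that frame
        advance(center_f)
        walker.pos = np.asarray(arena.center, dtype=float)
        walker.heading = rng.uniform(-math.pi, math.pi)

        p_escape = 1.0 / (1.0 + math.exp(-agent.escape_slope * (ev.final_diam - agent.escape_p50)))
        escapes = rng.uniform() < p_escape
        latency = float(rng.uniform(0.1, 0.8 * ev.expand_s)) if escapes else math.nan

        if escapes:
            esc_start = onset_f + int(round(latency * fps))
            advance(esc_start + 1)
            # planted escape: fast straight glide away from the loom side
            esc_frames = max(2, int(round(esc_dur * fps)))
            disp = agent.escape_speed * esc_dur
            start = walker.pos.copy()
            end = None
            j0 = rng.uniform(-math.pi / 3.0, math.pi / 3.0)
            # any candidate keeps a positive away-component; near a wall the
            # more tangential ones usually still fit the full dart
            for jitter in (j0, -j0, 1.2, -1.2, 0.0):
                direction = jitter if ev.side == "left" else _wrap_angle(math.pi + jitter)
                cand = start + disp * np.array([math.cos(direction), math.sin(direction)])
                if arena.contains(cand[:1], cand[1:])[0]:
                    end = cand
                    break
            if end is None:
                # cornered: shorten the straight-away dart to the wall
                direction = 0.0 if ev.side == "left" else math.pi
                cand = start + disp * np.array([math.cos(direction), math.sin(direction)])
                lo, hi = 0.0, 1.0
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    p = start + mid * (cand - start)
                    lo, hi = (mid, hi) if arena.contains(p[:1], p[1:])[0] else (lo, mid)
                end = start + lo * (cand - start)
            e1 = min(cursor + esc_frames, f0 + block)
            frac = np.arange(1, e1 - cursor + 1)[:, None] / esc_frames
            xy[cursor:e1] = start + frac * (end - start)
            hh[cursor:e1] = direction
            walker.pos = xy[e1 - 1].copy()
            walker.heading = direction
            cursor = e1
        advance(f0 + block)
        truth_events.append(LoomEvent(t_onset=ev.t_onset, side=ev.side,
                                      final_diam=ev.final_diam, escaped=bool(escapes),
                                      latency=latency))

    # stimulus columns: loom dot diameter ramp; dot placed laterally off-center
    diam = np.zeros(n)
    sx = np.full(n, np.nan)
    sy = np.full(n, np.nan)
    eid = np.full(n, -1, dtype=int)
    for k, ev in enumerate(looms.events):
        sel = (t >= ev.t_onset) & (t < ev.t_onset + ev.expand_s)
        diam[sel] = ev.final_diam * (t[sel] - ev.t_onset) / ev.expand_s
        side = -1.0 if ev.side == "left" else 1.0
        sx[sel] = arena.center[0] + side * ev.offset_mm
        sy[sel] = arena.center[1]
        eid[sel] = k
    frames = pd.DataFrame({"t": t, "x": xy[:, 0], "y": xy[:, 1], "heading": hh,
                           "stim_x": sx, "stim_y": sy, "stim_diam": diam, "epoch_id": eid})
    table = TrajectoryTable(frames=frames, fps=fps, arena=arena, animal_id=animal_id,
                            body_length=agent.body_length, meta={"seed": seed})
    truth = LoomSchedule(events=truth_events, inter_event=looms.inter_event,
                         grating_s=looms.grating_s, grating_gap_s=looms.grating_gap_s)
    return table, truth


def generate_length_cohort(
    n_wt: int,
    n_het: int,
    n_mut: int,
    base_mean: float = 9.0,
    base_sd: float = 0.7,
    stunt_shift: float = 3.0,
    stunt_rates: dict[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Body-length cohort with a planted stunted subpopulation.

    Lengths (tip of nose to end of trunk, mm) are normal(base_mean, base_sd);
    with per-genotype probability ``stunt_rates[g]`` an individual's length is
    shifted down by ``stunt_shift``.  The default stunting rates emulate the
    observed regime: ~78% of mutants stunted, a minority of wt/het carriers.
    Returns columns ``animal_id, genotype, length_mm, stunted_true``.
    """
    if stunt_rates is None:
        stunt_rates = {"wt": 0.15, "het": 0.20, "mut": 0.78}
    for g, p in stunt_rates.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"stunt rate for {g!r} outside [0,1]")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, count in (("wt", n_wt), ("het", n_het), ("mut", n_mut)):
        p = stunt_rates.get(genotype, 0.0)
        for i in range(count):
            stunted = bool(rng.uniform() < p)
            length = rng.normal(base_mean, base_sd) - (stunt_shift if stunted else 0.0)
            rows.append(dict(animal_id=f"{genotype}{i:04d}", genotype=genotype,
                             length_mm=length, stunted_true=stunted))
    return pd.DataFrame(rows, columns=["animal_id", "genotype", "length_mm", "stunted_true"])
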