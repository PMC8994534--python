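"""Split-dyad social metrics: orienting, place preference, motion, exclusion.

Two larvae occupy adjacent 50 x 20 mm tanks separated by an opaque divider;
after a 5-min habituation the divider is removed and the animals can see each
other for another 5 min.  Social engagement is scored as the percentage of
time spent oriented at 45-90 deg to the divider (facing toward it) and the
mean normalized proximity to the divider (relative place preference, 1 = at
the divider wall, 0 = at the far wall).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import TrajectoryTable

PHASES = {0: "presocial", 1: "social"}


class UndefinedMetricError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class PairingError(ValueError):
    pass


@dataclass
class DyadScore:
    """Per-animal, per-phase dyad metrics."""

    animal_id: str
    phase: str                   # "presocial" | "social"
    pct_orienting: float         # % frames with orienting angle in [45, 90] deg
    place_pref: float            # in [0, 1]; 1 = at the divider
    pct_motion: float            # % frames moving >= body_length / 3
    n_frames: int
    genotype: str | None = None
    partner_genotype: str | None = None
    excluded: bool = False
    pairing_unknown: bool = False


def heading_series(table: TrajectoryTable, min_step: float | None = None) -> np.ndarray:
    """Per-frame movement heading (rad) from the displacement to the next frame.

    Displacements below ``min_step`` (default body_length / 10) carry no
    orientation information and give NaN, as do frames adjacent to tracking
    gaps; the last frame is always NaN.
    """
    if min_step is None:
        bl = table.body_length if table.body_length else 5.0
        min_step = bl / 10.0
    if min_step < 0:
        raise ValueError("min_step must be >= 0")
    xy = table.xy
    dx = np.diff(xy[:, 0])
    dy = np.diff(xy[:, 1])
    step = np.hypot(dx, dy)
    h = np.full(len(xy), np.nan)
    ok = np.isfinite(step) & (step >= min_step) & (step > 0)
    h[:-1][ok] = np.arctan2(dy[ok], dx[ok])
    return h


def _divider_sign(table: TrajectoryTable) -> float:
    arena = table.arena
    if arena.shape != "rectangle" or arena.divider_at is None:
        raise UndefinedMetricError("dyad metrics require a rectangular tank with a divider")
    # +1 when the divider lies in the +y direction
    return 1.0 if arena.divider_at > 0 else -1.0


def pct_time_orienting(
    table: TrajectoryTable,
    band: tuple[float, float] = (45.0, 90.0),
    min_step: float | None = None,
    require_toward: bool = True,
) -> float:
    """% of defined-heading frames oriented at ``band`` degrees to the divider.

    The orienting angle is the acute angle between the movement heading and
    the divider line, in [0, 90] deg; with ``require_toward`` (default) only
    headings with a positive component toward the divider can score, so an
    animal facing straight away from its neighbor never counts as orienting.
    Band bounds are inclusive.
    """
    h = heading_series(table, min_step=min_step)
    defined = np.isfinite(h)
    if not defined.any():
        raise UndefinedMetricError("no frames with a defined heading")
    sgn = _divider_sign(table)
    hy = np.sin(h[defined]) * sgn          # component toward the divider
    hx = np.cos(h[defined])
    angle = np.degrees(np.arctan2(np.abs(hy), np.abs(hx)))  # acute angle to divider line
    tol = 1e-9  # inclusive bounds survive float rounding of exact 45/90 deg headings
    in_band = (angle >= band[0] - tol) & (angle <= band[1] + tol)
    if require_toward:
        in_band &= hy > 0
    return 100.0 * in_band.sum() / defined.sum()


def place_preference(table: TrajectoryTable) -> float:
    """Mean relative proximity to the divider, in [0, 1].

    Computed as the mean distance from the wall opposite the divider,
    normalized to the tank length: 1 = parked at the divider wall, 0 = at
    the far wall, 0.5 = uniform occupancy.
    """
    arena = table.arena
    _divider_sign(table)
    y = table.xy[:, 1]
    y = y[np.isfinite(y)]
    if y.size == 0:
        raise UndefinedMetricError("no tracked frames")
    L = arena.length
    dist_from_far_wall = (L - y) if arena.divider_at == 0 else y
    return float(np.mean(dist_from_far_wall) / L)


def pct_time_in_motion(table: TrajectoryTable, body_length: float | None = None) -> float:
    """% of frames in which the animal moved at least one-third body length.

    The threshold is inclusive: a displacement of exactly body_length / 3
    counts as motion.  Frames without a defined displacement (tracking gaps,
    the last frame) are excluded from the denominator.
    """
    bl = body_length if body_length is not None else table.body_length
    if bl is None:
        raise ConfigurationError("pct_time_in_motion requires body_length")
    xy = table.xy
    step = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    defined = np.isfinite(step)
    if not defined.any():
        raise UndefinedMetricError("no frames with a defined displacement")
    return 100.0 * (step[defined] >= bl / 3.0).sum() / defined.sum()


def phase_table(table: TrajectoryTable, phase: str) -> TrajectoryTable:
    """Restrict a dyad session to one phase (epoch_id 0 presocial, 1 social)."""
    inv = {v: k for k, v in PHASES.items()}
    frames = table.frames[table.frames["epoch_id"] == inv[phase]].reset_index(drop=True)
    return replace(table, frames=frames)


def score_dyad(table: TrajectoryTable) -> list[DyadScore]:
    """All dyad metrics for both phases of one animal's session.

    The exclusion rule uses the whole-experiment motion fraction, so scores
    from both phases must be kept together per animal (see
    :func:`apply_exclusion`).
    """
    out = []
    for phase in ("presocial", "social"):
        sub = phase_table(table, phase)
        out.append(DyadScore(
            animal_id=table.animal_id,
            phase=phase,
            pct_orienting=pct_time_orienting(sub),
            place_pref=place_preference(sub),
            pct_motion=pct_time_in_motion(sub),
            n_frames=len(sub),
            genotype=table.genotype,
        ))
    return out


def overall_pct_motion(scores: list[DyadScore]) -> dict[str, float]:
    """Frame-weighted whole-experiment motion fraction per animal."""
    agg: dict[str, list[tuple[float, int]]] = {}
    for s in scores:
        agg.setdefault(s.animal_id, []).append((s.pct_motion, s.n_frames))
    return {
        aid: float(np.average([m for m, _ in v], weights=[n for _, n in v]))
        for aid, v in agg.items()
    }


def apply_exclusion(scores: list[DyadScore], threshold: float = 10.0) -> list[DyadScore]:
    """Drop animals that spent under ``threshold`` % of the experiment moving.

    The cut is strict: exactly 10% motion is retained.  Returns the retained
    scores; every score of an excluded animal is marked ``excluded`` first.
    """
    overall = overall_pct_motion(scores)
    kept = []
    for s in scores:
        if overall[s.animal_id] < threshold:
            s.excluded = True
        else:
            kept.append(s)
    return kept


def regroup_by_stimulus(
    scores: list[DyadScore],
    pairs: list[tuple[str, str, str, str]],
) -> dict[str, list[DyadScore]]:
    """Re-key focal animals by the genotype of their stimulus (partner) fish.

    ``pairs`` holds (focal_id, partner_id, focal_genotype, partner_genotype)
    tuples.  Scores whose animal is absent from the pairing table are labeled
    ``"unknown"`` and flagged but retained.  A self-pairing is malformed
    input and rejected.
    """
    lookup: dict[str, str] = {}
    for focal, partner, _gf, gp in pairs:
        if focal == partner:
            raise PairingError(f"animal {focal!r} paired with itself")
        lookup[focal] = gp
    grouped: dict[str, list[DyadScore]] = {}
    for s in scores:
        gp = lookup.get(s.animal_id)
        if gp is None:
            s.partner_genotype = "unknown"
            s.pairing_unknown = True
            key = "unknown-stimulus"
        else:
            s.partner_genotype = gp
            key = f"{gp}-stimulus"
        grouped.setdefault(key, []).append(s)
    return grouped


def scores_table(scores: list[DyadScore]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores])
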