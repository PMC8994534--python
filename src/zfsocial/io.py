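"""Trajectory stream I/O: frame tables, arena geometry, validation, gap filling.

Every assay stage consumes and produces the same per-frame table: time, animal
centroid, optional heading, stimulus center/diameter, and an epoch label.  All
positions are in millimeters.  For a circular arena the origin is the arena
center; for a rectangular (dyad) tank the origin is the corner where the
divider meets the side wall, with y increasing toward the wall opposite the
divider.  Raw recordings in pixels are converted at read time via a px/mm
calibration factor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

#: canonical column order of a frame stream
FRAME_COLUMNS = ["t", "x", "y", "heading", "stim_x", "stim_y", "stim_diam", "epoch_id"]


class TrajectoryFormatError(ValueError):
    """Frame stream file does not have the expected columns."""


class TrajectoryValidationError(ValueError):
    """Frame stream content violates a table invariant."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena the animal swims in; owns the coordinate conventions.

    ``circle``: watch-glass dish, origin at center, ``radius`` in mm.
    ``rectangle``: dyad tank of ``length`` (divider-normal axis, y) by
    ``width`` (x) mm; ``divider_at`` is the y coordinate of the divider wall
    and must be 0 or ``length``.
    """

    shape: Literal["circle", "rectangle"]
    radius: float | None = None
    length: float | None = None
    width: float | None = None
    divider_at: float | None = None
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.shape == "circle":
            if self.radius is None or self.radius <= 0:
                raise ValueError("circular arena requires radius > 0")
        elif self.shape == "rectangle":
            if self.length is None or self.width is None or self.length <= 0 or self.width <= 0:
                raise ValueError("rectangular arena requires length > 0 and width > 0")
            if self.divider_at is None or self.divider_at not in (0.0, float(self.length)):
                raise ValueError("divider_at must be 0 or length")
        else:  # pragma: no cover - dataclass guards
            raise ValueError(f"unknown arena shape {self.shape!r}")

    @classmethod
    def circle(cls, radius: float, center: tuple[float, float] = (0.0, 0.0)) -> "ArenaGeometry":
        return cls(shape="circle", radius=float(radius), center=center)

    @classmethod
    def dyad_tank(cls, length: float = 50.0, width: float = 20.0, divider_at: float = 0.0) -> "ArenaGeometry":
        """Standard split-dyad tank: 50 mm x 20 mm, divider at y = 0."""
        return cls(shape="rectangle", length=float(length), width=float(width), divider_at=float(divider_at))

    def contains(self, x: np.ndarray, y: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "circle":
            cx, cy = self.center
            return (x - cx) ** 2 + (y - cy) ** 2 <= (self.radius + tol) ** 2
        return (x >= -tol) & (x <= self.width + tol) & (y >= -tol) & (y <= self.length + tol)

    def to_dict(self) -> dict:
        d = {"shape": self.shape}
        if self.shape == "circle":
            d.update(radius=self.radius, center=list(self.center))
        else:
            d.update(length=self.length, width=self.width, divider_at=self.divider_at)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaGeometry":
        if d["shape"] == "circle":
            return cls.circle(d["radius"], tuple(d.get("center", (0.0, 0.0))))
        return cls(shape="rectangle", length=d["length"], width=d["width"], divider_at=d["divider_at"])


@dataclass
class TrajectoryTable:
    """Time-indexed animal + stimulus state for one session.

    ``frames`` is a DataFrame with columns ``t, x, y, heading, stim_x, stim_y,
    stim_diam, epoch_id``: t in seconds from session start (strictly
    increasing), positions in mm (NaN = animal untracked), heading in radians
    (NaN when unknown), stim_diam 0 when no stimulus is shown, epoch_id -1
    between stimulus epochs.
    """

    frames: pd.DataFrame
    fps: float
    arena: ArenaGeometry
    animal_id: str = "animal"
    body_length: float | None = None
    genotype: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = _validate_frames(self.frames, self.fps)
        if self.body_length is not None and not self.body_length > 0:
            raise TrajectoryValidationError("body_length must be > 0 when present")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def t(self) -> np.ndarray:
        return self.frames["t"].to_numpy()

    @property
    def xy(self) -> np.ndarray:
        return self.frames[["x", "y"]].to_numpy()

    @property
    def stim_xy(self) -> np.ndarray:
        return self.frames[["stim_x", "stim_y"]].to_numpy()

    def epoch_ids(self) -> list[int]:
        """Sorted distinct stimulus epoch labels (excluding -1)."""
        ids = np.unique(self.frames["epoch_id"].to_numpy())
        return [int(i) for i in ids if i >= 0]

    def epoch(self, epoch_id: int) -> pd.DataFrame:
        return self.frames[self.frames["epoch_id"] == epoch_id]


def _validate_frames(frames: pd.DataFrame, fps: float) -> pd.DataFrame:
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise TrajectoryFormatError(f"frame table missing mandatory column(s): {missing}")
    frames = frames[FRAME_COLUMNS].reset_index(drop=True)
    t = frames["t"].to_numpy(dtype=float)
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise TrajectoryValidationError(
                f"time not strictly increasing at row {bad[0] + 1} (t={t[bad[0] + 1]!r})"
            )
        dt = np.median(np.diff(t))
        if fps > 0 and not math.isclose(dt, 1.0 / fps, rel_tol=0.10):
            raise TrajectoryValidationError(
                f"median inter-frame interval {dt:.4g}s deviates >10% from 1/fps={1.0 / fps:.4g}s"
            )
    sd = frames["stim_diam"].to_numpy(dtype=float)
    if np.any(sd[np.isfinite(sd)] < 0):
        raise TrajectoryValidationError("stim_diam must be >= 0")
    frames = frames.astype({c: float for c in FRAME_COLUMNS[:-1]})
    frames["stim_diam"] = frames["stim_diam"].fillna(0.0)
    frames["epoch_id"] = frames["epoch_id"].fillna(-1).astype(int)
    return frames


def read_frames(
    path: str | Path,
    fps: float,
    arena: ArenaGeometry,
    *,
    px_per_mm: float | None = None,
    animal_id: str = "animal",
    body_length: float | None = None,
    genotype: str | None = None,
) -> TrajectoryTable:
    """Read a delimited frame stream into a validated :class:`TrajectoryTable`.

    The file must be comma-delimited text with a header naming the columns
    ``t,x,y,heading,stim_x,stim_y,stim_diam,epoch_id`` (``nan`` spells a
    missing value).  If ``px_per_mm`` is given, all positions and diameters
    are divided by it (pixel recordings -> mm).
    """
    path = Path(path)
    try:
        frames = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TrajectoryFormatError(f"{path} is empty or not a CSV frame stream") from exc
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise TrajectoryFormatError(f"{path} missing mandatory column(s): {missing}")
    if px_per_mm is not None:
        for c in ("x", "y", "stim_x", "stim_y", "stim_diam"):
            frames[c] = frames[c] / px_per_mm
    sidecar = path.with_suffix(".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        animal_id = meta.get("animal_id", animal_id)
        body_length = meta.get("body_length", body_length)
        genotype = meta.get("genotype", genotype)
    return TrajectoryTable(
        frames=frames, fps=fps, arena=arena, animal_id=animal_id,
        body_length=body_length, genotype=genotype, meta=meta,
    )


def write_frames(table: TrajectoryTable, path: str | Path, *, sidecar: bool = True) -> None:
    """Write a frame stream as CSV (plus a JSON metadata sidecar).

    Floats are serialized with ``repr`` so that a read-back table is
    field-for-field equal to the original.
    """
    path = Path(path)
    df = table.frames.copy()
    with open(path, "w") as fh:
        fh.write(",".join(FRAME_COLUMNS) + "\n")
        cols = [df[c].to_numpy() for c in FRAME_COLUMNS]
        for i in range(len(df)):
            row = [repr(float(col[i])) if j < 7 else str(int(col[i])) for j, col in enumerate(cols)]
            fh.write(",".join(row) + "\n")
    if sidecar:
        meta = dict(table.meta)
        meta.update(
            animal_id=table.animal_id,
            fps=table.fps,
            body_length=table.body_length,
            genotype=table.genotype,
            arena=table.arena.to_dict(),
        )
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def fill_gaps(table: TrajectoryTable, max_gap_frames: int = 3) -> TrajectoryTable:
    """Linearly interpolate short tracking dropouts in the animal position.

    Runs of at most ``max_gap_frames`` consecutive missing (NaN) positions
    that are bracketed by observed frames are filled by linear interpolation
    in time; longer runs (and leading/trailing gaps) are left NaN, which is
    how downstream metrics recognize and exclude them.  Observed frames are
    never modified; the operation is idempotent.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    frames = table.frames.copy()
    missing = frames["x"].isna() | frames["y"].isna()
    if max_gap_frames == 0 or not missing.any():
        return replace(table, frames=frames)
    t = frames["t"].to_numpy()
    obs = np.flatnonzero(~missing.to_numpy())
    for col in ("x", "y"):
        v = frames[col].to_numpy(dtype=float)
        # locate maximal runs of missing frames
        m = missing.to_numpy()
        starts = np.flatnonzero(m & ~np.roll(m, 1))
        if m[0]:
            starts = np.union1d(starts, [0])
        for s in starts:
            e = s
            while e + 1 < len(m) and m[e + 1]:
                e += 1
            run = e - s + 1
            if run <= max_gap_frames and s > 0 and e + 1 < len(m) and not m[s - 1] and not m[e + 1]:
                v[s : e + 1] = np.interp(t[s : e + 1], [t[s - 1], t[e + 1]], [v[s - 1], v[e + 1]])
        frames[col] = v
    if obs.size:  # keep heading NaN where it was; positions only
        pass
    return replace(table, frames=frames)
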