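"""The social index (SI): observed animal-dot distance versus a time-shifted null.

The SI quantifies attraction of a solitary larva to a projected dot moving
with larva-like bout kinetics.  For each stimulus epoch the observed mean
animal-dot distance (IADr) is compared against the distance expected from
chance encounters alone, obtained by recomputing the mean distance after
time-shifting the animal trajectory relative to the stimulus trajectory by
several offsets greater than 60 s (IADs; their mean is mIADs):

    SI = (mIADs - IADr) / mIADs

SI is 1 for an animal glued to the dot, 0 for a trajectory unrelated to the
dot, and negative for active avoidance.  Shifts are circular within the
epoch, which preserves the marginal spatial distribution of both
trajectories and keeps the frame count identical between the real and every
shifted series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrajectoryTable


class NoStimulusFramesError(ValueError):
    """The table (or epoch) contains no stimulus-on frames."""


class InsufficientEpochError(ValueError):
    """Epoch too short for the requested time-shift offsets."""


class DegenerateGeometryError(ValueError):
    """mIADs is zero, so the index is undefined."""


@dataclass(frozen=True)
class SIConfig:
    """Shift-null configuration.

    ``n_offsets`` offsets are spaced evenly in the open interval
    (min_offset_s, epoch_duration - min_offset_s); every offset therefore
    exceeds 60 s by default.  ``chunk_s`` sets the averaging chunk for IADr
    (one 300 s chunk per 5-min presentation by default); chunks with fewer
    than ``min_valid_frac`` valid frames are excluded.
    """

    n_offsets: int = 10
    min_offset_s: float = 60.0
    chunk_s: float = 300.0
    min_valid_frac: float = 0.5


@dataclass
class SIResult:
    """Per-epoch social index and its ingredients."""

    epoch_id: int
    dot_diam: float
    IADr: float              # mm, observed mean animal-dot distance
    IADs_list: np.ndarray    # mm, one shifted mean per offset
    mIADs: float             # mm, chance-encounter expectation
    SI: float
    n_frames: int
    offsets_used: np.ndarray  # s


def animal_dot_distance(table: TrajectoryTable, epoch_id: int | None = None) -> pd.Series:
    """Per-frame Euclidean animal-dot distance (mm) over stimulus-on frames.

    Frames with a missing animal position are excluded.  Restricting to one
    epoch is optional; the index of the returned Series is the frame index
    in the original table.
    """
    fr = table.frames
    mask = fr["stim_diam"].to_numpy() > 0
    if epoch_id is not None:
        mask &= fr["epoch_id"].to_numpy() == epoch_id
    if not mask.any():
        raise NoStimulusFramesError("no stimulus-on frames in table")
    sub = fr[mask]
    d = np.hypot(sub["x"] - sub["stim_x"], sub["y"] - sub["stim_y"])
    return d[np.isfinite(d)]


def compute_IADr(distances: pd.Series | np.ndarray, t: np.ndarray | None = None,
                 chunk: float = 300.0) -> list[dict]:
    """Mean observed animal-dot distance in contiguous time chunks.

    ``distances`` is a per-frame distance series (NaN = invalid frame) and
    ``t`` the matching times; with ``t`` omitted the whole series is one
    chunk.  Returns one dict per chunk with ``IADr``, ``n_valid``,
    ``n_total`` and a ``valid_frac`` the caller can gate on.
    """
    if chunk <= 0:
        raise ValueError("chunk must be > 0")
    d = np.asarray(distances, dtype=float)
    if t is None:
        t = np.arange(len(d), dtype=float)
        edges = [(0.0, float(len(d)))]
    else:
        t = np.asarray(t, dtype=float)
        t0 = t[0]
        n_chunks = max(1, int(np.ceil((t[-1] - t0 + 1e-12) / chunk)))
        edges = [(t0 + i * chunk, t0 + (i + 1) * chunk) for i in range(n_chunks)]
    out = []
    for lo, hi in edges:
        sel = (t >= lo) & (t < hi)
        dv = d[sel]
        valid = np.isfinite(dv)
        n_tot = int(sel.sum())
        n_val = int(valid.sum())
        out.append(dict(
            t_start=lo, t_end=hi,
            IADr=float(np.mean(dv[valid])) if n_val else np.nan,
            n_valid=n_val, n_total=n_tot,
            valid_frac=n_val / n_tot if n_tot else 0.0,
        ))
    return out


def _epoch_arrays(table: TrajectoryTable, epoch_id: int):
    """Pairwise-valid animal and stimulus positions of one epoch, compacted.

    Frames with a missing animal position are dropped from BOTH the animal
    and the stimulus sequence before shifting, so IADr and every IADs use
    identical frame counts.
    """
    fr = table.frames
    mask = (fr["epoch_id"].to_numpy() == epoch_id) & (fr["stim_diam"].to_numpy() > 0)
    if not mask.any():
        raise NoStimulusFramesError(f"epoch {epoch_id} has no stimulus-on frames")
    sub = fr[mask]
    axy = sub[["x", "y"]].to_numpy()
    sxy = sub[["stim_x", "stim_y"]].to_numpy()
    t = sub["t"].to_numpy()
    ok = np.isfinite(axy).all(axis=1) & np.isfinite(sxy).all(axis=1)
    return axy[ok], sxy[ok], t[ok], float(sub["stim_diam"].iloc[0])


def default_offsets(epoch_duration: float, config: SIConfig = SIConfig()) -> np.ndarray:
    """Evenly spaced shift offsets strictly inside (min_offset, T - min_offset)."""
    lo, hi = config.min_offset_s, epoch_duration - config.min_offset_s
    if hi - lo <= 0:
        raise InsufficientEpochError(
            f"epoch of {epoch_duration:.1f}s cannot host offsets > {config.min_offset_s}s"
        )
    return np.linspace(lo, hi, config.n_offsets + 2)[1:-1]


def compute_shifted_IADs(table: TrajectoryTable, offsets: np.ndarray,
                         epoch_id: int | None = None) -> np.ndarray:
    """Mean animal-dot distance after circularly shifting the animal in time.

    For each offset (s) the compacted animal position sequence of the epoch
    is rolled by ``round(offset * fps)`` frames against the stimulus sequence
    and the mean distance recomputed.  An offset of 0 reproduces IADr exactly
    (useful as an identity check; the production offsets all exceed 60 s).
    """
    if epoch_id is None:
        ids = table.epoch_ids()
        if len(ids) != 1:
            raise ValueError("epoch_id required for multi-epoch tables")
        epoch_id = ids[0]
    axy, sxy, _, _ = _epoch_arrays(table, epoch_id)
    if len(axy) == 0:
        raise NoStimulusFramesError("no valid frames in epoch")
    out = np.empty(len(offsets))
    for i, off in enumerate(np.asarray(offsets, dtype=float)):
        s = int(round(off * table.fps)) % len(axy)
        shifted = np.roll(axy, s, axis=0)
        out[i] = np.mean(np.hypot(shifted[:, 0] - sxy[:, 0], shifted[:, 1] - sxy[:, 1]))
    return out


def compute_SI(table: TrajectoryTable, config: SIConfig = SIConfig()) -> list[SIResult]:
    """Social index per stimulus epoch.

    Positive SI means attraction (observed distance below the shifted
    chance expectation), negative means avoidance; SI never exceeds 1.
    Epochs shorter than ``2 * min_offset_s`` plus one frame are rejected;
    chunks with under half their frames valid are excluded from IADr.
    """
    results = []
    for eid in table.epoch_ids():
        axy, sxy, t, dot_diam = _epoch_arrays(table, eid)
        if len(axy) == 0:
            raise NoStimulusFramesError(f"epoch {eid} has no valid frames")
        duration = t[-1] - t[0] + 1.0 / table.fps
        if duration <= 2.0 * config.min_offset_s + 1.0 / table.fps:
            raise InsufficientEpochError(
                f"epoch {eid} ({duration:.1f}s) shorter than "
                f"{2 * config.min_offset_s:.0f}s plus one frame"
            )
        d = np.hypot(axy[:, 0] - sxy[:, 0], axy[:, 1] - sxy[:, 1])
        chunks = compute_IADr(d, t, chunk=config.chunk_s)
        kept = [c for c in chunks if c["valid_frac"] >= config.min_valid_frac]
        if not kept:
            raise NoStimulusFramesError(f"epoch {eid}: every chunk under-sampled")
        w = np.array([c["n_valid"] for c in kept], dtype=float)
        iadr = float(np.average([c["IADr"] for c in kept], weights=w))
        offsets = default_offsets(duration, config)
        iads = compute_shifted_IADs(table, offsets, epoch_id=eid)
        miads = float(np.mean(iads))
        if miads == 0.0:
            raise DegenerateGeometryError(f"epoch {eid}: mIADs = 0, SI undefined")
        si = (miads - iadr) / miads
        results.append(SIResult(epoch_id=eid, dot_diam=dot_diam, IADr=iadr,
                                IADs_list=iads, mIADs=miads, SI=si,
                                n_frames=len(axy), offsets_used=offsets))
    return results


def si_table(results: list[SIResult]) -> pd.DataFrame:
    """Flatten SI results for CSV export."""
    return pd.DataFrame([
        dict(epoch_id=r.epoch_id, dot_diam=r.dot_diam, IADr=r.IADr, mIADs=r.mIADs,
             SI=r.SI, n_frames=r.n_frames, n_offsets=len(r.offsets_used))
        for r in results
    ])
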