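"""Open-field locomotor metrics and the stunted-growth classifier.

Speed and thigmotaxis are scored from the same watch-glass sessions as the
social index and serve as sensorimotor controls: a genotype that swims
normally and hugs the wall normally but ignores the dot has a specifically
social deficit.  The stunted classifier flags animals whose body length falls
more than 1.5 wild-type standard deviations below the wild-type mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrajectoryTable


class UndefinedMetricError(ValueError):
    pass


class GeometryError(ValueError):
    pass


def average_speed(table: TrajectoryTable) -> float:
    """Total path length over total tracked duration (input units per second).

    Segments touching a tracking gap are excluded from both the numerator
    and the denominator, so gaps neither add distance nor dilute speed.
    """
    if len(table) < 2:
        raise UndefinedMetricError("average speed needs at least 2 frames")
    xy = table.xy
    t = table.t
    seg = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    dt = np.diff(t)
    ok = np.isfinite(seg)
    if not ok.any():
        raise UndefinedMetricError("no tracked segments")
    return float(seg[ok].sum() / dt[ok].sum())


def thigmotaxis_index(table: TrajectoryTable, outer_frac: float = 2.0 / 3.0) -> float:
    """Wall-hugging index: fraction of tracked frames in the outer annulus.

    A frame counts when the animal's radial distance from the dish center
    exceeds ``outer_frac`` of the dish radius (outer third of the radius by
    default; uniform occupancy of the disc gives 1 - (2/3)^2 = 5/9).
    """
    arena = table.arena
    if arena.shape != "circle":
        raise GeometryError("thigmotaxis is defined for circular arenas")
    xy = table.xy
    ok = np.isfinite(xy).all(axis=1)
    if not ok.any():
        raise UndefinedMetricError("no tracked frames")
    cx, cy = arena.center
    r = np.hypot(xy[ok, 0] - cx, xy[ok, 1] - cy)
    return float(np.mean(r > outer_frac * arena.radius))


@dataclass
class CohortLengths:
    """Wild-type length statistics and the stunting threshold for a cohort."""

    wt_mean: float
    wt_sd: float          # sample SD (ddof = 1) of the wt stratum
    threshold: float      # wt_mean - 1.5 * wt_sd
    n_wt: int


def classify_stunted(
    cohort: pd.DataFrame,
    wt_label: str = "wt",
    sd_factor: float = 1.5,
) -> tuple[CohortLengths, pd.DataFrame]:
    """Flag stunted animals: length strictly below wt mean - 1.5 x wt SD.

    ``cohort`` needs columns ``genotype`` and ``length_mm``.  The threshold
    is estimated from the wild-type stratum only (sample SD, ddof = 1) and
    applied to every animal; a length exactly at the threshold is NOT
    stunted.  Returns the cohort statistics and a copy of the frame with a
    boolean ``stunted`` column.
    """
    wt = cohort.loc[cohort["genotype"] == wt_label, "length_mm"].to_numpy(dtype=float)
    if wt.size < 2:
        raise ValueError(f"need >= 2 {wt_label!r} individuals to estimate the SD, got {wt.size}")
    mean = float(np.mean(wt))
    sd = float(np.std(wt, ddof=1))
    thr = mean - sd_factor * sd
    out = cohort.copy()
    out["stunted"] = out["length_mm"].to_numpy(dtype=float) < thr
    return CohortLengths(wt_mean=mean, wt_sd=sd, threshold=thr, n_wt=int(wt.size)), out


def stunted_fractions(flagged: pd.DataFrame) -> pd.Series:
    """Fraction of animals flagged stunted, per genotype."""
    return flagged.groupby("genotype")["stunted"].mean()
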