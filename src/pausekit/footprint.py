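"""Permanganate footprint quantitation and occupancy bounds.

Permanganate oxidizes unpaired thymines, so the single-stranded
transcription bubble of an engaged polymerase shows up as a run of
reactive T positions on a sequencing gel.  This module aggregates
background-subtracted reactivity over a region, calls the reactive region,
fits the linear bubble-fraction calibration, tests replicate fold-changes
with an independent-samples t-test, and converts an activation fold-change
into an upper bound on the pre-activation fractional gene occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .models import LaneProfile


@dataclass(frozen=True)
class CalibrationFit:
    """Least-squares line of aggregate signal against bubble fraction."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")


@dataclass(frozen=True)
class FoldChangeResult:
    """Treated/control fold of mean aggregate reactivity with a t-test."""

    fold: float
    sd: float
    p_value: float
    n_treated: int
    n_control: int
    zero_variance: bool = False

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be > 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def quantify_region(
    lane: LaneProfile,
    region: tuple[int, int],
    background_offsets: Sequence[int],
) -> float:
    """Background-subtracted aggregate reactivity over a region.

    Sums max(0, intensity - mean background) over thymine positions in the
    closed offset interval ``region``; background offsets must be thymine
    positions outside the region.
    """
    a, b = region
    if a > b:
        raise ValueError("region must satisfy a <= b")
    if a < lane.offsets.min() or b > lane.offsets.max():
        raise ValueError("region must lie within the lane")
    bg = list(background_offsets)
    if not bg:
        raise ValueError("background offset set is empty")
    for off in bg:
        idx = np.flatnonzero(lane.offsets == off)
        if idx.size == 0 or not lane.is_thymine[idx[0]]:
            raise ValueError(f"background offset {off} is not a thymine in the lane")
        if a <= off <= b:
            raise ValueError(f"background offset {off} lies inside the region")
    bg_mean = float(
        np.mean([lane.intensity_at(off) for off in bg])
    )
    in_region = (lane.offsets >= a) & (lane.offsets <= b) & lane.is_thymine
    if not np.any(in_region):
        raise ValueError("no thymine positions in the region")
    return float(np.sum(np.maximum(0.0, lane.intensities[in_region] - bg_mean)))


def call_reactive_region(
    lane: LaneProfile,
    z_threshold: float = 2.0,
    background_offsets: Sequence[int] | None = None,
) -> tuple[int, int] | None:
    """Longest run of reactive thymines, as a closed offset interval.

    A thymine is reactive when its intensity exceeds background mean +
    ``z_threshold`` x background sd.  When ``background_offsets`` is not
    given, background thymines are those at or below the median thymine
    intensity (robust to a minority reactive run).  Returns the interval
    from the first to the last thymine of the longest reactive run, or
    None when nothing qualifies.  Requires at least 5 background thymines.
    """
    t_idx = np.flatnonzero(lane.is_thymine)
    if background_offsets is None:
        t_int = lane.intensities[t_idx]
        bg_mask = t_int <= np.median(t_int)
        bg_vals = t_int[bg_mask]
    else:
        bg_vals = np.array(
            [lane.intensity_at(off) for off in background_offsets], dtype=float
        )
    if len(bg_vals) < 5:
        raise ValueError("need at least 5 background thymine positions")
    thr = float(np.mean(bg_vals)) + z_threshold * float(np.std(bg_vals, ddof=0))
    reactive = lane.intensities[t_idx] > thr
    if not np.any(reactive):
        return None
    # longest run over consecutive thymines (in offset order)
    best = (0, -1, -1)  # (length in T count, first T index, last T index)
    run_start = None
    for i, flag in enumerate(reactive):
        if flag and run_start is None:
            run_start = i
        if (not flag or i == len(reactive) - 1) and run_start is not None:
            end = i if flag else i - 1
            length = end - run_start + 1
            if length > best[0]:
                best = (length, run_start, end)
            run_start = None
    _, first, last = best
    return int(lane.offsets[t_idx[first]]), int(lane.offsets[t_idx[last]])


def fit_calibration(
    fractions: Sequence[float], signals: Sequence[float]
) -> CalibrationFit:
    """Ordinary least-squares line of aggregate signal vs. bubble fraction.

    Requires at least 3 distinct fractions.  When the signals are constant
    the slope is 0 and r_squared is defined as 0.
    """
    x = np.asarray(fractions, dtype=float)
    y = np.asarray(signals, dtype=float)
    if len(x) != len(y):
        raise ValueError("fractions and signals must align")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct fractions")
    if np.allclose(y, y[0]):
        return CalibrationFit(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    res = stats.linregress(x, y)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(float(res.rvalue**2), 1.0),
    )


def fold_change_test(
    treated: Sequence[float],
    control: Sequence[float],
    welch: bool = False,
) -> FoldChangeResult:
    """Fold-change of group means with an independent two-sample t-test.

    fold = mean(treated) / mean(control); the p-value is from a two-sided
    pooled-variance Student's t-test (Welch with ``welch=True``); the sd of
    the fold comes from first-order propagation of the group means'
    standard errors.  Zero within-group variance with unequal means is
    reported as p = 0 with ``zero_variance`` set.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if len(t) < 2 or len(c) < 2:
        raise ValueError("need at least 2 replicates per group")
    if np.any(t <= 0) or np.any(c <= 0):
        raise ValueError("aggregates must be positive")
    mc = float(c.mean())
    mt = float(t.mean())
    if mc == 0:
        raise ValueError("zero control mean")
    fold = mt / mc
    se_t = float(t.std(ddof=1)) / math.sqrt(len(t))
    se_c = float(c.std(ddof=1)) / math.sqrt(len(c))
    sd = fold * math.sqrt(
        (se_t / mt) ** 2 + (se_c / mc) ** 2
    ) if mt > 0 else 0.0
    if np.var(t, ddof=1) == 0 and np.var(c, ddof=1) == 0:
        p = 1.0 if mt == mc else 0.0
        return FoldChangeResult(
            fold=fold, sd=sd, p_value=p, n_treated=len(t), n_control=len(c),
            zero_variance=True,
        )
    res = stats.ttest_ind(t, c, equal_var=not welch)
    return FoldChangeResult(
        fold=fold,
        sd=sd,
        p_value=float(res.pvalue),
        n_treated=len(t),
        n_control=len(c),
    )


def occupancy_bound(fold: float) -> float:
    """Maximum pre-activation fractional occupancy, in percent.

    If activation multiplies the paused-site signal by ``fold`` and signal
    is proportional to the occupied fraction (the linear bubble-fraction
    calibration), the activated occupancy can be at most 100%, so the
    pre-activation occupancy is at most min(100, 100 / fold) percent.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    return min(100.0, 100.0 / fold)
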