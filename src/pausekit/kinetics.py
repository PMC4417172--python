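"""Pause half-life estimation and steady-state occupancy.

Blocking transcription initiation (e.g. with triptolide, a TFIIH
inhibitor) leaves paused polymerases to decay away; the permanganate
signal then falls exponentially and its half-life is the pause residence
half-life.  The steady-state relation connects the initiation rate and the
pause-exit rate to the fraction of gene copies bearing a paused
polymerase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .models import DecaySeries

LN2 = math.log(2)


@dataclass(frozen=True)
class HalfLifeEstimate:
    """Exponential-decay fit: t_half in minutes, rate = ln2 / t_half."""

    t_half: float
    decay_rate: float
    fit_r_squared: float

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValueError("t_half must be > 0")
        if abs(self.decay_rate * self.t_half - LN2) > 1e-9:
            raise ValueError("decay_rate must equal ln2 / t_half")


def normalize_series(series: DecaySeries) -> DecaySeries:
    """Divide all values by the replicate-mean value at t = 0."""
    t0 = float(np.mean(series.replicate_values[:, series.times == 0.0]))
    if t0 <= 0:
        raise ValueError("mean value at t = 0 must be > 0")
    return DecaySeries(
        times=series.times.copy(),
        replicate_values=series.replicate_values / t0,
        normalized=True,
    )


def fit_half_life(
    series: DecaySeries,
    value_floor: float = 1e-6,
) -> HalfLifeEstimate:
    """Log-linear least-squares fit of the decay series.

    Regresses ln(value) on time over all replicate points (intercept
    free); t_half = ln2 / (-slope).  Values at or below zero are floored
    at ``value_floor`` with a warning.  A non-negative slope (no decay) is
    an error.
    """
    times = series.times
    if len(np.unique(times)) < 3:
        raise ValueError("need at least 3 distinct time points")
    values = series.replicate_values
    if np.any(values <= 0):
        warnings.warn(
            f"flooring {int(np.sum(values <= 0))} non-positive values at "
            f"{value_floor} before the log fit",
            stacklevel=2,
        )
        values = np.maximum(values, value_floor)
    x = np.tile(times, values.shape[0])
    y = np.log(values).ravel()
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    if slope >= 0:
        raise ValueError(
            f"series does not decay (log-linear slope {slope:.4g} >= 0); "
            "cannot define a half-life"
        )
    resid = y - A @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    t_half = LN2 / (-slope)
    return HalfLifeEstimate(
        t_half=t_half, decay_rate=LN2 / t_half, fit_r_squared=max(0.0, min(r2, 1.0))
    )


def steady_state_occupancy(k_init: float, t_half: float) -> float:
    """Stationary paused fraction of a vacant<->paused two-state gene.

    With initiation rate ``k_init`` (per gene copy per minute) and
    pause-exit rate k_off = ln2 / ``t_half``, the stationary occupied
    fraction is k_init / (k_init + k_off): strictly increasing in both
    arguments and always < 1.
    """
    if k_init <= 0 or t_half <= 0:
        raise ValueError("k_init and t_half must be > 0")
    k_off = LN2 / t_half
    return k_init / (k_init + k_off)
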