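"""Discrete-cycle model of active neuronal necrosis.

The model assumes that, starting from an onset time ``t0``, a constant
fraction ``r`` of the residual neuron population dies during each cycle of
fixed length ``p`` days.  With ``N`` neurons per microscopy field at onset,
the population entering cycle ``k`` (k = 1, 2, ...) is

    N_k = N (1 - r)^(k - 1)

and the number of deaths occurring during cycle ``k`` — the count of
"active necrosis" events a snapshot of that field would show — is

    D_k = N r (1 - r)^(k - 1) = N_k - N_{k+1}.

Calendar time maps to a *continuous* cycle index

    k(t) = (t - t0) / p + 1        for t >= t0,

so that the expected active-necrosis count is a smooth geometric decay in
time after onset and exactly zero before it.  All counts are expected
values per field (the reference field is 143 um x 143 um); they are real
numbers, not integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DeathModelParams",
    "BEFORE_ONSET",
    "is_before_onset",
    "residual_neurons",
    "deaths_in_cycle",
    "cycles_at_time",
    "active_necrosis_at",
    "simulate_trajectory",
]

#: Sentinel cycle index returned for times earlier than the onset of
#: detectable necrosis.  NaN propagates safely through arithmetic and is
#: recognised by :func:`is_before_onset`.
BEFORE_ONSET: float = math.nan


def is_before_onset(k: float | np.ndarray) -> bool | np.ndarray:
    """True where a cycle index is the before-onset sentinel."""
    return np.isnan(k)


@dataclass(frozen=True)
class DeathModelParams:
    """Parameters of the cell-death cycle model.

    Parameters
    ----------
    n0 : float
        Initial neuron count per field at onset (cells, > 0; real-valued —
        it is an expected count, e.g. the fitted 30.3 cells/field).
    r : float
        Per-cycle death ratio, the fraction of residual neurons dying in
        one cycle (0 <= r < 1).
    period_days : float
        Cycle period p in days (> 0).
    onset_days : float
        Time t0 in days at which detectable active necrosis begins (>= 0).
    """

    n0: float
    r: float
    period_days: float
    onset_days: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.n0) or self.n0 <= 0:
            raise ValueError(f"n0 must be finite and > 0, got {self.n0}")
        if not np.isfinite(self.r) or not 0.0 <= self.r < 1.0:
            raise ValueError(f"r must satisfy 0 <= r < 1, got {self.r}")
        if not np.isfinite(self.period_days) or self.period_days <= 0:
            raise ValueError(
                f"period_days must be finite and > 0, got {self.period_days}"
            )
        if not np.isfinite(self.onset_days) or self.onset_days < 0:
            raise ValueError(
                f"onset_days must be finite and >= 0, got {self.onset_days}"
            )


def _check_cycle(k: np.ndarray) -> None:
    if np.any(k < 1.0):
        raise ValueError("cycle index k must be >= 1")


def residual_neurons(
    params: DeathModelParams, k: float | np.ndarray
) -> float | np.ndarray:
    """Expected residual neurons entering cycle ``k``: n0 (1-r)^(k-1).

    ``k`` may be fractional; values below 1 raise ``ValueError``.
    """
    k = np.asarray(k, dtype=float)
    _check_cycle(k)
    out = params.n0 * np.power(1.0 - params.r, k - 1.0)
    return float(out) if out.ndim == 0 else out


def deaths_in_cycle(
    params: DeathModelParams, k: float | np.ndarray
) -> float | np.ndarray:
    """Expected deaths during cycle ``k``: n0 r (1-r)^(k-1).

    Equals ``residual_neurons(k) - residual_neurons(k+1)`` exactly.
    """
    k = np.asarray(k, dtype=float)
    _check_cycle(k)
    out = params.n0 * params.r * np.power(1.0 - params.r, k - 1.0)
    return float(out) if out.ndim == 0 else out


def cycles_at_time(
    params: DeathModelParams, t_days: float | np.ndarray
) -> float | np.ndarray:
    """Continuous cycle index at calendar time ``t_days``.

    Returns ``(t - onset)/period + 1`` for ``t >= onset`` and the
    :data:`BEFORE_ONSET` sentinel (NaN) earlier.  Negative times raise.
    """
    t = np.asarray(t_days, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0 days")
    k = (t - params.onset_days) / params.period_days + 1.0
    k = np.where(t >= params.onset_days, k, BEFORE_ONSET)
    return float(k) if k.ndim == 0 else k


def active_necrosis_at(
    params: DeathModelParams, t_days: float | np.ndarray
) -> float | np.ndarray:
    """Expected active-necrosis count per field at time ``t_days``.

    Zero before onset; ``deaths_in_cycle(cycles_at_time(t))`` afterwards.
    """
    t = np.asarray(t_days, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0 days")
    k = (t - params.onset_days) / params.period_days + 1.0
    decay = np.power(1.0 - params.r, np.maximum(k, 1.0) - 1.0)
    out = np.where(t >= params.onset_days, params.n0 * params.r * decay, 0.0)
    return float(out) if out.ndim == 0 else out


def simulate_trajectory(
    params: DeathModelParams, times: Sequence[float]
) -> pd.Series:
    """Expected active-necrosis counts along an ordered time grid.

    Parameters
    ----------
    times : sequence of float
        Nondecreasing observation times in days, all >= 0.

    Returns
    -------
    pandas.Series
        Expected cells per field indexed by time (days).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be nonempty")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be nondecreasing")
    values = active_necrosis_at(params, t)
    return pd.Series(np.atleast_1d(values), index=pd.Index(t, name="time_days"),
                     name="expected_count")
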