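"""Three-state cohort trace and discounted QALY accumulation.

States: disease-free survival (DFS), progressed disease (PS) and death.
Occupancy is built by partitioned survival: DFS occupancy is the PFS
survivor function, the death fraction is one minus the OS survivor
function, and PS is the remainder.  This reproduces both input curves by
construction and needs no assumption about the PS-to-death transition.

Rewards use cycle-start occupancy over a full cycle, discounted at the
cycle-start time; an optional half-cycle correction averages adjacent
cycle boundaries instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .survival import WeibullParams, survival_at

__all__ = [
    "ModelSettings",
    "UtilitySchedule",
    "MarkovTrace",
    "QALYBreakdown",
    "build_trace",
    "transition_probability",
    "discount_factor",
    "accumulate_qalys",
]


@dataclass(frozen=True)
class ModelSettings:
    """Engine conventions: 6-week cycles, 52-week years, 30-year horizon,
    3% annual discounting of both costs and utilities."""

    cycle_length_weeks: float = 6.0
    weeks_per_year: float = 52.0
    horizon_years: float = 30.0
    annual_discount_rate: float = 0.03
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.cycle_length_weeks <= 0:
            raise ValueError("cycle length must be positive")
        if self.weeks_per_year <= 0:
            raise ValueError("weeks_per_year must be positive")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")
        if self.annual_discount_rate <= -1:
            raise ValueError("discount rate must exceed -1")

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_weeks / self.weeks_per_year

    @property
    def n_cycles(self) -> int:
        raw = self.horizon_years / self.cycle_years
        return int(round(raw))


def discount_factor(t_years, annual_rate: float):
    """(1 + rate)**(-t) — the present-value weight at ``t`` years."""
    if annual_rate <= -1:
        raise ValueError("discount rate must exceed -1")
    return (1.0 + annual_rate) ** (-np.asarray(t_years, dtype=float))


def transition_probability(params: WeibullParams, t: float, u: float) -> float:
    """Probability of the event within (t, t+u] given survival to t:
    ``1 - S(t+u)/S(t)``."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    if u <= 0:
        raise ValueError("cycle width u must be positive")
    s_t = survival_at(params, t)
    if s_t == 0.0:
        warnings.warn("S(t) underflowed to 0; transition probability set to 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    return 1.0 - survival_at(params, t + u) / s_t


@dataclass(frozen=True)
class UtilitySchedule:
    """Health-state utilities: DFS utility varies by time band (years since
    model start, right-open bands partitioning [0, inf)); PS utility is flat."""

    dfs_bands: Tuple[Tuple[float, float, float], ...]
    ps_utility: float

    def __post_init__(self) -> None:
        bands = tuple((float(a), float(b), float(u)) for a, b, u in self.dfs_bands)
        object.__setattr__(self, "dfs_bands", bands)
        if not bands:
            raise ValueError("at least one DFS band is required")
        if bands[0][0] != 0.0:
            raise ValueError("first band must start at 0")
        if not np.isinf(bands[-1][1]):
            raise ValueError("last band must extend to infinity")
        for (a0, b0, _), (a1, _, _) in zip(bands, bands[1:]):
            if b0 != a1:
                raise ValueError("bands must partition [0, inf) without gaps "
                                 "or overlap")
        for a, b, u in bands:
            if not (0.0 <= u <= 1.0):
                raise ValueError(f"utility {u} outside [0, 1]")
            if b <= a:
                raise ValueError("band end must exceed band start")
        if not (0.0 <= self.ps_utility <= 1.0):
            raise ValueError("PS utility outside [0, 1]")

    def dfs_utility_at(self, t_years) -> np.ndarray:
        t = np.asarray(t_years, dtype=float)
        starts = np.array([a for a, _, _ in self.dfs_bands])
        utils = np.array([u for _, _, u in self.dfs_bands])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, None)
        return utils[idx]


@dataclass
class MarkovTrace:
    """Per-cycle-boundary state occupancy.  Arrays have length
    ``n_cycles + 1``; entry k refers to time k cycles after model start."""

    cycles: np.ndarray
    years: np.ndarray
    dfs: np.ndarray
    ps: np.ndarray
    dead: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        total = self.dfs + self.ps + self.dead
        if np.max(np.abs(total - 1.0)) > 1e-12:
            raise ValueError("state occupancies must sum to 1 at every cycle")
        if np.any(np.diff(self.dead) < -1e-12):
            raise ValueError("death occupancy must be nondecreasing")

    @property
    def n_cycles(self) -> int:
        return self.cycles.size - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": self.cycles, "years": self.years,
            "dfs": self.dfs, "ps": self.ps, "dead": self.dead,
        })


def build_trace(pfs: WeibullParams, os: WeibullParams,
                settings: ModelSettings) -> MarkovTrace:
    """Partitioned-survival occupancy at every cycle boundary.

    ``dfs = S_PFS(t)``, ``dead = 1 - S_OS(t)``, ``ps = S_OS(t) - S_PFS(t)``
    clamped at zero.  Cycles where the OS curve dips below the PFS curve
    before clamping are counted in ``n_clamped``.
    """
    n = settings.n_cycles
    if n <= 0:
        raise ValueError("horizon shorter than one cycle")
    k = np.arange(n + 1, dtype=float)
    s_pfs = survival_at(pfs, k)
    s_os = survival_at(os, k)
    raw_ps = s_os - s_pfs
    n_clamped = int(np.count_nonzero(raw_ps < 0))
    ps = np.maximum(raw_ps, 0.0)
    dfs = np.minimum(s_pfs, s_os)  # consistent with the clamp: dfs+ps+dead == 1
    dead = 1.0 - s_os
    return MarkovTrace(cycles=k, years=k * settings.cycle_years,
                       dfs=dfs, ps=ps, dead=dead, n_clamped=n_clamped)


@dataclass(frozen=True)
class QALYBreakdown:
    dfs: float
    ps: float
    total: float
    per_cycle_dfs: np.ndarray = field(repr=False, default=None)
    per_cycle_ps: np.ndarray = field(repr=False, default=None)


def _cycle_occupancy(values: np.ndarray, settings: ModelSettings) -> np.ndarray:
    """Occupancy attributed to each of the n_cycles reward periods."""
    if settings.half_cycle_correction:
        return 0.5 * (values[:-1] + values[1:])
    return values[:-1]


def accumulate_qalys(trace: MarkovTrace, schedule: UtilitySchedule,
                     settings: ModelSettings) -> QALYBreakdown:
    """Discounted quality-adjusted life-years by state.

    Each cycle contributes ``occupancy * utility(t) * cycle_years``
    discounted at the cycle-start time, with the DFS utility looked up by
    the band containing the cycle-start year.
    """
    t_start = trace.years[:-1]
    df = discount_factor(t_start, settings.annual_discount_rate)
    cy = settings.cycle_years
    u_dfs = schedule.dfs_utility_at(t_start)
    q_dfs = _cycle_occupancy(trace.dfs, settings) * u_dfs * cy * df
    q_ps = _cycle_occupancy(trace.ps, settings) * schedule.ps_utility * cy * df
    return QALYBreakdown(dfs=float(q_dfs.sum()), ps=float(q_ps.sum()),
                         total=float(q_dfs.sum() + q_ps.sum()),
                         per_cycle_dfs=q_dfs, per_cycle_ps=q_ps)
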