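"""Synthetic time-to-event data with known ground truth.

The digitised trial survival curves behind the published model are not
available, so this module generates individual patient data (IPD) from
Weibull survivor functions by inverse transform, with administrative
(type-I) censoring, plus small Kaplan-Meier-style fixture curves pinned
to the trials' printed 3-year landmarks.  Everything here is labelled
SYNTHETIC; none of it is real trial data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .survival import KMDataset, WeibullParams

__all__ = [
    "IPDSample",
    "TrialFixture",
    "simulate_ipd",
    "km_estimate",
    "trial_fixture",
]


@dataclass
class IPDSample:
    """Per-subject observed time (cycles) and event flag (1 = event,
    0 = administratively censored), with the generating truth attached."""

    time: np.ndarray
    event: np.ndarray
    params: WeibullParams
    censor_time: float
    seed: int

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time < 0):
            raise ValueError("times must be nonnegative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return self.time.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_ipd(params: WeibullParams, n: int, admin_censor_time: float,
                 seed: int) -> IPDSample:
    """Draw n event times T = (-ln U / scale)**(1/shape) and censor at
    ``admin_censor_time`` (cycles)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if admin_censor_time <= 0:
        raise ValueError("censoring time must be positive")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / params.scale) ** (1.0 / params.shape)
    observed = np.minimum(t_event, admin_censor_time)
    event = (t_event <= admin_censor_time).astype(int)
    return IPDSample(time=observed, event=event, params=params,
                     censor_time=admin_censor_time, seed=seed)


def km_estimate(ipd: IPDSample) -> KMDataset:
    """Product-limit survivor curve of an IPD sample (steps at event times;
    a terminal step to exactly zero is dropped so the curve stays in (0, 1])."""
    if ipd.event.sum() == 0:
        raise ValueError("no events: the product-limit curve is flat at 1")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, event_observed=ipd.event)
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    # keep t=0 and the points where the curve actually steps down
    drop = np.empty(times.size, dtype=bool)
    drop[0] = False
    drop[1:] = surv[1:] >= surv[:-1] - 1e-15
    keep = ~drop
    keep[0] = True
    keep &= surv > 0.0
    at_risk = kmf.event_table["at_risk"].reindex(times[keep]).to_numpy()
    return KMDataset(times=times[keep], survival=surv[keep],
                     at_risk=at_risk, name="SYNTHETIC-KM")


# Printed 3-year landmarks (PFS, OS) of the two trials' arms.
_LANDMARKS: Dict[str, Tuple[float, float]] = {
    "CLASSIC-SO": (0.59, 0.78),
    "ACTS-SO": (0.596, 0.701),
    "XELOX": (0.74, 0.83),
    "S-1": (0.722, 0.801),
}
_SHAPES = {"pfs": 1.055532, "os": 1.19}


@dataclass(frozen=True)
class TrialFixture:
    """A synthetic pair of summary curves for one trial arm, generated from
    the Weibull family and pinned to the printed 3-year landmarks."""

    arm: str
    label: str
    pfs: KMDataset
    os: KMDataset


def _landmark_curve(s3: float, shape: float, name: str,
                    t3_cycles: float = 26.0) -> KMDataset:
    scale = -math.log(s3) / t3_cycles ** shape
    times = np.arange(0.0, t3_cycles + 1e-9, 2.0)
    surv = np.exp(-scale * times ** shape)
    surv[-1] = s3  # exact at the landmark
    return KMDataset(times=times, survival=surv, name=name)


def trial_fixture(arm: str) -> TrialFixture:
    """Synthetic PFS/OS curves for one of the four trial arms, passing
    exactly through the printed 3-year survival at t = 26 cycles."""
    if arm not in _LANDMARKS:
        raise ValueError(f"unknown arm {arm!r}; expected one of "
                         f"{tuple(_LANDMARKS)}")
    pfs3, os3 = _LANDMARKS[arm]
    label = f"SYNTHETIC-{arm}"
    return TrialFixture(
        arm=arm, label=label,
        pfs=_landmark_curve(pfs3, _SHAPES["pfs"], f"{label}-PFS"),
        os=_landmark_curve(os3, _SHAPES["os"], f"{label}-OS"),
    )
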