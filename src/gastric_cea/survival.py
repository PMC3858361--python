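"""Parametric survivor functions for progression-free and overall survival.

The whole model runs on the survivor convention ``S(t) = exp(-scale * t**shape)``
with time measured in model cycles (6-week periods by default).  A hazard
ratio acts multiplicatively on the scale, which for this family is exactly
equivalent to raising the survivor function to the power HR::

    S_active(t) = S_reference(t) ** HR

Two fitting routes are provided:

* summary curves (Kaplan-Meier style ``(time, survival)`` pairs) are fitted
  by ordinary least squares on the linearised form
  ``log(-log S) = log(scale) + shape * log(t)``;
* individual patient data with right-censoring are fitted by maximum
  likelihood (via :mod:`lifelines` for the Weibull family, closed form for
  the exponential).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "WeibullParams",
    "KMDataset",
    "FitReport",
    "survival_at",
    "adjust_by_hr",
    "fit_weibull",
    "fit_exponential",
    "average_reference",
]


@dataclass(frozen=True)
class WeibullParams:
    """Scale (lambda, per cycle**shape) and shape (gamma) of a Weibull survivor
    function ``S(t) = exp(-scale * t**shape)``.  ``shape == 1`` is the
    exponential special case."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not (self.shape > 0):
            raise ValueError(f"shape must be > 0, got {self.shape}")


def survival_at(params: WeibullParams, t) -> Union[float, np.ndarray]:
    """Survivor probability S(t) = exp(-scale * t**shape) at time ``t`` (cycles).

    ``t`` may be a scalar or array; negative times raise ``ValueError``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    out = np.exp(-params.scale * np.power(t_arr, params.shape))
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def adjust_by_hr(reference: WeibullParams, hr: float) -> WeibullParams:
    """Apply a hazard ratio to a reference curve: ``(scale*hr, shape)``.

    For the Weibull family this is the exact identity
    ``S_adjusted(t) == S_reference(t) ** hr`` for all t.
    """
    if not (hr > 0):
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    return WeibullParams(scale=reference.scale * hr, shape=reference.shape)


@dataclass
class KMDataset:
    """A summary survivor curve: strictly increasing times (cycles) with
    nonincreasing survival probabilities in (0, 1]."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: Optional[np.ndarray] = None
    name: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty curve")
        if self.times.shape != self.survival.shape:
            raise ValueError("times and survival must have equal length")
        if np.any(self.times < 0):
            raise ValueError("times must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.survival <= 0) or np.any(self.survival > 1):
            raise ValueError("survival values must lie in (0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be nonincreasing")
        if self.at_risk is not None:
            self.at_risk = np.asarray(self.at_risk)
            if self.at_risk.shape != self.times.shape:
                raise ValueError("at_risk must match times in length")
            if np.any(self.at_risk <= 0):
                raise ValueError("at_risk counts must be positive")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "survival": self.survival}
        if self.at_risk is not None:
            data["at_risk"] = self.at_risk
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str = "") -> "KMDataset":
        df = pd.read_csv(path)
        at_risk = df["at_risk"].to_numpy() if "at_risk" in df.columns else None
        return cls(df["time"].to_numpy(), df["survival"].to_numpy(),
                   at_risk=at_risk, name=name)


@dataclass(frozen=True)
class FitReport:
    """Result of fitting a parametric survivor function.

    ``aic = 2k - 2*log_likelihood`` and ``bic = k*ln(n) - 2*log_likelihood``
    for the reported ``k_params`` and ``n_obs``.  ``adjusted_r2`` is reported
    only for the linearised least-squares route (``method == "ols"``).
    """

    family: str                     # "weibull" | "exponential"
    params: WeibullParams
    log_likelihood: float
    aic: float
    bic: float
    n_obs: int
    k_params: int
    method: str                     # "ols" | "mle"
    adjusted_r2: Optional[float] = None


def _is_ipd(data) -> bool:
    if isinstance(data, KMDataset):
        return False
    if isinstance(data, pd.DataFrame):
        return True
    return hasattr(data, "time") and hasattr(data, "event")


def _ipd_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        times = data["time"].to_numpy(dtype=float)
        events = data["event"].to_numpy(dtype=int)
    else:
        times = np.asarray(data.time, dtype=float)
        events = np.asarray(data.event, dtype=int)
    if times.size < 10:
        raise ValueError("need at least 10 observations for IPD fitting")
    if events.sum() == 0:
        raise ValueError("all observations are censored; "
                         "the survivor function cannot be identified")
    return times, events


def _linearize(km: KMDataset) -> tuple[np.ndarray, np.ndarray]:
    """Points for the log(-log S) vs log t regression; drops t == 0 and S == 1."""
    mask = (km.times > 0) & (km.survival < 1.0)
    if np.count_nonzero(mask) < 3:
        raise ValueError(
            "need at least 3 time points with survival < 1 for curve fitting "
            "(a curve at 1 everywhere carries no event information)")
    x = np.log(km.times[mask])
    y = np.log(-np.log(km.survival[mask]))
    return x, y


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = resid.size
    sigma2 = float(np.sum(resid ** 2)) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def _report(family: str, params: WeibullParams, ll: float, n: int, k: int,
            method: str, adj_r2: Optional[float] = None) -> FitReport:
    return FitReport(
        family=family, params=params, log_likelihood=ll,
        aic=2 * k - 2 * ll, bic=k * math.log(n) - 2 * ll,
        n_obs=n, k_params=k, method=method, adjusted_r2=adj_r2)


def fit_weibull(data) -> FitReport:
    """Fit a Weibull survivor function.

    Summary curves use OLS on the linearised form (slope = shape,
    exp(intercept) = scale); IPD uses right-censored maximum likelihood.
    """
    if _is_ipd(data):
        times, events = _ipd_arrays(data)
        from lifelines import WeibullFitter

        wf = WeibullFitter()
        wf.fit(times, event_observed=events)
        # lifelines parameterises S(t) = exp(-(t/lambda_)**rho_)
        shape = float(wf.rho_)
        scale = float(wf.lambda_) ** (-shape)
        ll = float(wf.log_likelihood_)
        return _report("weibull", WeibullParams(scale, shape), ll,
                       n=times.size, k=2, method="mle")

    x, y = _linearize(data)
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    ll = _gaussian_loglik(resid)
    params = WeibullParams(scale=float(np.exp(intercept)), shape=float(slope))
    return _report("weibull", params, ll, n=n, k=2, method="ols",
                   adj_r2=adj_r2)


def fit_exponential(data) -> FitReport:
    """Fit an exponential survivor function (Weibull with shape fixed to 1)."""
    if _is_ipd(data):
        times, events = _ipd_arrays(data)
        d = int(events.sum())
        total_time = float(times.sum())
        rate = d / total_time
        ll = d * math.log(rate) - rate * total_time
        return _report("exponential", WeibullParams(rate, 1.0), ll,
                       n=times.size, k=1, method="mle")

    x, y = _linearize(data)
    n = x.size
    # slope fixed to 1: intercept-only regression of y - x
    intercept = float(np.mean(y - x))
    resid = y - (x + intercept)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else 1.0
    ll = _gaussian_loglik(resid)
    params = WeibullParams(scale=float(np.exp(intercept)), shape=1.0)
    return _report("exponential", params, ll, n=n, k=1, method="ols",
                   adj_r2=r2)


def average_reference(km_a: KMDataset, km_b: KMDataset,
                      n_a: int, n_b: int) -> KMDataset:
    """Patient-count-weighted average of two survivor curves.

    Curves are linearly interpolated in survival probability onto the union
    of their time grids, restricted to the overlapping time range.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("patient counts must be positive")
    lo = max(km_a.times.min(), km_b.times.min())
    hi = min(km_a.times.max(), km_b.times.max())
    if hi < lo:
        raise ValueError("curves do not overlap in time")
    grid = np.union1d(km_a.times, km_b.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    w_a = n_a / (n_a + n_b)
    s = (w_a * np.interp(grid, km_a.times, km_a.survival)
         + (1.0 - w_a) * np.interp(grid, km_b.times, km_b.survival))
    # weighted average of nonincreasing curves is nonincreasing; the
    # accumulate guards against floating-point wiggle only
    s = np.minimum.accumulate(s)
    return KMDataset(times=grid, survival=s,
                     name=f"average({km_a.name},{km_b.name})")
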