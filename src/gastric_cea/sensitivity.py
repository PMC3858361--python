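"""Deterministic and probabilistic sensitivity analysis.

Each uncertain input is a median with a plausible range.  For sampling,
the range is read as a 95% interval: sd = (high - low)/3.92 on the natural
scale (log scale for the lognormal, where the median fixes mu).  Gamma and
beta distributions are parameterised by mean-sd moment matching with the
median standing in for the mean.  Draws are confined to the family's
support, never clipped to the quoted range.  This median-plus-range to
distribution mapping is the single largest judgement call in the PSA and
is documented in the methods note.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .economics import nmb

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PSAResult",
    "Ellipse",
    "sample_param",
    "one_way",
    "run_psa",
    "ce_probability",
    "ceac",
    "confidence_ellipse",
]

_FAMILIES = ("lognormal", "gamma", "beta", "fixed")

# Totals for every strategy, given a full mapping of parameter values.
ModelFn = Callable[[Mapping[str, float]], Dict[str, Tuple[float, float]]]


@dataclass(frozen=True)
class ParamSpec:
    """An uncertain model input: median, range, distribution family and the
    name of the model parameter it drives."""

    name: str
    median: float
    low: float
    high: float
    distribution: str
    target: Optional[str] = None  # defaults to ``name``

    def __post_init__(self) -> None:
        if self.distribution not in _FAMILIES:
            raise ValueError(f"unknown distribution {self.distribution!r}; "
                             f"expected one of {_FAMILIES}")
        if not (self.low <= self.median <= self.high):
            raise ValueError(
                f"{self.name}: require low <= median <= high, got "
                f"{self.low}, {self.median}, {self.high}")
        if self.distribution == "beta":
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValueError(f"{self.name}: beta bounds must lie in [0, 1]")
        if self.distribution == "lognormal" and self.low <= 0:
            raise ValueError(f"{self.name}: lognormal needs positive bounds")
        if self.target is None:
            object.__setattr__(self, "target", self.name)


def sample_param(spec: ParamSpec, rng: np.random.Generator) -> float:
    """One draw from the moment-matched family of ``spec``."""
    if spec.distribution == "fixed" or spec.low == spec.high:
        return spec.median
    if spec.distribution == "lognormal":
        sigma = (math.log(spec.high) - math.log(spec.low)) / 3.92
        return float(rng.lognormal(mean=math.log(spec.median), sigma=sigma))
    sd = (spec.high - spec.low) / 3.92
    m = spec.median
    if spec.distribution == "gamma":
        shape = (m / sd) ** 2
        scale = sd ** 2 / m
        return float(rng.gamma(shape, scale))
    # beta
    var = sd ** 2
    if var >= m * (1.0 - m) or m <= 0.0 or m >= 1.0:
        warnings.warn(
            f"{spec.name}: infeasible beta moments (mean {m}, sd {sd}); "
            "falling back to uniform(low, high)", RuntimeWarning, stacklevel=2)
        return float(rng.uniform(spec.low, spec.high))
    common = m * (1.0 - m) / var - 1.0
    return float(rng.beta(m * common, (1.0 - m) * common))


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _raw_icer(totals: Dict[str, Tuple[float, float]],
              reference: str, comparator: str) -> float:
    c1, e1 = totals[reference]
    c2, e2 = totals[comparator]
    return (c2 - c1) / (e2 - e1)


def one_way(specs: Sequence[ParamSpec], model_fn: ModelFn,
            pair: Tuple[str, str],
            base_values: Mapping[str, float]) -> List[TornadoEntry]:
    """Tornado analysis: for every parameter, re-run the full model at its
    low and high end with all others held at their base value, and record
    the raw incremental ratio for ``pair = (reference, comparator)``.
    Entries are sorted by descending spread (ties by name)."""
    reference, comparator = pair
    entries = []
    for spec in specs:
        vals_low = dict(base_values)
        vals_low[spec.target] = spec.low
        vals_high = dict(base_values)
        vals_high[spec.target] = spec.high
        icer_low = _raw_icer(model_fn(vals_low), reference, comparator)
        icer_high = _raw_icer(model_fn(vals_high), reference, comparator)
        entries.append(TornadoEntry(spec.name, spec.low, spec.high,
                                    icer_low, icer_high))
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter, "low": e.low, "high": e.high,
        "icer_at_low": e.icer_at_low, "icer_at_high": e.icer_at_high,
        "spread": e.spread,
    } for e in entries])


@dataclass
class PSAResult:
    """Monte Carlo replicates: sampled parameters and per-strategy totals."""

    strategies: Tuple[str, ...]
    param_names: Tuple[str, ...]
    costs: np.ndarray   # (n, n_strategies)
    qalys: np.ndarray   # (n, n_strategies)
    params: np.ndarray  # (n, n_params)
    seed: int
    n_replicates: int

    def strategy_index(self, name: str) -> int:
        return self.strategies.index(name)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for j, s in enumerate(self.strategies):
            frames.append(pd.DataFrame({
                "replicate": np.arange(self.n_replicates),
                "strategy": s,
                "cost": self.costs[:, j],
                "qaly": self.qalys[:, j],
            }))
        return pd.concat(frames, ignore_index=True)

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.params, columns=list(self.param_names))


def run_psa(n: int, seed: int, specs: Sequence[ParamSpec], model_fn: ModelFn,
            base_values: Optional[Mapping[str, float]] = None,
            strategies: Sequence[str] = ("SO", "XELOX", "S-1")) -> PSAResult:
    """n Monte Carlo replicates; replicate i draws from a generator seeded
    with (seed, i), so results are reproducible and order-independent."""
    if n < 1:
        raise ValueError("need at least one replicate")
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    strategies = tuple(strategies)
    costs = np.empty((n, len(strategies)))
    qalys = np.empty((n, len(strategies)))
    params = np.empty((n, len(specs)))
    for i in range(n):
        rng = np.random.default_rng([int(seed), i])
        values = dict(base_values) if base_values else {}
        for j, spec in enumerate(specs):
            v = sample_param(spec, rng)
            params[i, j] = v
            values[spec.target] = v
        totals = model_fn(values)
        for k, s in enumerate(strategies):
            costs[i, k], qalys[i, k] = totals[s]
    return PSAResult(strategies=strategies,
                     param_names=tuple(s.name for s in specs),
                     costs=costs, qalys=qalys, params=params,
                     seed=int(seed), n_replicates=n)


def ce_probability(psa: PSAResult, pair: Tuple[str, str], wtp: float) -> float:
    """Fraction of replicates in which the first strategy of ``pair`` has the
    higher net monetary benefit at ``wtp``."""
    if psa.n_replicates < 1:
        raise ValueError("empty PSA")
    a = psa.strategy_index(pair[0])
    b = psa.strategy_index(pair[1])
    nmb_a = wtp * psa.qalys[:, a] - psa.costs[:, a]
    nmb_b = wtp * psa.qalys[:, b] - psa.costs[:, b]
    return float(np.mean(nmb_a > nmb_b))


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves: at each threshold, the
    fraction of replicates in which each strategy attains the maximum net
    monetary benefit.  Ties go to the earlier strategy in ``psa.strategies``
    (the fixed SO < XELOX < S-1 order by default), so fractions sum to 1."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    rows = []
    for w in wtp_grid:
        nmb_mat = w * psa.qalys - psa.costs
        winner = np.argmax(nmb_mat, axis=1)  # first max wins ties
        row = {"wtp": w}
        for k, s in enumerate(psa.strategies):
            row[f"p_{s}"] = float(np.mean(winner == k))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Ellipse:
    """A bivariate-normal confidence ellipse: centre, semi-axes at the
    chi-square(2) quantile, and rotation of the major axis (degrees)."""

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]
    angle_deg: float
    level: float
    _cov_inv: np.ndarray = field(repr=False, default=None)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts - np.asarray(self.center)
        m2 = np.einsum("ij,jk,ik->i", d, self._cov_inv, d)
        return m2 <= stats.chi2.ppf(self.level, df=2)


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> Ellipse:
    """Ellipse from the sample mean and covariance of (x, y) pairs covering
    ``level`` of a bivariate normal with those moments."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or det <= 1e-300:
        raise ValueError("singular covariance: points are degenerate")
    evals, evecs = np.linalg.eigh(cov)
    q = stats.chi2.ppf(level, df=2)
    # eigh returns ascending eigenvalues; report major axis first
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = tuple(float(math.sqrt(q * ev)) for ev in evals)
    angle = math.degrees(math.atan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=(float(mean[0]), float(mean[1])),
                   semi_axes=semi, angle_deg=angle, level=level,
                   _cov_inv=np.linalg.inv(cov))
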