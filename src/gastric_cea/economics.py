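"""Cost-effectiveness ratios, dominance and the efficiency frontier.

ICERs are always computed on unrounded model totals.  Negative ratios are
never reported as numbers: when one strategy is both cheaper and more
effective the comparison is labelled ``dominant``/``dominated`` instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import pandas as pd

__all__ = [
    "cer",
    "icer",
    "nmb",
    "frontier",
    "FrontierPoint",
    "FrontierResult",
    "CEResult",
    "compare",
]

ICERValue = Union[float, str]


def cer(cost: float, qaly: float) -> float:
    """Average cost-effectiveness ratio: total cost per total QALY."""
    if qaly <= 0:
        raise ValueError("QALYs must be positive for a CER")
    return cost / qaly


def icer(c1: float, e1: float, c2: float, e2: float) -> ICERValue:
    """ICER of strategy 2 versus strategy 1 on unrounded totals.

    Returns ``(c2-c1)/(e2-e1)`` when both increments share a sign that
    yields a meaningful ratio; otherwise a dominance label from strategy
    2's point of view: ``"dominant"`` (cheaper, at least as effective),
    ``"dominated"`` (costlier, at most as effective) or ``"equivalent"``.
    """
    dc = c2 - c1
    de = e2 - e1
    if de > 0 and dc <= 0:
        return "dominant"
    if de < 0 and dc >= 0:
        return "dominated"
    if de == 0:
        if dc > 0:
            return "dominated"
        if dc < 0:
            return "dominant"
        return "equivalent"
    return dc / de


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    return wtp * qaly - cost


@dataclass(frozen=True)
class FrontierPoint:
    name: str
    cost: float
    qaly: float
    icer_vs_previous: Union[float, None]  # None for the cheapest frontier point


@dataclass(frozen=True)
class FrontierResult:
    frontier: Tuple[FrontierPoint, ...]
    dominated: Mapping[str, str]  # name -> "strict" | "extended" | "duplicate"

    @property
    def frontier_names(self) -> Tuple[str, ...]:
        return tuple(p.name for p in self.frontier)


def frontier(strategies: Sequence[Tuple[str, float, float]]) -> FrontierResult:
    """Efficiency frontier over (name, cost, qaly) triples.

    Strictly dominated strategies (another has <= cost and >= QALY with at
    least one strict) are removed first, then extendedly dominated ones
    (those whose removal keeps frontier ICERs strictly increasing).  Exact
    duplicates keep the lexicographically first name.  Output is invariant
    to input order.
    """
    if len(strategies) < 1:
        raise ValueError("need at least one strategy")
    items = sorted(strategies, key=lambda s: (s[2], s[1], s[0]))
    dominated: Dict[str, str] = {}

    # exact duplicates: keep the name-first one
    seen: Dict[Tuple[float, float], str] = {}
    kept = []
    for name, c, e in items:
        key = (c, e)
        if key in seen:
            dominated[name] = "duplicate"
        else:
            seen[key] = name
            kept.append((name, c, e))

    def strictly_dominated(s, others) -> bool:
        _, c, e = s
        return any(oc <= c and oe >= e and (oc < c or oe > e)
                   for _, oc, oe in others)

    surviving = []
    for s in kept:
        others = [o for o in kept if o is not s]
        if strictly_dominated(s, others):
            dominated[s[0]] = "strict"
        else:
            surviving.append(s)

    # extended dominance: walk by increasing effectiveness keeping ICERs
    # strictly increasing; equal ICERs (collinear strategies) are kept
    stack: List[Tuple[str, float, float]] = []
    for s in surviving:
        stack.append(s)
        while len(stack) >= 3:
            (n0, c0, e0), (n1, c1, e1), (n2, c2, e2) = stack[-3:]
            icer_01 = (c1 - c0) / (e1 - e0)
            icer_12 = (c2 - c1) / (e2 - e1)
            if icer_12 < icer_01:
                dominated[n1] = "extended"
                stack.pop(-2)
            else:
                break

    points = []
    for i, (name, c, e) in enumerate(stack):
        if i == 0:
            points.append(FrontierPoint(name, c, e, None))
        else:
            _, pc, pe = stack[i - 1]
            points.append(FrontierPoint(name, c, e, (c - pc) / (e - pe)))
    return FrontierResult(frontier=tuple(points), dominated=dominated)


@dataclass(frozen=True)
class CEResult:
    """Per-strategy totals with the pairwise comparisons and the frontier."""

    totals: Mapping[str, Tuple[float, float]]  # name -> (cost, qaly)
    order: Tuple[str, ...]

    @property
    def frontier_result(self) -> FrontierResult:
        return frontier([(n, *self.totals[n]) for n in self.order])

    def cer(self, name: str) -> float:
        c, e = self.totals[name]
        return cer(c, e)

    def icer(self, reference: str, comparator: str) -> ICERValue:
        c1, e1 = self.totals[reference]
        c2, e2 = self.totals[comparator]
        return icer(c1, e1, c2, e2)

    def nmb(self, name: str, wtp: float) -> float:
        c, e = self.totals[name]
        return nmb(c, e, wtp)

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for n in self.order:
            c, e = self.totals[n]
            rows[n] = {"cost_total": c, "qaly_total": e, "cer": cer(c, e)}
        return pd.DataFrame(rows)


def compare(totals: Mapping[str, Tuple[float, float]],
            order: Sequence[str] = ("SO", "XELOX", "S-1")) -> CEResult:
    order = tuple(n for n in order if n in totals)
    missing = set(totals) - set(order)
    order = order + tuple(sorted(missing))
    return CEResult(totals=dict(totals), order=order)
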