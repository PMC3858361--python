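"""Per-cycle costs in the DFS and PS states, 2010 USD, Chinese payer view.

Drug acquisition rounds doses up to whole dispensing units (no vial or
tablet sharing) at a fixed body surface area.  Adjuvant drug costs accrue
while a model cycle overlaps the treatment window (XELOX: eight 3-week
regimen cycles = 24 weeks; S-1: one year of 6-week regimen cycles, with
the fractional last model cycle prorated).  Expected adverse-event costs
(sum of risk x cost over grade 3-4 events) are charged once in the first
cycle by default.  Surveillance imaging and laboratory work are charged to
DFS occupants on the schedule of the originating trial.  Progressed
patients receive second-line weekly paclitaxel (a 25% fraction) or
supportive care (the remainder), identical across strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .markov import MarkovTrace, ModelSettings, discount_factor

__all__ = [
    "DrugSpec",
    "AEProfile",
    "FollowupItem",
    "CostInputs",
    "CostBreakdown",
    "drug_units",
    "dfs_cycle_cost",
    "ps_cycle_cost",
    "accumulate_costs",
    "followup_events",
    "STRATEGIES",
]

STRATEGIES = ("SO", "XELOX", "S-1")


@dataclass(frozen=True)
class DrugSpec:
    """One drug within a regimen: dosing per administration, dispensing unit,
    administrations per regimen cycle and the total treatment window."""

    name: str
    price_key: str                    # key into CostInputs.drug_prices
    dose_per_m2: float                # mg per administration
    unit_size_mg: float               # mg per tablet/capsule/vial
    administrations_per_cycle: int    # per regimen cycle
    regimen_cycle_weeks: float
    treatment_weeks: float            # total duration of the regimen
    intravenous: bool = False         # infusion fee charged per administration

    def __post_init__(self) -> None:
        for f in ("dose_per_m2", "unit_size_mg", "regimen_cycle_weeks",
                  "treatment_weeks"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.administrations_per_cycle <= 0:
            raise ValueError("administrations_per_cycle must be positive")


# Regimens as run in the originating trials: XELOX = oral capecitabine
# 1000 mg/m2 twice daily days 1-14 (28 administrations) plus oxaliplatin
# 130 mg/m2 IV day 1 of each 3-week cycle, for 8 cycles; S-1 = oral
# 40 mg/m2 twice daily days 1-28 (56 administrations) of each 6-week
# cycle, for 1 year.
REGIMENS: Dict[str, Tuple[DrugSpec, ...]] = {
    "SO": (),
    "XELOX": (
        DrugSpec("capecitabine", "capecitabine_per_500mg", 1000.0, 500.0,
                 28, 3.0, 24.0, intravenous=False),
        DrugSpec("oxaliplatin", "oxaliplatin_per_50mg", 130.0, 50.0,
                 1, 3.0, 24.0, intravenous=True),
    ),
    "S-1": (
        DrugSpec("s1", "s1_per_20mg", 40.0, 20.0,
                 56, 6.0, 52.0, intravenous=False),
    ),
}


@dataclass(frozen=True)
class AEProfile:
    """Grade 3-4 adverse events: (name, risk, cost-key) triples; the expected
    cost is the risk-weighted sum of per-episode costs."""

    events: Tuple[Tuple[str, float, str], ...]

    def __post_init__(self) -> None:
        for name, risk, _ in self.events:
            if not (0.0 <= risk <= 1.0):
                raise ValueError(f"AE risk for {name} outside [0, 1]: {risk}")

    def expected_cost(self, ae_costs: Mapping[str, float]) -> float:
        return float(sum(risk * ae_costs[key] for _, risk, key in self.events))


@dataclass(frozen=True)
class FollowupItem:
    """A surveillance procedure with piecewise-constant frequency:
    ``intervals`` maps (start_year, end_year) to the gap in years between
    consecutive episodes."""

    name: str
    cost_key: str
    intervals: Tuple[Tuple[float, float, float], ...]  # (start, end, gap_years)

    def event_times(self, horizon_years: float) -> np.ndarray:
        times: List[float] = []
        for start, end, gap in self.intervals:
            if gap <= 0:
                raise ValueError("followup gap must be positive")
            t = start + gap
            stop = min(end, horizon_years)
            while t <= stop + 1e-9:
                times.append(t)
                t += gap
        return np.array(sorted(times))


# Surveillance per the trial protocols.  XELOX: abdominal MRI or CT every
# 6 months in years 1-3 then yearly; chest radiograph every 3 months in
# years 1-2, every 6 months in year 3, then yearly.  S-1: abdominal CT
# every 6 months in years 1-2 then yearly; laboratory evaluations every
# 2 months in the first year.  SO cohorts were surveilled like their trial
# counterparts; the S-1 (ACTS-GC style) schedule is used for SO.
FOLLOWUP: Dict[str, Tuple[FollowupItem, ...]] = {
    "XELOX": (
        FollowupItem("abdominal imaging", "imaging_xelox",
                     ((0.0, 3.0, 0.5), (3.0, math.inf, 1.0))),
        FollowupItem("chest radiograph", "chest_radiograph_per_episode",
                     ((0.0, 2.0, 0.25), (2.0, 3.0, 0.5), (3.0, math.inf, 1.0))),
    ),
    "S-1": (
        FollowupItem("abdominal CT", "abdominal_ct_per_episode",
                     ((0.0, 2.0, 0.5), (2.0, math.inf, 1.0))),
        FollowupItem("laboratory evaluations", "laboratory_evaluations_per_episode",
                     ((0.0, 1.0, 1.0 / 6.0),)),
    ),
}
FOLLOWUP["SO"] = FOLLOWUP["S-1"]


@dataclass(frozen=True)
class CostInputs:
    """All unit prices, risks and fractions feeding the cost model."""

    bsa: float = 1.72  # m2; calibrated to the reported DFS drug-cost level
    drug_prices: Mapping[str, float] = field(default_factory=lambda: {
        "capecitabine_per_500mg": 6.3,
        "oxaliplatin_per_50mg": 232.8,
        "paclitaxel_per_30mg": 115.4,
        "s1_per_20mg": 8.6,
    })
    administration_per_episode: float = 18.5
    supportive_care_per_3wk: float = 1415.4
    procedure_costs: Mapping[str, float] = field(default_factory=lambda: {
        "laboratory_evaluations_per_episode": 87.6,
        "abdominal_ct_per_episode": 105.2,
        "abdominal_mri_per_episode": 140.8,
        "chest_radiograph_per_episode": 8.4,
    })
    ae_costs: Mapping[str, float] = field(default_factory=lambda: {
        "nausea_vomiting_per_episode": 39.6,
        "neutropenia_per_episode": 530.8,
        "appetite_fatigue_per_episode": 115.4,
        "diarrhoea_pain_per_episode": 44.3,
        "thrombocytopenia_per_episode": 3551.7,
    })
    ae_profiles: Mapping[str, AEProfile] = field(default_factory=lambda: {
        "SO": AEProfile(()),
        "XELOX": AEProfile((
            ("nausea and vomiting", 0.15, "nausea_vomiting_per_episode"),
            ("neutropenia", 0.22, "neutropenia_per_episode"),
            ("decreased appetite/fatigue/asthenia", 0.12,
             "appetite_fatigue_per_episode"),
            ("diarrhoea and abdominal pain", 0.04, "diarrhoea_pain_per_episode"),
            ("thrombocytopenia", 0.08, "thrombocytopenia_per_episode"),
        )),
        "S-1": AEProfile((
            ("nausea", 0.037, "nausea_vomiting_per_episode"),
            ("diarrhoea", 0.031, "diarrhoea_pain_per_episode"),
            ("anorexia", 0.06, "appetite_fatigue_per_episode"),
        )),
    })
    second_line_fraction: float = 0.25
    paclitaxel_dose_per_m2: float = 80.0
    paclitaxel_infusions_per_4wk: int = 3
    amortize_ae: bool = False  # spread AE cost over the treatment window

    def __post_init__(self) -> None:
        if self.bsa <= 0:
            raise ValueError("body surface area must be positive")
        if not (0.0 <= self.second_line_fraction <= 1.0):
            raise ValueError("second_line_fraction outside [0, 1]")
        for mapping in (self.drug_prices, self.procedure_costs, self.ae_costs):
            for key, v in mapping.items():
                if v < 0:
                    raise ValueError(f"negative cost for {key}")

    def procedure_cost(self, key: str) -> float:
        # The XELOX protocol images with "MRI or CT" without proportions;
        # the mean of the two unit prices is used.
        if key == "imaging_xelox":
            return 0.5 * (self.procedure_costs["abdominal_ct_per_episode"]
                          + self.procedure_costs["abdominal_mri_per_episode"])
        return self.procedure_costs[key]


def drug_units(dose_per_m2: float, bsa: float, unit_size: float) -> int:
    """Whole dispensing units per administration: ceil(dose*bsa/unit_size)."""
    if unit_size <= 0:
        raise ValueError("unit size must be positive")
    if dose_per_m2 <= 0 or bsa <= 0:
        raise ValueError("dose and BSA must be positive")
    # guard against float droop on exact multiples (e.g. 1000*1.5/500)
    ratio = dose_per_m2 * bsa / unit_size
    return int(math.ceil(ratio - 1e-9))


def _drug_weekly_cost(drug: DrugSpec, inputs: CostInputs) -> float:
    units = drug_units(drug.dose_per_m2, inputs.bsa, drug.unit_size_mg)
    per_admin = units * inputs.drug_prices[drug.price_key]
    if drug.intravenous:
        per_admin += inputs.administration_per_episode
    return per_admin * drug.administrations_per_cycle / drug.regimen_cycle_weeks


def followup_events(strategy: str, inputs: CostInputs,
                    horizon_years: float) -> List[Tuple[float, float]]:
    """(year, cost) pairs for every surveillance episode within the horizon."""
    if strategy not in FOLLOWUP:
        raise ValueError(f"unknown strategy {strategy!r}")
    events: List[Tuple[float, float]] = []
    for item in FOLLOWUP[strategy]:
        cost = inputs.procedure_cost(item.cost_key)
        for t in item.event_times(horizon_years):
            events.append((float(t), cost))
    return sorted(events)


def _ae_cost_vector(strategy: str, inputs: CostInputs,
                    settings: ModelSettings, n: int) -> np.ndarray:
    expected = inputs.ae_profiles[strategy].expected_cost(inputs.ae_costs)
    out = np.zeros(n)
    if expected == 0.0:
        return out
    if inputs.amortize_ae:
        weeks = max(d.treatment_weeks for d in REGIMENS[strategy])
        n_treat = max(1, int(math.ceil(weeks / settings.cycle_length_weeks)))
        out[:min(n_treat, n)] = expected / n_treat
    else:
        out[0] = expected
    return out


def _dfs_cost_vector(strategy: str, inputs: CostInputs,
                     settings: ModelSettings) -> np.ndarray:
    """Cost per DFS occupant for each model cycle (length n_cycles)."""
    if strategy not in REGIMENS:
        raise ValueError(f"unknown strategy {strategy!r}; "
                         f"expected one of {STRATEGIES}")
    n = settings.n_cycles
    cw = settings.cycle_length_weeks
    cost = np.zeros(n)
    for drug in REGIMENS[strategy]:
        weekly = _drug_weekly_cost(drug, inputs)
        starts = np.arange(n) * cw
        overlap = np.clip(drug.treatment_weeks - starts, 0.0, cw)
        cost += weekly * overlap
    cost += _ae_cost_vector(strategy, inputs, settings, n)
    cy = settings.cycle_years
    for t, c in followup_events(strategy, inputs, settings.horizon_years):
        idx = min(int(math.ceil(t / cy - 1e-9)) - 1, n - 1)
        cost[max(idx, 0)] += c
    return cost


def dfs_cycle_cost(strategy: str, cycle_index: int, inputs: CostInputs,
                   settings: ModelSettings) -> float:
    """Cost per DFS occupant in one model cycle: drug acquisition and
    administration within the treatment window, expected adverse-event cost
    (cycle 0 by default) and surveillance episodes falling in the cycle."""
    vec = _dfs_cost_vector(strategy, inputs, settings)
    if not (0 <= cycle_index < vec.size):
        raise ValueError("cycle_index outside the model horizon")
    return float(vec[cycle_index])


def ps_cycle_cost(inputs: CostInputs, settings: ModelSettings) -> float:
    """Cost per progressed-state occupant per model cycle, identical across
    strategies: a 25% fraction on weekly paclitaxel (3 infusions per 4-week
    regimen cycle, time-scaled to the model cycle), the rest on supportive
    care priced per 3 weeks."""
    cw = settings.cycle_length_weeks
    units = drug_units(inputs.paclitaxel_dose_per_m2, inputs.bsa, 30.0)
    per_infusion = (units * inputs.drug_prices["paclitaxel_per_30mg"]
                    + inputs.administration_per_episode)
    second_line_weekly = inputs.paclitaxel_infusions_per_4wk * per_infusion / 4.0
    supportive_weekly = inputs.supportive_care_per_3wk / 3.0
    f = inputs.second_line_fraction
    return cw * (f * second_line_weekly + (1.0 - f) * supportive_weekly)


@dataclass(frozen=True)
class CostBreakdown:
    dfs: float
    ps: float
    total: float
    per_cycle_dfs: np.ndarray = field(repr=False, default=None)
    per_cycle_ps: np.ndarray = field(repr=False, default=None)


def accumulate_costs(trace: MarkovTrace, strategy: str, inputs: CostInputs,
                     settings: ModelSettings) -> CostBreakdown:
    """Discounted lifetime cost by state: cycle-start occupancy times the
    per-occupant cycle cost, discounted at the cycle-start time."""
    from .markov import _cycle_occupancy

    df = discount_factor(trace.years[:-1], settings.annual_discount_rate)
    dfs_occ = _cycle_occupancy(trace.dfs, settings)
    ps_occ = _cycle_occupancy(trace.ps, settings)
    c_dfs = _dfs_cost_vector(strategy, inputs, settings) * dfs_occ * df
    c_ps = ps_cycle_cost(inputs, settings) * ps_occ * df
    return CostBreakdown(dfs=float(c_dfs.sum()), ps=float(c_ps.sum()),
                         total=float(c_dfs.sum() + c_ps.sum()),
                         per_cycle_dfs=c_dfs, per_cycle_ps=c_ps)
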