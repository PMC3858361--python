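"""Analysis configuration: YAML loading, validation and model assembly.

The shipped default configuration encodes the published input tables
(survival parameters, unit costs, adverse-event risks, utilities) and is
the base case.  ``make_model_fn`` turns a configuration into a callable
mapping a parameter-value dictionary to per-strategy (cost, QALY) totals;
the survival curves are fixed, so traces are built once and reused across
sensitivity-analysis replicates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .costs import AEProfile, CostInputs, accumulate_costs
from .markov import (MarkovTrace, ModelSettings, UtilitySchedule,
                     accumulate_qalys, build_trace)
from .sensitivity import ParamSpec
from .survival import WeibullParams, adjust_by_hr

__all__ = [
    "AnalysisConfig",
    "PSASettings",
    "ConfigError",
    "load_config",
    "load_default_config",
    "dump_config",
    "config_hash",
    "strategy_curves",
    "base_values",
    "build_cost_inputs",
    "build_utility_schedules",
    "make_model_fn",
]

STRATEGY_ORDER = ("SO", "XELOX", "S-1")


class ConfigError(ValueError):
    """A configuration file violated the schema."""


@dataclass(frozen=True)
class PSASettings:
    n_replicates: int = 1000
    seed: int = 12345
    wtp_grid: Tuple[float, ...] = tuple(float(w) for w in range(0, 100001, 2000))

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("psa.n_replicates must be >= 1")


@dataclass(frozen=True)
class AnalysisConfig:
    settings: ModelSettings
    wtp_threshold: float
    bsa: float
    reference: Mapping[str, WeibullParams]          # {"pfs": .., "os": ..}
    hazard_ratios: Mapping[str, Mapping[str, float]]
    parameters: Tuple[ParamSpec, ...]
    one_way_extra: Tuple[ParamSpec, ...]
    psa: PSASettings

    @property
    def strategies(self) -> Tuple[str, ...]:
        return STRATEGY_ORDER

    def to_dict(self) -> dict:
        def spec_dict(s: ParamSpec) -> dict:
            return {"name": s.name, "target": s.target, "median": s.median,
                    "low": s.low, "high": s.high,
                    "distribution": s.distribution}

        grid = self.psa.wtp_grid
        return {
            "settings": dataclasses.asdict(self.settings),
            "wtp_threshold": self.wtp_threshold,
            "bsa_m2": self.bsa,
            "survival": {
                "reference": {k: {"scale": p.scale, "shape": p.shape}
                              for k, p in self.reference.items()},
                "hazard_ratios": {k: dict(v)
                                  for k, v in self.hazard_ratios.items()},
            },
            "psa": {"n_replicates": self.psa.n_replicates,
                    "seed": self.psa.seed,
                    "wtp_grid": {"start": grid[0], "stop": grid[-1],
                                 "step": grid[1] - grid[0] if len(grid) > 1
                                 else 1.0}},
            "parameters": [spec_dict(s) for s in self.parameters],
            "one_way_extra": [spec_dict(s) for s in self.one_way_extra],
        }


_TOP_KEYS = {"settings", "wtp_threshold", "bsa_m2", "survival", "psa",
             "parameters", "one_way_extra"}
_SETTINGS_KEYS = {"cycle_length_weeks", "weeks_per_year", "horizon_years",
                  "annual_discount_rate", "half_cycle_correction"}
_PARAM_KEYS = {"name", "target", "median", "low", "high", "distribution"}

# every target a parameter row may drive
VALID_TARGETS = frozenset({
    "cost_capecitabine", "cost_oxaliplatin", "cost_paclitaxel", "cost_s1",
    "cost_lab_eval", "cost_administration", "cost_supportive_care",
    "cost_abdominal_ct", "cost_abdominal_mri", "cost_chest_radiograph",
    "cost_ae_nausea_vomiting", "cost_ae_neutropenia",
    "cost_ae_appetite_fatigue", "cost_ae_diarrhoea_pain",
    "cost_ae_thrombocytopenia",
    "risk_xelox_nausea_vomiting", "risk_xelox_neutropenia",
    "risk_xelox_appetite_fatigue", "risk_xelox_diarrhoea_pain",
    "risk_xelox_thrombocytopenia",
    "risk_s1_nausea", "risk_s1_diarrhoea", "risk_s1_anorexia",
    "risk_second_line",
    "utility_dfs_xelox_y0_5", "utility_dfs_xelox_y5_10",
    "utility_dfs_s1", "utility_dfs_so", "utility_ps",
    "discount_rate",
})


def _reject_unknown(mapping: Mapping, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _parse_specs(rows, where: str) -> Tuple[ParamSpec, ...]:
    specs = []
    for i, row in enumerate(rows or []):
        _reject_unknown(row, _PARAM_KEYS, f"{where}[{i}]")
        for req in ("name", "median", "low", "high", "distribution"):
            if req not in row:
                raise ConfigError(f"{where}[{i}]: missing field {req!r}")
        try:
            spec = ParamSpec(name=row["name"], median=float(row["median"]),
                             low=float(row["low"]), high=float(row["high"]),
                             distribution=row["distribution"],
                             target=row.get("target"))
        except ValueError as exc:
            raise ConfigError(f"{where}[{i}] ({row.get('name')}): {exc}") from exc
        if spec.target not in VALID_TARGETS:
            raise ConfigError(
                f"{where}[{i}]: target {spec.target!r} does not resolve to "
                "a model parameter")
        specs.append(spec)
    return tuple(specs)


def _parse(raw: Mapping) -> AnalysisConfig:
    if not isinstance(raw, Mapping):
        raise ConfigError("top level of the config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")

    s = raw.get("settings", {})
    _reject_unknown(s, _SETTINGS_KEYS, "settings")
    try:
        settings = ModelSettings(**s)
    except ValueError as exc:
        raise ConfigError(f"settings: {exc}") from exc

    surv = raw.get("survival", {})
    _reject_unknown(surv, {"reference", "hazard_ratios"}, "survival")
    try:
        reference = {k: WeibullParams(**v)
                     for k, v in surv.get("reference", {}).items()}
        hrs = {arm: {k: float(v) for k, v in d.items()}
               for arm, d in surv.get("hazard_ratios", {}).items()}
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"survival: {exc}") from exc
    for curve in ("pfs", "os"):
        if curve not in reference:
            raise ConfigError(f"survival.reference missing {curve!r} curve")
    for arm, d in hrs.items():
        for curve in ("pfs", "os"):
            if curve not in d or d[curve] <= 0:
                raise ConfigError(
                    f"survival.hazard_ratios.{arm}: need positive {curve!r}")

    psa_raw = raw.get("psa", {})
    _reject_unknown(psa_raw, {"n_replicates", "seed", "wtp_grid"}, "psa")
    grid_raw = psa_raw.get("wtp_grid", {"start": 0, "stop": 100000,
                                        "step": 2000})
    if isinstance(grid_raw, Mapping):
        _reject_unknown(grid_raw, {"start", "stop", "step"}, "psa.wtp_grid")
        start, stop, step = (float(grid_raw["start"]), float(grid_raw["stop"]),
                             float(grid_raw["step"]))
        if step <= 0 or stop < start:
            raise ConfigError("psa.wtp_grid: need step > 0 and stop >= start")
        n_pts = int(round((stop - start) / step)) + 1
        grid = tuple(start + i * step for i in range(n_pts))
    else:
        grid = tuple(float(w) for w in grid_raw)
    psa = PSASettings(n_replicates=int(psa_raw.get("n_replicates", 1000)),
                      seed=int(psa_raw.get("seed", 12345)),
                      wtp_grid=grid)

    return AnalysisConfig(
        settings=settings,
        wtp_threshold=float(raw.get("wtp_threshold", 13527.0)),
        bsa=float(raw.get("bsa_m2", 1.72)),
        reference=reference,
        hazard_ratios=hrs,
        parameters=_parse_specs(raw.get("parameters"), "parameters"),
        one_way_extra=_parse_specs(raw.get("one_way_extra"), "one_way_extra"),
        psa=psa,
    )


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _parse(raw)


def load_default_config() -> AnalysisConfig:
    text = resources.files("gastric_cea").joinpath("defaults.yaml").read_text()
    return _parse(yaml.safe_load(text))


def dump_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def config_hash(config: AnalysisConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def strategy_curves(config: AnalysisConfig) -> Dict[str, Dict[str, WeibullParams]]:
    """Per-strategy PFS/OS Weibull parameters: the reference for SO, the
    hazard-ratio-scaled reference for the active arms."""
    curves = {"SO": {"pfs": config.reference["pfs"],
                     "os": config.reference["os"]}}
    for arm, hr in config.hazard_ratios.items():
        curves[arm] = {c: adjust_by_hr(config.reference[c], hr[c])
                       for c in ("pfs", "os")}
    return curves


def base_values(config: AnalysisConfig) -> Dict[str, float]:
    """Every parameter at its median (plus the configured discount rate)."""
    values = {spec.target: spec.median for spec in config.parameters}
    values["discount_rate"] = config.settings.annual_discount_rate
    return values


def build_cost_inputs(values: Mapping[str, float],
                      config: AnalysisConfig) -> CostInputs:
    v = values
    return CostInputs(
        bsa=config.bsa,
        drug_prices={
            "capecitabine_per_500mg": v["cost_capecitabine"],
            "oxaliplatin_per_50mg": v["cost_oxaliplatin"],
            "paclitaxel_per_30mg": v["cost_paclitaxel"],
            "s1_per_20mg": v["cost_s1"],
        },
        administration_per_episode=v["cost_administration"],
        supportive_care_per_3wk=v["cost_supportive_care"],
        procedure_costs={
            "laboratory_evaluations_per_episode": v["cost_lab_eval"],
            "abdominal_ct_per_episode": v["cost_abdominal_ct"],
            "abdominal_mri_per_episode": v["cost_abdominal_mri"],
            "chest_radiograph_per_episode": v["cost_chest_radiograph"],
        },
        ae_costs={
            "nausea_vomiting_per_episode": v["cost_ae_nausea_vomiting"],
            "neutropenia_per_episode": v["cost_ae_neutropenia"],
            "appetite_fatigue_per_episode": v["cost_ae_appetite_fatigue"],
            "diarrhoea_pain_per_episode": v["cost_ae_diarrhoea_pain"],
            "thrombocytopenia_per_episode": v["cost_ae_thrombocytopenia"],
        },
        ae_profiles={
            "SO": AEProfile(()),
            "XELOX": AEProfile((
                ("nausea and vomiting", v["risk_xelox_nausea_vomiting"],
                 "nausea_vomiting_per_episode"),
                ("neutropenia", v["risk_xelox_neutropenia"],
                 "neutropenia_per_episode"),
                ("decreased appetite/fatigue/asthenia",
                 v["risk_xelox_appetite_fatigue"],
                 "appetite_fatigue_per_episode"),
                ("diarrhoea and abdominal pain", v["risk_xelox_diarrhoea_pain"],
                 "diarrhoea_pain_per_episode"),
                ("thrombocytopenia", v["risk_xelox_thrombocytopenia"],
                 "thrombocytopenia_per_episode"),
            )),
            "S-1": AEProfile((
                ("nausea", v["risk_s1_nausea"], "nausea_vomiting_per_episode"),
                ("diarrhoea", v["risk_s1_diarrhoea"],
                 "diarrhoea_pain_per_episode"),
                ("anorexia", v["risk_s1_anorexia"],
                 "appetite_fatigue_per_episode"),
            )),
        },
        second_line_fraction=v["risk_second_line"],
    )


def build_utility_schedules(
        values: Mapping[str, float]) -> Dict[str, UtilitySchedule]:
    inf = float("inf")
    ps = values["utility_ps"]
    return {
        "SO": UtilitySchedule(
            dfs_bands=((0.0, 10.0, values["utility_dfs_so"]),
                       (10.0, inf, 1.0)),
            ps_utility=ps),
        "XELOX": UtilitySchedule(
            dfs_bands=((0.0, 5.0, values["utility_dfs_xelox_y0_5"]),
                       (5.0, 10.0, values["utility_dfs_xelox_y5_10"]),
                       (10.0, inf, 1.0)),
            ps_utility=ps),
        "S-1": UtilitySchedule(
            dfs_bands=((0.0, 10.0, values["utility_dfs_s1"]),
                       (10.0, inf, 1.0)),
            ps_utility=ps),
    }


def build_traces(config: AnalysisConfig) -> Dict[str, MarkovTrace]:
    curves = strategy_curves(config)
    return {arm: build_trace(c["pfs"], c["os"], config.settings)
            for arm, c in curves.items()}


def make_model_fn(config: AnalysisConfig):
    """Callable ``values -> {strategy: (cost, qaly)}`` over the full model.

    Survival curves (and hence traces) are fixed by the configuration; only
    costs, utilities and the discount rate respond to ``values``.
    """
    traces = build_traces(config)

    def model_fn(values: Mapping[str, float]) -> Dict[str, Tuple[float, float]]:
        rate = values.get("discount_rate",
                          config.settings.annual_discount_rate)
        settings = dataclasses.replace(config.settings,
                                       annual_discount_rate=rate)
        inputs = build_cost_inputs(values, config)
        schedules = build_utility_schedules(values)
        out = {}
        for arm in config.strategies:
            costs = accumulate_costs(traces[arm], arm, inputs, settings)
            qalys = accumulate_qalys(traces[arm], schedules[arm], settings)
            out[arm] = (costs.total, qalys.total)
        return out

    return model_fn
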