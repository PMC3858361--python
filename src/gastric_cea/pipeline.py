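"""Orchestration: base case, one-way (tornado) and probabilistic analyses.

Every saved output is accompanied by run metadata (configuration hash,
seed where applicable, package version) so identical inputs provably give
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import pandas as pd

from . import __version__
from .config import (AnalysisConfig, base_values, build_cost_inputs,
                     build_traces, build_utility_schedules, config_hash,
                     make_model_fn)
from .costs import accumulate_costs
from .economics import CEResult, cer, compare
from .markov import accumulate_qalys
from .sensitivity import (PSAResult, ceac, one_way, run_psa, tornado_frame)

__all__ = ["BaseCaseResult", "run_base_case", "run_dsa", "run_psa_analysis"]


@dataclass
class BaseCaseResult:
    """Per-strategy cost/QALY breakdowns plus the comparative results."""

    breakdown: pd.DataFrame        # rows = outcome, columns = strategies
    ce: CEResult
    config_hash: str

    def to_frame(self) -> pd.DataFrame:
        return self.breakdown

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.breakdown.to_csv(outdir / "base_case.csv")
        _write_meta(outdir / "base_case_meta.json", self.config_hash)


def _write_meta(path: Path, cfg_hash: str, seed: Optional[int] = None,
                **extra) -> None:
    meta = {"config_hash": cfg_hash, "package_version": __version__}
    if seed is not None:
        meta["seed"] = seed
    meta.update(extra)
    path.write_text(json.dumps(meta, indent=2, sort_keys=True))


def run_base_case(config: AnalysisConfig) -> BaseCaseResult:
    """Deterministic model run at the median of every input."""
    values = base_values(config)
    traces = build_traces(config)
    inputs = build_cost_inputs(values, config)
    schedules = build_utility_schedules(values)
    settings = config.settings

    rows: Dict[str, Dict[str, float]] = {}
    totals: Dict[str, Tuple[float, float]] = {}
    for arm in config.strategies:
        c = accumulate_costs(traces[arm], arm, inputs, settings)
        q = accumulate_qalys(traces[arm], schedules[arm], settings)
        rows[arm] = {
            "cost_dfs": c.dfs, "cost_ps": c.ps, "cost_total": c.total,
            "qaly_dfs": q.dfs, "qaly_ps": q.ps, "qaly_total": q.total,
            "cer": cer(c.total, q.total),
            "dead_at_horizon": traces[arm].dead[-1],
        }
        totals[arm] = (c.total, q.total)

    breakdown = pd.DataFrame(rows)[list(config.strategies)]
    return BaseCaseResult(breakdown=breakdown,
                          ce=compare(totals, order=config.strategies),
                          config_hash=config_hash(config))


def run_dsa(config: AnalysisConfig,
            reference: str = "XELOX", comparator: str = "S-1",
            outdir=None) -> pd.DataFrame:
    """One-way sensitivity analysis of the ICER for comparator vs reference
    over every uncertain input (plus the discount rate)."""
    specs = config.parameters + config.one_way_extra
    entries = one_way(specs, make_model_fn(config), (reference, comparator),
                      base_values(config))
    frame = tornado_frame(entries)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(outdir / "tornado.csv", index=False)
        _write_meta(outdir / "tornado_meta.json", config_hash(config),
                    reference=reference, comparator=comparator)
    return frame


def run_psa_analysis(config: AnalysisConfig, n: Optional[int] = None,
                     seed: Optional[int] = None,
                     outdir=None) -> Tuple[PSAResult, pd.DataFrame]:
    """Probabilistic sensitivity analysis plus acceptability curves."""
    n = n if n is not None else config.psa.n_replicates
    seed = seed if seed is not None else config.psa.seed
    psa = run_psa(n, seed, config.parameters, make_model_fn(config),
                  base_values(config), strategies=config.strategies)
    curves = ceac(psa, config.psa.wtp_grid)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        psa.to_frame().to_csv(outdir / "psa_replicates.csv", index=False)
        curves.to_csv(outdir / "ceac.csv", index=False)
        _write_meta(outdir / "psa_meta.json", config_hash(config), seed=seed,
                    n_replicates=n)
    return psa, curves
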