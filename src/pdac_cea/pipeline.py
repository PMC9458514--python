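"""End-to-end base-case pipeline: calibrate, run, account, rank.

This is the surface the CLI, the examples and the acceptance machinery share:
one call produces calibrated hazards, per-arm economics, the efficiency
frontier and a base-case summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anchors import OS, PFS, build_anchor_set, monthly_background_mortality
from .calibration import CalibrationResult, calibrate_arm
from .economics import CEResult, EconOutcome, accumulate, efficiency_frontier
from .engine import CohortTrace, run_cohort
from .params import GeneralParams, ModelSettings, StrategyParams, load_parameters

__all__ = ["ModelInputs", "BaseCaseRun", "load_inputs", "calibrate_all", "run_base_case", "summary_table"]


@dataclass
class ModelInputs:
    general: GeneralParams
    strategies: list  # of StrategyParams, natural history first
    settings: ModelSettings

    def strategy(self, name: str) -> StrategyParams:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class BaseCaseRun:
    inputs: ModelInputs
    calibrations: dict  # arm -> CalibrationResult
    traces: dict  # arm -> CohortTrace
    outcomes: dict  # arm -> EconOutcome
    frontier: CEResult


def load_inputs(directory=None) -> ModelInputs:
    general, strategies, settings = load_parameters(directory)
    return ModelInputs(general=general, strategies=strategies, settings=settings)


def calibrate_all(inputs: ModelInputs, seed: int = 0, anchors_path=None) -> dict:
    """Calibrate every arm to its packaged OS/PFS anchors."""
    out: dict[str, CalibrationResult] = {}
    for arm in inputs.strategies:
        out[arm.name] = calibrate_arm(
            arm,
            inputs.general,
            inputs.settings,
            build_anchor_set(arm.name, OS, anchors_path),
            build_anchor_set(arm.name, PFS, anchors_path),
            seed=seed,
        )
    return out


def run_base_case(
    inputs: ModelInputs | None = None,
    seed: int = 0,
    calibrations: dict | None = None,
) -> BaseCaseRun:
    """Full base case: calibrate each arm, run the cohort, accrue economics."""
    if inputs is None:
        inputs = load_inputs()
    if calibrations is None:
        calibrations = calibrate_all(inputs, seed=seed)
    background = monthly_background_mortality(
        inputs.general.start_age.base, inputs.settings.horizon_cycles
    )
    traces, outcomes = {}, {}
    for arm in inputs.strategies:
        hz = calibrations[arm.name].fitted
        trace = run_cohort(arm, inputs.general, hz, inputs.settings, background=background)
        traces[arm.name] = trace
        outcomes[arm.name] = accumulate(trace, arm, inputs.general, hz, inputs.settings)
    frontier = efficiency_frontier(
        list(outcomes.values()), wtp=inputs.settings.wtp_thresholds
    )
    return BaseCaseRun(
        inputs=inputs,
        calibrations=calibrations,
        traces=traces,
        outcomes=outcomes,
        frontier=frontier,
    )


def summary_table(run: BaseCaseRun) -> pd.DataFrame:
    """Base-case summary, one row per strategy ordered by cost."""
    rows = []
    for o in run.frontier.outcomes:
        rows.append(
            {
                "strategy": o.strategy,
                "life_years": o.life_years,
                "cost_usd": o.total_cost,
                "qalys": o.qalys,
                "median_os_months": o.median_os,
                "median_pfs_months": o.median_pfs,
                "os_5y_pct": 100 * o.landmark_os_5y,
                "os_10y_pct": 100 * o.landmark_os_10y,
                "pfs_5y_pct": 100 * o.landmark_pfs_5y,
                "pfs_10y_pct": 100 * o.landmark_pfs_10y,
                "trae_cost_month": o.trae_cost_month,
                "resection_rate_pct": (
                    100 * o.resection_rate if o.resection_rate is not None else np.nan
                ),
                "r0_resection_pct": (
                    100 * o.r0_fraction if o.r0_fraction is not None else np.nan
                ),
                "icer_vs_next": run.frontier.icers.get(o.strategy, np.nan),
            }
        )
    return pd.DataFrame(rows)
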