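"""Sensitivity analyses: one-way deterministic (tornado), probabilistic (PSA
with cost-effectiveness acceptability curves) and named scenario overrides.

The base calibration is held fixed throughout: varying a cost or utility
re-runs accounting only; varying a structural probability (dropout, R0 rate,
...) re-runs the cohort; varying a survival-median input re-derives the
monthly probability it feeds (the blended recurrence-death base or the
second-line death hazard).  The published "PDAC recurrence rate" enters as a
multiplicative scale on the calibrated progression hazards (value / base
value).  Re-calibration is only triggered by scenario overrides that replace
survival anchors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .anchors import OS, PFS, SurvivalAnchorSet, build_anchor_set, monthly_background_mortality
from .calibration import calibrate_arm, median_to_monthly_prob, recurrence_death_blend
from .economics import accumulate, efficiency_frontier
from .engine import run_cohort
from .params import (
    ARM_FOLFIRINOX,
    ARM_GNP,
    GeneralParams,
    Param,
    StrategyParams,
    iter_ranged_params,
)
from .pipeline import BaseCaseRun, ModelInputs, run_base_case

__all__ = [
    "TornadoEntry",
    "DistributionSpec",
    "PSAResult",
    "ScenarioOverrides",
    "one_way_dsa",
    "fit_distribution",
    "build_distribution_specs",
    "run_psa",
    "run_scenario",
    "pairwise_icer",
]

_MEDIAN_FIELDS = (
    "median_surv_recurrence_r0",
    "median_surv_recurrence_r1",
    "median_surv_recurrence_n0",
    "median_surv_recurrence_n1",
    "median_surv_second_line",
)

DOMINANT = "dominant"  # more QALYs for less money
DOMINATED = "dominated"  # fewer QALYs for more money


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float | str
    icer_at_high: float | str
    crosses_wtp: bool
    span: float

    @staticmethod
    def compute_span(icer_low, icer_high) -> float:
        if isinstance(icer_low, str) or isinstance(icer_high, str):
            return float("inf")
        return abs(icer_high - icer_low)


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one parameter in the PSA.

    ``family`` is ``beta`` (probabilities/utilities), ``gamma`` (costs and
    month-scale medians; disutilities via their magnitude), ``uniform``
    (fallback) or ``point``.  Hyperparameters are moment-matched: mean at the
    base value, standard deviation implied by the declared (low, high) range
    read as an approximate 95% interval.
    """

    parameter: str
    family: str
    args: tuple
    negate: bool = False  # sample magnitude, return negative (disutilities)
    stream: int = 0

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "point":
            out = np.full(size, self.args[0]) if size else self.args[0]
        elif self.family == "beta":
            out = rng.beta(*self.args, size=size)
        elif self.family == "gamma":
            shape, scale = self.args
            out = rng.gamma(shape, scale, size=size)
        elif self.family == "uniform":
            lo, hi = self.args
            out = rng.uniform(lo, hi, size=size)
        else:
            raise ValueError(f"unknown family {self.family}")
        return -out if self.negate else out


@dataclass
class PSAResult:
    iterations: int
    strategies: list
    costs: np.ndarray  # (iterations, n_strategies)
    qalys: np.ndarray
    wtp_grid: np.ndarray
    ceac: pd.DataFrame  # index wtp, one column per strategy: optimal share
    optimal_share: dict  # wtp threshold -> {strategy: share}
    failures: int = 0


@dataclass(frozen=True)
class ScenarioOverrides:
    """Named parameter and anchor replacements applied on top of the base case."""

    name: str = "scenario"
    general: dict = field(default_factory=dict)
    strategies: dict = field(default_factory=dict)  # arm -> {field: value}
    anchors: tuple = ()  # of SurvivalAnchorSet replacing packaged ones


def _with_general(general: GeneralParams, field_name: str, value: float) -> GeneralParams:
    cur = getattr(general, field_name)
    return dataclasses.replace(general, **{field_name: cur.replace(value)})


def _outcome_for(
    arm: StrategyParams,
    general: GeneralParams,
    run: BaseCaseRun,
    settings,
    background,
):
    """Re-run one arm with (possibly modified) parameters, base calibration fixed."""
    base_arm = run.inputs.strategy(arm.name)
    hz = run.calibrations[arm.name].fitted
    if arm.treated:
        prog_scale = arm.recurrence_rate.base / base_arm.recurrence_rate.base
        hz = dataclasses.replace(
            hz,
            death_base=recurrence_death_blend(arm),
            second_line_death=median_to_monthly_prob(arm.median_surv_second_line.base),
        )
    else:
        prog_scale = 1.0
    trace = run_cohort(arm, general, hz, settings, background=background, prog_scale=prog_scale)
    return accumulate(trace, arm, general, hz, settings)


def pairwise_icer(outcome_a, outcome_b):
    """ICER of strategy b vs a, or a dominance flag (b's perspective)."""
    dc = outcome_b.total_cost - outcome_a.total_cost
    dq = outcome_b.qalys - outcome_a.qalys
    if dq <= 0:
        return DOMINANT if dc < 0 else DOMINATED
    if dc <= 0:
        return DOMINANT
    return dc / dq


def one_way_dsa(
    run: BaseCaseRun,
    wtp: float = 100_000.0,
    comparison: tuple = (ARM_GNP, ARM_FOLFIRINOX),
) -> list:
    """One-way sweep of every ranged parameter; entries sorted by ICER span.

    Each entry reports the pairwise ICER of ``comparison[1]`` vs
    ``comparison[0]`` with the parameter at its low and at its high bound
    (all else at base); ``crosses_wtp`` is true when the optimum at ``wtp``
    changes (ICER beyond the threshold, or dominance flips).
    """
    inputs = run.inputs
    background = monthly_background_mortality(
        inputs.general.start_age.base, inputs.settings.horizon_cycles
    )
    ref_name, target_name = comparison
    entries = []
    for owner, field_name, label, p in iter_ranged_params(inputs.general, inputs.strategies):
        icers = {}
        for bound, value in (("low", p.low), ("high", p.high)):
            general = inputs.general
            arms = {s.name: s for s in inputs.strategies}
            if owner == "general":
                general = _with_general(general, field_name, value)
            else:
                arms[owner] = arms[owner].with_value(field_name, value)
            out_ref = _outcome_for(arms[ref_name], general, run, inputs.settings, background)
            out_tgt = _outcome_for(arms[target_name], general, run, inputs.settings, background)
            icers[bound] = pairwise_icer(out_ref, out_tgt)
        crosses = any(
            isinstance(v, str) and v == DOMINATED or (not isinstance(v, str) and v > wtp)
            for v in icers.values()
        )
        entries.append(
            TornadoEntry(
                parameter=label,
                low_value=p.low,
                high_value=p.high,
                icer_at_low=icers["low"],
                icer_at_high=icers["high"],
                crosses_wtp=crosses,
                span=TornadoEntry.compute_span(icers["low"], icers["high"]),
            )
        )
    entries.sort(key=lambda e: (-e.span, e.parameter))
    return entries


def tornado_frame(entries: list) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in entries])


# ---------------------------------------------------------------------------
# distributions


def _fit_beta(mean: float, sd: float) -> tuple | None:
    """Method-of-moments (alpha, beta) for the given mean and sd, or None."""
    if not (0.0 < mean < 1.0):
        return None
    v = sd * sd
    if v >= mean * (1.0 - mean):
        return None
    nu = mean * (1.0 - mean) / v - 1.0
    a, b = mean * nu, (1.0 - mean) * nu
    if a <= 0 or b <= 0:
        return None
    return (float(a), float(b))


def _fit_gamma(mean: float, sd: float) -> tuple | None:
    """Method-of-moments (shape, scale) for the given mean and sd, or None."""
    if mean <= 0 or sd <= 0:
        return None
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return (float(shape), float(scale))


def fit_distribution(
    parameter: str, base: float, low: float, high: float, stream: int = 0
) -> DistributionSpec:
    """Distribution anchored at the base case with range-implied spread.

    The mean is the base value and the standard deviation is the declared
    (low, high) range read as an approximate 95% interval, (high - low)/3.92.
    Probabilities and utilities get a beta; costs and month-medians a gamma;
    disutilities a gamma on their magnitude.  A degenerate range is a point
    mass; an infeasible moment match falls back to uniform(low, high).
    """
    if not (low <= base <= high):
        raise ValueError(f"{parameter}: range must bracket base")
    if high - low < 1e-12:
        return DistributionSpec(parameter, "point", (base,), stream=stream)
    sd = (high - low) / 3.92
    negate = base < 0 or (base == 0 and low < 0)
    if negate:
        args = _fit_gamma(-base, sd)
        if args is not None:
            return DistributionSpec(parameter, "gamma", args, negate=True, stream=stream)
        return DistributionSpec(parameter, "uniform", (-high, -low), negate=True, stream=stream)
    if 0.0 <= low and high <= 1.0 and base <= 1.0:
        args = _fit_beta(base, sd)
        if args is not None:
            return DistributionSpec(parameter, "beta", args, stream=stream)
    args = _fit_gamma(base, sd)
    if args is not None:
        return DistributionSpec(parameter, "gamma", args, stream=stream)
    return DistributionSpec(parameter, "uniform", (low, high), stream=stream)


def build_distribution_specs(inputs: ModelInputs) -> list:
    """One DistributionSpec per ranged parameter, stream indices assigned."""
    specs = []
    for i, (owner, field_name, label, p) in enumerate(
        iter_ranged_params(inputs.general, inputs.strategies)
    ):
        if field_name == "start_age":
            # cohort age is structural (drives the life-table lookup), held fixed
            specs.append(DistributionSpec(label, "point", (p.base,), stream=i))
            continue
        specs.append(fit_distribution(label, p.base, p.low, p.high, stream=i))
    return specs


def run_psa(
    run: BaseCaseRun,
    specs: list | None = None,
    iterations: int | None = None,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Joint parameter sampling; per-iteration costs/QALYs and the CEAC.

    All parameters are drawn independently, each from its own seeded
    substream, so results are reproducible and insensitive to spec order.
    The optimum per willingness-to-pay is the net-monetary-benefit argmax.
    """
    inputs = run.inputs
    if specs is None:
        specs = build_distribution_specs(inputs)
    if iterations is None:
        iterations = inputs.settings.psa_iterations
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 200_001.0, 5_000.0)

    draws = {}
    for spec in specs:
        rng = np.random.default_rng([seed, spec.stream])
        draws[spec.parameter] = spec.sample(rng, size=iterations)

    background = monthly_background_mortality(
        inputs.general.start_age.base, inputs.settings.horizon_cycles
    )
    strategies = [s.name for s in inputs.strategies]
    costs = np.full((iterations, len(strategies)), np.nan)
    qalys = np.full((iterations, len(strategies)), np.nan)
    failures = 0
    labels = {
        label: (owner, field_name)
        for owner, field_name, label, _ in iter_ranged_params(
            inputs.general, inputs.strategies
        )
    }
    for it in range(iterations):
        try:
            general = inputs.general
            arms = {s.name: s for s in inputs.strategies}
            gen_updates = {}
            arm_updates: dict[str, dict] = {}
            for label, (owner, field_name) in labels.items():
                value = float(draws[label][it])
                cur = getattr(general if owner == "general" else arms[owner], field_name)
                if owner == "general":
                    gen_updates[field_name] = cur.replace(value)
                else:
                    arm_updates.setdefault(owner, {})[field_name] = cur.replace(value)
            if gen_updates:
                general = dataclasses.replace(general, **gen_updates)
            for owner, upd in arm_updates.items():
                arms[owner] = dataclasses.replace(arms[owner], **upd)
            for j, name in enumerate(strategies):
                out = _outcome_for(arms[name], general, run, inputs.settings, background)
                costs[it, j] = out.total_cost
                qalys[it, j] = out.qalys
        except (ValueError, ZeroDivisionError):
            failures += 1
            costs[it] = np.nan
            qalys[it] = np.nan

    ok = ~np.isnan(costs).any(axis=1)
    ceac_rows = []
    for w in wtp_grid:
        nmb = qalys[ok] * w - costs[ok]
        best = np.argmax(nmb, axis=1)
        shares = [np.mean(best == j) for j in range(len(strategies))]
        ceac_rows.append(shares)
    ceac = pd.DataFrame(ceac_rows, index=wtp_grid, columns=strategies)
    ceac.index.name = "wtp"

    optimal_share = {}
    for w in inputs.settings.wtp_thresholds:
        nmb = qalys[ok] * w - costs[ok]
        best = np.argmax(nmb, axis=1)
        optimal_share[float(w)] = {
            name: float(np.mean(best == j)) for j, name in enumerate(strategies)
        }

    return PSAResult(
        iterations=iterations,
        strategies=strategies,
        costs=costs,
        qalys=qalys,
        wtp_grid=np.asarray(wtp_grid, dtype=float),
        ceac=ceac,
        optimal_share=optimal_share,
        failures=failures,
    )


def run_scenario(
    inputs: ModelInputs, overrides: ScenarioOverrides, seed: int = 0
):
    """Apply overrides, re-calibrating any arm whose anchors are replaced.

    Returns the scenario's :class:`BaseCaseRun` (frontier labelled by the
    scenario is the frontier attribute).  Unknown override keys raise.
    """
    general = inputs.general
    for key, value in overrides.general.items():
        if not hasattr(general, key):
            raise KeyError(f"unknown general override {key!r}")
        general = _with_general(general, key, value)
    strategies = []
    for arm in inputs.strategies:
        upd = overrides.strategies.get(arm.name, {})
        for key, value in upd.items():
            if getattr(arm, key, None) is None:
                raise KeyError(f"unknown override {key!r} for arm {arm.name}")
            arm = arm.with_value(key, value)
        strategies.append(arm)
    new_inputs = ModelInputs(general=general, strategies=strategies, settings=inputs.settings)

    replaced = {(a.arm, a.endpoint): a for a in overrides.anchors}
    calibrations = {}
    for arm in new_inputs.strategies:
        os_a = replaced.get((arm.name, OS), build_anchor_set(arm.name, OS))
        pfs_a = replaced.get((arm.name, PFS), build_anchor_set(arm.name, PFS))
        calibrations[arm.name] = calibrate_arm(
            arm, general, new_inputs.settings, os_a, pfs_a, seed=seed
        )
    return run_base_case(new_inputs, seed=seed, calibrations=calibrations)


def load_scenario_yaml(path) -> ScenarioOverrides:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    anchors = []
    for spec in doc.get("anchors", []):
        anchors.append(
            SurvivalAnchorSet(
                arm=spec["arm"],
                endpoint=spec["endpoint"],
                anchors=tuple((float(t), float(s)) for t, s in spec["points"]),
            )
        )
    return ScenarioOverrides(
        name=doc.get("name", "scenario"),
        general=doc.get("general", {}) or {},
        strategies=doc.get("strategies", {}) or {},
        anchors=tuple(anchors),
    )
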