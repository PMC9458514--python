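"""Discounted cost/QALY accounting and the ICER efficiency frontier.

Costs accrue on start-of-cycle occupancy; QALYs and life-years use
half-cycle-corrected occupancy (mean of start- and end-of-cycle).  Both are
discounted at the annual rate converted per monthly cycle.  Cost accrual per
state:

* neoadjuvant — chemotherapy per cycle, expected toxicity (rate-weighted
  toxicity cost plus, optionally, a rate-weighted inpatient month for
  hospitalised toxicity), administration, and (optionally) capecitabine/
  radiation in the final two cycles with one chemoradiation hospitalisation;
* resection cycle — surgery plus rate-weighted inpatient months for surgical
  complications and pancreatic fistula; a one-off endoscopic-ultrasound
  work-up cost is charged at model entry;
* recurrence — monthly disease-management (inpatient) cost and, by default,
  second-line therapy (drug + rate-weighted toxicity + administration),
  since recurrent patients move to second-line treatment;
* second line — drug, rate-weighted toxicity, administration;
* palliative — the published total palliative cost amortised over the
  expected palliative sojourn implied by its death hazard;
* untreated arm — monthly inpatient cost while progression-free, palliative
  stream after progression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anchors import OS, PFS
from .engine import (
    CohortTrace,
    HazardParams,
    HealthState,
    landmark_survival,
    median_survival,
    r0_fraction,
    resection_rate,
    survival_curve,
)
from .params import GeneralParams, ModelSettings, StrategyParams

__all__ = [
    "EconOutcome",
    "CEResult",
    "discount_factor",
    "half_cycle_occupancy",
    "accumulate",
    "efficiency_frontier",
]

_S = HealthState


@dataclass(frozen=True)
class EconOutcome:
    """Per-strategy discounted economics and clinical endpoints."""

    strategy: str
    total_cost: float
    qalys: float
    life_years: float
    median_os: float | None
    median_pfs: float | None
    landmark_os_5y: float
    landmark_os_10y: float
    landmark_pfs_5y: float
    landmark_pfs_10y: float
    trae_cost_month: float
    resection_rate: float | None
    r0_fraction: float | None

    def __post_init__(self):
        if self.qalys > self.life_years + 1e-9:
            raise ValueError("QALYs exceed life-years")
        if self.total_cost < 0 or self.qalys < 0:
            raise ValueError("negative cost or QALYs")


@dataclass
class CEResult:
    """Efficiency frontier over a set of strategies."""

    outcomes: list  # EconOutcome, ordered by cost
    dominated: set = field(default_factory=set)
    extended_dominated: set = field(default_factory=set)
    icers: dict = field(default_factory=dict)  # strategy -> ICER vs next-cheaper frontier member
    optimal: dict = field(default_factory=dict)  # wtp -> strategy
    ties: set = field(default_factory=set)

    @property
    def frontier(self) -> list:
        excluded = self.dominated | self.extended_dominated
        return [o for o in self.outcomes if o.strategy not in excluded]


def discount_factor(cycle: float, annual_rate: float) -> float:
    """Discount multiplier at a monthly cycle index: (1+r)^(-cycle/12)."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return float((1.0 + annual_rate) ** (-cycle / 12.0))


def half_cycle_occupancy(trace: CohortTrace) -> np.ndarray:
    """Effective occupancy per cycle: mean of start- and end-of-cycle."""
    occ = trace.occupancy
    return 0.5 * (occ[:-1] + occ[1:])


def _state_costs(
    arm: StrategyParams,
    general: GeneralParams,
    hazards: HazardParams,
    settings: ModelSettings,
    horizon: int,
):
    """Monthly cost matrix (cycle x state) plus the TRAE component alone."""
    C = np.zeros((horizon, len(_S)))
    T = np.zeros((horizon, len(_S)))
    g = general
    pall_sojourn = 1.0 / max(hazards.palliative_death, 1e-9)
    pall_monthly = g.cost_palliative_total.base / pall_sojourn

    if arm.treated:
        n = arm.n_cycles
        tox = arm.toxicity_rate.base
        trae_cycle = tox * arm.cost_toxicity_cycle.base
        if settings.toxicity_hospitalization_inpatient:
            trae_cycle += (
                tox * arm.hospitalization_for_toxicity.base * g.cost_pdac_month_inpatient.base
            )
        neo = arm.cost_chemo_cycle.base + arm.cost_admin_month.base + trae_cycle
        C[:n, _S.NEOADJUVANT] = neo
        T[:n, _S.NEOADJUVANT] = trae_cycle
        if settings.chemoradiation_addon and n >= 2:
            C[n - 2 : n, _S.NEOADJUVANT] += g.cost_capecitabine_rt_month.base
            C[n - 1, _S.NEOADJUVANT] += g.cost_chemoradiation_hosp.base

        # one-off surgical costs, charged to resection-cycle occupancy
        surgery = g.cost_resection.base + g.cost_pdac_month_inpatient.base * (
            arm.surgical_complication_rate.base + arm.fistula_rate.base
        )
        if n < horizon:
            C[n, _S.RESECTION] = surgery

        sl_tox = tox * arm.cost_toxicity_second_line_month.base
        sl_month = arm.cost_second_line_month.base + sl_tox + arm.cost_admin_month.base
        C[:, _S.SECOND_LINE] = sl_month
        T[:, _S.SECOND_LINE] = sl_tox

        rec = g.cost_pdac_month_inpatient.base
        if settings.recurrence_second_line:
            rec += sl_month
            T[:, _S.RECURRENCE] = sl_tox
        C[:, _S.RECURRENCE] = rec
        C[:, _S.PALLIATIVE] = pall_monthly
    else:
        # untreated: observation while progression-free; after progression the
        # published palliative total, amortised over the calibrated sojourn
        death = np.array([hazards.progressed_death_at(t) for t in range(horizon)])
        C[:, _S.PALLIATIVE] = g.cost_palliative_total.base * np.maximum(death, 1e-9)
    return C, T


def _state_utilities(
    arm: StrategyParams, general: GeneralParams, settings: ModelSettings, horizon: int
) -> np.ndarray:
    """Monthly utility matrix (cycle x state); raises on negative net utility."""
    g = general
    U = np.zeros((horizon, len(_S)))
    U[:, _S.REMISSION_R0] = g.utility_progression_free.base
    U[:, _S.REMISSION_R1] = g.utility_progression_free.base
    U[:, _S.RECURRENCE] = g.utility_progressive.base
    U[:, _S.SECOND_LINE] = g.utility_progressive.base
    U[:, _S.PALLIATIVE] = g.utility_palliative.base
    if arm.treated:
        neo_u = (
            g.utility_progression_free.base
            + arm.disutility_chemo.base
            + arm.toxicity_rate.base * arm.disutility_toxicity.base
        )
        if neo_u < 0:
            raise ValueError(
                f"net neoadjuvant utility negative ({neo_u:.3f}); check disutilities"
            )
        U[: arm.n_cycles, _S.NEOADJUVANT] = neo_u
        U[:, _S.RESECTION] = g.utility_surgery_recovery.base
    return U


def accumulate(
    trace: CohortTrace,
    arm_params: StrategyParams,
    general: GeneralParams,
    hazards: HazardParams,
    settings: ModelSettings,
) -> EconOutcome:
    """Fold a cohort trace into a discounted :class:`EconOutcome`."""
    H = trace.horizon
    disc = np.array([discount_factor(t, settings.discount_rate_annual) for t in range(H)])
    occ = trace.occupancy[:-1]  # start-of-cycle
    hc = half_cycle_occupancy(trace)

    C, T = _state_costs(arm_params, general, hazards, settings, H)
    U = _state_utilities(arm_params, general, settings, H)

    alive_mask = np.ones(len(_S))
    alive_mask[_S.DEAD] = 0.0
    cost_stream = (occ * C).sum(axis=1)
    # diagnostic work-up charged once, to the cohort alive at entry
    total_cost = float(cost_stream @ disc) + general.cost_eus.base * float(
        occ[0] @ alive_mask
    )

    qaly_stream = (hc * U).sum(axis=1) / 12.0
    qalys = float(qaly_stream @ disc)

    ly_stream = (hc * alive_mask).sum(axis=1) / 12.0
    life_years = float(ly_stream @ disc)

    trae_stream = (occ * T).sum(axis=1)
    trae_months = int(np.sum(trae_stream > 1e-12))
    trae_cost_month = float(trae_stream.sum() / trae_months) if trae_months else 0.0

    os_curve = survival_curve(trace, OS)
    pfs_curve = survival_curve(trace, PFS)
    return EconOutcome(
        strategy=arm_params.name,
        total_cost=total_cost,
        qalys=qalys,
        life_years=life_years,
        median_os=median_survival(os_curve),
        median_pfs=median_survival(pfs_curve),
        landmark_os_5y=landmark_survival(os_curve, 60.0),
        landmark_os_10y=landmark_survival(os_curve, 120.0),
        landmark_pfs_5y=landmark_survival(pfs_curve, 60.0),
        landmark_pfs_10y=landmark_survival(pfs_curve, 120.0),
        trae_cost_month=trae_cost_month,
        resection_rate=resection_rate(trace),
        r0_fraction=r0_fraction(trace),
    )


def efficiency_frontier(outcomes: list, wtp=None) -> CEResult:
    """Dominance pruning, frontier ICERs, and the optimal strategy per WTP.

    Sorts by cost; removes strictly dominated strategies (>= cost and
    <= QALYs, one strict), then iteratively removes extended-dominated ones
    (non-increasing incremental ICER along the chain).  Frontier ICERs are
    computed pairwise against the next-cheaper frontier member.  Ties on both
    cost and QALYs are flagged and broken deterministically by label order.
    """
    if len(outcomes) < 1:
        raise ValueError("need at least one strategy")
    if wtp is None:
        wtp = []
    wtp = np.atleast_1d(np.asarray(wtp, dtype=float))

    ordered = sorted(outcomes, key=lambda o: (o.total_cost, o.qalys, o.strategy))
    ties = {
        b.strategy
        for a, b in zip(ordered, ordered[1:])
        if a.total_cost == b.total_cost and a.qalys == b.qalys
    }

    dominated = set()
    for o in ordered:
        for other in ordered:
            if other.strategy == o.strategy:
                continue
            if (
                other.total_cost <= o.total_cost
                and other.qalys >= o.qalys
                and (other.total_cost < o.total_cost or other.qalys > o.qalys)
            ):
                dominated.add(o.strategy)
                break

    chain = [o for o in ordered if o.strategy not in dominated]
    # exact ties: keep the first by label order, treat the rest as dominated
    seen = set()
    deduped = []
    for o in chain:
        key = (o.total_cost, o.qalys)
        if key in seen:
            dominated.add(o.strategy)
            continue
        seen.add(key)
        deduped.append(o)
    chain = deduped
    extended = set()
    changed = True
    while changed and len(chain) > 2:
        changed = False
        icers = [
            (b.total_cost - a.total_cost) / (b.qalys - a.qalys)
            for a, b in zip(chain, chain[1:])
        ]
        for i in range(len(icers) - 1):
            if icers[i] >= icers[i + 1]:
                extended.add(chain[i + 1].strategy)
                chain = chain[: i + 1] + chain[i + 2 :]
                changed = True
                break

    icers = {}
    for a, b in zip(chain, chain[1:]):
        icers[b.strategy] = (b.total_cost - a.total_cost) / (b.qalys - a.qalys)

    optimal = {}
    for w in wtp:
        best = chain[0]
        for o in chain[1:]:
            if icers[o.strategy] <= w:
                best = o
        optimal[float(w)] = best.strategy

    return CEResult(
        outcomes=ordered,
        dominated=dominated,
        extended_dominated=extended,
        icers=icers,
        optimal=optimal,
        ties=ties,
    )
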