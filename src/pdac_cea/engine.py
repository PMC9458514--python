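"""Monthly Markov cohort engine over the treatment-pathway health states.

States
------
``NEOADJUVANT``  on first-line chemotherapy (cycles 0 .. n_cycles-1)
``RESECTION``    transitional single-cycle surgery state (cycle n_cycles)
``REMISSION_R0`` / ``REMISSION_R1``  post-resection remission by margin status
``RECURRENCE``   progressed disease after resection
``SECOND_LINE``  second-line chemotherapy after neoadjuvant dropout
``PALLIATIVE``   palliative care
``DEAD``         absorbing

The untreated (natural-history) arm starts progression-free (modelled in the
``REMISSION_R0`` slot) and progresses directly to ``PALLIATIVE``.

Competing risks within a cycle are ordered: all-cause (background) death is
evaluated first, disease events apply to the survivors.  All transition
probabilities are per monthly cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .anchors import OS, PFS, monthly_background_mortality
from .params import GeneralParams, ModelSettings, StrategyParams

__all__ = [
    "HealthState",
    "HazardParams",
    "CohortTrace",
    "transition_matrix",
    "build_transition_matrices",
    "run_cohort",
    "survival_curve",
    "median_survival",
    "landmark_survival",
    "resection_rate",
    "r0_fraction",
    "trace_to_frame",
]


class HealthState(IntEnum):
    NEOADJUVANT = 0
    RESECTION = 1
    REMISSION_R0 = 2
    REMISSION_R1 = 3
    RECURRENCE = 4
    SECOND_LINE = 5
    PALLIATIVE = 6
    DEAD = 7


_N = len(HealthState)
_PF_STATES = (
    HealthState.NEOADJUVANT,
    HealthState.RESECTION,
    HealthState.REMISSION_R0,
    HealthState.REMISSION_R1,
)
_MAX_PROB = 0.99  # cap on any single cause-specific monthly probability


@dataclass(frozen=True)
class HazardParams:
    """Piecewise-constant monthly disease hazards for one arm.

    ``knots`` are the segment boundaries (months) shared by the progression
    and progressed-state death drivers; ``progression`` holds the per-segment
    remission-to-progression probability and ``death_mult`` the per-segment
    multiplier on ``death_base`` giving the disease-death probability in the
    progressed state (recurrence for treated arms, palliative for the
    untreated arm, whose ``death_base`` is 1).  ``second_line_death`` and
    ``palliative_death`` are constant monthly probabilities derived from
    median survivals.
    """

    knots: tuple
    progression: tuple
    death_mult: tuple
    death_base: float = 1.0
    second_line_death: float = 0.0
    palliative_death: float = 0.0

    def __post_init__(self):
        if len(self.progression) != len(self.knots) - 1:
            raise ValueError("one progression probability per segment required")
        if len(self.death_mult) != len(self.knots) - 1:
            raise ValueError("one death multiplier per segment required")
        for name in ("second_line_death", "palliative_death", "death_base"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")
        for p in self.progression:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"progression probability outside [0, 1]: {p}")
        for m in self.death_mult:
            if m < 0:
                raise ValueError(f"negative death multiplier: {m}")

    def segment_index(self, cycle: float) -> int:
        knots = np.asarray(self.knots, dtype=float)
        return int(np.clip(np.searchsorted(knots, cycle, side="right") - 1, 0, len(knots) - 2))

    def progression_at(self, cycle: float, scale: float = 1.0) -> float:
        return min(self.progression[self.segment_index(cycle)] * scale, _MAX_PROB)

    def progressed_death_at(self, cycle: float) -> float:
        return min(self.death_mult[self.segment_index(cycle)] * self.death_base, _MAX_PROB)

    def scaled(self, prog_scale: float = 1.0, death_base: float | None = None) -> "HazardParams":
        """Copy with the progression hazard scaled and/or the death base swapped
        (used by the sensitivity analyses; segment structure is preserved)."""
        out = self
        if prog_scale != 1.0:
            out = replace(
                out,
                progression=tuple(min(p * prog_scale, _MAX_PROB) for p in out.progression),
            )
        if death_base is not None:
            out = replace(out, death_base=death_base)
        return out


@dataclass
class CohortTrace:
    """State occupancy over the horizon plus per-cycle transition flows.

    ``occupancy[t]`` is the distribution at the *start* of cycle t
    (t = 0 .. horizon); rows sum to 1.  ``matrices[t]`` maps cycle t to t+1.
    """

    arm: str
    occupancy: np.ndarray  # (horizon+1, n_states)
    matrices: np.ndarray  # (horizon, n_states, n_states)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def flows(self) -> np.ndarray:
        """Per-cycle transition mass: flows[t, i, j] = occupancy[t, i] * P[t, i, j]."""
        return self.occupancy[:-1, :, None] * self.matrices

    def flow_into(self, state: HealthState, cycle: int) -> float:
        """Mass entering ``state`` during the transition into cycle ``cycle``."""
        if cycle <= 0:
            return float(self.occupancy[0, state])
        src = self.occupancy[cycle - 1]
        col = self.matrices[cycle - 1][:, state]
        off = float(np.dot(src, col)) - src[state] * self.matrices[cycle - 1][state, state]
        return off


def _checked(p: float, what: str) -> float:
    if not (-1e-12 <= p <= 1 + 1e-12):
        raise ValueError(f"computed probability outside [0, 1] for {what}: {p}")
    return float(np.clip(p, 0.0, 1.0))


def transition_matrix(
    arm_params: StrategyParams,
    general: GeneralParams,
    hazards: HazardParams,
    cycle: int,
    settings: ModelSettings,
    background: np.ndarray | None = None,
    prog_scale: float = 1.0,
) -> np.ndarray:
    """Single-cycle transition matrix (rows = from-state, row-stochastic)."""
    if background is None:
        background = monthly_background_mortality(
            general.start_age.base, settings.horizon_cycles
        )
    if cycle >= settings.horizon_cycles:
        raise ValueError("cycle beyond horizon")
    return _build_matrices(
        arm_params, general, hazards, settings, background, prog_scale
    )[cycle]


def _build_matrices(
    arm: StrategyParams,
    general: GeneralParams,
    hazards: HazardParams,
    settings: ModelSettings,
    background: np.ndarray,
    prog_scale: float,
) -> np.ndarray:
    H = settings.horizon_cycles
    q = np.asarray(background, dtype=float)
    if q.shape[0] < H:
        raise ValueError("background mortality shorter than horizon")
    cycles = np.arange(H)
    surv = 1.0 - q[:H]

    p_prog = np.array([hazards.progression_at(t, prog_scale) for t in cycles])
    p_pdeath = np.array([hazards.progressed_death_at(t) for t in cycles])
    p_sl = hazards.second_line_death
    p_pall = hazards.palliative_death

    M = np.zeros((H, _N, _N))
    M[:, HealthState.DEAD, HealthState.DEAD] = 1.0

    S = HealthState
    if arm.treated:
        n = arm.n_cycles
        # per-cycle dropout from the cumulative phase probability
        d_cum = arm.dropout_rate.base
        pd_cycle = 1.0 - (1.0 - d_cum) ** (1.0 / n) if n > 0 else 0.0
        f_sl = settings.dropout_split_second_line
        f_pall = settings.dropout_split_palliative
        f_dead = settings.dropout_split_death
        for t in range(min(n, H)):
            stay = surv[t] * (1.0 - pd_cycle)
            M[t, S.NEOADJUVANT, S.SECOND_LINE] = surv[t] * pd_cycle * f_sl
            M[t, S.NEOADJUVANT, S.PALLIATIVE] = surv[t] * pd_cycle * f_pall
            M[t, S.NEOADJUVANT, S.DEAD] = q[t] + surv[t] * pd_cycle * f_dead
            dest = S.RESECTION if t == n - 1 else S.NEOADJUVANT
            M[t, S.NEOADJUVANT, dest] = stay
        for t in range(n, H):  # no mass remains, keep the row stochastic
            M[t, S.NEOADJUVANT, S.NEOADJUVANT] = 1.0
        # resection: single transitional cycle at t = n
        r0 = arm.r0_rate.base
        mort_surg = general.surgical_30day_mortality.base
        for t in range(H):
            alive_post = surv[t] * (1.0 - mort_surg)
            M[t, S.RESECTION, S.REMISSION_R0] = alive_post * r0
            M[t, S.RESECTION, S.REMISSION_R1] = alive_post * (1.0 - r0)
            M[t, S.RESECTION, S.DEAD] = q[t] + surv[t] * mort_surg
        # remission -> recurrence / death (background only)
        for rem in (S.REMISSION_R0, S.REMISSION_R1):
            M[:, rem, S.RECURRENCE] = surv * p_prog
            M[:, rem, S.DEAD] = q[:H]
            M[:, rem, rem] = surv * (1.0 - p_prog)
        M[:, S.RECURRENCE, S.DEAD] = q[:H] + surv * p_pdeath
        M[:, S.RECURRENCE, S.RECURRENCE] = surv * (1.0 - p_pdeath)
    else:
        # untreated: progression-free (REMISSION_R0 slot) -> palliative -> death
        for st in (S.NEOADJUVANT, S.RESECTION, S.REMISSION_R1, S.RECURRENCE):
            M[:, st, st] = 1.0
        M[:, S.REMISSION_R0, S.PALLIATIVE] = surv * p_prog
        M[:, S.REMISSION_R0, S.DEAD] = q[:H]
        M[:, S.REMISSION_R0, S.REMISSION_R0] = surv * (1.0 - p_prog)

    M[:, S.SECOND_LINE, S.DEAD] = q[:H] + surv * p_sl
    M[:, S.SECOND_LINE, S.SECOND_LINE] = surv * (1.0 - p_sl)
    if arm.treated:
        M[:, S.PALLIATIVE, S.DEAD] = q[:H] + surv * p_pall
        M[:, S.PALLIATIVE, S.PALLIATIVE] = surv * (1.0 - p_pall)
    else:
        M[:, S.PALLIATIVE, S.DEAD] = q[:H] + surv * p_pdeath
        M[:, S.PALLIATIVE, S.PALLIATIVE] = surv * (1.0 - p_pdeath)

    rowsums = M.sum(axis=2)
    if not np.allclose(rowsums, 1.0, atol=1e-9):
        bad = np.unravel_index(np.argmax(np.abs(rowsums - 1.0)), rowsums.shape)
        raise ValueError(f"transition row does not sum to 1 at cycle {bad[0]}, state {bad[1]}")
    if M.min() < -1e-12 or M.max() > 1 + 1e-12:
        raise ValueError("transition probability outside [0, 1]; inconsistent parameters")
    return M


def run_cohort(
    arm_params: StrategyParams,
    general: GeneralParams,
    hazards: HazardParams,
    settings: ModelSettings,
    background: np.ndarray | None = None,
    prog_scale: float = 1.0,
) -> CohortTrace:
    """Propagate a unit cohort through the arm's transition structure.

    The cohort starts 100% in ``NEOADJUVANT`` (treated arms) or 100%
    progression-free (untreated arm).
    """
    if background is None:
        background = monthly_background_mortality(
            general.start_age.base, settings.horizon_cycles
        )
    M = _build_matrices(arm_params, general, hazards, settings, background, prog_scale)
    H = settings.horizon_cycles
    occ = np.zeros((H + 1, _N))
    start = HealthState.NEOADJUVANT if arm_params.treated else HealthState.REMISSION_R0
    occ[0, start] = 1.0
    for t in range(H):
        occ[t + 1] = occ[t] @ M[t]
    return CohortTrace(arm=arm_params.name, occupancy=occ, matrices=M)


def survival_curve(trace: CohortTrace, endpoint: str) -> np.ndarray:
    """Survival proportion at each month 0..horizon.

    OS(t) = 1 - dead; PFS(t) = mass still progression-free (neither dead nor
    in recurrence, second-line or palliative care).
    """
    if endpoint == OS:
        return 1.0 - trace.occupancy[:, HealthState.DEAD]
    if endpoint == PFS:
        return trace.occupancy[:, list(_PF_STATES)].sum(axis=1)
    raise ValueError(f"unknown endpoint {endpoint!r}")


def median_survival(curve: np.ndarray) -> float | None:
    """Median of a monthly survival curve by linear interpolation.

    Event mass within a cycle is implicitly placed mid-cycle (the linear
    segment between the bracketing monthly points).  Returns ``None`` if the
    curve never falls below 0.5 within the horizon (censored).
    """
    curve = np.asarray(curve, dtype=float)
    below = np.nonzero(curve < 0.5)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return 0.0
    s0, s1 = curve[i - 1], curve[i]
    return float(i - 1 + (s0 - 0.5) / (s0 - s1))


def landmark_survival(curve: np.ndarray, month: float) -> float:
    """Survival at an arbitrary month, linearly interpolated between cycles."""
    months = np.arange(len(curve), dtype=float)
    return float(np.interp(month, months, curve))


def resection_rate(trace: CohortTrace, resection_cycle: int | None = None) -> float | None:
    """Fraction of the initial cohort that reaches surgery (None if no surgery)."""
    cyc = _resection_cycle(trace) if resection_cycle is None else resection_cycle
    if cyc is None:
        return None
    mass = trace.flow_into(HealthState.RESECTION, cyc)
    return float(mass / trace.occupancy[0].sum())


def r0_fraction(trace: CohortTrace, resection_cycle: int | None = None) -> float | None:
    """Among cohort mass surviving resection, the fraction assigned R0 margins."""
    cyc = _resection_cycle(trace) if resection_cycle is None else resection_cycle
    if cyc is None:
        return None
    r0 = trace.flow_into(HealthState.REMISSION_R0, cyc + 1)
    r1 = trace.flow_into(HealthState.REMISSION_R1, cyc + 1)
    if r0 + r1 <= 0.0:
        return None
    return float(r0 / (r0 + r1))


def _resection_cycle(trace: CohortTrace) -> int | None:
    occ = trace.occupancy[:, HealthState.RESECTION]
    if occ.max() <= 0:
        return None
    return int(np.argmax(occ > 0))


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """Trace as a DataFrame (cycle, one column per state, OS, PFS)."""
    df = pd.DataFrame(trace.occupancy, columns=[s.name for s in HealthState])
    df.insert(0, "cycle", np.arange(trace.occupancy.shape[0]))
    df["OS"] = survival_curve(trace, OS)
    df["PFS"] = survival_curve(trace, PFS)
    return df


def export_trace(trace: CohortTrace, path: Path | str) -> None:
    trace_to_frame(trace).to_csv(path, index=False)
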