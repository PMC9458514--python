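"""Calibration of piecewise-constant monthly hazards to survival anchors.

Each arm's free hazards — the per-segment remission-to-progression
probabilities (driving PFS) and the per-segment disease-death multipliers in
the progressed state (driving the OS/PFS gap) — are fitted so that the
simulated cohort's OS and PFS curves pass through the arm's anchor points.
The fit is a bounded nonlinear least-squares (sum of squared survival
deviations in proportion space) with seeded multistarts, so the result is
reproducible bit-for-bit for a given spec.

Fixed, parameter-derived hazards are built by :func:`base_hazards`: second
line death from its median survival, recurrence death *base* as the blend of
the margin- and node-stratified post-recurrence medians, and the treated
arms' palliative death from the assumed palliative median.  Calibration
scales the recurrence-death base per segment rather than replacing it, so the
published medians keep their role in the sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .anchors import OS, PFS, SurvivalAnchorSet
from .engine import HazardParams, landmark_survival, run_cohort, survival_curve
from .params import GeneralParams, ModelSettings, StrategyParams

__all__ = [
    "median_to_monthly_prob",
    "recurrence_death_blend",
    "base_hazards",
    "CalibrationSpec",
    "CalibrationResult",
    "simulate_anchors",
    "calibrate",
    "calibrate_arm",
]

#: segment boundaries (months) for the treated arms' piecewise hazards.
#: Each segment contains exactly one anchor time per endpoint (medians fall
#: between months 24 and 35, then the 5- and 10-year landmarks), which makes
#: the fit identifiable with a near-triangular structure.
TREATED_KNOTS = (6.0, 36.0, 60.0, 144.0)
#: the untreated arm has no resection event at month 6 (and only three
#: anchors per endpoint), so its segments start at diagnosis.
UNTREATED_KNOTS = (0.0, 36.0, 60.0, 144.0)

_MULT_CAP = 40.0  # upper bound on the recurrence-death multiplier


def median_to_monthly_prob(median: float) -> float:
    """Monthly event probability implied by a median time-to-event (months).

    Exponential assumption: p = 1 - 0.5**(1/median).
    """
    if median <= 0:
        raise ValueError(f"median must be > 0, got {median}")
    return 1.0 - 0.5 ** (1.0 / median)


def recurrence_death_blend(arm: StrategyParams) -> float:
    """Blended monthly post-recurrence death probability from published medians.

    Margin- and node-stratified medians are each converted to monthly
    probabilities and mixed with their observed frequencies (R0 rate, lymph
    node positivity); the two stratifications are averaged since the joint
    distribution is not published.
    """
    r0 = arm.r0_rate.base
    ln = arm.lymph_node_positivity.base
    by_margin = r0 * median_to_monthly_prob(arm.median_surv_recurrence_r0.base) + (
        1.0 - r0
    ) * median_to_monthly_prob(arm.median_surv_recurrence_r1.base)
    by_node = (1.0 - ln) * median_to_monthly_prob(
        arm.median_surv_recurrence_n0.base
    ) + ln * median_to_monthly_prob(arm.median_surv_recurrence_n1.base)
    return 0.5 * (by_margin + by_node)


def base_hazards(arm: StrategyParams, settings: ModelSettings) -> HazardParams:
    """Pre-calibration hazard skeleton for an arm (multipliers at 1)."""
    if arm.treated:
        return HazardParams(
            knots=TREATED_KNOTS,
            progression=(0.01, 0.02, 0.02),
            death_mult=(1.0, 1.0, 1.0),
            death_base=recurrence_death_blend(arm),
            second_line_death=median_to_monthly_prob(arm.median_surv_second_line.base),
            palliative_death=median_to_monthly_prob(settings.palliative_median_months),
        )
    return HazardParams(
        knots=UNTREATED_KNOTS,
        progression=(0.05, 0.05, 0.05),
        death_mult=(0.1, 0.1, 0.1),
        death_base=1.0,
        second_line_death=0.0,
        palliative_death=median_to_monthly_prob(settings.palliative_median_months),
    )


@dataclass
class CalibrationSpec:
    """What to fit: anchors, free parameters, bounds and optimiser settings."""

    arm_params: StrategyParams
    general: GeneralParams
    settings: ModelSettings
    hazards0: HazardParams
    os_anchors: SurvivalAnchorSet | None = None
    pfs_anchors: SurvivalAnchorSet | None = None
    fit_progression: bool = True
    fit_death: bool = True
    background: np.ndarray | None = None
    prog_bounds: tuple = (0.0, 0.9)
    mult_bounds: tuple | None = None  # default derived from death_base
    tol: float = 1e-10
    max_nfev: int = 400
    restarts: int = 5
    seed: int = 0
    converged_tol: float = 1e-8

    def __post_init__(self):
        if self.os_anchors is None and self.pfs_anchors is None:
            raise ValueError("at least one anchor set is required")
        n_free = (len(self.hazards0.progression) if self.fit_progression else 0) + (
            len(self.hazards0.death_mult) if self.fit_death else 0
        )
        n_anchor = sum(
            len(a.anchors) - 1 for a in (self.os_anchors, self.pfs_anchors) if a is not None
        )
        if n_anchor < n_free:
            raise ValueError(f"{n_free} free parameters but only {n_anchor} anchors")


@dataclass
class CalibrationResult:
    fitted: HazardParams
    objective_value: float
    residuals: list = field(default_factory=list)  # (endpoint, time, target, simulated)
    converged: bool = False
    n_evaluations: int = 0


def _apply_vector(spec: CalibrationSpec, x: np.ndarray) -> HazardParams:
    hz = spec.hazards0
    i = 0
    if spec.fit_progression:
        k = len(hz.progression)
        hz = replace(hz, progression=tuple(x[i : i + k]))
        i += k
    if spec.fit_death:
        k = len(hz.death_mult)
        hz = replace(hz, death_mult=tuple(x[i : i + k]))
    return hz


def simulate_anchors(hazards: HazardParams, spec: CalibrationSpec) -> dict:
    """Simulated survival at each anchor time, per endpoint.

    Runs the full cohort engine and reads the curves at the anchor times
    (linear interpolation between monthly cycles).
    """
    trace = run_cohort(
        spec.arm_params, spec.general, hazards, spec.settings, background=spec.background
    )
    out = {}
    for endpoint, aset in ((OS, spec.os_anchors), (PFS, spec.pfs_anchors)):
        if aset is None:
            continue
        curve = survival_curve(trace, endpoint)
        out[endpoint] = np.array(
            [landmark_survival(curve, t) for t in aset.times[1:]]  # skip t = 0
        )
    return out


def _residuals(spec: CalibrationSpec, x: np.ndarray) -> np.ndarray:
    sim = simulate_anchors(_apply_vector(spec, x), spec)
    res = []
    for endpoint, aset in ((OS, spec.os_anchors), (PFS, spec.pfs_anchors)):
        if aset is None:
            continue
        res.append(sim[endpoint] - aset.survival[1:])
    return np.concatenate(res)


def _bounds(spec: CalibrationSpec) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    if spec.fit_progression:
        n = len(spec.hazards0.progression)
        lo += [spec.prog_bounds[0]] * n
        hi += [spec.prog_bounds[1]] * n
    if spec.fit_death:
        n = len(spec.hazards0.death_mult)
        if spec.mult_bounds is not None:
            mb = spec.mult_bounds
        else:
            cap = min(_MULT_CAP, 0.99 / max(spec.hazards0.death_base, 1e-9))
            mb = (0.0, cap)
        lo += [mb[0]] * n
        hi += [mb[1]] * n
    return np.array(lo), np.array(hi)


def _initial_vector(spec: CalibrationSpec) -> np.ndarray:
    x0 = []
    if spec.fit_progression:
        x0 += list(spec.hazards0.progression)
    if spec.fit_death:
        x0 += list(spec.hazards0.death_mult)
    return np.array(x0, dtype=float)


def calibrate(spec: CalibrationSpec) -> CalibrationResult:
    """Fit the free hazard segments to the anchors.

    Deterministic bounded least-squares with seeded multistarts; the best of
    all starts is returned.  ``converged`` reflects the optimiser's own
    termination status (or an objective below ``converged_tol``); it is never
    silently true after exhausting restarts without success.
    """
    lo, hi = _bounds(spec)
    rng = np.random.default_rng(spec.seed)
    starts = [np.clip(_initial_vector(spec), lo, hi)]
    for _ in range(max(0, spec.restarts - 1)):
        starts.append(lo + (hi - lo) * rng.random(len(lo)))

    best = None
    n_eval = 0
    for x0 in starts:
        fit = least_squares(
            lambda x: _residuals(spec, x),
            x0,
            bounds=(lo, hi),
            method="trf",
            xtol=spec.tol,
            ftol=spec.tol,
            gtol=spec.tol,
            max_nfev=spec.max_nfev,
        )
        n_eval += fit.nfev
        if best is None or fit.cost < best.cost:
            best = fit
        if 2.0 * best.cost < spec.converged_tol:
            break

    fitted = _apply_vector(spec, best.x)
    sim = simulate_anchors(fitted, spec)
    residuals = []
    for endpoint, aset in ((OS, spec.os_anchors), (PFS, spec.pfs_anchors)):
        if aset is None:
            continue
        for t, target, s in zip(aset.times[1:], aset.survival[1:], sim[endpoint]):
            residuals.append((endpoint, float(t), float(target), float(s)))
    objective = float(2.0 * best.cost)  # least_squares cost is 1/2 * sum r^2
    converged = bool(best.status > 0) or objective < spec.converged_tol
    return CalibrationResult(
        fitted=fitted,
        objective_value=objective,
        residuals=residuals,
        converged=converged,
        n_evaluations=n_eval,
    )


def calibrate_arm(
    arm: StrategyParams,
    general: GeneralParams,
    settings: ModelSettings,
    os_anchors: SurvivalAnchorSet,
    pfs_anchors: SurvivalAnchorSet,
    seed: int = 0,
    **kwargs,
) -> CalibrationResult:
    """Calibrate one arm to its OS and PFS anchor sets (convenience wrapper)."""
    spec = CalibrationSpec(
        arm_params=arm,
        general=general,
        settings=settings,
        hazards0=base_hazards(arm, settings),
        os_anchors=os_anchors,
        pfs_anchors=pfs_anchors,
        seed=seed,
        **kwargs,
    )
    return calibrate(spec)
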