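"""Calibration: conversions, self-consistency, parameter recovery, fidelity."""

import dataclasses

import numpy as np
import pytest

from pdac_cea.anchors import OS, PFS, SurvivalAnchorSet, generate_synthetic_anchors
from pdac_cea.calibration import (
    CalibrationSpec,
    UNTREATED_KNOTS,
    base_hazards,
    calibrate,
    calibrate_arm,
    median_to_monthly_prob,
    recurrence_death_blend,
    simulate_anchors,
)
from pdac_cea.engine import HazardParams


def test_median_to_monthly_probability_closed_form():
    assert median_to_monthly_prob(1.0) == pytest.approx(0.5)
    assert median_to_monthly_prob(21.0) == pytest.approx(1 - 0.5 ** (1 / 21))
    assert median_to_monthly_prob(21.0) == pytest.approx(0.03247, abs=5e-6)
    assert median_to_monthly_prob(1e9) == pytest.approx(0.0, abs=1e-8)
    with pytest.raises(ValueError):
        median_to_monthly_prob(0.0)


def test_recurrence_death_blend_mixes_both_stratifications(folfirinox):
    p = recurrence_death_blend(folfirinox)
    strata = [
        median_to_monthly_prob(m)
        for m in (21, 17, 22, 18)  # R0, R1, N0, N1 medians
    ]
    assert min(strata) < p < max(strata)
    by_margin = 0.85 * strata[0] + 0.15 * strata[1]
    by_node = 0.44 * strata[2] + 0.56 * strata[3]
    assert p == pytest.approx(0.5 * (by_margin + by_node))


def _untreated_spec(inputs, natural_history, hz, os_anchors=None, pfs_anchors=None, **kw):
    return CalibrationSpec(
        arm_params=natural_history,
        general=inputs.general,
        settings=inputs.settings,
        hazards0=hz,
        os_anchors=os_anchors,
        pfs_anchors=pfs_anchors,
        background=np.zeros(inputs.settings.horizon_cycles),
        **kw,
    )


def test_simulate_anchors_zero_hazard_and_geometric(inputs, natural_history):
    hz = HazardParams(
        knots=(0.0, 144.0), progression=(0.0,), death_mult=(0.0,), death_base=1.0
    )
    aset = SurvivalAnchorSet("x", PFS, ((0.0, 1.0), (12.0, 0.4), (60.0, 0.1)))
    spec = _untreated_spec(inputs, natural_history, hz, pfs_anchors=aset)
    assert np.allclose(simulate_anchors(hz, spec)[PFS], 1.0)

    hz2 = dataclasses.replace(hz, progression=(0.5,))
    aset2 = SurvivalAnchorSet("x", PFS, ((0.0, 1.0), (2.0, 0.3)))
    spec2 = _untreated_spec(
        inputs, natural_history, hz2, pfs_anchors=aset2, fit_death=False
    )
    assert simulate_anchors(hz2, spec2)[PFS][0] == pytest.approx(0.25)


def test_engine_agrees_with_synthetic_fixture_when_noiseless(inputs, natural_history):
    """The engine's progression-free curve equals the closed-form fixture."""
    knots, probs = (0.0, 24.0, 144.0), (0.08, 0.03)
    times = (6.0, 24.0, 60.0, 120.0)
    fixture = generate_synthetic_anchors(knots, probs, times, noise_sd=0.0)
    hz = HazardParams(knots=knots, progression=probs, death_mult=(0.0, 0.0), death_base=1.0)
    aset = SurvivalAnchorSet("x", PFS, fixture.anchors)
    spec = _untreated_spec(inputs, natural_history, hz, pfs_anchors=aset)
    sim = simulate_anchors(hz, spec)[PFS]
    np.testing.assert_allclose(sim, fixture.survival[1:], atol=1e-9)


def test_single_segment_single_anchor_recovers_exponential_rate(inputs, natural_history):
    hz = HazardParams(knots=(0.0, 144.0), progression=(0.2,), death_mult=(0.0,), death_base=1.0)
    aset = SurvivalAnchorSet("x", PFS, ((0.0, 1.0), (12.0, 0.5)))
    spec = _untreated_spec(
        inputs, natural_history, hz, pfs_anchors=aset, fit_death=False, restarts=2
    )
    res = calibrate(spec)
    assert res.converged
    assert res.fitted.progression[0] == pytest.approx(1 - 0.5 ** (1 / 12), abs=1e-6)
    assert res.fitted.progression[0] == pytest.approx(0.0561, abs=5e-4)


def _oracle_illness_death(progs, deaths, knots, horizon):
    """Independent discrete recursion for the untreated structure, no
    background mortality: progression-free -> progressed -> dead."""
    seg = np.searchsorted(np.asarray(knots), np.arange(horizon), side="right") - 1
    seg = np.clip(seg, 0, len(progs) - 1)
    pf, prog, dead = 1.0, 0.0, 0.0
    os_curve, pfs_curve = [1.0], [1.0]
    for t in range(horizon):
        p, d = progs[seg[t]], deaths[seg[t]]
        prog_new = prog * (1 - d) + pf * p
        dead += prog * d
        pf *= 1 - p
        prog = prog_new
        os_curve.append(pf + prog)
        pfs_curve.append(pf)
    return np.array(os_curve), np.array(pfs_curve)


def _recovery_case(inputs, natural_history, rng, times=(6.0, 24.0, 60.0, 120.0)):
    # hazard ranges keep the curves from underflowing at the latest anchor,
    # so every segment stays identifiable from the anchor grid
    knots = UNTREATED_KNOTS
    progs = rng.uniform(0.01, 0.06, size=3)
    deaths = rng.uniform(0.03, 0.15, size=3)
    os_curve, pfs_curve = _oracle_illness_death(
        progs, deaths, knots, inputs.settings.horizon_cycles
    )
    months = np.arange(len(os_curve))
    os_a = SurvivalAnchorSet(
        "x", OS, ((0.0, 1.0),) + tuple((t, float(np.interp(t, months, os_curve))) for t in times)
    )
    pfs_a = SurvivalAnchorSet(
        "x", PFS, ((0.0, 1.0),) + tuple((t, float(np.interp(t, months, pfs_curve))) for t in times)
    )
    hz0 = HazardParams(
        knots=knots, progression=(0.05,) * 3, death_mult=(0.1,) * 3, death_base=1.0
    )
    spec = _untreated_spec(
        inputs,
        natural_history,
        hz0,
        os_anchors=os_a,
        pfs_anchors=pfs_a,
        restarts=1,
        mult_bounds=(0.0, 0.9),
    )
    return progs, deaths, spec


def test_noiseless_anchors_recover_known_hazards_exactly(inputs, natural_history):
    rng = np.random.default_rng(2024)
    progs, deaths, spec = _recovery_case(inputs, natural_history, rng)
    res = calibrate(spec)
    assert res.objective_value < 1e-8
    np.testing.assert_allclose(res.fitted.progression, progs, atol=1e-4)
    np.testing.assert_allclose(res.fitted.death_mult, deaths, atol=1e-4)


def test_more_anchors_reduce_error_under_noise(inputs, natural_history):
    """With anchor noise (sd 0.02), median recovery error shrinks when the
    anchor grid is refined from 4 to 8 time points."""
    errors = {4: [], 8: []}
    grids = {
        4: (6.0, 24.0, 60.0, 120.0),
        8: (6.0, 12.0, 24.0, 36.0, 60.0, 84.0, 108.0, 120.0),
    }
    for rep in range(20):
        for n, times in grids.items():
            progs, deaths, spec = _recovery_case(
                inputs, natural_history, np.random.default_rng(100 + rep), times=times
            )
            noise_rng = np.random.default_rng(500 + rep)
            for aset_name in ("os_anchors", "pfs_anchors"):
                aset = getattr(spec, aset_name)
                s = np.clip(
                    aset.survival[1:] + noise_rng.normal(0, 0.02, len(aset.survival) - 1),
                    0.0,
                    1.0,
                )
                s = np.minimum.accumulate(s)
                setattr(
                    spec,
                    aset_name,
                    SurvivalAnchorSet(
                        aset.arm, aset.endpoint, ((0.0, 1.0),) + tuple(zip(aset.times[1:], s))
                    ),
                )
            res = calibrate(spec)
            errors[n].extend(
                np.abs(np.concatenate([res.fitted.progression, res.fitted.death_mult])
                       - np.concatenate([progs, deaths]))
            )
    assert np.median(errors[8]) < np.median(errors[4])


def test_objective_zero_iff_residuals_zero(inputs, natural_history):
    rng = np.random.default_rng(3)
    _, _, spec = _recovery_case(inputs, natural_history, rng)
    res = calibrate(spec)
    devs = [sim - target for _, _, target, sim in res.residuals]
    assert res.objective_value == pytest.approx(np.sum(np.square(devs)))
    assert (res.objective_value < 1e-12) == np.allclose(devs, 0.0, atol=1e-7)


def test_calibration_is_deterministic(inputs, folfirinox):
    from pdac_cea.anchors import build_anchor_set

    kw = dict(
        os_anchors=build_anchor_set("FOLFIRINOX", OS),
        pfs_anchors=build_anchor_set("FOLFIRINOX", PFS),
    )
    r1 = calibrate_arm(folfirinox, inputs.general, inputs.settings, seed=11, **kw)
    r2 = calibrate_arm(folfirinox, inputs.general, inputs.settings, seed=11, **kw)
    assert r1.fitted == r2.fitted
    assert r1.objective_value == r2.objective_value


def test_underdetermined_spec_rejected(inputs, natural_history):
    hz = base_hazards(natural_history, inputs.settings)
    one_anchor = SurvivalAnchorSet("x", OS, ((0.0, 1.0), (12.0, 0.5)))
    with pytest.raises(ValueError):
        CalibrationSpec(
            arm_params=natural_history,
            general=inputs.general,
            settings=inputs.settings,
            hazards0=hz,
            os_anchors=one_anchor,
        )


def test_calibrated_untreated_arm_is_dominated_in_survival(base_run):
    """From the end of the neoadjuvant phase on, untreated overall survival
    never exceeds either treated arm's (during the first months the treated
    arms carry extra dropout mortality, so the curves may cross there)."""
    from pdac_cea.engine import survival_curve

    nh = survival_curve(base_run.traces["Natural history"], OS)
    for arm in ("FOLFIRINOX", "G-nP"):
        treated = survival_curve(base_run.traces[arm], OS)
        assert np.all(treated[6:] >= nh[6:] - 1e-9)
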