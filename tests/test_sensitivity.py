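"""One-way DSA, PSA distributions and sampling, scenario overrides."""

import dataclasses

import numpy as np
import pytest

from pdac_cea.params import ARM_FOLFIRINOX, ARM_GNP, ARM_NATURAL_HISTORY, Param
from pdac_cea.pipeline import ModelInputs
from pdac_cea.sensitivity import (
    DOMINATED,
    ScenarioOverrides,
    build_distribution_specs,
    fit_distribution,
    one_way_dsa,
    pairwise_icer,
    run_psa,
    run_scenario,
)


# ---------------------------------------------------------------------------
# distributions


def test_beta_fit_is_anchored_at_base_with_range_spread():
    """R0-style probability with range (0.40, 0.88): the fitted beta's mean
    sits at the base value and its spread reflects the declared interval."""
    spec = fit_distribution("r0_rate", 0.85, 0.40, 0.88)
    assert spec.family == "beta"
    a, b = spec.args
    assert a / (a + b) == pytest.approx(0.85, abs=1e-9)
    sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    assert sd == pytest.approx((0.88 - 0.40) / 3.92, abs=1e-9)


def test_degenerate_range_is_point_mass():
    spec = fit_distribution("x", 0.5, 0.5, 0.5)
    assert spec.family == "point"
    rng = np.random.default_rng(0)
    assert np.all(spec.sample(rng, size=10) == 0.5)


def test_utility_samples_stay_in_unit_interval():
    spec = fit_distribution("utility", 0.73, 0.62, 0.80)
    rng = np.random.default_rng(1)
    x = spec.sample(rng, size=5000)
    assert np.all((x >= 0) & (x <= 1))


def test_disutility_samples_are_negative_magnitudes():
    spec = fit_distribution("disutility", -0.12, -0.19, -0.05)
    rng = np.random.default_rng(2)
    x = spec.sample(rng, size=5000)
    assert np.all(x <= 0)
    assert np.mean(x) == pytest.approx(-0.12, abs=0.01)


def test_cost_fit_uses_gamma_anchored_at_base():
    spec = fit_distribution("cost", 29580.0, 15000.0, 41000.0)
    assert spec.family == "gamma"
    shape, scale = spec.args
    assert shape * scale == pytest.approx(29580.0, rel=1e-9)
    assert np.sqrt(shape) * scale == pytest.approx((41000.0 - 15000.0) / 3.92, rel=1e-9)


def test_range_must_bracket_base():
    with pytest.raises(ValueError):
        fit_distribution("x", 0.9, 0.1, 0.5)


# ---------------------------------------------------------------------------
# one-way DSA


@pytest.fixture(scope="module")
def tornado(base_run):
    return one_way_dsa(base_run, wtp=100_000.0)


def test_tornado_covers_every_ranged_parameter(tornado, inputs):
    from pdac_cea.params import iter_ranged_params

    n = sum(1 for _ in iter_ranged_params(inputs.general, inputs.strategies))
    assert len(tornado) == n
    assert all(e.span >= 0 or e.span == float("inf") for e in tornado)
    spans = [e.span for e in tornado if np.isfinite(e.span)]
    assert spans == sorted(spans, reverse=True)


def test_zero_width_range_has_zero_span(base_run):
    inputs = base_run.inputs
    frozen = inputs.strategy(ARM_FOLFIRINOX)
    frozen = dataclasses.replace(frozen, cost_chemo_cycle=Param(863.5, 863.5, 863.5))
    strategies = [frozen if s.name == ARM_FOLFIRINOX else s for s in inputs.strategies]
    run = dataclasses.replace(
        base_run, inputs=ModelInputs(inputs.general, strategies, inputs.settings)
    )
    entries = one_way_dsa(run, wtp=100_000.0)
    entry = next(e for e in entries if e.parameter == "FOLFIRINOX.cost_chemo_cycle")
    assert entry.span == pytest.approx(0.0, abs=1e-9)


def test_icer_monotone_in_own_cost(tornado):
    """Raising a strategy's own cost can only raise its pairwise ICER."""
    for name in ("FOLFIRINOX.cost_chemo_cycle", "FOLFIRINOX.cost_second_line_month"):
        e = next(x for x in tornado if x.parameter == name)
        low = -np.inf if isinstance(e.icer_at_low, str) else e.icer_at_low
        high = np.inf if isinstance(e.icer_at_high, str) and e.icer_at_high == DOMINATED else e.icer_at_high
        assert low <= high or isinstance(e.icer_at_high, str)


def test_unanchored_neoadjuvant_mortality_is_inert(tornado):
    """The 30-day neoadjuvant mortality is embedded in the calibrated early
    hazards, so its one-way excursion moves nothing."""
    e = next(x for x in tornado if x.parameter == "general.neoadjuvant_30day_mortality")
    assert e.span == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# PSA


def test_point_mass_psa_reproduces_base_case(base_run):
    from pdac_cea.params import iter_ranged_params
    from pdac_cea.sensitivity import DistributionSpec

    inputs = base_run.inputs
    specs = [
        DistributionSpec(label, "point", (p.base,), stream=i)
        for i, (_, _, label, p) in enumerate(
            iter_ranged_params(inputs.general, inputs.strategies)
        )
    ]
    res = run_psa(base_run, specs, iterations=3, seed=5)
    for j, name in enumerate(res.strategies):
        assert np.allclose(res.costs[:, j], base_run.outcomes[name].total_cost, rtol=1e-12)
        assert np.allclose(res.qalys[:, j], base_run.outcomes[name].qalys, rtol=1e-12)


def test_same_seed_gives_bitwise_identical_ceac(base_run):
    r1 = run_psa(base_run, iterations=40, seed=9)
    r2 = run_psa(base_run, iterations=40, seed=9)
    assert r1.ceac.equals(r2.ceac)
    assert np.array_equal(r1.costs, r2.costs)


def test_ceac_shares_sum_to_one_and_better_arm_share_rises(base_run):
    """Shares sum to one; with only costs sampled (QALY ordering fixed, the
    two-strategy restriction where the claim holds), the acceptance share of
    the costlier-but-more-effective arm is monotone in willingness-to-pay."""
    from pdac_cea.params import iter_ranged_params
    from pdac_cea.sensitivity import DistributionSpec

    inputs = base_run.inputs
    specs = []
    for i, (_, field_name, label, p) in enumerate(
        iter_ranged_params(inputs.general, inputs.strategies)
    ):
        if field_name.startswith("cost_"):
            specs.append(fit_distribution(label, p.base, p.low, p.high, stream=i))
        else:
            specs.append(DistributionSpec(label, "point", (p.base,), stream=i))
    res = run_psa(base_run, specs, iterations=150, seed=13)
    np.testing.assert_allclose(res.ceac.sum(axis=1), 1.0, atol=1e-12)
    i_f = res.strategies.index(ARM_FOLFIRINOX)
    i_g = res.strategies.index(ARM_GNP)
    shares = []
    for w in res.wtp_grid:
        nmb_f = res.qalys[:, i_f] * w - res.costs[:, i_f]
        nmb_g = res.qalys[:, i_g] * w - res.costs[:, i_g]
        shares.append(np.mean(nmb_f > nmb_g))
    assert np.all(np.diff(shares) >= -1e-12)


def test_shrinking_ranges_converge_to_base_case(base_run):
    """PSA means approach the base-case point as ranges shrink toward base."""
    inputs = base_run.inputs
    gaps = []
    for shrink in (1.0, 0.3, 0.05):
        general = inputs.general
        strategies = []
        shrunk_general = {}
        for f in dataclasses.fields(general):
            p = getattr(general, f.name)
            shrunk_general[f.name] = Param(
                p.base, p.base - shrink * (p.base - p.low), p.base + shrink * (p.high - p.base)
            )
        general = dataclasses.replace(general, **shrunk_general)
        for s in inputs.strategies:
            if not s.treated:
                strategies.append(s)
                continue
            upd = {}
            for f in dataclasses.fields(s):
                p = getattr(s, f.name)
                if isinstance(p, Param):
                    upd[f.name] = Param(
                        p.base,
                        p.base - shrink * (p.base - p.low),
                        p.base + shrink * (p.high - p.base),
                    )
            strategies.append(dataclasses.replace(s, **upd))
        shrunk_inputs = ModelInputs(general, strategies, inputs.settings)
        run = dataclasses.replace(base_run, inputs=shrunk_inputs)
        res = run_psa(run, iterations=120, seed=21)
        gap = 0.0
        for j, name in enumerate(res.strategies):
            gap += abs(np.nanmean(res.costs[:, j]) - base_run.outcomes[name].total_cost)
        gaps.append(gap)
    assert gaps[2] < gaps[1] < gaps[0]


# ---------------------------------------------------------------------------
# scenarios


def test_empty_overrides_reproduce_base_case(base_run):
    res = run_scenario(base_run.inputs, ScenarioOverrides(name="noop"), seed=1)
    for name, out in base_run.outcomes.items():
        assert res.outcomes[name].total_cost == pytest.approx(out.total_cost)
        assert res.outcomes[name].qalys == pytest.approx(out.qalys)


def test_r0_override_passes_through_to_output(base_run):
    ov = ScenarioOverrides(name="r0", strategies={ARM_FOLFIRINOX: {"r0_rate": 0.88}})
    res = run_scenario(base_run.inputs, ov, seed=1)
    assert res.outcomes[ARM_FOLFIRINOX].r0_fraction == pytest.approx(0.88, abs=1e-9)


def test_unknown_override_key_raises(base_run):
    with pytest.raises(KeyError):
        run_scenario(
            base_run.inputs, ScenarioOverrides(strategies={ARM_FOLFIRINOX: {"bogus": 1}})
        )
    with pytest.raises(KeyError):
        run_scenario(base_run.inputs, ScenarioOverrides(general={"bogus": 1}))


def test_raising_survival_anchors_never_lowers_qalys(base_run):
    """Better prognosis (every anchor's survival raised) cannot reduce the
    affected arm's QALYs."""
    from pdac_cea.anchors import OS, PFS, SurvivalAnchorSet, build_anchor_set

    lifted = []
    for endpoint in (OS, PFS):
        aset = build_anchor_set(ARM_FOLFIRINOX, endpoint)
        pts = [(0.0, 1.0)] + [
            (t, min(1.0, s + 0.05)) for t, s in aset.anchors[1:]
        ]
        lifted.append(SurvivalAnchorSet(ARM_FOLFIRINOX, endpoint, tuple(pts)))
    res = run_scenario(
        base_run.inputs, ScenarioOverrides(name="lifted", anchors=tuple(lifted)), seed=1
    )
    assert res.outcomes[ARM_FOLFIRINOX].qalys >= base_run.outcomes[ARM_FOLFIRINOX].qalys - 1e-6


def test_pairwise_icer_dominance_flags():
    from tests.test_economics import _outcome

    a, b = _outcome("a", 100.0, 1.0), _outcome("b", 50.0, 2.0)
    assert pairwise_icer(a, b) == "dominant"
    assert pairwise_icer(b, a) == DOMINATED
    c = _outcome("c", 150.0, 2.0)
    assert pairwise_icer(a, c) == pytest.approx(50.0)
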