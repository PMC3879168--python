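"""Model core: parameters, scenarios, right-hand side, observables."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitoswitch import (
    G2_INIT,
    METAPHASE_INIT,
    ModelParameters,
    ModelState,
    SCENARIOS,
    effective_rates,
    make_scenario,
    observables,
    rhs,
)
from mitoswitch.model import state_bounds, validate_state

from conftest import random_valid_states
from _reference import rhs_reference

PUBLISHED_DEFAULTS = {
    "CycT": 1.0, "Va25": 2.0, "Vi25": 2.0, "Vawee": 2.0, "Viwee": 2.0,
    "kagwl": 10.0, "kigwl_p": 0.02, "kigwl_pp": 0.0, "kigwl": 2.0,
    "kaensa": 2.0, "kiensa": 0.6, "kas": 100.0, "kdis": 1.0,
    "Cdc25T": 1.0, "Wee1T": 1.0, "GwlT": 1.0, "ENSAT": 1.0, "PP2T": 0.5,
    "k25_p": 0.01, "k25_pp": 1.0, "kwee_p": 0.01, "kwee_pp": 1.0,
    "RO": 0.0, "OA": 0.0,
}


def test_default_preset_is_published_parameter_set(defaults):
    assert dataclasses.asdict(defaults) == PUBLISHED_DEFAULTS


@pytest.mark.parametrize("cdc25, wee1, expected_k25, expected_kwee", [
    (0.0, 1.0, 0.01, 1.0),    # G2: basal Cdc25, fully active Wee1
    (1.0, 0.0, 1.0, 0.01),    # mitosis: active Cdc25, phosphorylated Wee1
])
def test_effective_rates_examples(defaults, cdc25, wee1, expected_k25, expected_kwee):
    state = ModelState(0.0, cdc25, wee1, 0.0, 0.0, 0.5)
    k25, kwee = effective_rates(state, defaults)
    assert k25 == pytest.approx(expected_k25)
    assert kwee == pytest.approx(expected_kwee)


@given(cdc25=st.floats(0.0, 1.0), c=st.floats(0.001, 5.0))
def test_effective_rates_collapse_when_activities_equal(cdc25, c):
    # with equal basal and activated catalytic constants the effective
    # rate is independent of the phosphorylation state of the regulator
    p = ModelParameters(k25_p=c, k25_pp=c)
    k25, _ = effective_rates(np.array([0, cdc25, 1, 0, 0, 0.5]), p)
    assert k25 == pytest.approx(c * p.Cdc25T)


def test_rhs_at_g2_initial_condition(defaults):
    # only the basal Cdc25 activity moves the system out of G2
    d = rhs(0.0, G2_INIT.as_array(), defaults)
    np.testing.assert_allclose(d, [0.01, 0, 0, 0, 0, 0], atol=1e-15)


def test_rhs_pure_complex_release_term(defaults):
    # with all free PP2A sequestered and nothing phosphorylated, the only
    # flux is complex dissociation: (kdis + kiensa) * PP2T = 1.6 * 0.5
    d = rhs(0.0, np.zeros(6), defaults)
    assert d[5] == pytest.approx(0.8)


@given(pp2=st.floats(0.0, 0.5), mpf=st.floats(0.0, 1.0))
def test_rhs_association_term_vanishes_when_free_ensap_zero(defaults, pp2, mpf):
    # ENSAPt equal to the bound complex means no free phospho-ENSA, so
    # the PP2 derivative reduces to the release term alone
    y = np.array([mpf, 0.3, 0.4, 0.2, defaults.PP2T - pp2, pp2])
    d = rhs(0.0, y, defaults)
    assert d[5] == pytest.approx(
        (defaults.kdis + defaults.kiensa) * (defaults.PP2T - pp2))


def test_rhs_matches_independent_transcription(defaults):
    # two-implementor oracle at 100 random valid states, all scenarios
    for label in SCENARIOS:
        p = make_scenario(label, RO=2.0, OA=3.0)
        for y in random_valid_states(p, 100):
            np.testing.assert_allclose(
                rhs(0.0, y, p), rhs_reference(y, p), rtol=0, atol=1e-12)


def test_rhs_rejects_non_finite_state(defaults):
    y = G2_INIT.as_array()
    y[0] = np.nan
    with pytest.raises(FloatingPointError):
        rhs(0.0, y, defaults)


@pytest.mark.parametrize("state_kw, params_kw, field, expected", [
    ({"MPF": 0.96}, {"RO": 100.0}, "MPFa", 0.96 / 101),
    ({"PP2": 0.5}, {}, "PP2a", 0.5),
    ({"MPF": 0.96}, {}, "preMPF", 0.04),
    ({"PP2": 0.1}, {}, "complex", 0.4),
])
def test_observables_examples(state_kw, params_kw, field, expected):
    base = {"MPF": 0.0, "Cdc25": 0.0, "Wee1": 1.0, "Gwl": 0.0,
            "ENSAPt": 0.0, "PP2": 0.5}
    obs = observables(ModelState(**{**base, **state_kw}),
                      ModelParameters(**params_kw))
    assert getattr(obs, field) == pytest.approx(expected)


@given(ro1=st.floats(0.0, 200.0), ro2=st.floats(0.0, 200.0))
def test_inhibitor_dose_monotonicity(ro1, ro2):
    # active fractions strictly decrease with dose at fixed state
    state = METAPHASE_INIT
    m1 = observables(state, ModelParameters(RO=ro1)).MPFa
    m2 = observables(state, ModelParameters(RO=ro2)).MPFa
    if ro1 < ro2:
        assert m1 > m2
    p1 = observables(state, ModelParameters(OA=ro1)).PP2a
    p2 = observables(state, ModelParameters(OA=ro2)).PP2a
    if ro1 < ro2:
        assert p1 > p2


@pytest.mark.parametrize("label, expected", [
    ("pp2a_b55", {"kigwl": 2.0, "kigwl_p": 0.02, "kigwl_pp": 0.0}),
    ("oa_insensitive", {"kigwl": 0.0, "kigwl_p": 2.0, "kigwl_pp": 0.0}),
    ("oa_sensitive", {"kigwl": 0.0, "kigwl_p": 0.02, "kigwl_pp": 2.0}),
])
def test_scenario_presets(label, expected):
    p = make_scenario(label)
    for key, val in expected.items():
        assert getattr(p, key) == val
    # non-listed parameters keep the published defaults
    assert (p.kagwl, p.kaensa, p.PP2T) == (10.0, 2.0, 0.5)


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError, match="unknown scenario"):
        make_scenario("fcp1")


def test_parameter_validation():
    with pytest.raises(ValueError, match="finite and >= 0"):
        ModelParameters(kagwl=-1.0)
    with pytest.raises(ValueError, match="substoichiometric"):
        ModelParameters(PP2T=1.2)


def test_config_roundtrip_lossless():
    p = make_scenario("oa_sensitive", RO=25.0, OA=100.0, kagwl=3.5)
    assert ModelParameters.from_config(p.to_config()) == p


def test_config_accepts_primed_aliases():
    text = "kigwl' = 2\nkigwl = 0\nk25'' = 0.7\n"
    p = ModelParameters.from_config(text)
    assert (p.kigwl_p, p.kigwl, p.k25_pp) == (2.0, 0.0, 0.7)
    with pytest.raises(ValueError, match="unknown parameter"):
        ModelParameters.from_config("nosuch = 1\n")


def test_state_validation_hard_fail_and_clamp(defaults):
    bad = np.array([1.5, 0, 1, 0, 0, 0.5])  # MPF above CycT
    with pytest.raises(ValueError, match="outside admissible box"):
        validate_state(bad, defaults)
    clamped = validate_state(bad, defaults, clamp=True)
    lo, hi = state_bounds(defaults)
    assert np.all(clamped >= lo) and np.all(clamped <= hi)
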