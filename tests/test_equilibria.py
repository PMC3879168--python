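"""Steady states, stability classification and fold structure."""

import numpy as np
import pytest

from mitoswitch import (
    G2_INIT,
    METAPHASE_INIT,
    ModelParameters,
    balance_curve,
    find_all_equilibria,
    find_steady_state,
    integrate,
    is_bistable,
    make_scenario,
)
from mitoswitch.equilibria import ConvergenceError, jacobian_fd


def test_mitotic_steady_state_default_variant(defaults):
    # the PP2A/B55 variant's high-activity state: Cdk1 mostly active,
    # Cdc25 on, Wee1 off, Gwl almost fully phosphorylated
    eq = find_steady_state(defaults, METAPHASE_INIT)
    assert eq.stability == "stable"
    assert eq.residual < 1e-10
    np.testing.assert_allclose(
        eq.state, [0.9645, 0.9739, 0.0261, 0.9926, 0.7679, 0.0258], atol=5e-4)


def test_printed_metaphase_state_is_oa_sensitive_steady_state():
    # the published metaphase coordinates coincide (at their printed
    # precision) with the mitotic steady state of the OA-sensitive
    # Gwl-phosphatase variant, not the default PP2A/B55 one
    eq = find_steady_state(make_scenario("oa_sensitive"), METAPHASE_INIT)
    assert abs(eq.state[3] - 0.9) < 0.05
    assert abs(eq.state[4] - 0.75) < 0.005
    # whereas the default variant's Gwl coordinate rounds to 1.0
    eq_b55 = find_steady_state(ModelParameters(), METAPHASE_INIT)
    assert eq_b55.state[3] > 0.95


def test_zero_cyclin_b_closed_form_steady_state():
    # with no Cyclin B nothing is phosphorylated: the unique steady
    # state is (0, 0, Wee1T, 0, 0, PP2T), stable
    p = ModelParameters(CycT=0.0)
    eqs = find_all_equilibria(p)
    assert len(eqs) == 1
    np.testing.assert_allclose(eqs[0].state, [0, 0, 1, 0, 0, 0.5], atol=1e-9)
    assert eqs[0].stability == "stable"


def test_jacobian_matches_symbolic_derivative(defaults):
    # finite-difference Jacobian validated against a sympy derivation
    # of the equations, at the mitotic steady state and a generic point
    import sympy as sp

    MPF, Cdc25, Wee1, Gwl, ENSAPt, PP2 = sp.symbols(
        "MPF Cdc25 Wee1 Gwl ENSAPt PP2")
    p = defaults
    MPFa = MPF / (1 + p.RO)
    PP2a = PP2 / (1 + p.OA)
    k25 = p.k25_p * (p.Cdc25T - Cdc25) + p.k25_pp * Cdc25
    kwee = p.kwee_p * (p.Wee1T - Wee1) + p.kwee_pp * Wee1
    exprs = sp.Matrix([
        k25 * (p.CycT - MPF) - kwee * MPF,
        p.Va25 * MPFa * (p.Cdc25T - Cdc25) - p.Vi25 * PP2a * Cdc25,
        p.Vawee * PP2a * (p.Wee1T - Wee1) - p.Viwee * MPFa * Wee1,
        p.kagwl * MPFa * (p.GwlT - Gwl)
        - (p.kigwl_p + p.kigwl_pp * p.PP2T / (1 + p.OA) + p.kigwl * PP2a) * Gwl,
        p.kaensa * Gwl * (p.ENSAT - ENSAPt) - p.kiensa * ENSAPt,
        -p.kas * (ENSAPt - (p.PP2T - PP2)) * PP2
        + (p.kdis + p.kiensa) * (p.PP2T - PP2),
    ])
    variables = (MPF, Cdc25, Wee1, Gwl, ENSAPt, PP2)
    jac_fn = sp.lambdify(variables, exprs.jacobian(variables), "numpy")
    for y in (METAPHASE_INIT.as_array(),
              np.array([0.3, 0.4, 0.6, 0.5, 0.45, 0.2])):
        np.testing.assert_allclose(jacobian_fd(y, p),
                                   np.array(jac_fn(*y), dtype=float),
                                   rtol=1e-6, atol=1e-6)


def test_nonconvergence_reported():
    # a hopeless guess far outside any basin structure cannot satisfy
    # the residual contract silently
    p = ModelParameters()
    with pytest.raises(ConvergenceError):
        find_steady_state(p, np.full(6, 1e6), tol=1e-30)


@pytest.fixture(scope="module")
def default_branch():
    return balance_curve(ModelParameters(), grid=np.linspace(0, 1, 51))


class TestBalanceCurve:
    def test_two_folds_bound_the_bistable_window(self, default_branch):
        br = default_branch
        assert len(br.folds) == 2
        lo, hi = br.bistable_window()
        assert br.folds[0] < lo < hi < br.folds[1]

    def test_equilibrium_counts_change_by_two_at_folds(self, default_branch):
        counts = default_branch.counts()
        changes = np.abs(np.diff(counts))
        assert set(changes) <= {0, 2}
        assert np.count_nonzero(changes) == 2

    def test_window_structure_two_stable_one_unstable(self, default_branch):
        br = default_branch
        for value, eqs in zip(br.grid, br.equilibria):
            stable = sum(e.is_stable for e in eqs)
            if br.folds[0] < value < br.folds[1]:
                assert (len(eqs), stable) == (3, 2)
            elif not np.isclose(value, br.folds).any():
                assert (len(eqs), stable) == (1, 1)

    def test_branch_agrees_with_long_integration(self, default_branch):
        # both basins' long-time endpoints match the reported stable
        # equilibria (independent integration oracle)
        br = default_branch
        inside = [i for i, v in enumerate(br.grid)
                  if br.folds[0] + 0.01 < v < br.folds[1] - 0.01]
        for i in inside[:3]:
            p = ModelParameters(CycT=float(br.grid[i]))
            stable = sorted((e.state for e in br.equilibria[i] if e.is_stable),
                            key=lambda s: s[0])
            lo = integrate(p, G2_INIT.as_array() * [0, 0, 1, 0, 0, 1],
                           500, output_step=500).states[-1]
            hi = integrate(p, np.array([p.CycT, 1, 0, 1, 1 - 1e-9, 0]),
                           500, output_step=500).states[-1]
            np.testing.assert_allclose(lo, stable[0], atol=1e-6)
            np.testing.assert_allclose(hi, stable[1], atol=1e-6)


def test_stable_state_persists_unstable_state_departs(defaults):
    p = defaults.replace(CycT=0.12)  # inside the bistable window
    eqs = find_all_equilibria(p)
    stable = [e for e in eqs if e.is_stable]
    saddle = [e for e in eqs if e.stability == "unstable"]
    assert len(stable) == 2 and len(saddle) == 1
    for eq in stable:
        traj = integrate(p, eq.state, 100, output_step=10)
        assert np.max(np.abs(traj.states - eq.state)) < 1e-6
    # nudge off the saddle along its unstable eigenvector: departs
    J = jacobian_fd(saddle[0].state, p)
    w, v = np.linalg.eig(J)
    direction = np.real(v[:, np.argmax(w.real)])
    y0 = np.clip(saddle[0].state + 1e-4 * direction, 0, None)
    traj = integrate(p, y0, 100, output_step=10)
    assert np.max(np.abs(traj.states[-1] - saddle[0].state)) > 1e-2


def test_pp2a_b55_feedback_widens_bistable_range():
    # the extra Gwl<->PP2A/B55 double-negative loop extends the range of
    # total Cyclin B over which both states coexist
    widths = {}
    for label in ("pp2a_b55", "oa_insensitive"):
        br = balance_curve(make_scenario(label), grid=np.linspace(0, 1, 51))
        assert len(br.folds) == 2
        widths[label] = br.folds[1] - br.folds[0]
    assert widths["pp2a_b55"] >= widths["oa_insensitive"]


def test_gwl_activation_rate_zero_is_monostable():
    # without Cdk1-dependent Gwl phosphorylation the ENSA brake never
    # engages and the switch collapses to a single branch
    assert not is_bistable(ModelParameters(kagwl=0.0),
                           grid=np.linspace(0, 1, 21))


def test_invalid_grid_rejected(defaults):
    with pytest.raises(ValueError, match="strictly increasing"):
        balance_curve(defaults, grid=np.array([0.5, 0.2]))
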