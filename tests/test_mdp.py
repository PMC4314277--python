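"""Single-model backward induction against independent oracles."""

import numpy as np
import pytest

from infovalue import (
    ActionSpace,
    ConfigurationError,
    DynamicsModel,
    InstanceTooLargeError,
    ModelValidationError,
    NonStochasticRowError,
    Policy,
    SolverConfig,
    StateSpace,
    brute_force_value,
    evaluate_policy,
    solve_model,
)
from infovalue.fixtures import toy_a

from _oracles import mc_policy_value


def test_horizon_one_optimum_is_best_immediate_return():
    m = toy_a()
    vf, pol = solve_model(m, SolverConfig(horizon=1))
    np.testing.assert_allclose(vf.initial, m.returns.max(axis=1))
    np.testing.assert_array_equal(pol.actions[0], m.returns.argmax(axis=1))


def test_horizon_two_value_matches_hand_bellman():
    m = toy_a()
    vf, _ = solve_model(m, SolverConfig(horizon=2))
    v1 = m.returns.max(axis=1)
    q0 = m.returns + np.einsum("xay,y->xa", m.kernel, v1)
    np.testing.assert_allclose(vf.initial, q0.max(axis=1), atol=1e-12)


def test_solver_matches_brute_force_enumeration():
    m = toy_a()
    cfg = SolverConfig(horizon=3)
    vf, _ = solve_model(m, cfg)
    np.testing.assert_allclose(vf.initial, brute_force_value(m, cfg), atol=1e-12)


def test_policy_evaluation_matches_monte_carlo():
    m = toy_a()
    cfg = SolverConfig(horizon=4)
    vf, pol = solve_model(m, cfg)
    exact = evaluate_policy(m, pol, cfg).initial[0]
    mean, se = mc_policy_value(
        m.kernel, m.returns, pol.actions, 0, cfg.horizon, np.random.default_rng(7)
    )
    assert abs(mean - exact) < 5 * se + 1e-6


def test_tie_break_prefers_lowest_action_index():
    states = StateSpace(("s0",))
    actions = ActionSpace(("a0", "a1"))
    kernel = np.ones((1, 2, 1))
    returns = np.array([[1.0, 1.0]])
    m = DynamicsModel(states, actions, kernel, returns)
    _, pol = solve_model(m, SolverConfig(horizon=3))
    assert (pol.actions == 0).all()


def test_terminal_values_enter_the_recursion():
    m = toy_a()
    terminal = np.array([5.0, -1.0])
    vf, _ = solve_model(m, SolverConfig(horizon=1), terminal=terminal)
    q = m.returns + np.einsum("xay,y->xa", m.kernel, terminal)
    np.testing.assert_allclose(vf.initial, q.max(axis=1))
    np.testing.assert_allclose(vf.values[1], terminal)


def test_discount_scales_future_returns():
    m = toy_a()
    vf, _ = solve_model(m, SolverConfig(horizon=2, discount=0.5))
    v1 = m.returns.max(axis=1)
    q0 = m.returns + 0.5 * np.einsum("xay,y->xa", m.kernel, v1)
    np.testing.assert_allclose(vf.initial, q0.max(axis=1))


def test_admissibility_mask_restricts_maximisation():
    base = toy_a()
    mask = np.array([[True, False], [True, True]])
    actions = ActionSpace(("light", "heavy"), admissible=mask)
    m = DynamicsModel(base.states, actions, base.kernel, base.returns)
    _, pol = solve_model(m, SolverConfig(horizon=3))
    assert (pol.actions[:, 0] == 0).all()


def test_non_stochastic_row_names_state_and_action():
    bad = toy_a().kernel.copy()
    bad[1, 0] = [0.4, 0.4]
    with pytest.raises(NonStochasticRowError, match="'high'.*'light'"):
        DynamicsModel(toy_a().states, toy_a().actions, bad, toy_a().returns)


def test_shape_validation():
    m = toy_a()
    with pytest.raises(ModelValidationError):
        DynamicsModel(m.states, m.actions, m.kernel[:, :1, :], m.returns)
    with pytest.raises(ModelValidationError):
        DynamicsModel(m.states, m.actions, m.kernel, m.returns[:, :1])


def test_inadmissible_policy_rejected():
    base = toy_a()
    mask = np.array([[True, False], [True, True]])
    actions = ActionSpace(("light", "heavy"), admissible=mask)
    m = DynamicsModel(base.states, actions, base.kernel, base.returns)
    cfg = SolverConfig(horizon=2)
    bad = Policy(np.array([[1, 0], [0, 0]]))
    with pytest.raises(ConfigurationError, match="inadmissible"):
        evaluate_policy(m, bad, cfg)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SolverConfig(horizon=0)
    with pytest.raises(ConfigurationError):
        SolverConfig(discount=0.0)
    with pytest.raises(ConfigurationError):
        SolverConfig(discount=1.5)


def test_brute_force_guard():
    m = toy_a()
    with pytest.raises(InstanceTooLargeError):
        brute_force_value(m, SolverConfig(horizon=20), max_policies=100)
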