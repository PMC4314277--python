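"""EVPI / EVPXI metrics: hand-checkable identities and guaranteed inequalities."""

import numpy as np
import pytest

from infovalue import (
    ConfigurationError,
    DynamicsModel,
    ModelSet,
    ModelState,
    SolverConfig,
    UndefinedGainError,
    VOISurface,
    average_model,
    brute_force_value,
    evpi,
    evpxi_direct,
    evpxi_residual,
    evpxi_single_model,
    model_optimal_values,
    passive_solve,
    summarize_gain,
    voi_vs_baseline,
)
from infovalue.fixtures import random_model_set, toy_b, toy_c


def test_evpi_matches_brute_force_oracle():
    models, q = toy_b()
    cfg = SolverConfig(horizon=3)
    per_model = np.stack([brute_force_value(m, cfg) for m in models.models])
    base = brute_force_value(average_model(models, q), cfg)
    for x in range(2):
        res = evpi(models, q, x, cfg)
        expected = q.weights @ per_model[:, x] - base[x]
        assert res.value == pytest.approx(expected, abs=1e-10)


def test_evpi_positive_when_models_prescribe_different_actions():
    models, q = toy_b()
    cfg = SolverConfig(horizon=10)
    assert evpi(models, q, 1, cfg).value > 0.0


def test_evpi_zero_at_simplex_vertices():
    models, _ = toy_b()
    cfg = SolverConfig(horizon=10)
    for k in range(2):
        for x in range(2):
            assert evpi(models, ModelState.vertex(2, k), x, cfg).value == 0.0


def test_direct_and_residual_evpxi_agree():
    models, _ = toy_c()
    cfg = SolverConfig(horizon=6)
    rng = np.random.default_rng(11)
    for _ in range(10):
        q = ModelState(rng.dirichlet(np.ones(4)))
        for factor in ("first", "second"):
            d = evpxi_direct(models, q, 0, cfg, factor=factor)
            r = evpxi_residual(models, q, 0, cfg, factor=factor)
            assert d.value == pytest.approx(r.value, abs=1e-10)


def test_evpxi_with_all_singleton_groups_equals_evpi():
    models, q = toy_b()
    grouped = ModelSet(models.models, group_labels=["g0", "g1"])
    cfg = SolverConfig(horizon=8)
    full = evpi(grouped, q, 1, cfg)
    part = evpxi_direct(grouped, q, 1, cfg, factor="group")
    assert part.value == pytest.approx(full.value, abs=1e-12)


def test_single_model_evpxi_equals_evpi_for_two_models():
    models, q = toy_b()
    cfg = SolverConfig(horizon=8)
    full = evpi(models, q, 1, cfg)
    for k in range(2):
        single = evpxi_single_model(models, q, 1, cfg, model_index=k)
        assert single.value == pytest.approx(full.value, abs=1e-12)


def test_single_model_evpxi_validation():
    models, q = toy_b()
    cfg = SolverConfig(horizon=2)
    with pytest.raises(ConfigurationError):
        evpxi_single_model(models, q, 0, cfg, model_index=5)


def test_evpxi_bounded_by_evpi_with_active_baseline():
    models, _ = toy_c()
    cfg = SolverConfig(horizon=3)
    rng = np.random.default_rng(5)
    for _ in range(5):
        q = ModelState(rng.dirichlet(np.ones(4)))
        full = evpi(models, q, 0, cfg, baseline_mode="active")
        for factor in ("first", "second"):
            part = evpxi_direct(models, q, 0, cfg, factor=factor, baseline_mode="active")
            assert -1e-10 <= part.value <= full.value + 1e-10


def test_voi_vs_baseline_exact_for_shared_kernel_models():
    # with one common kernel the policy value is linear in the returns, so the
    # passive optimum equals the belief-weighted value of its own policy and
    # voi_vs_baseline(passive policy) reduces exactly to passive-baseline EVPI
    base, _ = toy_b()
    k = base[0].kernel
    r2 = base[0].returns.copy()
    r2[1] = [2.0, 0.5]
    m1 = DynamicsModel(base.states, base.actions, k, base[0].returns, label="r1")
    m2 = DynamicsModel(base.states, base.actions, k, r2, label="r2")
    models = ModelSet([m1, m2])
    q = ModelState(np.array([0.4, 0.6]))
    cfg = SolverConfig(horizon=6)
    _, pol = passive_solve(models, q, cfg)
    for x in range(2):
        direct = voi_vs_baseline(models, q, x, cfg, pol)
        ref = evpi(models, q, x, cfg)
        assert direct.value == pytest.approx(ref.value, abs=1e-12)


def test_voi_vs_baseline_dominates_active_evpi():
    rng = np.random.default_rng(17)
    cfg = SolverConfig(horizon=3)
    for _ in range(10):
        models, q = random_model_set(rng)
        _, pol = passive_solve(models, q, cfg)
        vs = voi_vs_baseline(models, q, 0, cfg, pol)
        ref = evpi(models, q, 0, cfg, baseline_mode="active")
        assert vs.value >= ref.value - 1e-10


def test_negative_passive_evpi_is_reported_raw_with_warning():
    # seed 1 of the random fixture family is a pre-found case where the
    # frozen-belief averaged model out-values the belief-weighted optima
    rng = np.random.default_rng(1)
    models, q = random_model_set(rng)
    cfg = SolverConfig(horizon=3)
    with pytest.warns(UserWarning, match="EVPI is negative"):
        res = evpi(models, q, 0, cfg)
    assert res.value < -1e-8


def test_model_optimal_values_reuse_matches_fresh_computation():
    models, q = toy_c()
    cfg = SolverConfig(horizon=5)
    mv = model_optimal_values(models, cfg)
    a = evpi(models, q, 1, cfg, model_values=mv)
    b = evpi(models, q, 1, cfg)
    assert a.value == pytest.approx(b.value, abs=0.0)


def test_summarize_gain_and_errors():
    v = np.array([1.0, 3.0])
    r = np.array([10.0, 30.0])
    assert summarize_gain(v, r) == pytest.approx(10.0)
    assert summarize_gain(v, r, weights=[1.0, 0.0]) == pytest.approx(10.0)
    with pytest.raises(UndefinedGainError):
        summarize_gain(v, np.zeros(2))
    with pytest.raises(ConfigurationError):
        summarize_gain(v, np.ones(3))


def test_voisurface_csv_round_trip(tmp_path):
    import pandas as pd

    table = pd.DataFrame(
        {"metric": ["EVPI", "EVPI"], "value": [0.1, 0.2], "baseline_value": [1.0, 2.0]}
    )
    surf = VOISurface("EVPI", table)
    path = tmp_path / "s.csv"
    surf.to_csv(path)
    back = VOISurface.from_csv(path)
    assert back.metric == "EVPI"
    np.testing.assert_allclose(back.table["value"], table["value"])
    assert summarize_gain(back, back) == pytest.approx(10.0)
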