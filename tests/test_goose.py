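"""Synthetic goose harvest family: vital rates, objective, and family structure."""

import numpy as np
import pytest

from infovalue import (
    HYPOTHESES,
    DomainError,
    GooseSpec,
    ModelState,
    build_goose_family,
    density_dependence_subfamily,
    evpi,
    export_surfaces,
    harvest_utility,
    mean_map,
    objective_return,
)
from infovalue.goose import _vital_rates


@pytest.fixture(scope="module")
def coarse_family():
    spec = GooseSpec.coarse()
    models, weights = build_goose_family(spec)
    return spec, models, weights


def test_harvest_utility_values():
    spec = GooseSpec()
    assert harvest_utility(60.0, spec) == pytest.approx(1.0)
    assert harvest_utility(70.0, spec) == pytest.approx(0.9375)
    assert harvest_utility(50.0, spec) == pytest.approx(0.9375)
    assert harvest_utility(100.0, spec) == pytest.approx(0.0)
    assert harvest_utility(140.0, spec) == pytest.approx(0.0)  # floor, not negative
    with pytest.raises(DomainError):
        harvest_utility(-1.0, spec)


def test_objective_return_hand_computed():
    spec = GooseSpec()
    # harvest 0.1 * 60 = 6 thousand; E[u] = 0.75*1 + 0.25*0 = 0.75
    forecast = [(60.0, 0.75), (100.0, 0.25)]
    assert objective_return((10.0, 50.0), 0.1, forecast, spec) == pytest.approx(4.5)
    with pytest.raises(DomainError):
        objective_return((-1.0, 50.0), 0.1, forecast, spec)


def test_family_is_complete_three_by_three_cross(coarse_family):
    _, models, weights = coarse_family
    assert len(models) == 9
    firsts = {a for a, _ in models.factor_labels}
    seconds = {b for _, b in models.factor_labels}
    assert firsts == {f"s:{h}" for h in HYPOTHESES}
    assert seconds == {f"r:{h}" for h in HYPOTHESES}
    np.testing.assert_allclose(weights.weights, np.full(9, 1.0 / 9.0))


def test_kernel_rows_are_stochastic(coarse_family):
    _, models, _ = coarse_family
    for m in models.models:
        np.testing.assert_allclose(m.kernel.sum(axis=2), 1.0, atol=1e-9)


def test_temperature_marginal_is_exogenous(coarse_family):
    spec, models, _ = coarse_family
    S = models.states.size
    A = models.actions.size
    nT = len(spec.temperature_levels)
    joint = models[4].kernel.reshape(S, A, -1, nT)
    np.testing.assert_allclose(
        joint.sum(axis=2), np.broadcast_to(spec.temperature_probs, (S, A, nT)), atol=1e-9
    )


def test_zero_harvest_yields_zero_return(coarse_family):
    _, models, _ = coarse_family
    for m in models.models:
        np.testing.assert_allclose(m.returns[:, 0], 0.0)


def test_survival_strictly_decreasing_in_density():
    spec = GooseSpec()
    n = np.linspace(0.0, 150.0, 61)
    s, _ = _vital_rates(spec, "density", "independent", n, np.zeros_like(n))
    assert (np.diff(s) < 0).all()


def test_density_dependent_equilibria_in_goal_band():
    spec = GooseSpec()
    for hyp_s in ("density", "density_temperature"):
        for hyp_r in HYPOTHESES:
            y, a = 5.0, 40.0
            for _ in range(300):
                y, a = mean_map(spec, hyp_s, hyp_r, y, a)
            assert 60.0 <= y + a <= 90.0


def test_low_density_growth_is_shared():
    spec = GooseSpec()
    # at negligible density every hypothesis shares lambda = s * (1 + r) = 1.10
    for hyp_s in HYPOTHESES:
        for hyp_r in HYPOTHESES:
            s, r = _vital_rates(spec, hyp_s, hyp_r, np.array(0.0), np.array(0.0))
            lam = float(s * (1.0 + r))
            assert lam == pytest.approx(1.10, abs=0.02)


def test_state_index_snaps_to_nearest_grid_point():
    spec = GooseSpec()
    assert spec.state_index(10.0, 60.0, "average") == spec.state_index(11.0, 59.0, "average")
    cs = GooseSpec.coarse()
    models, _ = build_goose_family(cs)
    # on the coarse grid 11 young snaps to 7.5 and 55 adults to 60
    xi = cs.state_index(11.0, 55.0, "cold")
    assert models.states.labels[xi] == (7.5, 60.0, "cold")


def test_degenerate_family_has_identical_models():
    spec = GooseSpec.coarse().degenerate()
    models, _ = build_goose_family(spec)
    for m in models.models[1:]:
        np.testing.assert_allclose(m.kernel, models[0].kernel, atol=1e-12)
        np.testing.assert_allclose(m.returns, models[0].returns, atol=1e-12)


def test_density_dependence_subfamily_selects_corner_models(coarse_family):
    _, models, _ = coarse_family
    idx = density_dependence_subfamily(models)
    assert len(idx) == 4
    labels = {models.factor_labels[k] for k in idx}
    assert labels == {
        (f"s:{a}", f"r:{b}")
        for a in ("independent", "density_temperature")
        for b in ("independent", "density_temperature")
    }


def test_evpi_nonnegative_on_coarse_grid(coarse_family):
    spec, models, weights = coarse_family
    surf = export_surfaces(models, weights, spec.solver_config(), spec, metric="EVPI")
    assert (surf.table["value"] >= -1e-8).all()
    assert (surf.table["baseline_value"] >= 0.0).all()


def test_export_surfaces_shapes_and_columns(coarse_family):
    spec, models, weights = coarse_family
    cfg = spec.solver_config()
    n_grid = len(spec.young_grid) * len(spec.adult_grid)
    for metric in ("EVPI", "EVPXI_factor"):
        surf = export_surfaces(models, weights, cfg, spec, metric=metric)
        assert len(surf.table) == n_grid
        assert {"metric", "temperature_level", "young_thousands", "adults_thousands",
                "value", "baseline_value"} <= set(surf.table.columns)
    single = export_surfaces(models, weights, cfg, spec, metric="EVPXI_single")
    assert len(single.table) == 9
    assert "model" in single.table.columns
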