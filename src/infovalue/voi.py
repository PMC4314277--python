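"""Value-of-information metrics for sequential decisions under model uncertainty.

EVPI — expected value of perfect information — is the average of the per-model
optimal values minus the optimal value attainable under the current model
state:

    EVPI(x, q) = sum_k q(k) V*_k(x)  -  V_t[x, q],

where the baseline ``V_t[x, q]`` is either the passive-adaptive optimum (the
belief-averaged model solved with ``q`` frozen; the default, as used in goose
harvest management practice) or the active-adaptive belief-MDP optimum.

EVPXI — expected value of partial information — apportions that loss between
crossed uncertainty factors.  It admits two algebraically equivalent
computations: the *direct* form averages within-level optima over the factor
marginal and subtracts the full-set baseline; the *residual* form subtracts
the marginal-weighted within-level EVPIs from the full-set EVPI.  Their
agreement is a strong end-to-end consistency check and is enforced in tests.

A hierarchical variant scores a single model against the rest, and
``voi_vs_baseline`` contrasts perfect information with any supplied
(typically suboptimal) policy, which can only widen the gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .adaptive import active_solve, passive_solve
from .beliefs import FactorView, ModelSet, ModelState, factor_view
from .errors import ConfigurationError, UndefinedGainError
from .mdp import Policy, SolverConfig, evaluate_policy, solve_model

NEGATIVE_WARN_TOL = 1e-8


@dataclass
class VOIResult:
    """One evaluated information-value metric at a (state, belief) point."""

    metric: str
    value: float
    state: int
    model_state: np.ndarray
    baseline_mode: str
    factor: Optional[str] = None
    detail: dict = field(default_factory=dict)


@dataclass
class VOISurface:
    """A VOI metric tabulated over a grid of system states and/or beliefs."""

    metric: str
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "VOISurface":
        table = pd.read_csv(path)
        if "metric" not in table.columns or "value" not in table.columns:
            raise ConfigurationError("surface CSV must carry 'metric' and 'value' columns")
        return cls(str(table["metric"].iloc[0]), table)


def model_optimal_values(
    models: ModelSet, config: SolverConfig, terminal=None
) -> np.ndarray:
    """Per-model optimal epoch-0 values, shape (n_models, n_states).

    These do not depend on the belief, so callers sweeping many beliefs can
    compute them once and pass them to the metric functions.
    """
    return np.stack(
        [solve_model(m, config, terminal)[0].initial for m in models.models]
    )


def _baseline_value(models, q, x, config, baseline_mode, terminal):
    if baseline_mode == "passive":
        vf, _ = passive_solve(models, q, config, terminal)
        return float(vf.initial[x])
    if baseline_mode == "active":
        sol = active_solve(models, config, terminal, mode="exact_reachable")
        return float(sol.value(x, q))
    raise ConfigurationError(f"unknown baseline_mode {baseline_mode!r}")


def _warn_if_negative(name: str, value: float) -> None:
    if value < -NEGATIVE_WARN_TOL:
        warnings.warn(
            f"{name} is negative ({value:.3e}); reported raw — with a passive baseline "
            "small negative values can arise because the frozen-belief averaged model "
            "is an approximation, larger ones indicate a solver problem",
            stacklevel=3,
        )


def evpi(
    models: ModelSet,
    q: ModelState,
    x: int,
    config: SolverConfig,
    baseline_mode: str = "passive",
    terminal: Optional[Sequence[float]] = None,
    model_values: Optional[np.ndarray] = None,
) -> VOIResult:
    """Expected value of perfect information at system state ``x`` and belief ``q``."""
    if model_values is None:
        model_values = model_optimal_values(models, config, terminal)
    first = float(q.weights @ model_values[:, x])
    base = _baseline_value(models, q, x, config, baseline_mode, terminal)
    value = first - base
    _warn_if_negative("EVPI", value)
    return VOIResult(
        "EVPI", value, x, q.weights.copy(), baseline_mode,
        detail={"perfect_information_value": first, "baseline_value": base},
    )


def _level_optimum(models, view: FactorView, level, config, baseline_mode, x, terminal):
    """Baseline-mode optimum for the models grouped under one factor level."""
    sub = models.subset(view.member_indices[level])
    q_cond = ModelState(view.conditionals[level])
    return _baseline_value(sub, q_cond, x, config, baseline_mode, terminal)


def evpxi_direct(
    models: ModelSet,
    q: ModelState,
    x: int,
    config: SolverConfig,
    factor: str = "first",
    baseline_mode: str = "passive",
    terminal: Optional[Sequence[float]] = None,
) -> VOIResult:
    """EVPXI by the 3-step direct route.

    For each level k' of the factor, solve the within-level model average under
    the conditional belief; average those optima over the factor marginal; then
    subtract the full-set baseline optimum.  Zero-marginal levels contribute 0.
    """
    view = factor_view(q, models, factor)
    acc = 0.0
    per_level = {}
    for lev in view.levels:
        w = view.marginal[lev]
        if w <= 0.0:
            continue
        opt = _level_optimum(models, view, lev, config, baseline_mode, x, terminal)
        per_level[lev] = opt
        acc += w * opt
    base = _baseline_value(models, q, x, config, baseline_mode, terminal)
    value = acc - base
    _warn_if_negative("EVPXI", value)
    return VOIResult(
        "EVPXI_direct", value, x, q.weights.copy(), baseline_mode, factor=factor,
        detail={"level_optima": per_level, "baseline_value": base},
    )


def evpxi_residual(
    models: ModelSet,
    q: ModelState,
    x: int,
    config: SolverConfig,
    factor: str = "first",
    baseline_mode: str = "passive",
    terminal: Optional[Sequence[float]] = None,
) -> VOIResult:
    """EVPXI by the 4-step residual route: full-set EVPI minus the
    marginal-weighted within-level EVPIs.  Algebraically identical to
    :func:`evpxi_direct`; computed along a genuinely different path so their
    agreement is an informative check."""
    view = factor_view(q, models, factor)
    full = evpi(models, q, x, config, baseline_mode, terminal)
    within = 0.0
    per_level = {}
    for lev in view.levels:
        w = view.marginal[lev]
        if w <= 0.0:
            continue
        sub = models.subset(view.member_indices[lev])
        q_cond = ModelState(view.conditionals[lev])
        lev_evpi = evpi(sub, q_cond, x, config, baseline_mode, terminal)
        per_level[lev] = lev_evpi.value
        within += w * lev_evpi.value
    value = full.value - within
    _warn_if_negative("EVPXI", value)
    return VOIResult(
        "EVPXI_residual", value, x, q.weights.copy(), baseline_mode, factor=factor,
        detail={"full_evpi": full.value, "within_level_evpi": per_level},
    )


def evpxi_single_model(
    models: ModelSet,
    q: ModelState,
    x: int,
    config: SolverConfig,
    model_index: int,
    baseline_mode: str = "passive",
    terminal: Optional[Sequence[float]] = None,
) -> VOIResult:
    """Value of resolving whether one particular model is the right one.

    The set is split hierarchically into the singleton {model_index} and the
    remaining models, and the residual decomposition is applied to that
    two-group hierarchy; the singleton group has zero within-group EVPI, so
    the metric is the full-set EVPI minus (1 - q_i) times the EVPI of the rest
    under the conditional belief.
    """
    K = len(models)
    if not (0 <= model_index < K):
        raise ConfigurationError(f"model_index {model_index} out of range for {K} models")
    if K < 2:
        raise ConfigurationError("at least two models are required")
    groups = ["singleton" if k == model_index else "rest" for k in range(K)]
    grouped = ModelSet(models.models, factor_labels=models.factor_labels, group_labels=groups)
    res = evpxi_residual(grouped, q, x, config, factor="group", baseline_mode=baseline_mode,
                         terminal=terminal)
    return VOIResult(
        "EVPXI_single", res.value, x, q.weights.copy(), baseline_mode,
        factor=f"model:{models.models[model_index].label}", detail=res.detail,
    )


def voi_vs_baseline(
    models: ModelSet,
    q: ModelState,
    x: int,
    config: SolverConfig,
    baseline_policy: Policy,
    terminal: Optional[Sequence[float]] = None,
    model_values: Optional[np.ndarray] = None,
) -> VOIResult:
    """Value of perfect information relative to an arbitrary (suboptimal) strategy.

    The baseline is the belief-weighted true value of following
    ``baseline_policy`` under each candidate model; suboptimal decision making
    can only increase the contrast with perfect information.
    """
    if model_values is None:
        model_values = model_optimal_values(models, config, terminal)
    first = float(q.weights @ model_values[:, x])
    evals = np.array(
        [evaluate_policy(m, baseline_policy, config, terminal).initial[x] for m in models.models]
    )
    base = float(q.weights @ evals)
    return VOIResult(
        "VOI_baseline", first - base, x, q.weights.copy(), "supplied_policy",
        detail={"perfect_information_value": first, "baseline_value": base},
    )


def summarize_gain(voi_values, reference_values, weights=None) -> float:
    """Percentage gain: 100 x (weighted mean VOI) / (weighted mean baseline value).

    Accepts :class:`VOISurface` objects (using their ``value`` /
    ``baseline_value`` columns) or plain arrays on matching grids.
    """
    if isinstance(voi_values, VOISurface):
        voi_values = voi_values.table["value"].to_numpy()
    if isinstance(reference_values, VOISurface):
        reference_values = reference_values.table["baseline_value"].to_numpy()
    v = np.asarray(voi_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if v.shape != r.shape:
        raise ConfigurationError("VOI and reference surfaces must share a grid")
    if weights is None:
        w = np.full(v.shape, 1.0 / v.size)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    ref_mean = float(w.ravel() @ r.ravel())
    if ref_mean == 0.0:
        raise UndefinedGainError("reference surface has zero weighted mean value")
    return 100.0 * float(w.ravel() @ v.ravel()) / ref_mean
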