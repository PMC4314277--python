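"""Finite-horizon stochastic dynamic programming for a single known model.

States and actions live on finite grids.  A :class:`DynamicsModel` couples a
transition kernel ``P(x' | x, a)`` with an immediate-return table ``R(a | x)``.
Values are accumulated backwards from a terminal condition by the standard
recursion

    V_t(x) = R(a | x) + gamma * sum_{x'} P(x' | x, a) * V_{t+1}(x'),

either for a fixed policy (:func:`evaluate_policy`) or maximised over
admissible actions via Bellman's equation (:func:`solve_model`).  A
policy-enumeration oracle (:func:`brute_force_value`) provides an exact
cross-check on tiny instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InstanceTooLargeError, ModelValidationError, NonStochasticRowError

#: absolute tolerance for "rows sum to one" checks
STOCHASTIC_ATOL = 1e-9


@dataclass(frozen=True)
class StateSpace:
    """Ordered finite collection of system states.

    Each state has a hashable label and, optionally, a coordinate tuple
    (e.g. ``(young, adults, temperature)`` in a population model).
    """

    labels: tuple
    coords: Optional[tuple] = None

    def __post_init__(self):
        if len(self.labels) < 1:
            raise ConfigurationError("state space must contain at least one state")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("state labels must be unique")
        if self.coords is not None and len(self.coords) != len(self.labels):
            raise ConfigurationError("coords must align with labels")

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConfigurationError(f"unknown state label {label!r}") from None


@dataclass(frozen=True)
class ActionSpace:
    """Ordered finite action set with an optional per-state admissibility mask.

    ``admissible[x, a]`` is True when action ``a`` may be taken in state ``x``;
    inadmissible pairs are excluded from maximisation, never penalised.
    """

    labels: tuple
    admissible: Optional[np.ndarray] = None  # (S, A) bool; None means all admissible

    def __post_init__(self):
        if len(self.labels) < 1:
            raise ConfigurationError("action space must contain at least one action")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("action labels must be unique")
        if self.admissible is not None:
            adm = np.asarray(self.admissible, dtype=bool)
            if adm.ndim != 2 or adm.shape[1] != len(self.labels):
                raise ConfigurationError("admissible mask must have shape (n_states, n_actions)")
            if not adm.any(axis=1).all():
                raise ConfigurationError("every state needs at least one admissible action")
            object.__setattr__(self, "admissible", adm)

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConfigurationError(f"unknown action label {label!r}") from None

    def mask(self, n_states: int) -> np.ndarray:
        """Boolean admissibility mask of shape (n_states, n_actions)."""
        if self.admissible is None:
            return np.ones((n_states, self.size), dtype=bool)
        return self.admissible


class DynamicsModel:
    """One hypothesis about resource dynamics: kernel P_k and returns R_k.

    Parameters
    ----------
    states, actions
        Shared discretisation of the decision problem.
    kernel
        Array of shape (S, A, S); ``kernel[x, a, x']`` is the probability of
        moving to ``x'`` when action ``a`` is taken in state ``x``.  Rows for
        admissible (x, a) pairs must be stochastic.
    returns
        Array of shape (S, A) of immediate returns in utility units.
    label
        Identifier ``k`` of the hypothesis.
    """

    def __init__(self, states: StateSpace, actions: ActionSpace, kernel, returns, label="model"):
        self.states = states
        self.actions = actions
        self.kernel = np.asarray(kernel, dtype=float)
        self.returns = np.asarray(returns, dtype=float)
        self.label = label
        self.validate()

    def validate(self) -> None:
        S, A = self.states.size, self.actions.size
        if self.kernel.shape != (S, A, S):
            raise ModelValidationError(
                f"kernel shape {self.kernel.shape} != {(S, A, S)} for model {self.label!r}"
            )
        if self.returns.shape != (S, A):
            raise ModelValidationError(
                f"returns shape {self.returns.shape} != {(S, A)} for model {self.label!r}"
            )
        if not np.isfinite(self.returns).all():
            raise ModelValidationError(f"non-finite returns in model {self.label!r}")
        if (self.kernel < -STOCHASTIC_ATOL).any():
            raise ModelValidationError(f"negative transition probability in model {self.label!r}")
        mask = self.actions.mask(S)
        row_sums = self.kernel.sum(axis=2)
        bad = mask & (np.abs(row_sums - 1.0) > STOCHASTIC_ATOL)
        if bad.any():
            x, a = map(int, np.argwhere(bad)[0])
            raise NonStochasticRowError(
                f"model {self.label!r}: kernel row for state {self.states.labels[x]!r}, "
                f"action {self.actions.labels[a]!r} sums to {row_sums[x, a]:.6g}, not 1"
            )

    @property
    def n_states(self) -> int:
        return self.states.size

    @property
    def n_actions(self) -> int:
        return self.actions.size


@dataclass
class SolverConfig:
    """Backward-induction settings.

    horizon
        Number of decision epochs (epoch 0 is the first decision).
    discount
        Per-epoch discount factor in (0, 1]; 1 gives the cumulative objective.
    tie_tolerance
        Actions whose Bellman values are within this of the maximum are tied;
        the lowest action index wins, for determinism across platforms.
    """

    horizon: int = 50
    discount: float = 1.0
    tie_tolerance: float = 1e-10

    def __post_init__(self):
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1")
        if not (0.0 < self.discount <= 1.0):
            raise ConfigurationError("discount must lie in (0, 1]")
        if self.tie_tolerance < 0:
            raise ConfigurationError("tie_tolerance must be nonnegative")


@dataclass
class Policy:
    """Time- and state-specific action prescription A_t.

    ``actions[t, x]`` is the index of the action taken in state ``x`` at
    decision epoch ``t``.
    """

    actions: np.ndarray  # (horizon, S) int
    horizon: int = field(default=0)

    def __post_init__(self):
        self.actions = np.asarray(self.actions, dtype=int)
        if self.actions.ndim != 2:
            raise ConfigurationError("policy actions must be a (horizon, n_states) array")
        if self.horizon == 0:
            self.horizon = self.actions.shape[0]
        if self.actions.shape[0] != self.horizon:
            raise ConfigurationError("policy does not cover every decision epoch")


@dataclass
class ValueFunction:
    """Accumulated values ``values[t, x]`` with ``values[horizon]`` the terminal row."""

    values: np.ndarray  # (horizon + 1, S)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def horizon(self) -> int:
        return self.values.shape[0] - 1

    @property
    def initial(self) -> np.ndarray:
        """Values at epoch 0 — the cumulative objective over the whole time frame."""
        return self.values[0]


def _terminal_array(model: DynamicsModel, terminal) -> np.ndarray:
    if terminal is None:
        return np.zeros(model.n_states)
    arr = np.asarray(terminal, dtype=float)
    if arr.shape != (model.n_states,):
        raise ConfigurationError("terminal values must be given for every state")
    return arr


def evaluate_policy(
    model: DynamicsModel,
    policy: Policy,
    config: SolverConfig,
    terminal: Optional[Sequence[float]] = None,
) -> ValueFunction:
    """Accumulate returns backwards for a fixed policy.

    Satisfies V_t(x) = R(a|x) + gamma * sum P(x'|x,a) V_{t+1}(x') with
    a = policy(t, x), and V at the horizon equal to ``terminal`` (default 0).
    """
    if policy.horizon < config.horizon:
        raise ConfigurationError(
            f"policy covers {policy.horizon} epochs but horizon is {config.horizon}"
        )
    S = model.n_states
    mask = model.actions.mask(S)
    V = np.empty((config.horizon + 1, S))
    V[config.horizon] = _terminal_array(model, terminal)
    idx = np.arange(S)
    for t in range(config.horizon - 1, -1, -1):
        a = policy.actions[t]
        if (a < 0).any() or (a >= model.n_actions).any() or not mask[idx, a].all():
            raise ConfigurationError(f"policy prescribes an inadmissible action at epoch {t}")
        V[t] = model.returns[idx, a] + config.discount * np.einsum(
            "ij,j->i", model.kernel[idx, a, :], V[t + 1]
        )
    return ValueFunction(V)


def solve_model(
    model: DynamicsModel,
    config: SolverConfig,
    terminal: Optional[Sequence[float]] = None,
) -> tuple[ValueFunction, Policy]:
    """Bellman backward induction: optimal values and a deterministic optimal policy."""
    S = model.n_states
    mask = model.actions.mask(S)
    V = np.empty((config.horizon + 1, S))
    V[config.horizon] = _terminal_array(model, terminal)
    A_star = np.empty((config.horizon, S), dtype=int)
    for t in range(config.horizon - 1, -1, -1):
        Q = model.returns + config.discount * np.einsum("xay,y->xa", model.kernel, V[t + 1])
        Q = np.where(mask, Q, -np.inf)
        best = Q.max(axis=1)
        # lowest-index action within tie_tolerance of the maximum
        A_star[t] = (Q >= best[:, None] - config.tie_tolerance).argmax(axis=1)
        V[t] = Q[np.arange(S), A_star[t]]
    return ValueFunction(V), Policy(A_star, config.horizon)


def brute_force_value(
    model: DynamicsModel,
    config: SolverConfig,
    terminal: Optional[Sequence[float]] = None,
    max_policies: int = 10**6,
) -> np.ndarray:
    """Exact optimum per state by exhaustive enumeration of time-state policies.

    Test oracle only; refuses instances whose policy count exceeds
    ``max_policies``.
    """
    S = model.n_states
    mask = model.actions.mask(S)
    per_state = [np.flatnonzero(mask[x]) for x in range(S)]
    n_per_epoch = int(np.prod([len(p) for p in per_state]))
    count = n_per_epoch ** config.horizon
    if count > max_policies:
        raise InstanceTooLargeError(
            f"{count} candidate policies exceed the brute-force guard of {max_policies}"
        )
    best = np.full(S, -np.inf)
    choices = [per_state[x] for _ in range(config.horizon) for x in range(S)]
    for flat in itertools.product(*choices):
        acts = np.asarray(flat, dtype=int).reshape(config.horizon, S)
        vf = evaluate_policy(model, Policy(acts, config.horizon), config, terminal)
        best = np.maximum(best, vf.initial)
    return best
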