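"""Model-state (belief) algebra over a finite set of competing models.

Uncertainty about which dynamics model is correct is carried by a probability
vector ``q`` over the model set — the *model state*.  It evolves by Bayes'
theorem as transitions are observed, it averages the set into a single
composite model, and, when the models are indexed by crossed or hierarchical
factors (e.g. survival hypothesis x reproduction hypothesis), it factors into
marginal and conditional views used by partial-information metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ImpossibleObservationError
from .mdp import DynamicsModel, StateSpace, ActionSpace

WEIGHT_ATOL = 1e-9


class ModelSet:
    """Ordered collection of :class:`DynamicsModel` sharing one state/action space.

    Parameters
    ----------
    models
        The candidate models, in a fixed order (belief vectors align with it).
    factor_labels
        Optional ``(k1, k2)`` pair per model when the set is a complete cross
        of two uncertainty factors.
    group_labels
        Optional hierarchical group identifier per model.
    """

    def __init__(self, models: Sequence[DynamicsModel], factor_labels=None, group_labels=None):
        if len(models) < 1:
            raise ConfigurationError("a model set needs at least one model")
        first = models[0]
        for m in models[1:]:
            if m.states.labels != first.states.labels or m.actions.labels != first.actions.labels:
                raise ConfigurationError("all models must share the same state and action spaces")
        self.models = list(models)
        self.factor_labels = list(factor_labels) if factor_labels is not None else None
        self.group_labels = list(group_labels) if group_labels is not None else None
        if self.factor_labels is not None:
            if len(self.factor_labels) != len(models):
                raise ConfigurationError("one factor pair per model is required")
            lv1 = sorted({a for a, _ in self.factor_labels}, key=str)
            lv2 = sorted({b for _, b in self.factor_labels}, key=str)
            expected = {(a, b) for a in lv1 for b in lv2}
            if set(map(tuple, self.factor_labels)) != expected or len(self.factor_labels) != len(expected):
                raise ConfigurationError("crossed factor labels must form a complete cross")
        if self.group_labels is not None and len(self.group_labels) != len(models):
            raise ConfigurationError("one group label per model is required")

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, k: int) -> DynamicsModel:
        return self.models[k]

    @property
    def states(self) -> StateSpace:
        return self.models[0].states

    @property
    def actions(self) -> ActionSpace:
        return self.models[0].actions

    def subset(self, indices: Sequence[int]) -> "ModelSet":
        """Sub-collection (labels dropped; the subset is its own flat model set)."""
        return ModelSet([self.models[i] for i in indices])


@dataclass
class ModelState:
    """Probability vector of confidence weights, one per model."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ConfigurationError("model-state weights must be a vector")
        if (self.weights < -WEIGHT_ATOL).any():
            raise ConfigurationError("model-state weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > WEIGHT_ATOL:
            raise ConfigurationError(
                f"model-state weights sum to {self.weights.sum():.6g}, not 1"
            )

    def __len__(self) -> int:
        return len(self.weights)

    @classmethod
    def uniform(cls, n: int) -> "ModelState":
        return cls(np.full(n, 1.0 / n))

    @classmethod
    def vertex(cls, n: int, k: int) -> "ModelState":
        w = np.zeros(n)
        w[k] = 1.0
        return cls(w)


@dataclass
class FactorView:
    """Marginal/conditional decomposition of a belief along one factor.

    ``conditionals[level]`` is the belief over that level's member models
    (aligned with ``member_indices[level]``); levels with zero marginal weight
    have conditional ``None`` and are listed in ``undefined_levels``.
    """

    levels: list
    marginal: dict
    conditionals: dict
    member_indices: dict
    undefined_levels: list = field(default_factory=list)


def bayes_update(q: ModelState, models: ModelSet, x: int, a: int, x_next: int) -> ModelState:
    """Posterior model state after observing the transition (x, a) -> x_next.

    q'(k) is proportional to q(k) * P_k(x_next | x, a); models with zero prior
    weight stay at zero.  Raises :class:`ImpossibleObservationError` when the
    observation has zero likelihood under the whole prior.
    """
    like = np.array([m.kernel[x, a, x_next] for m in models.models])
    post = q.weights * like
    total = post.sum()
    if total <= 0.0:
        raise ImpossibleObservationError(
            f"observed transition {x}->{x_next} under action {a} has zero total likelihood"
        )
    return ModelState(post / total)


def average_model(models: ModelSet, q: ModelState) -> DynamicsModel:
    """Belief-weighted composite model: kernel sum_k q(k) P_k, returns sum_k q(k) R_k."""
    if len(q) != len(models):
        raise ConfigurationError("belief length must match the number of models")
    w = q.weights
    kernel = sum(wk * m.kernel for wk, m in zip(w, models.models))
    returns = sum(wk * m.returns for wk, m in zip(w, models.models))
    return DynamicsModel(models.states, models.actions, kernel, returns, label="averaged")


def factor_view(q: ModelState, models: ModelSet, factor: str = "first") -> FactorView:
    """Marginal and conditional beliefs along one uncertainty factor.

    ``factor`` is ``"first"`` or ``"second"`` for crossed labels, or
    ``"group"`` for a hierarchical grouping.
    """
    if factor in ("first", "second"):
        if models.factor_labels is None:
            raise ConfigurationError("crossed factor labels are not present on this model set")
        pos = 0 if factor == "first" else 1
        labels = [lab[pos] for lab in models.factor_labels]
    elif factor == "group":
        if models.group_labels is None:
            raise ConfigurationError("group labels are not present on this model set")
        labels = list(models.group_labels)
    else:
        raise ConfigurationError(f"unknown factor {factor!r}")

    levels = sorted(set(labels), key=str)
    marginal, conditionals, members, undefined = {}, {}, {}, []
    for lev in levels:
        idx = [k for k, lab in enumerate(labels) if lab == lev]
        members[lev] = idx
        mass = float(q.weights[idx].sum())
        marginal[lev] = mass
        if mass > 0.0:
            conditionals[lev] = q.weights[idx] / mass
        else:
            conditionals[lev] = None
            undefined.append(lev)
    return FactorView(levels, marginal, conditionals, members, undefined)


def belief_grid(num_models: int, resolution: int) -> list[ModelState]:
    """Regular lattice on the belief simplex: weights i/resolution summing to 1.

    Contains all simplex vertices; size is C(resolution + num_models - 1,
    num_models - 1).
    """
    if num_models < 1 or resolution < 1:
        raise ConfigurationError("num_models and resolution must be >= 1")
    out = []
    for cut in combinations_with_replacement(range(num_models), resolution):
        counts = np.bincount(cut, minlength=num_models)
        out.append(ModelState(counts / resolution))
    return out
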