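"""Small fully specified decision problems used throughout the test-bed.

toy_a   one model, two states, two actions — the basic solver fixture.
toy_b   two models on toy_a's space differing in a single kernel row, chosen
        so that their optimal policies disagree (information has value).
toy_c   four models forming a complete 2x2 cross of two uncertainty factors.

``random_model_set`` draws "competing hypotheses" families the way model sets
arise in resource management: the candidate models describe one common system
under one common objective, so they share the return table and their kernels
are perturbations of a common base.
"""

from __future__ import annotations

import numpy as np

from .beliefs import ModelSet, ModelState
from .mdp import ActionSpace, DynamicsModel, StateSpace

_STATES = StateSpace(("low", "high"))
_ACTIONS = ActionSpace(("light", "heavy"))

# shared immediate returns, rows = states, cols = actions
_RETURNS = np.array([[0.2, 0.5], [1.0, 2.0]])

# kernel[x, a, x']
_KERNEL_A = np.array(
    [
        [[0.3, 0.7], [0.8, 0.2]],  # from "low":  light, heavy
        [[0.1, 0.9], [0.3, 0.7]],  # from "high": light, heavy
    ]
)


def toy_a() -> DynamicsModel:
    """Single 2-state / 2-action model."""
    return DynamicsModel(_STATES, _ACTIONS, _KERNEL_A, _RETURNS, label="toyA")


def toy_b() -> tuple[ModelSet, ModelState]:
    """Two models differing only in the heavy-from-high kernel row.

    Under the second model heavy harvesting from the high state almost always
    crashes the system, so the models prescribe different actions there.
    """
    k2 = _KERNEL_A.copy()
    k2[1, 1] = [0.95, 0.05]  # heavy from "high" collapses to "low"
    m1 = DynamicsModel(_STATES, _ACTIONS, _KERNEL_A, _RETURNS, label="resilient")
    m2 = DynamicsModel(_STATES, _ACTIONS, k2, _RETURNS, label="fragile")
    return ModelSet([m1, m2]), ModelState(np.array([0.5, 0.5]))


def toy_c() -> tuple[ModelSet, ModelState]:
    """Complete 2x2 cross: factor one sets the heavy-from-high row, factor two
    the heavy-from-low row."""
    rows_f1 = {"resilient": [0.3, 0.7], "fragile": [0.95, 0.05]}
    rows_f2 = {"quick": [0.5, 0.5], "slow": [0.9, 0.1]}
    models, labels = [], []
    for f1, row1 in rows_f1.items():
        for f2, row2 in rows_f2.items():
            k = _KERNEL_A.copy()
            k[1, 1] = row1
            k[0, 1] = row2
            models.append(DynamicsModel(_STATES, _ACTIONS, k, _RETURNS, label=f"{f1}-{f2}"))
            labels.append((f1, f2))
    return ModelSet(models, factor_labels=labels), ModelState.uniform(4)


def random_model_set(
    rng: np.random.Generator,
    n_states: int = 3,
    n_actions: int = 2,
    n_models: int = 2,
    crossed: bool = False,
    mix: float = 0.5,
) -> tuple[ModelSet, ModelState]:
    """Random family of competing dynamics hypotheses.

    All models share a return table drawn once (the management objective is a
    property of the problem, not of the hypothesis); each model's kernel is a
    ``mix``-weighted blend of a common base kernel and model-specific
    Dirichlet(1) rows.  With ``crossed=True``, ``n_models`` must be a perfect
    square and the models receive complete 2-factor cross labels.
    """
    states = StateSpace(tuple(f"s{i}" for i in range(n_states)))
    actions = ActionSpace(tuple(f"a{j}" for j in range(n_actions)))
    returns = rng.uniform(0.0, 1.0, size=(n_states, n_actions))
    base = rng.dirichlet(np.ones(n_states), size=(n_states, n_actions))
    models = []
    for k in range(n_models):
        own = rng.dirichlet(np.ones(n_states), size=(n_states, n_actions))
        kernel = (1.0 - mix) * base + mix * own
        models.append(DynamicsModel(states, actions, kernel, returns, label=f"m{k}"))
    labels = None
    if crossed:
        side = int(round(np.sqrt(n_models)))
        if side * side != n_models:
            raise ValueError("crossed=True needs a square number of models")
        labels = [(f"f1:{k // side}", f"f2:{k % side}") for k in range(n_models)]
    q = ModelState(rng.dirichlet(np.ones(n_models)))
    return ModelSet(models, factor_labels=labels), q
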