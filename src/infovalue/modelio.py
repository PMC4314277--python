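"""Reading and writing model-set specification files.

The interchange format is a single YAML document (format_version 1):

.. code-block:: yaml

    format_version: 1
    states:                     # list of labels, or mappings with coords
      - {label: low,  coords: [0.0]}
      - {label: high, coords: [1.0]}
    actions: [light, heavy]
    admissible:                 # optional; omitted = everything admissible
      low: [light]
    models:
      - label: m1
        factor: [resilient, quick]   # optional crossed pair
        group: g1                    # optional hierarchical group
        kernel:                      # state x action x successor
          - [[0.3, 0.7], [0.8, 0.2]]
          - [[0.1, 0.9], [0.3, 0.7]]
        returns:                     # state x action
          - [0.2, 0.5]
          - [1.0, 2.0]
    weights: [1.0]
    solver: {horizon: 3, discount: 1.0, tie_tolerance: 1.0e-10}

Validation raises :class:`SchemaError` for structural problems,
:class:`NonStochasticRowError` (naming the state and action) for bad kernel
rows, and :class:`WeightSumError` when the weights do not sum to one.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import yaml

from .beliefs import ModelSet, ModelState
from .errors import SchemaError, WeightSumError
from .mdp import ActionSpace, DynamicsModel, SolverConfig, StateSpace

logger = logging.getLogger("infovalue")

FORMAT_VERSION = 1


def _require(doc: dict, key: str, path: str):
    if key not in doc:
        raise SchemaError(f"{path}: missing required field {key!r}")
    return doc[key]


def _parse_states(raw, path="states") -> StateSpace:
    if not isinstance(raw, list) or not raw:
        raise SchemaError(f"{path}: must be a nonempty list")
    labels, coords = [], []
    has_coords = isinstance(raw[0], dict) and "coords" in raw[0]
    for i, item in enumerate(raw):
        if isinstance(item, dict):
            labels.append(_require(item, "label", f"{path}[{i}]"))
            if has_coords:
                coords.append(tuple(_require(item, "coords", f"{path}[{i}]")))
        else:
            labels.append(item)
    return StateSpace(tuple(labels), coords=tuple(coords) if has_coords else None)


def read_model_spec(path) -> tuple[ModelSet, ModelState, SolverConfig]:
    """Load and fully validate a model-spec YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: document must be a mapping")
    version = doc.get("format_version", FORMAT_VERSION)
    if version != FORMAT_VERSION:
        raise SchemaError(f"{path}: unsupported format_version {version}")

    states = _parse_states(_require(doc, "states", str(path)))
    action_labels = _require(doc, "actions", str(path))
    if not isinstance(action_labels, list) or not action_labels:
        raise SchemaError(f"{path}: 'actions' must be a nonempty list")

    admissible = None
    if doc.get("admissible"):
        adm = np.ones((states.size, len(action_labels)), dtype=bool)
        for state_label, allowed in doc["admissible"].items():
            x = states.index(state_label)
            adm[x] = [a in allowed for a in action_labels]
        admissible = adm
    actions = ActionSpace(tuple(action_labels), admissible=admissible)

    raw_models = _require(doc, "models", str(path))
    if not isinstance(raw_models, list) or not raw_models:
        raise SchemaError(f"{path}: 'models' must be a nonempty list")
    models, factors, groups = [], [], []
    for i, rm in enumerate(raw_models):
        kernel = np.asarray(_require(rm, "kernel", f"models[{i}]"), dtype=float)
        returns = np.asarray(_require(rm, "returns", f"models[{i}]"), dtype=float)
        S, A = states.size, actions.size
        if kernel.shape != (S, A, S):
            raise SchemaError(
                f"models[{i}]: kernel shape {kernel.shape} inconsistent with "
                f"{S} states x {A} actions"
            )
        if returns.shape != (S, A):
            raise SchemaError(f"models[{i}]: returns shape {returns.shape} != {(S, A)}")
        models.append(
            DynamicsModel(states, actions, kernel, returns, label=rm.get("label", f"m{i}"))
        )
        if "factor" in rm:
            factors.append(tuple(rm["factor"]))
        if "group" in rm:
            groups.append(rm["group"])
    if factors and len(factors) != len(models):
        raise SchemaError(f"{path}: 'factor' must be given for every model or none")
    if groups and len(groups) != len(models):
        raise SchemaError(f"{path}: 'group' must be given for every model or none")

    weights = np.asarray(_require(doc, "weights", str(path)), dtype=float)
    if weights.shape != (len(models),):
        raise SchemaError(f"{path}: {len(weights)} weights for {len(models)} models")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise WeightSumError(f"{path}: model weights sum to {weights.sum():.6g}, not 1")

    solver = doc.get("solver", {})
    config = SolverConfig(
        horizon=int(solver.get("horizon", 50)),
        discount=float(solver.get("discount", 1.0)),
        tie_tolerance=float(solver.get("tie_tolerance", 1e-10)),
    )
    model_set = ModelSet(models, factor_labels=factors or None, group_labels=groups or None)
    logger.info(
        "read_model_spec path=%s models=%d states=%d actions=%d horizon=%d",
        path, len(models), states.size, actions.size, config.horizon,
    )
    return model_set, ModelState(weights), config


def write_model_spec(path, models: ModelSet, q: ModelState, config: SolverConfig) -> None:
    """Serialize a model set to the YAML interchange format (round-trips losslessly)."""
    states = models.states
    doc: dict = {"format_version": FORMAT_VERSION}
    if states.coords is not None:
        doc["states"] = [
            {"label": lab, "coords": [float(c) for c in xy]}
            for lab, xy in zip(states.labels, states.coords)
        ]
    else:
        doc["states"] = list(states.labels)
    doc["actions"] = list(models.actions.labels)
    mask = models.actions.mask(states.size)
    if not mask.all():
        doc["admissible"] = {
            states.labels[x]: [a for j, a in enumerate(models.actions.labels) if mask[x, j]]
            for x in range(states.size)
            if not mask[x].all()
        }
    entries = []
    for i, m in enumerate(models.models):
        entry = {
            "label": m.label,
            "kernel": m.kernel.tolist(),
            "returns": m.returns.tolist(),
        }
        if models.factor_labels is not None:
            entry["factor"] = list(models.factor_labels[i])
        if models.group_labels is not None:
            entry["group"] = models.group_labels[i]
        entries.append(entry)
    doc["models"] = entries
    doc["weights"] = [float(w) for w in q.weights]
    doc["solver"] = {
        "horizon": config.horizon,
        "discount": config.discount,
        "tie_tolerance": config.tie_tolerance,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
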