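"""Passive and active adaptive optimization over system state x model state.

Passive optimization freezes the current belief ``q`` for the remainder of the
time frame and solves the resulting model-averaged MDP — decision making that
accounts for uncertainty but not for learning.  Active optimization solves the
belief-state Bellman equation

    V_t(x, q) = max_a { Rbar(a|x,q)
                        + sum_{x'} Pbar(x'|x,a,q) V_{t+1}(x', q') },

where ``q'`` is the Bayes posterior after observing x -> x', so anticipated
learning feeds back into the choice of action.  Two active modes are offered:
``exact_reachable`` enumerates the finitely many reachable posteriors (the
reference implementation, feasible at short horizons), and ``grid`` projects
posteriors back onto a fixed simplex lattice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .beliefs import ModelSet, ModelState, average_model, belief_grid, bayes_update
from .errors import ConfigurationError, InstanceTooLargeError
from .mdp import Policy, SolverConfig, ValueFunction, solve_model

_ROUND = 12  # decimals used to key memoized beliefs


def passive_solve(
    models: ModelSet,
    q: ModelState,
    config: SolverConfig,
    terminal: Optional[Sequence[float]] = None,
) -> tuple[ValueFunction, Policy]:
    """Optimal values/policy of the belief-averaged model with ``q`` held fixed."""
    return solve_model(average_model(models, q), config, terminal)


@dataclass
class AdaptiveValue:
    """Active-adaptive solution; query with :meth:`value` / :meth:`action`."""

    models: ModelSet
    config: SolverConfig
    mode: str
    _impl: object

    def value(self, x: int, q: ModelState, t: int = 0) -> float:
        """Optimal accumulated value from epoch ``t`` in state ``x`` at belief ``q``."""
        return self._impl.value(x, q, t)

    def action(self, x: int, q: ModelState, t: int = 0) -> int:
        """Index of the optimal action at (t, x, q)."""
        return self._impl.action(x, q, t)


class _ExactReachable:
    """Memoized recursion over the exactly reachable belief tree."""

    def __init__(self, models, config, terminal, max_nodes):
        self.models = models
        self.config = config
        self.terminal = (
            np.zeros(models.states.size) if terminal is None else np.asarray(terminal, float)
        )
        self.max_nodes = max_nodes
        self.memo = {}
        self.mask = models.actions.mask(models.states.size)
        # stacked kernels/returns: (K, S, A, S) and (K, S, A)
        self.P = np.stack([m.kernel for m in models.models])
        self.R = np.stack([m.returns for m in models.models])

    def _solve(self, t, x, w):
        if t == self.config.horizon:
            return (float(self.terminal[x]), -1)
        key = (t, x, tuple(np.round(w, _ROUND)))
        hit = self.memo.get(key)
        if hit is not None:
            return hit
        if len(self.memo) >= self.max_nodes:
            raise InstanceTooLargeError(
                f"reachable-belief tree exceeded the guard of {self.max_nodes} nodes"
            )
        last = t == self.config.horizon - 1
        best_v, best_a = -np.inf, -1
        for a in range(self.models.actions.size):
            if not self.mask[x, a]:
                continue
            rbar = float(w @ self.R[:, x, a])
            pred = w @ self.P[:, x, a, :]  # Bayes predictive over successors
            if last:
                cont = float(pred @ self.terminal)
            else:
                cont = 0.0
                for xn in np.flatnonzero(pred > 0):
                    post = w * self.P[:, x, a, xn]
                    post = post / post.sum()
                    cont += pred[xn] * self._solve(t + 1, xn, post)[0]
            qa = rbar + self.config.discount * cont
            if qa > best_v + self.config.tie_tolerance:
                best_v, best_a = qa, a
        res = (best_v, best_a)
        self.memo[key] = res
        return res

    def value(self, x, q, t=0):
        return self._solve(t, x, np.asarray(q.weights, float))[0]

    def action(self, x, q, t=0):
        return self._solve(t, x, np.asarray(q.weights, float))[1]


class _Grid:
    """Backward induction on a fixed simplex lattice.

    Posteriors that fall off the lattice are projected back: by linear
    interpolation along the one-dimensional simplex for two models, and by
    nearest lattice point otherwise.
    """

    def __init__(self, models, config, terminal, resolution):
        if resolution is None or resolution < 1:
            raise ConfigurationError("grid mode needs a positive grid_resolution")
        self.models = models
        self.config = config
        K = len(models)
        S = models.states.size
        A = models.actions.size
        self.points = belief_grid(K, resolution)
        W = np.stack([p.weights for p in self.points])  # (G, K)
        G = W.shape[0]
        P = np.stack([m.kernel for m in models.models])  # (K, S, A, S)
        R = np.stack([m.returns for m in models.models])  # (K, S, A)
        mask = models.actions.mask(S)

        Rbar = np.einsum("gk,ksa->gsa", W, R)
        Pbar = np.einsum("gk,ksay->gsay", W, P)
        # posterior at (g, x, a, x'): W[g] * P[:, x, a, x'], normalized
        post = W[:, :, None, None, None] * P.transpose(1, 2, 3, 0)[None].transpose(0, 4, 1, 2, 3)
        # post shape (G, K, S, A, S); normalize over K where predictive > 0
        tot = post.sum(axis=1)  # == Pbar
        with np.errstate(invalid="ignore", divide="ignore"):
            post = np.where(tot[:, None] > 0, post / np.where(tot[:, None] == 0, 1, tot[:, None]), 0)

        if K == 2:
            # barycentric interpolation on q[0] in {0, 1/res, ..., 1}
            p0 = np.clip(post[:, 0], 0.0, 1.0) * resolution
            lo = np.floor(p0).astype(int)
            hi = np.minimum(lo + 1, resolution)
            frac = p0 - lo
            # grid points ordered by belief_grid; build lookup from q0-step to index
            step0 = np.rint(W[:, 0] * resolution).astype(int)
            lut = np.empty(resolution + 1, dtype=int)
            lut[step0] = np.arange(G)
            self.interp = ("linear", lut[lo], lut[hi], frac)
        else:
            flat = post.transpose(0, 2, 3, 4, 1).reshape(-1, K)
            d2 = ((flat[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
            nearest = d2.argmin(axis=1).reshape(G, S, A, S)
            self.interp = ("nearest", nearest)

        T = config.horizon
        term = np.zeros(S) if terminal is None else np.asarray(terminal, float)
        V = np.empty((T + 1, G, S))
        V[T] = term[None, :]
        Astar = np.empty((T, G, S), dtype=int)
        for t in range(T - 1, -1, -1):
            if self.interp[0] == "linear":
                _, ilo, ihi, frac = self.interp
                Vnext = (1 - frac) * V[t + 1][ilo, np.arange(S)[None, None, None, :]] + frac * V[
                    t + 1
                ][ihi, np.arange(S)[None, None, None, :]]
            else:
                idx = self.interp[1]
                Vnext = V[t + 1][idx, np.arange(S)[None, None, None, :]]
            Q = Rbar + config.discount * np.einsum("gsay,gsay->gsa", Pbar, Vnext)
            Q = np.where(mask[None], Q, -np.inf)
            best = Q.max(axis=2)
            Astar[t] = (Q >= best[..., None] - config.tie_tolerance).argmax(axis=2)
            V[t] = np.take_along_axis(Q, Astar[t][..., None], axis=2)[..., 0]
        self.W = W
        self.V = V
        self.Astar = Astar
        self.resolution = resolution

    def _locate(self, q):
        d2 = ((self.W - np.asarray(q.weights)[None, :]) ** 2).sum(axis=1)
        return int(d2.argmin())

    def value(self, x, q, t=0):
        if len(q) == 2:
            res = self.resolution
            p0 = float(np.clip(q.weights[0], 0, 1)) * res
            lo, frac = int(np.floor(p0)), p0 - np.floor(p0)
            hi = min(lo + 1, res)
            step0 = np.rint(self.W[:, 0] * res).astype(int)
            lut = np.empty(res + 1, dtype=int)
            lut[step0] = np.arange(len(self.W))
            return float((1 - frac) * self.V[t, lut[lo], x] + frac * self.V[t, lut[hi], x])
        return float(self.V[t, self._locate(q), x])

    def action(self, x, q, t=0):
        return int(self.Astar[t, self._locate(q), x])


def active_solve(
    models: ModelSet,
    config: SolverConfig,
    terminal: Optional[Sequence[float]] = None,
    mode: str = "exact_reachable",
    grid_resolution: Optional[int] = None,
    max_nodes: int = 10**5,
) -> AdaptiveValue:
    """Solve the active-adaptive Bellman equation over (system state, belief)."""
    if mode == "exact_reachable":
        impl = _ExactReachable(models, config, terminal, max_nodes)
    elif mode == "grid":
        impl = _Grid(models, config, terminal, grid_resolution)
    else:
        raise ConfigurationError(f"unknown active mode {mode!r}")
    return AdaptiveValue(models, config, mode, impl)
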