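"""Independent oracles used to cross-check the implementation.

These deliberately avoid the package's solver code paths: the Monte-Carlo
oracle simulates trajectories forward, and the decision-tree oracle evaluates
the active-adaptive recursion by plain exhaustive recursion on raw arrays.
"""

from __future__ import annotations

import numpy as np


def mc_policy_value(kernel, returns, actions, x0, horizon, rng, n_rollouts=20000,
                    discount=1.0, terminal=None):
    """Monte-Carlo estimate of the value of a fixed policy from state ``x0``.

    ``kernel``/``returns`` are raw (S, A, S) and (S, A) arrays; ``actions`` is
    the (horizon, S) integer policy table.  Returns (mean, standard error).
    """
    S = returns.shape[0]
    term = np.zeros(S) if terminal is None else np.asarray(terminal, float)
    totals = np.empty(n_rollouts)
    for i in range(n_rollouts):
        x = x0
        acc = 0.0
        disc = 1.0
        for t in range(horizon):
            a = actions[t, x]
            acc += disc * returns[x, a]
            x = rng.choice(S, p=kernel[x, a])
            disc *= discount
        totals[i] = acc + disc * term[x]
    return float(totals.mean()), float(totals.std(ddof=1) / np.sqrt(n_rollouts))


def tree_active_value(kernels, returns, w, x, horizon, discount=1.0, terminal=None,
                      admissible=None):
    """Exact active-adaptive value by exhaustive recursion (no memoization).

    ``kernels`` is a list of (S, A, S) arrays (one per model), ``returns`` a
    list of (S, A) arrays, ``w`` the belief vector.  This mirrors the Bellman
    equation over (state, belief) directly and is exponential in the horizon,
    so keep instances tiny.
    """
    kernels = [np.asarray(P, float) for P in kernels]
    returns = [np.asarray(R, float) for R in returns]
    S, A = returns[0].shape
    term = np.zeros(S) if terminal is None else np.asarray(terminal, float)
    adm = np.ones((S, A), bool) if admissible is None else np.asarray(admissible, bool)

    def rec(t, x, w):
        if t == horizon:
            return float(term[x])
        best = -np.inf
        for a in range(A):
            if not adm[x, a]:
                continue
            rbar = sum(w[k] * returns[k][x, a] for k in range(len(w)))
            val = rbar
            for xn in range(S):
                pred = sum(w[k] * kernels[k][x, a, xn] for k in range(len(w)))
                if pred <= 0.0:
                    continue
                post = np.array([w[k] * kernels[k][x, a, xn] for k in range(len(w))])
                post = post / post.sum()
                val += discount * pred * rec(t + 1, xn, post)
            best = max(best, val)
        return best

    return rec(0, x, np.asarray(w, float))
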