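"""Exhaustive posterior evaluation for small problems.

Enumerates every valid sampler state (all base graphs, delta sequences,
changepoint vectors and lag vectors) and normalizes the scores into an exact
posterior.  Exponential in every dimension — intended for 2-3 genes and a
handful of time points, where it serves as the ground truth the RJMCMC chain
is checked against.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from .scoring import Model, SamplerState, segment_bounds


def _subsets(items):
    items = list(items)
    for mask in range(1 << len(items)):
        yield frozenset(x for i, x in enumerate(items) if mask >> i & 1)


def _changepoint_vectors(T: int, m: int, min_seg_len: int, first_cp_min: int):
    ms = min_seg_len
    if m == 1:
        yield ()
        return
    for combo in combinations(range(first_cp_min, T + 2 - ms), m - 1):
        ok = all(b - a >= ms for a, b in zip(combo, combo[1:]))
        if ok and (T + 1) - combo[-1] >= ms:
            yield combo


def enumerate_states(model: Model, m_max: int | None = None):
    """Yield every valid SamplerState of the model (up to ``m_max`` segments)."""
    m_max = m_max or model.priors.m_max
    edges = range(model.E_max)
    ms = model.priors.min_seg_len

    def graphs_ok(g):
        return model.fan_in_ok(frozenset(g))

    base_graphs = [g for g in _subsets(edges) if graphs_ok(g)]
    for m in range(1, m_max + 1):
        for L in _changepoint_vectors(model.T, m, ms, model.first_cp_min):
            bounds = segment_bounds(L, model.T)
            lag_sets = [list(model.feasible_lags(end)) for _, end in bounds]

            def delta_seqs(g, k):
                if k == len(L):
                    yield ()
                    return
                for toggles in _subsets(edges):
                    delta = frozenset((e, -1 if e in g else 1) for e in toggles)
                    g2 = g ^ toggles
                    if not graphs_ok(g2):
                        continue
                    for rest in delta_seqs(g2, k + 1):
                        yield (delta, *rest)

            for g1 in base_graphs:
                for deltas in delta_seqs(set(g1), 0):
                    for tau in _tau_vectors(lag_sets):
                        yield SamplerState(g1, deltas, L, tau)


def _tau_vectors(lag_sets):
    if not lag_sets:
        yield ()
        return
    first, rest = lag_sets[0], lag_sets[1:]
    for t in first:
        for tail in _tau_vectors(rest):
            yield (t, *tail)


def exact_posterior(model: Model, m_max: int | None = None) -> dict[SamplerState, float]:
    """Normalized posterior probability of every valid state."""
    states = list(enumerate_states(model, m_max))
    logs = np.array([model.log_posterior(s).total for s in states])
    probs = np.exp(logs - logsumexp(logs))
    return dict(zip(states, probs))


def total_variation(p: dict, q: dict) -> float:
    """TV distance between two distributions given as dicts."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)
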