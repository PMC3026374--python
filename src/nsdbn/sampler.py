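"""Reversible-jump MCMC over graph sequences, changepoints and lags.

Eleven move types explore the state space:

=====  ==========================================  ==============
move   effect                                      reverse
=====  ==========================================  ==============
MT1    add an edge to one segment's graph G_i      MT2
MT2    delete an edge from one segment's G_i       MT1
MT3    add an edge change to one delta             MT4
MT4    delete an edge change from one delta        MT3
MT5    move an edge change between deltas          MT5
MT6    shift one changepoint (lag re-drawn)        MT6
MT7    re-draw one segment's lag                   MT7
MT8    merge two adjacent deltas                   MT9
MT9    split one delta at a new changepoint        MT8
MT10   insert a changepoint with an empty delta    MT11
MT11   delete a changepoint with an empty delta    MT10
=====  ==========================================  ==============

Every proposal carries the exact log proposal-probability of itself and of the
reverse move, so the Metropolis-Hastings ratio is correct across dimension
changes (the state space is discrete: no Jacobian term).  All uniform choices
are drawn from a single seeded generator in a fixed order, making chains
bit-reproducible.

Constraints respected throughout: every edge originates from the target's
candidate regulators (encoded in the model's edge universe), segments keep a
minimum length, and each segment's lag tau_h never exceeds its end - 1, so a
child time with t - tau_h >= 1 always exists.  Merging two segments assigns
the smaller of the two lags to the merged segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, InvalidStateError
from .scoring import (Model, SamplerState, ScoreComponents, graph_sequence,
                      initial_state, segment_bounds)

MOVE_TYPES = ("MT1", "MT2", "MT3", "MT4", "MT5", "MT6", "MT7", "MT8", "MT9", "MT10", "MT11")


@dataclass
class ChainConfig:
    iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 1
    seed: int = 0
    move_weights: dict | None = None  # move type -> nonnegative weight

    def weights(self) -> np.ndarray:
        if self.move_weights is None:
            w = np.ones(len(MOVE_TYPES))
        else:
            unknown = set(self.move_weights) - set(MOVE_TYPES)
            if unknown:
                raise ConfigError(f"unknown move types {sorted(unknown)}")
            w = np.array([float(self.move_weights.get(mt, 0.0)) for mt in MOVE_TYPES])
        if (w < 0).any() or w.sum() <= 0:
            raise ConfigError("move weights must be nonnegative and not all zero")
        return w / w.sum()

    def validate(self) -> None:
        if self.iterations <= 0 or self.burn_in < 0 or self.burn_in >= self.iterations:
            raise ConfigError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        self.weights()


@dataclass
class MoveProposal:
    move_type: str
    new_state: SamplerState
    log_q_fwd: float  # log prob of proposing new_state from the current state
    log_q_rev: float  # log prob of proposing the current state back
    reverse: tuple    # (reverse move type, reverse choices)

    @property
    def log_proposal_ratio(self) -> float:
        return self.log_q_rev - self.log_q_fwd


@dataclass
class Trace:
    """Post-burn-in samples with scores, plus bookkeeping for summaries."""

    samples: list  # list of (SamplerState, ScoreComponents)
    accepted: dict
    proposed: dict
    config: ChainConfig
    T: int
    gene_names: list
    edges: list  # edge id -> (parent gene index, child gene index)


# ---------------------------------------------------------------------------
# structural validity of a trial state


def _structurally_valid(model: Model, state: SamplerState) -> bool:
    try:
        graphs = graph_sequence(state)
    except InvalidStateError:
        return False
    cap = model.priors.max_fan_in
    for g in graphs:
        fan: dict[int, int] = {}
        for e in g:
            c = model.edges[e][1]
            fan[c] = fan.get(c, 0) + 1
            if fan[c] > cap:
                return False
    return True


class _Choice:
    """Uniform choice that either samples (rng) or validates given choices."""

    def __init__(self, choices, rng):
        self.choices = list(choices) if choices is not None else None
        self.rng = rng
        self.pos = 0
        self.logp = 0.0

    def pick(self, options):
        options = list(options)
        if not options:
            raise _Infeasible
        self.logp -= math.log(len(options))
        if self.choices is None:
            return options[self.rng.integers(len(options))]
        val = self.choices[self.pos]
        self.pos += 1
        if val not in options:
            raise ValueError(f"choice {val!r} not in the move's support")
        return val

    def pick_subset(self, items):
        """Independent fair coin per item (2^s equally likely subsets)."""
        items = list(items)
        self.logp -= len(items) * math.log(2.0)
        if self.choices is None:
            keep = [x for x in items if self.rng.integers(2)]
            return frozenset(keep)
        val = self.choices[self.pos]
        self.pos += 1
        if not frozenset(val) <= frozenset(items):
            raise ValueError("subset choice outside the move's support")
        return frozenset(val)


class _Infeasible(Exception):
    """The chosen move has no admissible realisation from this state."""


def _fan_in_ok_with(model: Model, graph: frozenset, e: int) -> bool:
    child = model.edges[e][1]
    fan = sum(1 for f in graph if model.edges[f][1] == child)
    return fan < model.priors.max_fan_in


def _edit_segment_graph(model_state: SamplerState, graphs, i: int, e: int,
                        add: bool) -> SamplerState:
    """Add or delete edge ``e`` in segment ``i``'s graph only.

    The base graph or the two flanking deltas are adjusted so every other
    segment's graph is untouched; delta well-formedness is preserved by
    construction (the edge's status in the neighbouring graphs is unchanged).
    """
    state = model_state
    m = state.m
    sign_in = 1 if add else -1
    deltas = list(state.deltas)
    g1 = state.g1
    if i == 0:
        g1 = (g1 | {e}) if add else (g1 - {e})
    else:
        d = set(deltas[i - 1])
        if (e, -sign_in) in d:
            d.discard((e, -sign_in))
        else:
            d.add((e, sign_in))
        deltas[i - 1] = frozenset(d)
    if i < m - 1:
        d = set(deltas[i])
        if (e, sign_in) in d:
            d.discard((e, sign_in))
        else:
            d.add((e, -sign_in))
        deltas[i] = frozenset(d)
    return replace(state, g1=g1, deltas=tuple(deltas))


def _lag_pairs(model: Model, end_a: int, end_b: int, tau_merged: int):
    """(lag_a, lag_b) pairs whose minimum equals the merged lag."""
    fa = model.feasible_lags(end_a)
    fb = model.feasible_lags(end_b)
    return [(a, b) for a in fa for b in fb if min(a, b) == tau_merged]


# ---------------------------------------------------------------------------
# the eleven moves


def _directed(model: Model, state: SamplerState, move_type: str,
              choices=None, rng=None):
    """Execute one move with explicit or sampled choices.

    Returns (new_state, log_choice_prob, (reverse_move, reverse_choices)) or
    raises _Infeasible when the move has no admissible realisation.
    """
    ch = _Choice(choices, rng)
    T, ms = model.T, model.priors.min_seg_len
    m = state.m
    E = model.E_max

    if move_type == "MT1":
        i = ch.pick(range(m))
        graphs = graph_sequence(state)
        gi = graphs[i]
        cands = [e for e in range(E) if e not in gi
                 and _fan_in_ok_with(model, gi, e)]
        e = ch.pick(cands)
        new = _edit_segment_graph(state, graphs, i, e, add=True)
        return new, ch.logp, ("MT2", (i, e))

    if move_type == "MT2":
        i = ch.pick(range(m))
        gi = graph_sequence(state)[i]
        e = ch.pick(sorted(gi))
        new = _edit_segment_graph(state, graph_sequence(state), i, e, add=False)
        return new, ch.logp, ("MT1", (i, e))

    if move_type == "MT3":
        if m < 2:
            raise _Infeasible
        i = ch.pick(range(m - 1))
        graphs = graph_sequence(state)
        gi = graphs[i]
        touched = {e for e, _ in state.deltas[i]}
        cands = []
        for e in range(E):
            if e in touched:
                continue
            s = -1 if e in gi else 1
            trial_deltas = list(state.deltas)
            trial_deltas[i] = state.deltas[i] | {(e, s)}
            if _structurally_valid(model, replace(state, deltas=tuple(trial_deltas))):
                cands.append((e, s))
        e, s = ch.pick(cands)
        new_deltas = list(state.deltas)
        new_deltas[i] = state.deltas[i] | {(e, s)}
        new = replace(state, deltas=tuple(new_deltas))
        return new, ch.logp, ("MT4", (i, (e, s)))

    if move_type == "MT4":
        if m < 2:
            raise _Infeasible
        i = ch.pick(range(m - 1))
        cands = []
        for chg in state.deltas[i]:
            trial_deltas = list(state.deltas)
            trial_deltas[i] = state.deltas[i] - {chg}
            if _structurally_valid(model, replace(state, deltas=tuple(trial_deltas))):
                cands.append(chg)
        chg = ch.pick(sorted(cands))
        new_deltas = list(state.deltas)
        new_deltas[i] = state.deltas[i] - {chg}
        new = replace(state, deltas=tuple(new_deltas))
        return new, ch.logp, ("MT3", (i, chg))

    if move_type == "MT5":
        if m < 3:
            raise _Infeasible
        i = ch.pick(range(m - 1))
        chg = ch.pick(sorted(state.deltas[i]))
        j = ch.pick([k for k in range(m - 1) if k != i])
        if any(e == chg[0] for e, _ in state.deltas[j]):
            raise _Infeasible
        new_deltas = list(state.deltas)
        new_deltas[i] = state.deltas[i] - {chg}
        new_deltas[j] = state.deltas[j] | {chg}
        new = replace(state, deltas=tuple(new_deltas))
        if not _structurally_valid(model, new):
            raise _Infeasible
        return new, ch.logp, ("MT5", (j, chg, i))

    if move_type == "MT6":
        if m < 2:
            raise _Infeasible
        i = ch.pick(range(m - 1))
        lprev = state.L[i - 1] if i > 0 else 1
        lnext = state.L[i + 1] if i < m - 2 else T + 1
        lo = max(lprev + ms, model.first_cp_min) if i == 0 else lprev + ms
        new_l = ch.pick(range(lo, lnext - ms + 1))
        new_tau_i = ch.pick(model.feasible_lags(new_l - 1))
        L = list(state.L)
        tau = list(state.tau)
        old_l, old_tau = L[i], tau[i]
        L[i], tau[i] = new_l, new_tau_i
        new = replace(state, L=tuple(L), tau=tuple(tau))
        return new, ch.logp, ("MT6", (i, old_l, old_tau))

    if move_type == "MT7":
        h = ch.pick(range(m))
        end = segment_bounds(state.L, T)[h][1]
        new_tau = ch.pick(model.feasible_lags(end))
        tau = list(state.tau)
        old_tau = tau[h]
        tau[h] = new_tau
        new = replace(state, tau=tuple(tau))
        return new, ch.logp, ("MT7", (h, old_tau))

    if move_type == "MT8":
        if m < 3:
            raise _Infeasible
        k = ch.pick(range(m - 2))
        d1, d2 = state.deltas[k], state.deltas[k + 1]
        if {e for e, _ in d1} & {e for e, _ in d2}:
            raise _Infeasible  # cancellation: not reproducible by a split
        composed = d1 | d2
        deltas = state.deltas[:k] + (composed,) + state.deltas[k + 2:]
        removed_l = state.L[k + 1]
        L = state.L[:k + 1] + state.L[k + 2:]
        merged = min(state.tau[k + 1], state.tau[k + 2])
        tau = state.tau[:k + 1] + (merged,) + state.tau[k + 3:]
        new = replace(state, deltas=deltas, L=L, tau=tau)
        return new, ch.logp, ("MT9", (k, removed_l, d1, (state.tau[k + 1], state.tau[k + 2])))

    if move_type == "MT9":
        if m < 2 or m >= model.priors.m_max:
            raise _Infeasible
        k = ch.pick(range(m - 1))
        start, end = segment_bounds(state.L, T)[k + 1]
        split = ch.pick(range(start + ms, end + 1 - ms + 1))
        part_a = ch.pick_subset(sorted(state.deltas[k]))
        part_b = state.deltas[k] - part_a
        tau_old = state.tau[k + 1]
        ta, tb = ch.pick(_lag_pairs(model, split - 1, end, tau_old))
        deltas = state.deltas[:k] + (part_a, part_b) + state.deltas[k + 1:]
        L = state.L[:k + 1] + (split,) + state.L[k + 1:]
        tau = state.tau[:k + 1] + (ta, tb) + state.tau[k + 2:]
        new = replace(state, deltas=deltas, L=L, tau=tau)
        if not _structurally_valid(model, new):
            raise _Infeasible  # intermediate graph can break the fan-in cap
        return new, ch.logp, ("MT8", (k,))

    if move_type == "MT10":
        if m >= model.priors.m_max:
            raise _Infeasible
        bounds = segment_bounds(state.L, T)
        cand_times = []
        for h, (s, e) in enumerate(bounds):
            lo = max(s + ms, model.first_cp_min) if h == 0 else s + ms
            cand_times.extend((t, h) for t in range(lo, e + 1 - ms + 1))
        t = ch.pick([t for t, _ in cand_times])
        h = dict(cand_times)[t]
        s, e = bounds[h]
        # content: empty delta or one signed edge change valid at this position
        gh = graph_sequence(state)[h]
        contents = [None]
        for e_id in range(E):
            sign = -1 if e_id in gh else 1
            trial_deltas = (state.deltas[:h] + (frozenset({(e_id, sign)}),)
                            + state.deltas[h:])
            trial = replace(state, deltas=trial_deltas, L=state.L[:h] + (t,) + state.L[h:],
                            tau=state.tau[:h] + (1, 1) + state.tau[h + 1:])
            if _structurally_valid(model, trial):
                contents.append((e_id, sign))
        content = ch.pick(contents)
        tau_old = state.tau[h]
        ta, tb = ch.pick(_lag_pairs(model, t - 1, e, tau_old))
        new_delta = frozenset() if content is None else frozenset({content})
        deltas = state.deltas[:h] + (new_delta,) + state.deltas[h:]
        L = state.L[:h] + (t,) + state.L[h:]
        tau = state.tau[:h] + (ta, tb) + state.tau[h + 1:]
        new = replace(state, deltas=deltas, L=L, tau=tau)
        return new, ch.logp, ("MT11", (h,))

    if move_type == "MT11":
        if m < 2:
            raise _Infeasible
        cands = []
        for k, d in enumerate(state.deltas):
            if len(d) > 1:
                continue
            trial = replace(state, deltas=state.deltas[:k] + state.deltas[k + 1:],
                            L=state.L[:k] + state.L[k + 1:],
                            tau=state.tau[:k] + (min(state.tau[k], state.tau[k + 1]),)
                                + state.tau[k + 2:])
            if _structurally_valid(model, trial):
                cands.append(k)
        k = ch.pick(cands)
        removed = next(iter(state.deltas[k])) if state.deltas[k] else None
        deltas = state.deltas[:k] + state.deltas[k + 1:]
        removed_l = state.L[k]
        L = state.L[:k] + state.L[k + 1:]
        merged = min(state.tau[k], state.tau[k + 1])
        tau = state.tau[:k] + (merged,) + state.tau[k + 2:]
        new = replace(state, deltas=deltas, L=L, tau=tau)
        return new, ch.logp, ("MT10", (removed_l, removed, (state.tau[k], state.tau[k + 1])))

    raise ConfigError(f"unknown move type {move_type!r}")


def apply_move(model: Model, state: SamplerState, move_type: str, choices):
    """Deterministically execute a move with explicit choices.

    Returns (new_state, log_choice_prob).  Used to realise reverse moves.
    """
    new, logp, _rev = _directed(model, state, move_type, choices=list(choices))
    return new, logp


def propose(model: Model, state: SamplerState, move_type: str, rng,
            log_move_weights=None) -> MoveProposal | None:
    """Sample one proposal; None means the move has no admissible realisation."""
    try:
        new, logp_fwd, (rev_mt, rev_choices) = _directed(model, state, move_type, rng=rng)
    except _Infeasible:
        return None
    _, logp_rev = apply_move(model, new, rev_mt, rev_choices)
    if log_move_weights is None:
        lw_f = lw_r = 0.0
    else:
        lw_f = log_move_weights[MOVE_TYPES.index(move_type)]
        lw_r = log_move_weights[MOVE_TYPES.index(rev_mt)]
    return MoveProposal(move_type, new, lw_f + logp_fwd, lw_r + logp_rev,
                        (rev_mt, rev_choices))


def accept(current_total: float, proposed_total: float, log_proposal_ratio: float,
           rng) -> bool:
    """Metropolis-Hastings acceptance with probability min(1, ratio)."""
    log_alpha = proposed_total - current_total + log_proposal_ratio
    return log_alpha >= 0 or rng.random() < math.exp(log_alpha)


def run_chain(model: Model, cfg: ChainConfig) -> Trace:
    """Run the RJMCMC chain and collect thinned post-burn-in samples.

    Starts at one segment with the empty graph; the single lag is drawn from
    the lag prior restricted to feasible values.  Identical seeds give
    identical traces.
    """
    cfg.validate()
    weights = cfg.weights()
    log_w = np.full(len(MOVE_TYPES), -np.inf)
    nz = weights > 0
    log_w[nz] = np.log(weights[nz])
    rng = np.random.Generator(np.random.PCG64(cfg.seed))

    p = np.asarray(model.candidates.lag_probs, dtype=float)
    feas = np.array(model.feasible_lags(model.T))
    p0 = p[feas - 1] / p[feas - 1].sum()
    state = initial_state(int(rng.choice(feas, p=p0)))
    violations = model.validate_state(state)
    if violations:
        raise InvalidStateError(f"invalid initial state: {violations}")
    score = model.log_posterior(state)

    samples: list = []
    accepted = {mt: 0 for mt in MOVE_TYPES}
    proposed = {mt: 0 for mt in MOVE_TYPES}
    for it in range(cfg.iterations):
        mt = MOVE_TYPES[rng.choice(len(MOVE_TYPES), p=weights)]
        proposed[mt] += 1
        prop = propose(model, state, mt, rng, log_move_weights=log_w)
        if prop is not None:
            new_score = model.log_posterior(prop.new_state)
            if accept(score.total, new_score.total, prop.log_proposal_ratio, rng):
                state, score = prop.new_state, new_score
                accepted[mt] += 1
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            samples.append((state, score))
    return Trace(samples, accepted, proposed, cfg, model.T,
                 list(model.data.gene_names), list(model.edges))


def validate_state(state: SamplerState, model: Model) -> list[str]:
    """Convenience wrapper; empty list means every invariant holds."""
    return model.validate_state(state)
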