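"""Log-posterior of a piecewise-constant DBN sequence.

The model: the series of T time points is cut into m contiguous segments by
changepoints L = (L_1, ..., L_{m-1}); segment h is governed by one directed
graph G_h and one lag tau_h.  The graph sequence is stored as a base graph G_1
plus edge-change sets (deltas), one per changepoint.  The log posterior (up to
the constant evidence term) decomposes as

    log P(state | D)  =  log P(D | G^T, m, tau^T)        extended BDe
                       + log P(G^T | m)                  exponential structure prior
                       + log P(m)                        exponential segment-count prior
                       + log P(L | m)                    uniform over valid changepoint vectors
                       + log P(tau^T | m)                empirical lag prior

Within a segment the data are multinomial with a Dirichlet prior whose
hyperparameters are weighted by the segment length over the sample size:
alpha_ijk(I_h) = alpha * |I_h| / (r_i * q_ih * N).  Each child at time t reads
its parents at time t - tau_h; child times with t - tau_h < 1 are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .errors import InvalidStateError, ScoringError
from .preprocess import DiscreteMatrix
from .regulators import CandidateRegulators

# ---------------------------------------------------------------------------
# State


@dataclass(frozen=True)
class SamplerState:
    """Full RJMCMC configuration: base graph, deltas, changepoints, lags.

    ``g1`` is a frozenset of edge ids (indices into the model's admissible edge
    list); ``deltas[i]`` is a frozenset of (edge_id, sign) with sign +1 (edge
    appears going into segment i+1) or -1 (edge disappears); ``L`` are 1-based
    changepoint start times, strictly increasing; ``tau`` has one lag per
    segment.
    """

    g1: frozenset
    deltas: tuple
    L: tuple
    tau: tuple

    @property
    def m(self) -> int:
        return len(self.tau)

    def __post_init__(self):
        if len(self.deltas) != len(self.L) or len(self.tau) != len(self.L) + 1:
            raise InvalidStateError("deltas/L/tau lengths inconsistent")


def initial_state(tau: int = 1) -> SamplerState:
    """Least-informative valid state: one segment, empty graph."""
    return SamplerState(frozenset(), (), (), (tau,))


def segment_bounds(L: Sequence[int], T: int) -> list[tuple[int, int]]:
    """Inclusive (start, end) time bounds per segment; segment h covers L_{h-1}..L_h - 1."""
    starts = [1, *L]
    ends = [*(l - 1 for l in L), T]
    return list(zip(starts, ends))


def graph_sequence(state: SamplerState) -> list[frozenset]:
    """Derive G_1..G_m by applying the deltas; raises on ill-formed deltas."""
    g = state.g1
    seq = [g]
    for i, d in enumerate(state.deltas):
        adds = {e for e, s in d if s > 0}
        rems = {e for e, s in d if s < 0}
        if len(adds) + len(rems) != len(d):
            raise InvalidStateError(f"delta {i} touches an edge twice")
        if adds & g:
            raise InvalidStateError(f"delta {i} adds an edge already present")
        if rems - g:
            raise InvalidStateError(f"delta {i} removes an absent edge")
        g = (g - rems) | adds
        seq.append(g)
    return seq


# ---------------------------------------------------------------------------
# Model context


@dataclass
class PriorConfig:
    """Hyperparameters of the score; defaults follow common practice for this model."""

    lambda_m: float = 1.0       # segment-count exponential rate
    lambda_s: float = 2.0       # structure-change exponential rate
    alpha: float = 1.0          # equivalent sample size of the Dirichlet prior
    tau_max: int = 2
    m_max: int | None = None    # default floor(T/2)
    min_seg_len: int = 2
    max_fan_in: int = 4
    self_loops: bool = True


class Model:
    """Binds discrete data, candidate regulators and priors; scores states.

    Builds the admissible edge universe (edges into each child from its
    candidate regulators, plus self-loops when enabled) and memoizes per-family
    segment scores, so that re-scoring a state after a local move costs a few
    dictionary lookups.
    """

    def __init__(self, data: DiscreteMatrix, candidates: CandidateRegulators,
                 priors: PriorConfig | None = None, flat_likelihood: bool = False):
        self.flat_likelihood = flat_likelihood  # score only the priors (diagnostics)
        self.data = data
        self.candidates = candidates
        self.priors = priors or PriorConfig(tau_max=candidates.tau_max)
        if self.priors.tau_max != candidates.tau_max:
            raise InvalidStateError("priors.tau_max must match the candidate lag distribution")
        self.T = data.n_times
        self.n = data.n_genes
        if self.priors.m_max is None:
            self.priors.m_max = max(1, self.T // 2)
        # cap m_max at the largest segment count with a feasible changepoint vector
        while self.priors.m_max > 1 and self.n_changepoint_vectors(self.priors.m_max) == 0:
            self.priors.m_max -= 1
        self.gene_index = {g: i for i, g in enumerate(data.gene_names)}
        edges: list[tuple[int, int]] = []
        for child_name, regs in sorted(candidates.parents_of.items()):
            if child_name not in self.gene_index:
                continue
            c = self.gene_index[child_name]
            for r in sorted(regs):
                if r in self.gene_index and r != child_name:
                    edges.append((self.gene_index[r], c))
            if self.priors.self_loops:
                edges.append((c, c))
        self.edges = sorted(set(edges))
        self.edge_index = {e: i for i, e in enumerate(self.edges)}
        self.edge_child = np.array([c for _, c in self.edges], dtype=int) if self.edges else np.zeros(0, int)
        self.log_p = np.log(np.asarray(candidates.lag_probs, dtype=float))
        self._levels = np.asarray(data.levels, dtype=np.int64)
        self._family_cache: dict = {}
        self._lnZ_s = math.log(sum(math.exp(-self.priors.lambda_s * s)
                                   for s in range(len(self.edges) + 1)))
        lam = self.priors.lambda_m
        self._lnZ_m = math.log(sum(math.exp(-lam * k) for k in range(1, self.priors.m_max + 1)))

    # -- structural helpers ------------------------------------------------

    @property
    def E_max(self) -> int:
        return len(self.edges)

    def parents_in_graph(self, graph: frozenset) -> dict[int, tuple[int, ...]]:
        by_child: dict[int, list[int]] = {}
        for e in graph:
            p, c = self.edges[e]
            by_child.setdefault(c, []).append(p)
        return {c: tuple(sorted(ps)) for c, ps in by_child.items()}

    def fan_in_ok(self, graph: frozenset) -> bool:
        if not graph:
            return True
        counts = np.bincount(self.edge_child[list(graph)], minlength=self.n)
        return counts.max() <= self.priors.max_fan_in

    def feasible_lags(self, seg_end: int) -> range:
        """Lags usable for a segment ending at ``seg_end``: 1..min(tau_max, seg_end-1)."""
        return range(1, min(self.priors.tau_max, seg_end - 1) + 1)

    @property
    def first_cp_min(self) -> int:
        """Smallest admissible first changepoint.

        Besides the minimum segment length, the first segment must contain at
        least one scored child time (t > tau_max): a segment lying wholly in
        the conditioned-on prefix would be likelihood-free and its graph
        unidentifiable.
        """
        return max(1 + self.priors.min_seg_len, self.priors.tau_max + 2)

    def n_changepoint_vectors(self, m: int) -> int:
        """Count of valid strictly-increasing changepoint vectors for m segments."""
        ms = self.priors.min_seg_len
        # choose m-1 points in [first_cp_min, T+1-ms] with pairwise gaps >= ms
        a, b, g = self.first_cp_min, self.T + 1 - ms, ms
        k = m - 1
        if k == 0:
            return 1
        span = b - a + 1 - (g - 1) * (k - 1)
        if span < k:
            return 0
        return math.comb(span, k)

    # -- likelihood --------------------------------------------------------

    def family_log_score(self, child: int, parents: tuple[int, ...],
                         start: int, end: int, lag: int) -> float:
        """Segment-weighted BDe term for one child within one segment.

        Child times are restricted to t > tau_max for *every* state (the
        first tau_max slices are conditioned on, not modelled), so competing
        states always score the identical observation set; otherwise a state
        could inflate its marginal likelihood simply by arranging lags and
        early changepoints so that fewer observations are scored.  A segment
        lying entirely within the conditioned-on prefix contributes 0.
        """
        key = (child, parents, start, end, lag)
        hit = self._family_cache.get(key)
        if hit is not None:
            return hit
        t_lo = max(start, self.priors.tau_max + 1)
        if t_lo > end:
            val = 0.0
        else:
            counts = segment_counts(self._levels, child, parents, t_lo, end, lag,
                                    self.data.r)
            val = log_segment_bde_from_counts(counts, end - start + 1, self.T,
                                              self.priors.alpha)
        self._family_cache[key] = val
        return val

    def log_extended_bde(self, state: SamplerState) -> float:
        if self.flat_likelihood:
            return 0.0
        graphs = graph_sequence(state)
        total = 0.0
        for (start, end), lag, graph in zip(segment_bounds(state.L, self.T), state.tau, graphs):
            par = self.parents_in_graph(graph)
            for child in range(self.n):
                total += self.family_log_score(child, par.get(child, ()), start, end, lag)
        return total

    # -- priors ------------------------------------------------------------

    def log_structure_prior(self, state: SamplerState) -> float:
        lam = self.priors.lambda_s
        total = -self.E_max * math.log(2.0)  # uniform over admissible base graphs
        for d in state.deltas:
            s = len(d)
            if s > self.E_max:
                raise InvalidStateError("delta larger than the admissible edge universe")
            total += -lam * s - self._lnZ_s
        return total

    def log_m_prior(self, m: int) -> float:
        if not 1 <= m <= self.priors.m_max:
            raise InvalidStateError(f"segment count m={m} outside 1..{self.priors.m_max}")
        return -self.priors.lambda_m * m - self._lnZ_m

    def log_changepoint_prior(self, state: SamplerState) -> float:
        count = self.n_changepoint_vectors(state.m)
        if count == 0:
            raise InvalidStateError("no valid changepoint vector for this m")
        return -math.log(count)

    def log_lag_prior(self, tau: Sequence[int]) -> float:
        return float(sum(self.log_p[t - 1] for t in tau))

    # -- posterior ---------------------------------------------------------

    def log_posterior(self, state: SamplerState) -> "ScoreComponents":
        return ScoreComponents(
            log_lik=self.log_extended_bde(state),
            log_struct_prior=self.log_structure_prior(state),
            log_m_prior=self.log_m_prior(state.m),
            log_cp_prior=self.log_changepoint_prior(state),
            log_lag_prior=self.log_lag_prior(state.tau),
        )

    def log_posterior_fresh(self, state: SamplerState) -> "ScoreComponents":
        """Full recompute bypassing the family cache (consistency oracle)."""
        cache, self._family_cache = self._family_cache, {}
        try:
            return self.log_posterior(state)
        finally:
            self._family_cache = cache

    # -- validation --------------------------------------------------------

    def validate_state(self, state: SamplerState) -> list[str]:
        """Return all invariant violations (empty list = valid state)."""
        out: list[str] = []
        ms, T = self.priors.min_seg_len, self.T
        m = state.m
        if not 1 <= m <= self.priors.m_max:
            out.append(f"m={m} outside 1..{self.priors.m_max}")
        if any(not 0 <= e < self.E_max for e in state.g1):
            out.append("base graph contains an edge outside the admissible universe")
        try:
            graphs = graph_sequence(state)
        except InvalidStateError as err:
            out.append(str(err))
            graphs = None
        if graphs is not None:
            for h, g in enumerate(graphs):
                if any(not 0 <= e < self.E_max for e in g):
                    out.append(f"graph {h + 1} leaves the admissible universe")
                    break
                if not self.fan_in_ok(g):
                    out.append(f"graph {h + 1} exceeds the fan-in cap")
        if state.L and state.L[0] < self.first_cp_min:
            out.append(f"first changepoint {state.L[0]} inside the conditioned prefix")
        prev = 1
        for i, l in enumerate(state.L):
            if l - prev < ms:
                out.append(f"segment {i + 1} shorter than {ms}")
            prev = l
        if T + 1 - prev < ms:
            out.append(f"last segment shorter than {ms}")
        for h, ((_, end), t) in enumerate(zip(segment_bounds(state.L, T), state.tau)):
            lo, hi = 1, min(self.priors.tau_max, end - 1)
            if not lo <= t <= hi:
                out.append(f"lag tau_{h + 1}={t} outside {lo}..{hi}")
        return out


# ---------------------------------------------------------------------------
# Score components


@dataclass(frozen=True)
class ScoreComponents:
    log_lik: float
    log_struct_prior: float
    log_m_prior: float
    log_cp_prior: float
    log_lag_prior: float

    @property
    def total(self) -> float:
        return (self.log_lik + self.log_struct_prior + self.log_m_prior
                + self.log_cp_prior + self.log_lag_prior)


# ---------------------------------------------------------------------------
# Free functions (building blocks; also used directly by tests)


def segment_counts(levels: np.ndarray, child: int, parents: Sequence[int],
                   start: int, end: int, lag: int, r: int = 3) -> np.ndarray:
    """N_jk counts for one child over one segment.

    Child values are read at t in [start, end] with t - lag >= 1; parents at
    t - lag (possibly before the segment start).  Returns an array of shape
    (q, r) where q = r^len(parents) and the parent configuration index is the
    little-endian base-r encoding of the parents' levels (sorted parent order).
    """
    ts = np.arange(max(start, lag + 1), end + 1)
    if ts.size == 0:
        raise ScoringError(f"segment [{start},{end}] with lag {lag} has no usable time points")
    k = levels[child, ts - 1]
    q = r ** len(parents)
    if parents:
        j = np.zeros(ts.size, dtype=np.int64)
        for idx, p in enumerate(parents):
            j += levels[p, ts - lag - 1] * (r ** idx)
    else:
        j = np.zeros(ts.size, dtype=np.int64)
    flat = np.bincount(j * r + k, minlength=q * r)
    return flat.reshape(q, r)


def log_segment_bde_from_counts(counts: np.ndarray, seg_len: int, N: int,
                                alpha: float = 1.0) -> float:
    """Log BDe term for one family given its (q, r) count table.

    Hyperparameters are segment-weighted: alpha_ijk = alpha*|I_h|/(r*q*N).
    """
    q, r = counts.shape
    a_ijk = alpha * seg_len / (r * q * N)
    if a_ijk <= 0:
        raise ScoringError("nonpositive Dirichlet hyperparameter")
    a_ij = r * a_ijk
    n_ij = counts.sum(axis=1)
    val = (gammaln(a_ij) - gammaln(a_ij + n_ij)).sum()
    val += (gammaln(a_ijk + counts) - gammaln(a_ijk)).sum()
    return float(val)


def _family_log_score(levels: np.ndarray, r: int, alpha: float, N: int,
                      child: int, parents: tuple[int, ...],
                      start: int, end: int, lag: int) -> float:
    counts = segment_counts(levels, child, parents, start, end, lag, r)
    return log_segment_bde_from_counts(counts, end - start + 1, N, alpha)


def log_segment_bde(levels: np.ndarray, parent_sets: dict[int, Sequence[int]],
                    start: int, end: int, lag: int, T: int,
                    r: int = 3, alpha: float = 1.0) -> float:
    """Segment-weighted BDe log score of one segment for all children."""
    n = levels.shape[0]
    total = 0.0
    for child in range(n):
        parents = tuple(sorted(parent_sets.get(child, ())))
        total += _family_log_score(levels, r, alpha, T, child, parents, start, end, lag)
    return total


def log_m_prior(m: int, lambda_m: float, m_max: int) -> float:
    """Truncated exponential prior over the number of segments."""
    if not 1 <= m <= m_max:
        raise InvalidStateError(f"m={m} outside 1..{m_max}")
    lnZ = math.log(sum(math.exp(-lambda_m * k) for k in range(1, m_max + 1)))
    return -lambda_m * m - lnZ


def log_structure_prior(delta_sizes: Sequence[int], lambda_s: float, E_max: int) -> float:
    """Exponential prior on the number of edge changes at each changepoint."""
    lnZ = math.log(sum(math.exp(-lambda_s * s) for s in range(E_max + 1)))
    total = -E_max * math.log(2.0)
    for s in delta_sizes:
        if s > E_max:
            raise InvalidStateError("delta larger than the admissible edge universe")
        total += -lambda_s * s - lnZ
    return total


def log_lag_prior(tau: Sequence[int], p: np.ndarray) -> float:
    """Product of empirical lag probabilities, in log."""
    p = np.asarray(p, dtype=float)
    out = 0.0
    for t in tau:
        if not 1 <= t <= p.size:
            raise InvalidStateError(f"lag {t} outside 1..{p.size}")
        if p[t - 1] <= 0:
            raise ScoringError(f"lag {t} has zero prior probability")
        out += math.log(p[t - 1])
    return out
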