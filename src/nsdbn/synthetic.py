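"""Ground-truth generator for piecewise-constant multinomial DBN dynamics.

Simulates the generative model the score assumes: time is cut into segments,
each governed by one directed graph and one lag; within a segment each gene's
level (down/normal/up) at time t is drawn from a conditional probability table
row indexed by its parents' levels at t - tau.  Levels are emitted as
continuous fold-ratio values (level mean + Gaussian noise) so the full
pipeline — imputation, discretization, event detection, sampling — can run on
data with a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .preprocess import DiscreteMatrix, ExpressionMatrix
from .regulators import RegulatorPair

R = 3  # expression levels: 0 down, 1 normal, 2 up
DEFAULT_LEVEL_MEANS = (0.5, 1.0, 1.5)  # fold-ratio scale; straddles the 0.70/1.2 cutoffs


@dataclass
class GroundTruth:
    """Everything the generator knows: graphs, changepoints, lags, CPTs."""

    graphs: list[frozenset]           # per segment, frozenset of (parent, child) gene indices
    changepoints: tuple               # L, 1-based segment start times (length m-1)
    lags: tuple                       # tau, one per segment
    cpts: list[dict]                  # per segment: child -> (q, 3) row-stochastic table
    parent_sets: list[dict]           # per segment: child -> tuple of parents (sorted)
    level_means: tuple = DEFAULT_LEVEL_MEANS
    noise_sd: float = 0.05

    @property
    def m(self) -> int:
        return len(self.graphs)


MAX_TRUE_IN_DEGREE = 1  # single-regulator families stay identifiable from a short series


def _random_graph(rng, n_genes: int, sparsity: float) -> set:
    """Bernoulli(sparsity) edges, trimmed so no child keeps more than two parents."""
    edges = {(p, c) for p in range(n_genes) for c in range(n_genes)
             if p != c and rng.random() < sparsity}
    by_child: dict[int, list[int]] = {}
    for p, c in edges:
        by_child.setdefault(c, []).append(p)
    out = set()
    for c, ps in by_child.items():
        ps = sorted(ps)
        if len(ps) > MAX_TRUE_IN_DEGREE:
            keep = rng.choice(len(ps), size=MAX_TRUE_IN_DEGREE, replace=False)
            ps = [ps[i] for i in sorted(keep)]
        out.update((p, c) for p in ps)
    return out


def _perturb_graph(rng, graph: set, n_genes: int, n_changes: int) -> set:
    """Flip ``n_changes`` off-diagonal edges (the smooth-change assumption).

    Flips are drawn sequentially, each respecting the in-degree cap of the
    graph as rewired so far, and each touching a different target gene: every
    rewiring event toggles the regulation of one distinct gene, which keeps
    the structural change spread across families rather than stacked on one.
    """
    out = set(graph)
    used_children: set[int] = set()
    for _ in range(n_changes):
        flippable = []
        for p in range(n_genes):
            for c in range(n_genes):
                if p == c or c in used_children:
                    continue
                e = (p, c)
                in_deg = sum(1 for pp, cc in out if cc == c)
                if e in out or in_deg < MAX_TRUE_IN_DEGREE:
                    flippable.append(e)
        if not flippable:
            break
        e = flippable[int(rng.integers(len(flippable)))]
        out.symmetric_difference_update({e})
        used_children.add(e[1])
    return out


def _parent_sets(graph: set, n_genes: int) -> dict:
    out: dict[int, tuple] = {c: () for c in range(n_genes)}
    for p, c in graph:
        out[c] = tuple(sorted({*out[c], p}))
    return out


def _sample_cpt(rng, n_parents: int, concentration: float) -> np.ndarray:
    """Row-stochastic (q, 3) table, one row per parent configuration.

    Children with parents draw each row from Dirichlet(concentration) — a
    small concentration gives near-one-hot rows, i.e. the child is almost a
    deterministic function of its lagged parents — and the rows are rotated
    so that each row's peak sits at the rounded mean of the parent levels.
    Regulation is therefore *activating*: a parent moving up pushes the child
    up after the lag, which matches the lagged same-direction co-movement the
    potential-regulator scan looks for, keeps every parent marginally
    informative, and keeps the child's level occupancy centred (a gene parked
    at one level drags its mean toward that level's emission value and erases
    its own fold-ratio signal, since the discretizer references the per-gene
    mean).  Parentless genes get a single moderately spread row
    (Dirichlet(5,5,5)): frozen roots would silence every cascade downstream.
    """
    q = R ** n_parents
    if n_parents == 0:
        return rng.dirichlet([20.0] * R, size=q)
    rows = rng.dirichlet([concentration] * R, size=q)
    for j in range(q):
        s, jj = 0, j
        for _ in range(n_parents):
            s += jj % R
            jj //= R
        peak = (2 * s + n_parents) // (2 * n_parents)  # rounded mean of parent levels
        rows[j] = np.roll(rows[j], peak - int(np.argmax(rows[j])))
    # stochasticity floor: a fully deterministic feedback loop would lock the
    # system into one pattern for the whole segment and skew level occupancy
    return 0.98 * rows + 0.02 / R


def simulate(
    n_genes: int = 6,
    T: int = 60,
    m: int = 2,
    tau=2,
    seed: int = 0,
    sparsity: float = 0.2,
    cpt_concentration: float = 0.02,
    noise_sd: float = 0.05,
    n_changes: int = 2,
    changepoints=None,
    level_means=DEFAULT_LEVEL_MEANS,
    graphs=None,
) -> tuple[ExpressionMatrix, DiscreteMatrix, GroundTruth]:
    """Generate one non-stationary DBN time series with known ground truth.

    ``tau`` may be a single lag (shared by all segments) or a sequence of m
    lags.  Changepoints default to an even split of 1..T.  Graph changes
    between consecutive segments are ``n_changes`` random edge flips; a child
    whose parent set is unchanged keeps its conditional table, so the
    between-segment signal is purely structural.  ``graphs`` (a list of m
    edge sets of (parent, child) gene indices) pins the structural ground
    truth instead of sampling it — the usual setup for a recovery study,
    where the network is fixed and only the stochastic realisation varies
    with the seed.  Fully reproducible from ``seed``.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    taus = tuple(tau) if np.iterable(tau) else (int(tau),) * m
    if len(taus) != m:
        raise ConfigError("tau must be scalar or one lag per segment")
    if changepoints is None:
        changepoints = tuple(round(1 + (T) * h / m) for h in range(1, m))
    changepoints = tuple(int(c) for c in changepoints)
    if len(changepoints) != m - 1:
        raise ConfigError("need m-1 changepoints")
    starts = [1, *changepoints]
    ends = [*(c - 1 for c in changepoints), T]
    for s, e, t in zip(starts, ends, taus):
        if e < s + 1:
            raise ConfigError("every segment needs at least 2 time points")
        if not 1 <= t <= e - 1:
            raise ConfigError(f"lag {t} infeasible for a segment ending at {e}")

    if graphs is None:
        graphs = [set(_random_graph(rng, n_genes, sparsity))]
        for _ in range(m - 1):
            graphs.append(_perturb_graph(rng, graphs[-1], n_genes, n_changes))
    else:
        if len(graphs) != m:
            raise ConfigError("need one graph per segment")
        graphs = [set(g) for g in graphs]
    parent_sets = [_parent_sets(g, n_genes) for g in graphs]

    cpts: list[dict] = []
    for h in range(m):
        table: dict[int, np.ndarray] = {}
        for child in range(n_genes):
            if h > 0 and parent_sets[h][child] == parent_sets[h - 1][child]:
                table[child] = cpts[h - 1][child]
            else:
                table[child] = _sample_cpt(rng, len(parent_sets[h][child]), cpt_concentration)
        cpts.append(table)


    levels = np.zeros((n_genes, T), dtype=np.int64)
    seg_of_t = np.zeros(T + 1, dtype=int)
    for h, (s, e) in enumerate(zip(starts, ends)):
        seg_of_t[s:e + 1] = h
    for t in range(1, T + 1):
        h = seg_of_t[t]
        lag = taus[h]
        for child in range(n_genes):
            parents = parent_sets[h][child]
            if t - lag < 1:
                # baseline: time courses start at the normal level, as in a
                # stimulus-response experiment sampled from treatment onset
                levels[child, t - 1] = 1
                continue
            else:
                j = 0
                for idx, p in enumerate(parents):
                    j += levels[p, t - lag - 1] * (R ** idx)
                probs = cpts[h][child][j]
            levels[child, t - 1] = rng.choice(R, p=probs)

    means = np.asarray(level_means, dtype=float)
    values = means[levels] + rng.normal(0.0, noise_sd, size=levels.shape)
    gene_names = [f"G{i + 1}" for i in range(n_genes)]
    expr = ExpressionMatrix(values, gene_names)
    disc = DiscreteMatrix(levels.copy(), list(gene_names), values.mean(axis=1))
    truth = GroundTruth([frozenset(g) for g in graphs], changepoints, taus, cpts,
                        parent_sets, tuple(level_means), noise_sd)
    return expr, disc, truth


def fixture_detection_toy() -> tuple[ExpressionMatrix, list[RegulatorPair]]:
    """Three genes rising in a cascade (A before B before C), with the exact
    regulator pairs a width-3 window scan must return.

    Each gene has a single burst well above the 1.2-fold cutoff: A at t=2,
    B at t=4, C at t=6 over T=8 points.  Hand enumeration with tau_max=3:
    within-window ordered same-direction pairs are A->B (lag 2) and B->C
    (lag 2); A->C at lag 4 does not fit inside any window.
    """
    base = np.ones((3, 8))
    base[0, 1] = 1.6   # A bursts at t=2
    base[1, 3] = 1.6   # B bursts at t=4
    base[2, 5] = 1.6   # C bursts at t=6
    expr = ExpressionMatrix(base, ["A", "B", "C"])
    expected = [
        RegulatorPair("A", "B", 2, "up", window_start=2, regulator_time=2),
        RegulatorPair("B", "C", 2, "up", window_start=4, regulator_time=4),
    ]
    return expr, expected
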