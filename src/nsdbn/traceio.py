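"""Plain-text persistence of sampler traces.

Two tab-delimited files describe a trace:

* the *score log*: one row per collected sample with the segment count and
  every log-score component;
* the *structure log*: one row per sample with comma-joined changepoints,
  comma-joined lags, and per-segment edge lists written as
  ``parent>child`` pairs joined by commas, segments separated by ``|``.

Both re-load into a :class:`~nsdbn.sampler.Trace`, so detection, sampling and
summarizing can run as separate processes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .sampler import ChainConfig, Trace
from .scoring import SamplerState, ScoreComponents, graph_sequence

SCORE_COLUMNS = ["sample", "m", "total", "log_lik", "log_struct_prior",
                 "log_m_prior", "log_cp_prior", "log_lag_prior"]


def write_trace(trace: Trace, score_path, structure_path) -> None:
    score_rows = []
    struct_rows = []
    for idx, (state, score) in enumerate(trace.samples):
        score_rows.append((idx, state.m, score.total, score.log_lik,
                           score.log_struct_prior, score.log_m_prior,
                           score.log_cp_prior, score.log_lag_prior))
        graphs = graph_sequence(state)
        seg_strs = []
        for g in graphs:
            pairs = sorted((trace.gene_names[trace.edges[e][0]],
                            trace.gene_names[trace.edges[e][1]]) for e in g)
            seg_strs.append(",".join(f"{p}>{c}" for p, c in pairs))
        struct_rows.append((idx, state.m,
                            ",".join(str(l) for l in state.L),
                            ",".join(str(t) for t in state.tau),
                            "|".join(seg_strs)))
    pd.DataFrame(score_rows, columns=SCORE_COLUMNS).to_csv(score_path, sep="\t", index=False)
    pd.DataFrame(struct_rows, columns=["sample", "m", "L", "tau", "segments"]).to_csv(
        structure_path, sep="\t", index=False)


def read_trace(score_path, structure_path, gene_names, T: int) -> Trace:
    scores = pd.read_csv(score_path, sep="\t")
    structs = pd.read_csv(structure_path, sep="\t", dtype=str, keep_default_na=False)
    gene_index = {g: i for i, g in enumerate(gene_names)}
    edge_index: dict[tuple, int] = {}
    edges: list[tuple] = []

    def edge_id(p: str, c: str) -> int:
        key = (gene_index[p], gene_index[c])
        if key not in edge_index:
            edge_index[key] = len(edges)
            edges.append(key)
        return edge_index[key]

    samples = []
    for srow, trow in zip(scores.itertuples(index=False), structs.itertuples(index=False)):
        L = tuple(int(x) for x in trow.L.split(",")) if trow.L else ()
        tau = tuple(int(x) for x in trow.tau.split(","))
        seg_graphs = []
        for seg in trow.segments.split("|"):
            g = set()
            if seg:
                for pair in seg.split(","):
                    p, c = pair.split(">")
                    g.add(edge_id(p, c))
            seg_graphs.append(frozenset(g))
        deltas = []
        for a, b in zip(seg_graphs, seg_graphs[1:]):
            deltas.append(frozenset({*((e, 1) for e in b - a), *((e, -1) for e in a - b)}))
        state = SamplerState(seg_graphs[0], tuple(deltas), L, tau)
        comp = ScoreComponents(srow.log_lik, srow.log_struct_prior, srow.log_m_prior,
                               srow.log_cp_prior, srow.log_lag_prior)
        samples.append((state, comp))
    return Trace(samples, {}, {}, ChainConfig(), T, list(gene_names), edges)
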