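"""Posterior summaries and evaluation against a reference network.

Turns a trace of sampled states into the quantities a practitioner reports:
the posterior over the number of segments, per-time-point changepoint
probabilities, per-time and per-segment edge posteriors, and — when a gold
standard reference network is available — ROC curves, AUROC and TP|FP=k.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd

from .errors import EvaluationError
from .sampler import Trace
from .scoring import graph_sequence, segment_bounds


@dataclass
class EdgePosterior:
    """probs[p, c, t] = posterior probability that edge p->c is active at time t+1."""

    probs: np.ndarray  # shape (n, n, T)
    gene_names: list


@dataclass(frozen=True)
class ReferenceNetwork:
    edges: frozenset  # of (parent gene name, child gene name)
    genes: tuple

    def __post_init__(self):
        universe = set(self.genes)
        for p, c in self.edges:
            if p not in universe or c not in universe:
                raise EvaluationError(f"reference edge {p}->{c} outside the gene universe")


def read_reference(path, genes) -> ReferenceNetwork:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    edges = frozenset((str(r[0]), str(r[1])) for r in df.itertuples(index=False))
    return ReferenceNetwork(edges, tuple(genes))


def _require_samples(trace: Trace):
    if not trace.samples:
        raise EvaluationError("trace holds no samples")


def segment_count_posterior(trace: Trace) -> dict[int, float]:
    """Empirical posterior over the number of segments m."""
    _require_samples(trace)
    counts = Counter(state.m for state, _ in trace.samples)
    total = len(trace.samples)
    return {m: c / total for m, c in sorted(counts.items())}


def changepoint_posterior(trace: Trace) -> np.ndarray:
    """Fraction of samples whose changepoint vector contains each t (index t-1)."""
    _require_samples(trace)
    hits = np.zeros(trace.T + 1)
    for state, _ in trace.samples:
        for l in state.L:
            hits[l] += 1
    return hits[1:] / len(trace.samples)  # entry t-1 corresponds to time t


def edge_posterior(trace: Trace) -> EdgePosterior:
    """Per-time edge posteriors: P(edge active in the segment covering t)."""
    _require_samples(trace)
    n = len(trace.gene_names)
    probs = np.zeros((n, n, trace.T))
    for state, _ in trace.samples:
        graphs = graph_sequence(state)
        for (start, end), g in zip(segment_bounds(state.L, trace.T), graphs):
            for e in g:
                p, c = trace.edges[e]
                probs[p, c, start - 1:end] += 1
    probs /= len(trace.samples)
    return EdgePosterior(probs, list(trace.gene_names))


def modal_segmentation(trace: Trace) -> list[tuple[int, int]]:
    """Most frequent m, with its changepoints at the highest-posterior locations."""
    _require_samples(trace)
    post_m = segment_count_posterior(trace)
    modal_m = max(post_m, key=lambda m: (post_m[m], -m))
    if modal_m == 1:
        return [(1, trace.T)]
    sub = [state for state, _ in trace.samples if state.m == modal_m]
    hits = np.zeros(trace.T + 2)
    for state in sub:
        for l in state.L:
            hits[l] += 1
    order = np.argsort(-hits, kind="stable")
    cps = sorted(int(t) for t in order[: modal_m - 1])
    return segment_bounds(cps, trace.T)


def per_segment_edge_scores(ep: EdgePosterior, segments: list[tuple[int, int]]) -> list[np.ndarray]:
    """Time-average of the edge posterior over each segment of a segmentation."""
    return [ep.probs[:, :, start - 1:end].mean(axis=2) for start, end in segments]


def _score_pairs(scores: np.ndarray, genes, ref: ReferenceNetwork,
                 include_self: bool = False):
    n = len(genes)
    out = []
    for p in range(n):
        for c in range(n):
            if p == c and not include_self:
                continue
            label = (genes[p], genes[c]) in ref.edges
            out.append((float(scores[p, c]), label))
    return out


def roc_auroc(scores: np.ndarray, genes, ref: ReferenceNetwork,
              include_self: bool = False) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUROC of an edge-score matrix against a reference network.

    An edge is kept when its score is strictly greater than the threshold;
    thresholds sweep the distinct scores plus {0, 1}.  AUROC by trapezoidal
    integration of TPR against FPR.
    """
    pairs = _score_pairs(scores, genes, ref, include_self)
    n_pos = sum(1 for _, lab in pairs if lab)
    n_neg = len(pairs) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("reference network leaves no positives or no negatives")
    thresholds = sorted({0.0, 1.0, *(s for s, _ in pairs)}, reverse=True)
    rows = []
    for th in thresholds:
        tp = sum(1 for s, lab in pairs if s > th and lab)
        fp = sum(1 for s, lab in pairs if s > th and not lab)
        rows.append((th, tp, fp, tp / n_pos, fp / n_neg))
    # close the curve: below every score all edges are kept
    rows.append((-np.inf, n_pos, n_neg, 1.0, 1.0))
    curve = pd.DataFrame(rows, columns=["threshold", "TP", "FP", "TPR", "FPR"])
    auroc = float(np.trapezoid(curve["TPR"], curve["FPR"]))
    return curve, auroc


def tp_at_fp(scores: np.ndarray, genes, ref: ReferenceNetwork,
             fp_level: int = 5, include_self: bool = False) -> int:
    """TP count at the threshold yielding ``fp_level`` false positives.

    When no threshold gives exactly that many, the threshold with the largest
    FP count not exceeding ``fp_level`` is used.
    """
    curve, _ = roc_auroc(scores, genes, ref, include_self)
    ok = curve[curve["FP"] <= fp_level]
    return int(ok["TP"].max()) if len(ok) else 0


# ---------------------------------------------------------------------------
# file output


def write_summaries(trace: Trace, out_dir, ref: ReferenceNetwork | None = None) -> dict:
    """Write all posterior tables; returns the evaluation metrics computed."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    post_m = segment_count_posterior(trace)
    pd.DataFrame(sorted(post_m.items()), columns=["m", "probability"]).to_csv(
        out / "segment_count_posterior.tsv", sep="\t", index=False)
    cp = changepoint_posterior(trace)
    pd.DataFrame({"t": np.arange(1, trace.T + 1), "probability": cp}).to_csv(
        out / "changepoint_posterior.tsv", sep="\t", index=False)
    ep = edge_posterior(trace)
    segments = modal_segmentation(trace)
    seg_scores = per_segment_edge_scores(ep, segments)
    rows = []
    genes = ep.gene_names
    for h, mat in enumerate(seg_scores, start=1):
        for p in range(len(genes)):
            for c in range(len(genes)):
                if p == c:
                    continue
                rows.append((genes[p], genes[c], h, mat[p, c]))
    pd.DataFrame(rows, columns=["parent", "child", "segment", "probability"]).to_csv(
        out / "edge_posterior.tsv", sep="\t", index=False)
    metrics: dict = {"modal_segments": len(segments)}
    if ref is not None:
        aurocs, tps = [], []
        for h, mat in enumerate(seg_scores, start=1):
            curve, auroc = roc_auroc(mat, genes, ref)
            curve.to_csv(out / f"roc_segment{h}.tsv", sep="\t", index=False)
            aurocs.append(auroc)
            tps.append(tp_at_fp(mat, genes, ref))
        metrics["auroc_per_segment"] = aurocs
        metrics["tp_at_fp5_per_segment"] = tps
    return metrics
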