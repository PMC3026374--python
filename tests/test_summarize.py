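import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from nsdbn.errors import EvaluationError
from nsdbn.sampler import ChainConfig, Trace
from nsdbn.scoring import SamplerState, ScoreComponents
from nsdbn.summarize import (ReferenceNetwork, changepoint_posterior,
                             edge_posterior, modal_segmentation,
                             per_segment_edge_scores, roc_auroc,
                             segment_count_posterior, tp_at_fp)

SC = ScoreComponents(0, 0, 0, 0, 0)


def make_trace(states, T=10, genes=("A", "B", "C"), edges=((0, 1), (1, 2), (0, 2))):
    samples = [(s, SC) for s in states]
    return Trace(samples, {}, {}, ChainConfig(), T, list(genes), list(edges))


def st(g1=(), deltas=(), L=(), tau=None):
    tau = tau if tau is not None else (1,) * (len(L) + 1)
    return SamplerState(frozenset(g1), tuple(frozenset(d) for d in deltas),
                        tuple(L), tuple(tau))


class TestPosteriors:
    def test_segment_count_frequencies(self):
        # m values: 1, 1, 2, 2
        trace = make_trace([st(), st(), st(L=(6,), deltas=({},)), st(L=(5,), deltas=({},))])
        post = segment_count_posterior(trace)
        assert post == {1: 0.5, 2: 0.5}

    def test_degenerate_segment_count(self):
        trace = make_trace([st(L=(6,), deltas=({},))] * 3)
        assert segment_count_posterior(trace) == {2: 1.0}

    def test_changepoint_fractions(self):
        trace = make_trace([st(), st(L=(6,), deltas=({},))])
        cp = changepoint_posterior(trace)
        assert cp[5] == 0.5 and cp.sum() == 0.5

    def test_all_single_segment_gives_zero_vector(self):
        cp = changepoint_posterior(make_trace([st()] * 4))
        assert (cp == 0).all()

    def test_changepoint_mass_equals_expected_segments_minus_one(self):
        states = [st(), st(L=(4,), deltas=({},)),
                  st(L=(4, 7), deltas=({}, {})), st(L=(6,), deltas=({},))]
        trace = make_trace(states)
        cp = changepoint_posterior(trace)
        mean_m = np.mean([s.m for s in states])
        assert abs(cp.sum() - (mean_m - 1)) < 1e-12

    def test_empty_trace_rejected(self):
        with pytest.raises(EvaluationError):
            segment_count_posterior(make_trace([]))


class TestEdgePosterior:
    def test_constant_edge(self):
        trace = make_trace([st(g1=(0,))] * 3)
        ep = edge_posterior(trace)
        assert (ep.probs[0, 1, :] == 1.0).all()

    def test_edge_only_in_second_segment(self):
        # hand-built 3-sample trace: edge 0 appears at t >= 6 in every sample
        s = st(g1=(), deltas=({(0, 1)},), L=(6,))
        trace = make_trace([s, s, s])
        ep = edge_posterior(trace)
        assert (ep.probs[0, 1, :5] == 0.0).all()
        assert (ep.probs[0, 1, 5:] == 1.0).all()

    def test_summed_probs_equal_mean_edge_count(self):
        states = [st(g1=(0, 1)), st(g1=(2,)), st(g1=())]
        trace = make_trace(states)
        ep = edge_posterior(trace)
        assert abs(ep.probs[:, :, 0].sum() - 1.0) < 1e-12  # (2+1+0)/3

    def test_modal_segmentation_uses_most_frequent_m(self):
        states = [st(L=(6,), deltas=({},))] * 3 + [st()]
        segs = modal_segmentation(make_trace(states))
        assert segs == [(1, 5), (6, 10)]
        scores = per_segment_edge_scores(edge_posterior(make_trace(states)), segs)
        assert len(scores) == 2 and scores[0].shape == (3, 3)


def pair_counting_auroc(scores, genes, ref):
    """Oracle: probability a random true edge outscores a random non-edge."""
    pos, neg = [], []
    for p in range(len(genes)):
        for c in range(len(genes)):
            if p == c:
                continue
            (pos if (genes[p], genes[c]) in ref.edges else neg).append(scores[p, c])
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def setup_method(self):
        self.genes = ["A", "B", "C"]
        self.ref = ReferenceNetwork(frozenset({("A", "B"), ("B", "C")}),
                                    ("A", "B", "C"))
        self.scores = np.zeros((3, 3))
        for (i, j), v in {(0, 1): .9, (1, 0): .4, (0, 2): .6,
                          (2, 0): .1, (1, 2): .5, (2, 1): .2}.items():
            self.scores[i, j] = v

    def test_perfect_separation(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 2] = 0.9
        _, auroc = roc_auroc(s, self.genes, self.ref)
        assert auroc == 1.0

    def test_uninformative_scores(self):
        s = np.full((3, 3), 0.5)
        _, auroc = roc_auroc(s, self.genes, self.ref)
        assert abs(auroc - 0.5) < 1e-12

    def test_three_gene_toy_matches_pair_counting(self):
        _, auroc = roc_auroc(self.scores, self.genes, self.ref)
        assert abs(auroc - pair_counting_auroc(self.scores, self.genes, self.ref)) < 1e-12

    def test_matches_mann_whitney(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 6))
            genes = [f"g{i}" for i in range(n)]
            scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=(n, n))
            edges = {(genes[i], genes[j]) for i in range(n) for j in range(n)
                     if i != j and rng.random() < 0.4}
            if not edges or len(edges) == n * (n - 1):
                continue
            ref = ReferenceNetwork(frozenset(edges), tuple(genes))
            _, auroc = roc_auroc(scores, genes, ref)
            pos = [scores[i, j] for i in range(n) for j in range(n)
                   if i != j and (genes[i], genes[j]) in edges]
            neg = [scores[i, j] for i in range(n) for j in range(n)
                   if i != j and (genes[i], genes[j]) not in edges]
            u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert abs(auroc - u / (len(pos) * len(neg))) < 1e-9

    def test_invariant_under_monotone_transform(self):
        _, a1 = roc_auroc(self.scores, self.genes, self.ref)
        _, a2 = roc_auroc(self.scores ** 3, self.genes, self.ref)
        assert abs(a1 - a2) < 1e-12

    def test_degenerate_reference_rejected(self):
        empty = ReferenceNetwork(frozenset(), ("A", "B", "C"))
        with pytest.raises(EvaluationError):
            roc_auroc(self.scores, self.genes, empty)


class TestTpAtFp:
    def test_perfect_scores_saturate(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 2] = 0.9
        ref = ReferenceNetwork(frozenset({("A", "B"), ("B", "C")}), ("A", "B", "C"))
        assert tp_at_fp(s, ["A", "B", "C"], ref, fp_level=0) == 2

    def test_all_equal_scores_falls_back_to_zero(self):
        s = np.full((3, 3), 0.5)
        ref = ReferenceNetwork(frozenset({("A", "B")}), ("A", "B", "C"))
        assert tp_at_fp(s, ["A", "B", "C"], ref, fp_level=3) == 0

    def test_matches_exhaustive_threshold_enumeration(self, rng):
        for _ in range(100):
            n = 4
            genes = [f"g{i}" for i in range(n)]
            scores = rng.random((n, n)).round(2)
            edges = {(genes[i], genes[j]) for i in range(n) for j in range(n)
                     if i != j and rng.random() < 0.3}
            if not edges or len(edges) == n * (n - 1):
                continue
            ref = ReferenceNetwork(frozenset(edges), tuple(genes))
            fp_level = int(rng.integers(0, 6))
            got = tp_at_fp(scores, genes, ref, fp_level)
            # oracle: check every candidate threshold directly
            pairs = [(scores[i, j], (genes[i], genes[j]) in edges)
                     for i in range(n) for j in range(n) if i != j]
            best = 0
            for th in {s for s, _ in pairs} | {0.0, 1.0, -1.0}:
                fp = sum(1 for s, lab in pairs if s > th and not lab)
                tp = sum(1 for s, lab in pairs if s > th and lab)
                if fp <= fp_level:
                    best = max(best, tp)
            assert got == best
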