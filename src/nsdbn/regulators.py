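"""Potential-regulator detection.

A transcription factor's expression change precedes that of its targets, so a
gene whose initial up (down) regulation event falls a few time points before
another gene's same-direction event is a *potential regulator* of that gene.
A window of width ``tau_max`` slides along the series; ordered same-direction
event pairs inside one window become regulator->target pairs with the time
difference as the lag.  The pairs yield (a) per-target candidate parent sets
that restrict the structure search and (b) an empirical lag distribution that
serves as the prior over segment lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DetectionError
from .preprocess import RegulationEvent


@dataclass(frozen=True)
class RegulatorPair:
    """One potential regulation: regulator's event precedes the target's."""

    regulator: str
    target: str
    lag: int
    direction: str
    window_start: int  # earliest window (1-based start) containing both events
    regulator_time: int


@dataclass
class CandidateRegulators:
    """Per-target allowed parents plus the empirical lag distribution."""

    parents_of: dict[str, set[str]]
    lag_probs: np.ndarray  # length tau_max, sums to 1
    tau_max: int

    def __post_init__(self) -> None:
        self.lag_probs = np.asarray(self.lag_probs, dtype=float)
        if self.lag_probs.shape != (self.tau_max,):
            raise ValueError("lag_probs must have length tau_max")
        if not np.isclose(self.lag_probs.sum(), 1.0):
            raise ValueError("lag_probs must sum to 1")


def scan_windows(events: list[RegulationEvent], tau_max: int, T: int) -> list[RegulatorPair]:
    """Collect regulator->target pairs from a sliding window of width ``tau_max``.

    The window starts at every t in 1..T-tau_max+1; inside one window each
    ordered pair of same-direction events on distinct genes yields a pair with
    lag = target time - regulator time (hence 1 <= lag <= tau_max-1).
    Duplicates from overlapping windows are collapsed.
    """
    if tau_max < 2:
        raise DetectionError("tau_max must be >= 2 to pair events inside a window")
    if tau_max > T:
        raise DetectionError(f"tau_max={tau_max} exceeds the series length T={T}")
    seen: dict[tuple, RegulatorPair] = {}
    by_dir: dict[str, list[RegulationEvent]] = {}
    for e in events:
        by_dir.setdefault(e.direction, []).append(e)
    for direction, evs in by_dir.items():
        evs = sorted(evs, key=lambda e: e.time)
        for a in evs:
            for b in evs:
                dt = b.time - a.time
                if a.gene == b.gene or dt < 1 or dt > tau_max - 1:
                    continue
                if b.time > T:
                    continue
                key = (a.gene, b.gene, dt, direction, a.time)
                if key not in seen:
                    w0 = max(1, b.time - tau_max + 1)
                    seen[key] = RegulatorPair(a.gene, b.gene, dt, direction, w0, a.time)
    return sorted(
        seen.values(),
        key=lambda p: (p.regulator, p.target, p.regulator_time, p.lag, p.direction),
    )


def lag_distribution(pairs: list[RegulatorPair], tau_max: int, pseudocount: float = 1.0) -> np.ndarray:
    """Empirical lag distribution p over 1..tau_max with an additive pseudocount.

    The pseudocount keeps every lag reachable by the lag-change move even when
    no detected pair exhibits it; an empty pair list yields the uniform vector.
    """
    if tau_max < 1:
        raise DetectionError("tau_max must be >= 1")
    counts = np.zeros(tau_max)
    for p in pairs:
        if 1 <= p.lag <= tau_max:
            counts[p.lag - 1] += 1
    weighted = counts + pseudocount
    return weighted / weighted.sum()


def candidate_parent_sets(
    pairs: list[RegulatorPair],
    all_genes: list[str],
    tau_max: int,
    pseudocount: float = 1.0,
) -> CandidateRegulators:
    """Build per-target candidate parent sets and the lag prior.

    A target with no detected regulators falls back to *all other genes* as
    candidates: the detection step is prior knowledge used to shrink the search
    space, not a hard claim that the gene is unregulated.
    """
    parents: dict[str, set[str]] = {g: set() for g in all_genes}
    for p in pairs:
        if p.target in parents:
            parents[p.target].add(p.regulator)
    for g in all_genes:
        if not parents[g]:
            parents[g] = {h for h in all_genes if h != g}
    return CandidateRegulators(parents, lag_distribution(pairs, tau_max, pseudocount), tau_max)


def save_candidates(c: CandidateRegulators, parents_path, lags_path) -> None:
    rows = [(t, ",".join(sorted(c.parents_of[t]))) for t in sorted(c.parents_of)]
    pd.DataFrame(rows).to_csv(parents_path, sep="\t", header=False, index=False)
    lag_rows = [(j + 1, p) for j, p in enumerate(c.lag_probs)]
    pd.DataFrame(lag_rows).to_csv(lags_path, sep="\t", header=False, index=False)


def load_candidates(parents_path, lags_path) -> CandidateRegulators:
    pdf = pd.read_csv(parents_path, sep="\t", header=None, dtype=str)
    parents = {
        str(row[0]): set(str(row[1]).split(",")) if isinstance(row[1], str) and row[1] else set()
        for row in pdf.itertuples(index=False)
    }
    ldf = pd.read_csv(lags_path, sep="\t", header=None)
    probs = ldf[1].to_numpy(dtype=float)
    return CandidateRegulators(parents, probs / probs.sum(), len(probs))
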