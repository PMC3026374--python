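"""Recover a rewired regulatory cascade end to end.

Simulates the six-gene study system (two regulations shut down at t=31),
runs detection and the reversible-jump sampler, and prints the posterior
summaries next to the ground truth.
"""

from nsdbn import structure_recovery_study
from nsdbn.study import STUDY_CHANGEPOINT, STUDY_GRAPH_1, STUDY_GRAPH_2

res = structure_recovery_study(seed=1, iterations=40_000, burn_in=10_000)

print("truth: two segments, changepoint at t=31, lag 2;")
print(f"  segment-1 edges: {sorted(STUDY_GRAPH_1)}")
print(f"  segment-2 edges: {sorted(STUDY_GRAPH_2)} (two edges removed)\n")
print(f"posterior over number of segments: "
      f"{ {m: round(p, 3) for m, p in res['segment_count_posterior'].items()} }")
print(f"modal segment count:   {res['modal_segments']}  (true: 2)")
print(f"changepoint mode:      t={res['changepoint_mode']}  (true: {STUDY_CHANGEPOINT})")
print(f"lag posterior mode:    {res['lag_mode']}  (true: 2)")
print(f"mean per-segment AUROC of edge posteriors vs truth: "
      f"{res['mean_segment_auroc']:.3f}")
print("\nAUROC near 1 means the per-segment edge posteriors rank every true"
      "\nregulation above every absent one.")
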