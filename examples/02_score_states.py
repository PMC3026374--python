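"""Score competing network hypotheses on simulated data.

Simulates a stationary series where gene G2 copies gene G1 at lag 2, then
compares the log posterior of the empty network against the true edge at the
true and at a wrong lag.  The winning state should be the true edge at lag 2.
"""

import numpy as np

from nsdbn import SamplerState, discretize, simulate
from nsdbn.regulators import CandidateRegulators
from nsdbn.scoring import Model, PriorConfig

expr, disc, truth = simulate(n_genes=2, T=50, m=1, tau=2, seed=4,
                             graphs=[{(0, 1)}])
genes = disc.gene_names
cand = CandidateRegulators({g: {h for h in genes if h != g} for g in genes},
                           np.array([1 / 3] * 3), 3)
model = Model(disc, cand, PriorConfig(tau_max=3, self_loops=False))

e_01 = model.edge_index[(0, 1)]
states = {
    "empty graph, lag 2": SamplerState(frozenset(), (), (), (2,)),
    "G1->G2,     lag 1": SamplerState(frozenset({e_01}), (), (), (1,)),
    "G1->G2,     lag 2": SamplerState(frozenset({e_01}), (), (), (2,)),
    "G2->G1,     lag 2": SamplerState(frozenset({model.edge_index[(1, 0)]}), (), (), (2,)),
}
print("log posterior (higher is better); data generated by G1->G2 at lag 2\n")
for name, st in states.items():
    sc = model.log_posterior(st)
    print(f"  {name}: total={sc.total:9.2f}  (log-lik {sc.log_lik:9.2f})")
print("\nthe margin between the true state and the rest is the evidence the"
      "\nsampler climbs; tens of log units means the edge and lag are certain")
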