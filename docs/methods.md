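# Methods

## Model

The observed data are a real-valued gene × time matrix with T time points.
After imputation, each gene is discretized to r = 3 levels by fold change
against its own mean (up if ≥ 1.2-fold, down if ≤ 0.70-fold, both
inclusive).  The generative model is a piecewise-constant dynamic Bayesian
network: changepoints L = (L₁,…,L_{m−1}) cut 1..T into m contiguous
segments; segment h carries one directed graph G_h over the genes and one
lag τ_h; within the segment, gene i's level at time t is multinomial given
its parents' levels at t − τ_h.  Because parents act at a strictly earlier
time, feedback loops and even self-regulation are representable; the
acyclicity constraint of static Bayesian networks does not apply.

The graph sequence is parameterised as a base graph plus per-changepoint
edge-change sets ΔG_i (signed edge toggles), following the assumption that
networks change smoothly: the prior on each change set is exponential in its
size, P(ΔG_i) ∝ exp(−λ_s·s_i), normalised over change counts 0..E_max where
E_max is the number of admissible edges.  The number of segments carries a
truncated exponential prior P(m) ∝ exp(−λ_m·m), m ∈ 1..m_max.  Lags carry
an empirical prior p over 1..τ_max estimated by the regulator-detection
scan.  The changepoint vector carries a normalised uniform prior over all
valid vectors given m.  This last term is a deliberate design choice: the
posterior decomposition could instead leave L implicit (a flat unnormalised
weight per configuration), but then the marginal posterior over m absorbs
the combinatorial growth of the number of changepoint vectors and no longer
tracks the exponential prior; normalising makes P(m) mean what it says.

### Likelihood

Within a segment the marginal likelihood is the Bayesian–Dirichlet
equivalent (BDe) score with segment-weighted hyperparameters
α_ijk(I_h) = α·|I_h|/(r_i·q_ih·N), where |I_h| is the segment length, q_ih
the number of parent configurations and N = T; segments are scored
independently and multiplied (summed in log).  α (the equivalent sample
size) defaults to 1.

Child observations are restricted to t > τ_max for **every** state: the
first τ_max time slices are conditioned on rather than modelled.  Under the
naive alternative (skip only child times with t − τ_h < 1), two states can
score *different numbers of observations*, and a state that arranges an
early changepoint with a large first-segment lag scores fewer points and
receives a spuriously higher marginal likelihood; in synthetic experiments
this reproducibly manufactured a changepoint near the start of the series.
Conditioning on the initial slices — the standard convention for DBN
scoring — makes all states comparable on an identical observation set.
A corollary: changepoints are restricted to t ≥ τ_max + 2, so the first
segment always contains at least one scored observation (a segment wholly
inside the conditioned prefix would have an unidentifiable graph).

## Potential-regulator detection

The change of a transcription factor's expression precedes that of its
targets.  The detector marks, for each threshold on a grid (up thresholds
1.0–1.2, down thresholds 0.6–0.8, step 0.05), each gene's *initial*
up/down-regulation time point, then slides a window of width τ_max across
the series; ordered same-direction event pairs on distinct genes inside one
window become regulator → target pairs with lag = time difference (hence
1..τ_max−1).  Event comparisons are strict (> up-threshold, < down-threshold)
so a gene resting exactly at its mean never fires the 1.0 threshold;
discretization keeps the inclusive cutoffs.  Pair counts by lag, plus a
pseudocount of 1 per lag, give the empirical lag prior; per-target
regulator sets restrict the admissible edges during sampling.  A target
with no detected regulator falls back to all other genes — the restriction
is prior knowledge, not a hard claim.  Simultaneous events are not paired
(the model's lags start at 1), and regulations that begin only in a later
segment are invisible to the detector, which sees initial events only; both
are known limitations.

## Sampler

Reversible-jump MCMC with Metropolis–Hastings acceptance over eleven move
types.  MT1/MT2 add/delete an edge in **one segment's** graph, adjusting the
flanking change sets so other segments are untouched; this per-segment
reading matters in practice, since base-graph-only edits leave the chain
stuck in representation ("gauge") traps where a wrong base graph hides
behind an early delta.  MT3/MT4 add/delete a signed change in one delta;
MT5 moves a change between deltas; MT6 redraws one changepoint uniformly in
its feasible interval and redraws the left segment's lag (the joint redraw
keeps the move exactly reversible); MT7 redraws one lag; MT8/MT9 merge and
split adjacent deltas (a merged segment takes the smaller of the two lags;
a merge whose composition would cancel changes is proposed as a no-op, as
no split can reproduce it); MT10/MT11 insert/delete a changepoint carrying
an empty or single-change delta (the single-change variant lets the chain
cross the prior valley of a bare changepoint insertion).  Dimension changes
carry exact reverse-proposal probabilities; the state space is discrete so
no Jacobian terms arise.  Move types are selected uniformly by default
(configurable weights); inapplicable draws count as rejections.  All
randomness flows through one seeded generator, making traces
bit-reproducible.  Chains start at one segment with the empty graph and a
lag drawn from the lag prior.

Constraints maintained throughout: minimum segment length 2 (configurable);
τ_h ≤ (segment end) − 1 and τ_h ≤ τ_max; every edge's parent within the
target's candidate set; a fan-in cap of 4 parents per child (configurable);
self-edges optional (off in the recovery study, whose generator has none).

Scoring after a move reuses memoized per-family segment scores, so a
proposal costs a few table lookups; a from-scratch recompute path exists
and the suite asserts both agree to 1e−9.

## Posterior summaries and evaluation

From the thinned post-burn-in trace: the empirical distribution of m;
per-time changepoint probabilities; per-time edge posteriors (fraction of
samples whose active graph at t contains the edge).  For per-segment
reporting, the modal segmentation takes the most frequent m and places its
changepoints at the highest-posterior locations among samples with that m,
and edge posteriors are time-averaged within each modal segment.  Given a
reference network, ROC curves sweep the distinct scores (strictly-greater
thresholding, curve closed at (1,1)), AUROC is the trapezoidal area —
equal to the tie-corrected Mann–Whitney statistic — and TP|FP=k reports
true positives at the threshold with the largest false-positive count not
exceeding k.  Self-edges are excluded from evaluation by default.

## Synthetic data

The generator simulates exactly the model the score assumes, with choices
aimed at data that behave like stimulus-response expression time courses:

- **Emission**: level means (0.5, 1.0, 1.5) on the fold-ratio scale with
  Gaussian noise (default sd 0.05), so the discretizer's fixed cutoffs
  recover the levels at low noise.
- **Conditional tables**: rows drawn from Dirichlet(concentration), default
  0.02 — near-deterministic — then rotated so each row's peak is the
  rounded mean of the parent levels.  Regulation is therefore activating
  (lagged same-direction co-movement), which is what the detector assumes;
  it also keeps every parent marginally informative (a parity-style rule
  would make single-edge moves blind to multi-parent families) and keeps
  level occupancy centred so per-gene means stay near 1 — a prerequisite
  for fold-ratio coding.  A 2% uniform leak prevents deterministic feedback
  loops from freezing.  Parentless genes draw a single spread row; children
  whose parent set is unchanged across a changepoint keep their table, so
  between-segment signal is purely structural.
- **Structure**: random graphs use Bernoulli edges trimmed to in-degree ≤ 1
  (single-regulator families remain identifiable from ~30 points per
  segment); between-segment changes are sequential edge flips on distinct
  target genes.  A fixed graph sequence can be supplied instead.
- **Initial conditions**: the first lag-many points sit at the normal
  level, like a time course sampled from treatment onset; random starts
  would let a target's initial threshold crossing precede its regulator's,
  breaking event-order detection.

What passing tests on these data do **not** show: robustness to probe-level
microarray noise, to non-activating (repressive) regulation — which the
detector's same-direction pairing cannot see — to regulations that switch
on mid-series, or to dense many-parent families, all of which degrade real
data performance.

## Recovery study

The fixed study system is a six-gene activating cascade (G1→G2→G3,
G1→G4→G5→G6), T = 60, lag 2, whose program partly shuts down at t = 31:
edges G2→G3 and G4→G5 are removed (two-edge change).  Seeds vary only the
stochastic realisation, the usual design when a gold-standard network is
fixed.  Priors for the study: λ_s = 2, λ_m = 0.3, α = 1, τ_max = 3,
m_max = 10, no self-edges.  Chains run 60 000 iterations with 15 000
burn-in (about 5 s per seed; the exhaustive-posterior check uses 500 000
iterations on a two-gene problem where all few-hundred states are
enumerated).  A shutdown-type rewiring is used because the detector can
only see regulations active from the start of the series; a rewiring that
*adds* an edge mid-series is invisible to initial-event detection and the
candidate restriction would exclude the new edge outright.

## Numerical choices and degenerate inputs

- Imputation: interior gaps take the neighbour mean; boundary gaps copy the
  neighbour; runs of missing values fill left-to-right using the already
  imputed left neighbour and the next observed value (idempotent).  A fully
  missing gene row is an error, as is a nonpositive gene mean.
- Ties in ROC thresholds are handled by evaluating at distinct scores only.
- The uniform prior over base graphs contributes the constant −E_max·ln 2;
  it cancels in all MCMC ratios and is kept only so reported totals are
  comparable across states.
- m_max defaults to ⌊T/2⌋ and is capped at the largest m with a feasible
  changepoint vector.
- log Γ evaluations use `scipy.special.gammaln`; segment count tables are
  built with `numpy.bincount` over base-3 parent-configuration codes.
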