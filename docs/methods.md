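# Methods

## Problem setting and model

The package infers a directed, lag-annotated regulatory network from a single
gene-expression time course D = {X₁,…,Xₙ}, Xᵢ = (x_{i1},…,x_{im}), with
equally spaced time points and no missing values. It targets the small-n,
small-m regime (n ≤ ~10 genes, m ≈ 20–50 points) where per-target model
fitting is tractable and marginal time-delayed association is informative.
The pipeline is decomposed per target gene: (1) candidate regulator
selection, (2) lag alignment, (3) nonlinear model fitting, (4) regulator
read-off; the per-target edge sets are unioned.

### Time-delayed association measures

All three measures score a regulator series x against a target series y at
lag τ by pairing x(k) with y(k+τ) on the overlapping window of length
N = m − τ. The direction convention is *regulator leads*: lag τ means the
regulator's level at time t influences the target at t + τ.

* **TDMI.** Mutual information in nats from an equal-width 2-D histogram on
  the window, with bins = max(2, ⌊√N⌋) per axis by default (configurable).
  Equal-width binning with ≈√N bins is the standard coarse estimator for
  series this short; anything finer is dominated by sampling noise.
* **TDMIC.** The maximal information coefficient of the lag-shifted pair:
  max over grid shapes (n_x, n_y), n_x·n_y ≤ max(4, N^0.6), n_x, n_y ≥ 2, of
  grid mutual information normalised by log min(n_x, n_y). For each shape one
  axis is rank-equipartitioned and the other optimised *exactly* by dynamic
  programming over contiguous partitions of the sorted points (the additive
  decomposition of N·I − N·H(label) over bins makes the DP exact); both
  orientations are tried and the larger kept. Degenerate (constant) series
  return 0. Note one sample-size artefact: a noiseless monotone relation
  attains 1.0 only when some admissible grid can split the window into
  equal-count cells; a 17-point window under a 2×2 budget caps at
  H(9/17, 8/17)/log 2 ≈ 0.9975. This is a property of the MIC definition at
  small N, not of the implementation.
* **TDCC.** Pearson correlation computed with means and variances on the
  overlapping window itself; zero-variance windows return 0. The same
  measure provides each pair's working lag, τ* = argmax_τ |C(τ)|, ties going
  to the smallest lag so instantaneous explanations are preferred when
  nothing distinguishes them.

### Hybrid rank aggregation

For target k every other gene is scored by the lag-maximised value of each
measure (|TDCC| for correlation). Genes are ranked per measure (rank 1 =
strongest; ties share the smallest rank) and the three ranks are summed; the
L genes with the smallest rank sum are the candidates, ties broken by larger
TDMIC, then larger TDMI, then smaller gene index — a fixed chain chosen for
determinism. Aggregating ranks rather than raw scores sidesteps the fact
that the three measures live on incommensurable scales and avoids any global
edge-weight threshold. The target never competes for its own candidate set,
so self-regulation is never inferred (reference self-loops remain countable
as false negatives during evaluation).

Parameters: `tau_max` (default 6 sampling intervals) bounds the lag scan;
`min_lag` (default 0) can be raised to 1 to forbid instantaneous regulation;
`L` (default 2) is the candidate count — on the benchmark-scale networks
about 30 % of the gene count is a good rule of thumb.

### Lag-aligned design

Each candidate enters at its own lag τᵢ. Because the tree model consumes all
candidates simultaneously, one common output window t = max(τᵢ)..m−1 is used:
target[j] is the target at window time j and inputs[i][j] the i-th candidate
τᵢ steps earlier, giving an L × m_eff matrix with m_eff = m − max(τᵢ)
(required ≥ 5). Lags are those estimated during scoring and are not
re-optimised inside model fitting.

### Complex-valued flexible neural tree

The per-target model is an expression tree: leaves are candidate inputs
z₁..z_L, internal nodes are flexible neurons +n computing net = w₀ + Σ wⱼzⱼ
with complex weights and threshold, activated by the complex Elliot function
f(net) = net/(a + |net|/r) with per-node real a, r > 0 (output modulus
bounded by r, denominator strictly positive). Evaluation is post-order and
vectorised over time. Real expression data carry no imaginary part; the
default encoding is z = x + 0j, with a unit-circle alternative
z = cos(πx) + j·sin(πx) for min-max-normalised data exposed as `phase`
(complex-valued models can exploit phase structure, but nothing in real
expression data dictates either embedding). The real prediction is Re(out),
which preserves sign and ordering against the real target (modulus is
available but discards sign). Function set defaults to arities {2, 3} with
maximum depth 4 — candidate sets are small, so larger arities only bloat the
search space. Trees serialise to versioned JSON (prefix-order nodes, complex
numbers as [re, im]).

### Fitting: genetic programming + bat algorithm

Fitness of a tree is the RMSE between prediction and target over the window
(Eq. of merit for all reporting). Selection additionally adds a parsimony
penalty of `parsimony` (default 0.02 on min-max-normalised data) per
*distinct input used*, so an input must buy at least that much RMSE to keep
its edge in the read-off; reported/trace RMSE stays the raw error. Without
this pressure an input whose weight contributes nothing survives by drift
and every target tends to emit all L edges regardless of fit.

One generation = tournament selection (size 3) → subtree-exchange crossover
(p = 0.7) → mutation (p = 0.3; uniformly one of: replace a random subtree,
retarget one terminal, redraw one node's parameters) → elitism (best
individual copied unchanged); offspring overflowing the depth bound are
pruned by replacing the overflowing subtree with a random leaf. The initial
population seeds one single-input neuron +2(zᵢ, zᵢ) per input and one
pairwise neuron per input pair before filling with grow-method random trees,
so every small regulator subset competes from generation 0.

Every `param_opt_every` generations (default 5; 3 in the small preset) the
best individual of each *distinct terminal subset* (capped at
`param_opt_fraction` of the population) has its flattened parameter vector
(Re/Im of weights and threshold, then a, r per node, prefix order) refined by
a standard frequency-tuned bat algorithm: velocities pulled toward the global
best with random frequency in [0, 2], a pulse-rate-gated local walk around
the best scaled by mean loudness, acceptance gated by loudness with geometric
decay (α = γ = 0.9, A₀ = 0.9, r₀ = 0.5), velocities clamped to ±1 per
coordinate (the data are bounded), a and r clamped to ≥ 10⁻³ on unflatten.
Refining per-subset rather than the plain top fraction matters: competing
regulator subsets are then compared at their tuned optima instead of at
whatever parameters drift produced, which is what lets the penalised RMSE
act as honest model selection. Bat 0 starts at the incumbent parameters, so
refinement never returns a worse tree.

Search stops at `max_generations` or when the best raw RMSE reaches
`target_rmse`. Full defaults are population 50 / 100 generations / 30 bats ×
100 iterations; the documented `OptimizerConfig.small()` preset (population
20, 15 generations, refinement every 3 generations, 10 bats × 20 iterations,
target RMSE 0.02) is sized for the few-gene benchmark problems and is what
the test suite and the acceptance script use — at this scale it already
matches an oracle that selects regulator subsets by exhaustively penalised
least squares, so the larger defaults buy nothing on 6-gene problems.

Reproducibility: a single root seed; each target gene gets an independent
stream derived via `SeedSequence((seed, target_index))`, so whole-run output
is byte-identical across repeats while targets stay statistically
independent.

### Network assembly and evaluation

One edge per distinct terminal surviving in a target's best tree, annotated
with the candidate's lag and the model RMSE; duplicates collapse. Evaluation
against a reference network is direction-sensitive and ignores lags (common
reference networks are unlagged). The pair universe is every ordered pair of
distinct genes, plus self-pairs when `include_self` is set — both
conventions are exposed because published specificity numbers are ambiguous
about self-pairs. Metrics: sensitivity TP/(TP+FN), precision TP/(TP+FP),
specificity TN/(FP+TN), F = harmonic mean of sensitivity and precision; any
0/0 yields 0 with a warning. Multi-run summaries report mean ± SD of each
metric over `n_runs` derived seeds plus the hit ratio (fraction of runs
attaining the maximum observed F-score). The lag-blind ablation is simply
`tau_max = 0, min_lag = 0` through the identical code path.

## Synthetic data generator

`generate_network` draws distinct directed non-self edges, lags uniform on
{1..τ_max} and weights uniform on ±[0.2, 1] (bounded away from 0 so "true
edge" is meaningful for recovery); driver genes are those with in-degree 0.
`simulate_expression` gives every gene a sinusoid baseline (amplitude
0.2–0.35, period 8–16 samples, random phase); drivers additionally carry a
smooth AR(1) component (innovation SD 0.08, persistence 0.8) that is part of
the *dynamics* — it is seeded from the spec seed and present even in
noiseless runs, because without it the near-periodic trajectories make
distinct lags nearly indistinguishable. A regulated gene follows

    x_k(t) = clip(0.5 + link(Σ_e w_e (x_reg(t−lag_e) − 0.5)) + ε_t, 0, 1),

ε ~ N(0, noise_sd), with the Elliot saturation (a = r = 0.5, keeping the
response inside [0, 1]) as default link so that parameter recovery by the
CVFNT is well-posed; centred linear and logistic links exercise model
misspecification. A burn-in of max(lag) steps is discarded, so every emitted
regulated value reflects the regulatory dynamics; with a linear unit-weight
single edge the target is an exact lagged copy of its regulator.

What the generator does *not* emulate: mRNA degradation kinetics,
autoregulation, perturbation/knockout designs, measurement-platform
artefacts, or the heavy-tailed noise of real arrays. Passing recovery tests
therefore demonstrates that the pipeline identifies lagged nonlinear
dependencies of the assumed form at realistic sample sizes — not that it
matches any particular wet-lab benchmark score.

### Identifiability caveats (what the tests reflect)

Two properties of marginal-association screening show up clearly in the
synthetic experiments and bound what any configuration of this method can do:

* **Deterministic confounding.** In a *noiseless* cascade or fan-out, a
  sibling or grand-regulator is an exact monotone function of the direct
  regulator, so all three measures tie at their maxima and RMSE cannot
  separate them either — the direct edge is not identifiable from marginal
  statistics. A little observation noise actually breaks these ties in
  favour of direct edges, so recovery is *not* monotone in noise near σ = 0;
  degradation sets in from moderate noise upwards (the suite asserts the
  decay over σ = 0.05 → 0.6 at the candidate level, and exact rank-1
  identification only for disjoint driver→target pairs).
* **Candidate-count ceiling.** Targets with in-degree > L structurally lose
  edges, and every fitted tree names at least one regulator, so in-degree-0
  genes contribute unavoidable false positives. With L = 2 on 6-gene /
  7-edge networks these two effects cap the expected F-score around 0.8
  before any estimation error.

## Numerical and degenerate-input conventions

Min-max per-gene normalisation is applied before scoring and modelling by
default (bounded inputs for the saturating activation and scale-free
binning); constant genes map to 0.5 and simply rank at the bottom (zero
association). Zero-variance windows give TDCC 0; constant series give
TDMIC 0; MI of a constant series is 0 by construction. Metric 0/0 cases
return 0 with a warning. Column order in input files is the temporal order;
all lags are integer sampling intervals; internal indexing is 0-based.

## Known limitations

* Marginal (unconditional) association screening cannot remove indirect
  edges; no conditional-MI or partial-correlation deconfounding is included.
* Lags are point estimates from TDCC and are not revisited during fitting.
* The complex-valued machinery is exercised with real-encoded inputs by
  default; benefits of the `phase` embedding are data-dependent and
  unvalidated here.
* Only the Elliot activation is implemented; alternative optimizers beyond
  the bat algorithm are an extension point (`_bat_optimize_vec` is the only
  coupling), not shipped.
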