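# Methods

This note documents the models, the parameter choices, the numerical
guards, and what the synthetic-data experiments do and do not demonstrate.

## Continuous optimizers

Both optimizers are evaluation-budgeted: the run-time unit is one objective
evaluation (`FEs`), never an iteration count, and every objective call
increments the counter exactly once. Canonical PSO evaluates the population
(clamped into the box), updates personal and global bests under *strict*
improvement (exact ties keep the incumbent), then applies the velocity and
position updates with fresh uniform draws per term and per dimension.
Velocities start at zero; velocity components are clamped to ±V_max and
positions to the box bounds after every move (clamping, not reflection — the
same style as the velocity clamp).

SRWPSO's iteration structure is: random-replacement pass → one shared
adaptive-weight update → velocity/position updates → evaluation pass.
Decisions worth spelling out:

- **Replacement semantics.** The replacement pass hybridizes each personal
  best with the global best (per dimension, gated by `a < C` with a fresh
  Cauchy draw per dimension), re-evaluates the hybrid, and accepts it
  *unconditionally* — the personal best and its score are overwritten even
  when worse. This is deliberate diversity injection: the otherwise
  redundant extra evaluation pass only has an effect if the hybrid is what
  gets evaluated and stored. Consequence: personal-best scores are **not**
  monotone under SRWPSO; only the global best is, and the tests assert
  monotonicity of the global best alone. The decay parameter `a` is
  recomputed from the current `FEs` at each particle's turn.
- **Adaptive weight guards.** `ω = (1 − FEs/MaxFEs)^β` is computed in log
  space; a zero base (budget exhausted) yields ω = 0, and ω is capped at 10
  because the Cauchy-tailed β can otherwise overflow the power. The cap is
  dynamically harmless: velocity clamping bounds the step regardless. ω is
  computed once per iteration and shared by all particles. With the
  strategy off, ω ≡ 1, which is exactly the canonical update.
- **Adaptive scalar S.** A single global scalar, updated after *every*
  evaluation of the final pass: halved when that evaluation strictly
  improved the global best, incremented by 1 otherwise. Initial value 0.01.
- **Ablation identity.** With all three strategies off, SRWPSO consumes the
  random stream identically to PSO and reproduces it step for step (tested
  as exact trace equality under a shared seed). The eight on/off
  combinations give the standard ablation family
  (PSO/SOBPSO/RRPSO/AWPSO/SRPSO/SWPSO/RWPSO/SRWPSO), exposed as
  `ABLATION_VARIANTS`.
- **Sobol initialization.** Owen-scrambled Sobol points (scipy's
  implementation; direction numbers support up to 21,201 dimensions),
  seeded from the run seed, mapped by `X = lb + S·(ub − lb)`. Scrambling
  rather than the plain sequence is a deliberate choice: the plain
  sequence's leading points are the cube corner and the cube midpoint,
  which under a symmetric box land exactly on the global optimum of most
  unshifted analytic benchmarks — planting the answer in every initial
  population and making seeds share one deterministic initialization.
  Scrambled nets keep the low-discrepancy guarantee (the discrepancy
  comparison against uniform sampling is part of the acceptance checks)
  while randomizing per seed.
- **Budget edges.** When fewer evaluations remain than particles, the
  evaluation pass truncates; a trace checkpoint `(FEs, best)` is recorded
  after every evaluation batch.

Default constants: population 30, budget 300,000 evaluations, V_max = 6,
c₁ = c₂ = 2, S₀ = 0.01, box [−100, 100]. The built-in objective suite
provides the analytic base functions these benchmark families are built
from; `shift_rotate` composes `f(M(x − o)) + bias` for users who supply
shift/rotation data. Hybrid and composition benchmark instances require
external component definitions and are intentionally not reproduced.

## Binary variant

Each particle holds a continuous position in `[0,1]^D` *and* a persistent
mask. The V-shaped transfer `V(x) = |tanh x|` converts a coordinate into a
bit-flip probability; masks advance by one flip draw per dimension per
move. Resolution of the representation ambiguities:

- Initial masks threshold the initial continuous positions at 0.5, giving
  an unbiased Bernoulli(½) start under uniform or Sobol initialization.
- Personal/global bests store (mask, continuous position, score) triples;
  all comparisons use mask fitness.
- The replacement gate applies per dimension *jointly* to the coordinate
  and the bit, taking the global best's pair when the gate fires, so the
  hybrid personal best remains a consistent (coordinate, bit) pair; the
  hybrid's mask is what gets re-evaluated. (An alternative reading applies
  the transfer to the velocity, Rashedi-style; it is noted but not
  implemented.)
- Runs are iteration-limited (default 50 iterations, population 20);
  the nominal budget feeding the decay terms is
  `N + iterations × (2N with replacement, N without)`.
- Fitness is evaluated once per (particle, step) on a fixed bit vector;
  masks are never re-randomized inside a fitness call.

On enumerable problems (D = 8, all 2⁸ masks checked by brute force) the
swarm returns the exact optimum in ≥ 90% of seeded runs — the acceptance
check for search adequacy at feature-selection scale.

## FKNN

Memberships of the k nearest training points (stable index order breaks
distance ties) are averaged with weights `d^(−2/(m−1))`; the output is a
convex combination of unit-sum rows, hence itself unit-sum. Defaults
k = 5, m = 2 — the standard values in the fuzzy-KNN literature; the
membership-initialization scheme defaults to crisp one-hot, with the
Keller-style neighborhood scheme (0.51 + 0.49·fraction for the own class,
0.49·fraction otherwise) available. A query that coincides exactly with
training points takes the mean of the matched membership rows (the
distance-weight limit concentrates all mass there). Prediction is argmax
membership, ties to the lowest class label. Features are min–max scaled
(fitted on training data only) inside the selection pipeline before any
distance is computed — unscaled Euclidean distances on mixed clinical units
would be dominated by the largest-scale feature.

## Wrapper pipeline

Per outer fold (stratified, default 10 folds — stratification keeps
per-fold class balance stable at cohort-scale n): the scaler is fitted on
the outer-training partition; a stratified 80/20 hold-out of that partition
(fixed and seeded per fold) provides the inner error estimate, so each
mask's fitness is deterministic and cheap; bSRWPSO searches masks; the
winning mask's FKNN is refitted on the full outer-training partition and
scored once on the untouched outer test fold. Masks recur as the swarm
converges, so fitness values are memoized per fold. Nothing fitted ever
sees an outer-test row — the leakage contract is asserted in the tests with
an instrumented classifier. Alternative inner estimates (inner k-fold,
leave-one-out) would be straightforward but make fitness stochastic or
k-times costlier; the fixed hold-out was chosen for determinism.

Metrics (accuracy, sensitivity, MCC, F-measure with
`F = TP/(TP + (FN+FP)/2)`) are computed one-vs-rest for a designated
positive class (default: the first class label; configurable). MCC is
defined as 0 when its denominator vanishes. Repeated selection reseeds
each repeat from a spawned seed sequence and reports per-feature selection
counts over all repeats × folds.

CSV input requires complete numeric feature columns; missing values are
rejected with the offending cell named, never imputed.

## Synthetic cohort generator

Emulates the *shape* of a small clinical cohort table: default 300
samples, 36 non-negative continuous features, binary label (class 1 =
case), 4 informative features. Base features are iid standard normal with
a log-normal distortion (`exp(skew·z)`, default skew 0.5 — moderate right
skew typical of counts and titers); informative columns then receive an
additive class shift of `effect_size` pooled standard deviations *in data
space* (default 2.0), so the standardized mean difference measured on the
generated sample equals the configured effect regardless of skew. Fixed
per-feature decade scales (10^U(0,2)) emulate mixed units; they cancel in
any standardized statistic and are removed by the pipeline's min–max
scaling.

What the generator does **not** emulate: feature–feature correlation
(clinical panels are collinear — differential counts sum to totals),
label noise, missingness, categorical demographics, and any particular
clinical meaning of the label. Passing the recovery checks therefore shows
the pipeline can find independent, additively shifted signals at realistic
cohort sizes; it does not certify performance on correlated or noisy
real-world panels.

## Statistics harness

Wilcoxon signed-rank: two-sided, zero differences dropped, ties mid-ranked;
the exact null (counting recursion over doubled rank sums) for ≤ 12 nonzero
pairs, the tie-corrected normal approximation with continuity correction
beyond (the two branches agree within 0.02 at the boundary). Friedman-style
mean ranks summarize each cell by its mean over runs and average
within-problem ranks (ties averaged); orientation (minimize scores vs
maximize accuracies) is an explicit flag, since benchmark tables and
classification tables rank in opposite directions. Win/tie/loss counts a
`+` only when the reference's mean is better *and* the paired Wilcoxon p is
below α = 0.05. "STD" in the output tables is the sample standard
deviation (n−1), the convention of the tables this format follows. No
multiple-testing correction is applied.

## Problem sizes in the checked experiments

The test suite and the acceptance script run the benchmark grid at
dimension 10 with a 20,000-evaluation budget over 10–15 seeds, and the
end-to-end pipeline at 2–3 repeats × 10 folds on the default 300 × 36
cohort — sizes at which every stochastic property checked (strategy
benefit, planted-feature recovery, > 0.80 held-out accuracy) holds with
comfortable margin while keeping a full run in minutes.

## Known limitations

- Ackley at dimension 10 under a 20,000-evaluation budget often stalls near
  its outer plateau for PSO-family optimizers; the comparison checks use
  medians across seeds for exactly this reason.
- The replacement strategy's unconditional acceptance can transiently
  erase good personal bests; with tiny budgets this slows convergence
  rather than helping.
- FKNN stores the full training set and computes dense distance matrices;
  it is meant for cohort-scale n (hundreds), not for large datasets.
- The binary representation's flip law depends on the magnitude of the
  continuous coordinate relative to V_max; very large V_max on the unit box
  saturates flip probabilities near 1 and degrades the search toward random
  walk (the default V_max = 6 with unit box is already near this regime but
  is retained as the family default; the global-best archive makes the
  search robust to it).
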