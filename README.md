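# srwpso

Boosted particle swarm optimization (**SRWPSO**), its binary variant
(**bSRWPSO**), and a **bSRWPSO-FKNN** wrapper feature-selection pipeline for
tabular clinical data, together with the benchmark/statistics harness used
to evaluate them.

## The problem

Clinical tabular datasets — a few hundred patients, dozens of laboratory
features on wildly different scales — need feature selection before a
distance-based classifier is useful: most features are noise, and a
36-dimensional Euclidean metric drowns the signal. Wrapper selection
searches the space of feature subsets directly, scoring each candidate
subset by the measured error of the downstream classifier. That search
space is `{0,1}^D`, far too large to enumerate, so a discrete metaheuristic
does the searching.

This package provides the whole chain, aimed at researchers who want a
reproducible swarm-based selection pipeline for small clinical cohorts, or
a clean PSO-variant testbed with a proper comparison harness.

## The algorithms

**SRWPSO** augments canonical PSO (velocity update
`V ← ωV + c₁r₁(pB − X) + c₂r₂(gBest − X)`, clamped to ±V_max) with three
independently switchable strategies:

- **SOB** — Sobol low-discrepancy initialization of the population;
- **RRS** — random replacement: per dimension `j`, `pBᵢⱼ ← gBestⱼ` when
  `a < C`, with `C = tan(π(rand − ½))` a standard Cauchy draw and
  `a = 1 − FEs/MaxFEs` decaying linearly over the evaluation budget; the
  hybridized personal best is re-evaluated (and may temporarily degrade —
  only the global best is monotone);
- **AWS** — adaptive inertia weight `ω = (1 − FEs/MaxFEs)^β`,
  `β = 1 − C₁·S/MaxFEs`, where `S` starts at 0.01 and is halved on each
  global-best improvement, incremented otherwise.

**bSRWPSO** runs these dynamics on `[0,1]^D` while each particle carries a
binary mask; after every move each mask bit flips with probability
`V(x_d) = |tanh(x_d)|` (the V-shaped transfer).

**FKNN** (fuzzy K-nearest neighbors) classifies by graded class
memberships: `μᵢ(x) = Σⱼ μᵢⱼ wⱼ / Σⱼ wⱼ` over the k nearest neighbors,
with weights `wⱼ = ‖x − xⱼ‖^(−2/(m−1))` and fuzzy strength `m > 1`.

The wrapper fitness of a mask with `R` selected features out of `D` is

```
Fitness = 0.99 · Error + 0.01 · R/D
```

so classification error dominates and smaller subsets break ties; the empty
mask gets the sentinel value 1.0.

The harness adds the comparison statistics used for stochastic optimizers:
per-cell AVG/STD over repeated runs, paired Wilcoxon signed-rank tests,
significance-gated win/tie/loss (`+/=/−`) counts, and Friedman mean ranks.

## Worked example

```python
import numpy as np
from srwpso import (SwarmConfig, make_objective, run_pso, run_srwpso,
                    SyntheticSpec, generate_synthetic_classification,
                    SelectionConfig, run_feature_selection)

# continuous optimization: canonical PSO vs SRWPSO on the 10-D Rastrigin
spec = make_objective("rastrigin", 10)
cfg = SwarmConfig(dim=10, population_size=30, max_evaluations=20_000, seed=1)
print(f"PSO    best: {run_pso(spec, cfg).best_score:.4f}")
print(f"SRWPSO best: {run_srwpso(spec, cfg).best_score:.4f}")

# feature selection on a synthetic clinical-style cohort
# (300 samples, 36 skewed features, the first 4 informative)
ds = generate_synthetic_classification(SyntheticSpec(seed=1))
report = run_feature_selection(ds, SelectionConfig(seed=1))
print(f"mean outer-fold accuracy: {report.mean_accuracy:.3f}")
top = np.argsort(report.selection_counts)[::-1][:6]
for j in top:
    print(f"  {ds.feature_names[j]}: selected in {report.selection_counts[j]}/10 folds")
```

prints

```
PSO    best: 56.2474
SRWPSO best: 9.9496
mean outer-fold accuracy: 0.957
  inf03: selected in 10/10 folds
  inf04: selected in 9/10 folds
  inf02: selected in 8/10 folds
  inf01: selected in 8/10 folds
  noise36: selected in 5/10 folds
  noise12: selected in 4/10 folds
```

The three strategies cut the Rastrigin score by a factor of ~5 under an
identical evaluation budget, and the wrapper pipeline ranks all four
planted informative features above every noise feature while classifying
held-out folds at 95.7% accuracy.

`FuzzyKNN` is a scikit-learn-compatible classifier and
`BinarySwarmFeatureSelector` a scikit-learn-compatible selector
(`fit` / `get_support` / `transform`), so both compose with sklearn
pipelines and model selection.

A CLI mirrors the library:

```bash
srwpso optimize --objective rastrigin --dim 10 --max-fes 20000 --seed 1 --trace trace.csv
srwpso synth --n 300 --features 36 --informative 4 --effect 2.0 --seed 1 --out cohort.csv
srwpso select --data cohort.csv --label-col CLASS --folds 10 --repeats 10 --seed 1 --out report/
srwpso benchmark --objectives sphere,rastrigin,ackley --dim 10 --runs 15 --out bench/
```

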