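# Methods

## Problem and model

Wrapper feature selection on an n × D matrix with class labels, in the regime
D ≫ n (thousands of features, tens of samples). A candidate solution is a bit
mask x ∈ {0, 1}^D; the objective, minimized, is

    fitness(x) = ω · E(x) + (1 − ω) · d/D

with E(x) the KNN error on the masked features, d the number of selected
features, and ω = 0.99. With this weighting one misclassified sample on a
12-sample holdout costs 0.0825 while one extra feature in a 500-feature
problem costs 2·10⁻⁵: error dominates, size breaks ties.

The search is a binary PSO whose social structure follows manta-ray foraging.
Particles keep a fixed index order ("the chain"); the cognitive attractor of
particle i is the personal best of particle i − 1 (the head uses its own).
Per particle per iteration one uniform draw chooses cyclone learning
(probability ½) versus chain learning; inside cyclone a second draw compares
against t/T to choose a continuous random reference (exploration, likely
early) or the global best (exploitation, likely late). After every main phase
the entire swarm somersaults: positions are replaced by
pbest + 2·r₁·(gbest − r₂·pbest) thresholded at 0.5, which preserves every bit
on which pbest and gbest agree and resamples the disagreements. Two
evaluation sweeps per iteration give exactly N + 2NT objective calls per run
(N + NT for the one-sweep baseline BPSO).

Assumptions: the objective is deterministic per mask (the inner split is
frozen per run), minimization is elitist (personal/global bests only improve
on strictly smaller fitness), and the chain order is never re-sorted.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| N (`n_particles`) | 20 | swarm size; standard for this family |
| T (`n_iterations`) | 100 | iteration budget |
| ω (`omega`) | 0.99 | error-vs-size weight; conventional value |
| k (`n_neighbors`) | 5 | KNN neighbour count |
| w | 0.9 → 0.4 | inertia, linearly decreasing in t/T |
| c₁..c₄ | schedules | c₁ = 2·erf(0.5 − t/T), c₂ = 3·erf(1.7 − t/T), c₃ ≡ c₂, c₄ ≡ c₁ |
| c₅, c₆ | 2 | constants of the random-reference cyclone branch |
| `v_clamp` | 6.0 | symmetric velocity bound; tanh(6) ≈ 0.99999, so larger magnitudes are saturated by the transfer function anyway |
| `test_fraction` | 0.2 | inner stratified holdout measuring E |
| `scale` | True | min-max scaling on training statistics (expression scales vary by orders of magnitude) |
| `memoize` | False | cache fitness by mask; changes cost, never the trajectory |

Initialization: position bits iid Bernoulli(0.5) (unbiased over subset
space), velocities uniform in [−1, 1]. Both are conventions; the method does
not prescribe them.

## Numerical and tie-break choices

* The V-shaped transfer uses the velocity **magnitude**, Tf = tanh(|v|), and
  complements the current bit with probability Tf. A signed tanh would never
  flip negative-velocity bits, which contradicts the V-shaped family's
  definition.
* Somersault values exactly equal to 0.5 map to 0, biasing ties toward
  smaller subsets, consistent with minimizing d/D.
* Personal bests replace only on strict improvement; global-best ties break
  to the lowest particle index. Together with a single seeded random stream
  consumed in a documented fixed order (branch draw, optional reference draw,
  r₁, r₂, transfer draws, then the somersault draws), runs are bit-for-bit
  reproducible.
* r₁/r₂ are drawn per dimension by default (the BPSO convention; avoids
  lock-step bit dynamics); `SwarmConfig(per_dimension_random=False)` switches
  to per-particle scalars.
* KNN is deterministic: distance ties break to the lower training-row index,
  vote ties to the smallest label.
* The empty mask gets sentinel fitness 1.0 (worse than any valid subset)
  without calling the classifier; the objective is undefined at d = 0.
* The random cyclone reference stays continuous in [0, 1]^D — it only enters
  a velocity difference, so rounding it to bits would discard information.
* Constant training columns min-max scale to 0; applied values outside the
  training range are not clipped.
* The iteration budget runs exactly T loop bodies (t = 1..T); coefficient
  schedules are evaluated at t/T, so c₁ crosses zero at the half-way point.

## Synthetic data

`SyntheticSpec` plants a known signal: informative feature j of a class-c
sample is Normal(δ·m_cj, 1) where m is a {−1, 0, +1} class-signature matrix
with distinct rows; redundant features are a random informative parent plus
Normal(0, `redundancy_noise`); noise features are standard normal. Defaults —
60 samples, 3 balanced classes, 10 informative + 20 redundant + 470 noise,
δ = 3, `redundancy_noise` = 0.5 (parent correlation ≈ 0.9, a plausible
co-expressed-gene stand-in) — emulate the sample-starved, feature-rich shape
of published tumor expression panels at desk scale.

What the generator does **not** emulate: heavy-tailed and count-like marginal
distributions, correlated noise blocks and batch effects, class-dependent
covariance, or label noise. Passing tests on this generator therefore
demonstrate correctness of the optimizer and protocol, not expected
performance on real expression data.

## Evaluation protocol

Two layers. Inside a run, E comes from the frozen stratified 80/20 split of
whatever data the optimizer is given. Around runs, the benchmark harness
first reserves an unseen outer test fold (10-fold by default, re-randomized
per run with recorded seeds), selects features on the remainder only, and
reports accuracy of the selected subset on the unseen fold with the same KNN
configuration; both the inner and the unseen accuracy are logged. Runs are
paired: for run index r every algorithm sees the same outer split and
optimizer seed. Note the fairness caveat: at equal T the manta-ray variant
spends 2N evaluations per iteration versus N for the baselines; evaluation
counts are recorded per run so evaluation-matched comparisons can be made by
halving T.

Aggregation: mean ± std tables, Friedman average ranks across datasets
(average-rank ties; the chi-square stage is delegated to scipy and reported
when at least three algorithms are compared), and two-sided Wilcoxon
signed-rank tests, with identical paired samples reported as NaN rather than
a fabricated p-value.

## Known limitations

* Subset shrinkage is slow at the default budget. The V-shaped rule flips
  bits at rate tanh(|v|) and velocities decay only geometrically once a bit
  agrees with its attractors, so per-bit churn stays high for tens of
  iterations. On the 500-feature recovery benchmark the acceptance script
  measures median subset sizes around 150 after T = 100 — far smaller than
  the ~250 at initialization but not the single-digit subsets one might hope
  for; runs of a few hundred iterations continue to shrink the subset slowly.
* Consequently recall of the planted informative block is partial (the script
  measures medians near 0.4–0.5): once two or three signal features give zero
  holdout error, the size penalty does not distinguish an informative
  original from its redundant copies, so completeness of the recovered block
  is not an optimization target the objective actually rewards.
* With tiny inner test sets (12 samples at n = 60), E is quantized at ~0.083
  and saturates at zero early, after which only the weak size term drives the
  search.
* The fitness landscape is evaluated on a single frozen split; subsets can
  overfit that split, which is why reported accuracy comes from the unseen
  outer fold.
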