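# Methods

This note records the model, the defaults, the numerical choices, and the
limits of what the synthetic batteries demonstrate.

## The BER optimizer

A population of n agents searches a box-bounded space under a minimization
convention. Each iteration:

1. **Grouping.** The exploitation share interpolates linearly from 30% at
   t = 0 to 70% at t = N (rounding half-down, each group keeps ≥ 1 member
   for n ≥ 2). Agent order is shuffled every iteration, so membership churns.
2. **Exploration move.** S′ = S + D(2r₂ − 1) with D = r₁(S − 1); r₁, r₂ are
   fresh elementwise-uniform [0,1] vectors per agent per iteration. The
   "− 1" subtracts the scalar 1 from every coordinate: the update is applied
   exactly as defined, even though it makes the step scale depend on the
   coordinate frame.
3. **Exploitation move.** A fair coin chooses between stepping toward the
   leader, S′ = r²(S + r₃(L − S)), and probing a shell around it,
   S′ = r(S* + k), k = z + 2t²/N². The factor r = h·cos x/(1 − cos x) uses
   h ~ U[0,2] and x ~ U[x_min, 180] **degrees**; because the ratio diverges
   as x → 0 it is clamped to ±r_cap (default 10) and the angle draw is kept
   above x_min = 1°.
4. **Elitism.** The leader updates only on strict improvement, and if no
   current agent carries the leader's position it is reinserted over the
   worst agent, so the best-fitness trajectory is non-increasing by
   construction.
5. **Stagnation mutation.** An agent whose fitness fails to improve by more
   than 1e-12 for 3 consecutive iterations is replaced wholesale by a
   per-coordinate draw k·z² − r (the update has no S(t) term on the right,
   so replacement, not perturbation, is the faithful reading), then clipped
   to bounds.

All positions are clipped to the bounds after every move. Every stochastic
draw flows from one seeded `numpy` generator stored in the optimizer state,
so runs are bit-reproducible. Non-finite objective values are warned about
and treated as +∞.

Defaults: n = 15, N = 50, stagnation window 3, tolerance 1e-12, r_cap 10,
x_min 1°. The evaluation budget is n(N+1) plus one evaluation per mutation
fired.

Note a structural property of the exploitation rules: both r²(S + D) and
r(S* + k) contract toward the origin when |r| < 1, which is the frequent
case. On origin-centred benchmarks (sphere, sum-squares, Schwefel 2.22)
this accelerates convergence dramatically; on problems whose optimum is far
from the origin the exploration group and mutation carry more of the load.
The dominance battery therefore treats uniform random search at the same
evaluation budget as the null control rather than reading the absolute
convergence level as evidence.

## Binary feature selection

Mask dynamics run in [−4, 4]^D, where the sigmoid transfer spans
≈ [0.018, 0.982]; a coordinate is selected iff its sigmoid exceeds 0.5
(equivalently, the coordinate is positive). The threshold is deterministic —
reproducibility is preferred over the stochastic-threshold variant — and an
all-off position forces the single largest coordinate on, so masks are never
empty. The composite fitness is α·error + (1 − α)·|S|/D with α = 0.99,
matching the convention of wrapper-selection work that reports an
(error, selected-size) pair; the wrapper defaults to 5-nearest-neighbours
under 5-fold stratified cross-validation for desk-scale speed, with an LSTM
wrapper selectable where fidelity to the full pipeline matters more than
runtime. Fitness values are memoized by mask, since the CV is deterministic
given the seed. The binary-PSO control (inertia 0.72, cognitive/social 1.49,
velocity cap 2) shares the transfer rule and fitness exactly, so differences
between the two methods isolate the update dynamics.

## LSTM and MLP classifiers

A flat d-vector becomes an ordered sequence of L steps × m features
(row-major; m = 1 for small tables, m = 32 is the natural choice at
d = 1024). One gated cell is unrolled over the sequence:
f, i, O = σ(W·[y_{t−1}, X_t] + b); C* = act(·); C_t = C_{t−1}∘f + C*∘i;
y_t = O ∘ tanh C_t. The candidate activation defaults to **sigmoid** (with
the conventional tanh selectable); under the sigmoid candidate and C₀ = 0
the cell state is confined to [0, t] after t steps. Classification is a
single logistic unit on the final y_t.

Training minimizes binary cross-entropy with hand-derived
backpropagation-through-time gradients (verified against central finite
differences in the test suite) under Adam, with mini-batches reshuffled per
epoch from a seeded generator. Initialization is uniform ± 1/√fan-in, with
the forget-gate bias set to 1 so the memory cell initially retains
information — the usual LSTM practice, which matters for gradient flow once
the unrolled length reaches tens of steps. Features are standardized on the
training portion; a stratified 20% split yields per-epoch train/validation
accuracy traces. Identical seed and data give bit-identical parameters.

The MLP baseline (one ReLU hidden layer, default width 64, logistic output)
is trained by the same loop so both models share the TrainConfig surface,
the traces, and the determinism contract.

## Hyperparameter tuning

BER searches [0,1]^k; coordinates decode onto named axes — hidden size
[8, 256] (log, integer), learning rate [1e-4, 1e-1] (log, real), batch size
[16, 128] (log, integer), and the sequence step width over the power-of-two
divisors of d. Search-time fitness is the validation error of a model
trained under a reduced epoch budget (default 10); the winning configuration
is retrained at the full 50 epochs. Each evaluation's training seed derives
deterministically from the run seed and the evaluation index, so whole
searches replay exactly. Failed trainings score +∞ and the search continues.
The null control re-evaluates the same fitness at uniformly random
positions with an equal evaluation budget. Replication batteries summarize
per-run accuracies as min / quartiles / median / max / mean / SD, with
quartiles by linear interpolation between closest ranks.

## Evaluation statistics

Confusion-derived metrics follow the standard definitions; specificity is
TN/(TN+FP) (the true-negative rate). The positive class defaults to
Osteoarthritis (label 1) and is configurable. Balanced accuracy is
(TPR + TNR)/2. 95% intervals use the Wald normal approximation
p̂ ± 1.96·√(p̂(1−p̂)/n), clipped to [0,1]; n defaults to the evaluated test
count. Metrics with a zero denominator are reported as undefined rather
than coerced.

The Wilcoxon signed-rank test drops zero differences and midranks ties. For
n ≤ 20 the two-tailed p is exact: the null distribution of the
positive-rank sum is built by a dynamic program over doubled midranks
(equivalent to enumerating all 2ⁿ sign assignments, which the tests do
independently), and p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))). Beyond n = 20
the normal approximation applies with continuity and tie corrections.
One-way ANOVA uses the standard between/within decomposition with the F
tail from scipy; an all-constant input is flagged degenerate instead of
dividing by zero. `complexity_product` reports the raw n·d·iterations work
units of a population search.

## Synthetic data

The generator emulates the *structure* of a two-class deep-feature matrix:
k informative Gaussian features with class means ±δ/2 and noise σ, one
correlated redundant copy per informative feature (ρ·x + √(1−ρ²)·noise),
and pure-noise nuisance features. Defaults mirror the application's class
imbalance at one-tenth scale (159 Normal : 225 Osteoarthritis) with a
desk-scale d = 100 (1024 available by flag). Because the class-conditional
model is Gaussian, the Bayes error of any feature subset is known in closed
form, which anchors the generator's own tests (single-feature error ≈
Φ(−3) at δ = 6, chance-level behaviour at δ = 0).

What passing batteries do **not** show: real CNN activations are not
Gaussian, not independent beyond one redundancy layer, and carry no simple
informative/nuisance split, so results here demonstrate algorithmic
correctness and relative behaviour (bBER vs random masks, tuned vs random
configurations), not clinical performance.

## Problem sizes and batteries

The packaged batteries run at desk scale: optimizer dominance on the 10-d
sphere (n = 15, N = 100, 10 seeds vs equal-budget random search);
feature-selection recovery on d = 50 tables with 5 informative features at
δ = 4 (10 seeded runs, informative recall compared against the
equal-size-random-mask expectation, wrapper error against the all-features
baseline); learnability on a separable d = 20 fixture (both models at 50
epochs across 10 seeds); and tuning with population 4 × 3 iterations against
the same number of random configurations at a 5-epoch search budget
(10 batteries). These sizes keep a full run to roughly a minute while
leaving each comparison statistically one-sided enough to be meaningful.

## Known limitations

- The exploration update's "(S − 1)" makes step sizes frame-dependent; it
  is retained as defined rather than normalized.
- The exploitation contraction toward the origin biases the optimizer on
  origin-centred objectives (see above).
- Single-cell, unidirectional LSTM only; no stacked or bidirectional
  variants, and binary labels only.
- Wald intervals are anti-conservative near p̂ = 0 or 1; no multiple-testing
  correction is applied (planned single comparisons only).
- Wall-clock timing columns in pipeline reports are hardware-dependent and
  excluded from all assertions.
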