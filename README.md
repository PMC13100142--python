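# biruni

Swarm-intelligence tooling for radiographic feature classification: the
**Al-Biruni Earth Radius (BER)** metaheuristic, its **binary variant (bBER)**
for wrapper feature selection over deep-feature tables, an **LSTM / MLP**
classification layer with BER-driven hyperparameter tuning, and the
statistical machinery used to compare optimizers (confusion-matrix metrics
with Wald intervals, balanced accuracy, exact Wilcoxon signed-rank, one-way
ANOVA).

The motivating application is knee-osteoarthritis (KOA) screening: deep
features extracted from knee X-rays (typically 1024-dimensional CNN
activations, two classes Normal vs Osteoarthritis) are pruned by wrapper
feature selection and classified by a gated recurrent model. This package
implements the full algorithmic pipeline and exercises it on synthetic
feature tables with known ground truth, so everything runs without images,
pretrained networks, or downloads.

## The optimizer

BER is a population method that splits its n agents into an exploration and
an exploitation group, shifting the exploitation share linearly from 30% to
70% of the population over N iterations. Moves are built from the
trigonometric step factor

    r = h · cos(x) / (1 − cos(x)),   h ~ U[0,2],  0 < x ≤ 180°

(clamped to ±r_cap, since the ratio diverges as x → 0). Exploration perturbs
an agent around its own position, S′ = S + r₁(S − 1)(2r₂ − 1); exploitation
either steps toward the leader L, S′ = r²(S + r₃(L − S)), or probes a
widening shell around it, S′ = r(S* + k) with k = z + 2t²/N². Elitism keeps
the best-so-far solution alive, and agents whose fitness stalls for three
consecutive iterations are replaced by a mutation draw k·z² − r.

For feature selection the same dynamics run in a continuous box [−4, 4]^D;
a position maps to a feature mask through a sigmoid transfer with a 0.5
threshold, and a candidate mask is scored by

    fitness = α · CV-error(wrapper | selected) + (1 − α) · |selected|/D,  α = 0.99.

The classifier is an LSTM assembled from the standard gate equations
(forget/input/output gates, candidate cell state, y_t = O_t ∘ tanh C_t)
unrolled over the feature vector reinterpreted as an ordered sequence, and
trained by backpropagation through time; a one-hidden-layer MLP is the
baseline. A binary PSO with the identical transfer rule and fitness serves
as the comparison control.

## Worked example

```python
import numpy as np
from biruni import *

# 1. minimize the 10-d sphere
spec = make_benchmark("sphere", 10).to_objective()
res = run(spec, BERSettings(population_size=15, iterations=50, seed=42))
print(res.best_fitness, res.evaluations)
# 6.637885909675806e-38 830

# 2. recover informative features from a synthetic deep-feature table
table = generate_features(SynthSpec(n_class0=60, n_class1=60, d=50, k=5,
                                    delta=4.0, seed=7))
mask, fit, _ = select_features(
    table, BERSettings(population_size=10, iterations=20, seed=7),
    FSFitnessConfig(seed=7))
print(mask.n_selected, round(fit, 4))
# 17 0.0034

# 3. the comparison statistics
w = wilcoxon_signed_rank(np.linspace(0.005, 0.05, 10))
print(w.w_plus, w.p_two_tailed)      # 55.0 0.001953125
print(balanced_accuracy(0.99707887, 0.993119266))   # 0.995099068
```

The sphere run drives the best fitness from a random start down to ~1e-38
in 830 evaluations (uniform random search with the same budget stays above
10³). The selection run keeps 17 of 50 features at a composite fitness of
0.0034 — near-zero cross-validated error plus a small size penalty — and the
mask covers the informative block. Ten all-positive paired differences give
the maximal rank sum W⁺ = 55 with an exact two-tailed p of 2/1024 ≈ 0.002,
and averaging a sensitivity of 0.99708 with a specificity of 0.99312 gives a
balanced accuracy of 0.995099.

The same operations are available from a shell:

```bash
biruni simulate --n0 159 --n1 225 --d 100 --k 10 --delta 3 --seed 7 --out synth.csv
biruni select --features synth.csv --pop 15 --iters 50 --seed 42 --algo ber --out mask.json
biruni train --features synth.csv --model lstm --epochs 50 --seed 42 --out model.json
biruni pipeline --seed 3 --out-dir run_out
```

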