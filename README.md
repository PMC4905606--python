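# mgmsteps

Learning sparse **mixed graphical models** (MGMs) over continuous and
categorical variables, with **edge-type-specific sparsity penalties** and
**stability-based penalty selection (StEPS)**.

Biomedical datasets routinely mix continuous measurements (expression,
spirometry, anthropometrics) with categorical ones (diagnosis, smoking
history, genotype). A pairwise MGM puts both in one Markov random field,

```
p(x, y) ∝ exp( Σ_{s,t} -½ β_st x_s x_t + Σ_s α_s x_s
               + Σ_{s,j} ρ_sj(y_j) x_s + Σ_{r≤j} ϕ_rj(y_r, y_j) )
```

whose nonzero interaction blocks define an undirected network: `β_st` links
two continuous variables (cc), the vector `ρ_sj` a continuous–categorical
pair (cd), and the matrix `ϕ_rj` two categorical variables (dd). The model
is learned by minimizing the negative log-pseudolikelihood plus a separate
group-lasso penalty per edge type,

```
min_Θ  ℓ̃(Θ)/n + λ_cc Σ_{t<s}|β_st| + λ_cd Σ_{s,j}‖ρ_sj‖₂ + λ_dd Σ_{r<j}‖ϕ_rj‖_F ,
```

via accelerated proximal gradient. A single shared λ systematically
over-selects cc edges and misses dd edges; separating the three penalties
fixes this, and **StEPS** chooses them efficiently: learn single-λ models on
N=20 subsamples of size `b = ⌊10√n⌋` across a λ grid, measure per-edge-type
subsample instability `ξ̂ = 2θ̂(1−θ̂)`, monotonize each curve and take, per
edge type, the smallest λ whose instability stays below γ = 0.05 — a linear
search that needs no extra model fits beyond single-λ StARS. The package
also ships the classical baselines (AIC, BIC, K-fold CV, oracle), the cubic
three-dimensional stability search used to validate StEPS's independence
assumption, the scale-free mixed-data simulator used for benchmarking,
edge-recovery scoring (precision/recall/F1/accuracy/MCC, per edge type),
and generative classification of any categorical variable from a trained
model.

## Worked example

```python
import numpy as np
from mgmsteps import (SimulationConfig, assign_parameters,
                      generate_scale_free_network, sample_dataset,
                      LambdaGrid, steps_select, stars_select,
                      adjacency_from_parameters, edge_confusion,
                      recovery_metrics)

# one scale-free network: 12 continuous + 12 four-level categorical nodes
cfg = SimulationConfig(p=12, q=12, n_samples=400)
graph = generate_scale_free_network(24, seed=7)
model = assign_parameters(graph, cfg, linear=False, seed=8)
data = sample_dataset(model, 400, seed=9)
truth = graph.adjacency()

grid = LambdaGrid((0.64, 0.32, 0.16, 0.08, 0.04))
steps = steps_select(data, grid, seed=10)          # N=20 subsamples, b=200
print("selected:", steps.chosen.astuple())
met = recovery_metrics(edge_confusion(
    adjacency_from_parameters(steps.params), truth, 12, 12))
print({k: round(v, 3) for k, v in met.items() if k != "degenerate"})
```

prints

```
selected: (0.64, 0.32, 0.16)
{'precision': 1.0, 'recall': 0.529, 'f1': 0.692, 'accuracy': 0.942, 'mcc': 0.705}
```

i.e. StEPS kept a strong continuous–continuous penalty (.64) but relaxed
the mixed penalty to .32 and the categorical–categorical penalty to .16,
and the refit network recovers the generating graph with MCC 0.71 and no
false positives — a single shared λ on the same data (`stars_select`)
selects .32 for everything and reaches MCC 0.66 with lower recall.

The same pipeline is available from the shell:

```
mgmsteps simulate --networks 1 --nodes 24 --continuous 12 --samples 400 \
    --nonlinear --seed 7 --outdir sim/
mgmsteps steps --data sim/net0_nonlin.tsv --seed 10 --out fit
mgmsteps evaluate --predicted fit.edges.tsv --truth sim/net0_nonlin_truth.tsv \
    --data sim/net0_nonlin.tsv --by-type
```

Subcommands: `simulate`, `fit`, `select` (aic/bic/cv/oracle), `steps`
(incl. `--cubic`), `evaluate`, `classify`, `benchmark`.

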