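# countsim

How much does the sequencing measurement process itself degrade
expression-based classification and biomarker discovery?  `countsim` is a
seeded simulation framework for answering that question.  It generates
"true" gene-expression data from a known high-dimensional Gaussian model,
transforms it into RNA-Seq-like read counts or SAGE-like tag counts
through a Poisson measurement model, and runs a Monte-Carlo evaluation of
t-test feature selection and small-sample classification (LDA, 3NN,
RBF-SVM) on the raw and the transformed data.  It is aimed at statisticians
and computational biologists who study classifier and feature-selection
behaviour under measurement distortion, where real data cannot help
because the ground truth is unknown.

## Model

Expression for `D = 20,000` genes is multivariate Gaussian with a block
compound-symmetry covariance (pathways of `l = 5` genes, within-block
correlation ρ).  Ten *global markers* separate the classes
(`N(m₀·1, σ₀²Σ)` vs `N(m₁·1, σ₁²Σ)` with `m₀ = 0`, `m₁ = 1`,
`σ = 0.6`); 50 *heterogeneous markers* per class-1 subclass are elevated
only in their own subtype; 2,000 high-variance non-markers are per-gene
Gaussian mixtures `p·N(m₀,σ₀²) + (1−p)·N(m₁,σ₁²)`, `p ~ U(0,1)`; the
remaining 17,890 are i.i.d. `N(m₀, σ₀²)` nulls.

Sequencing is modelled as a Poisson generalized linear model with a random
per-sample depth `sᵢ ~ U(α, β)` and Gaussian technical noise θ:

    E[Xᵢⱼ | sᵢ] = sᵢ · exp(λᵢⱼ + θᵢⱼ),    θᵢⱼ ~ N(0, (|m₁−m₀|·COV)²)

SAGE and NGS differ only in the depth range (50K–100K tags vs up to 10⁸
reads); `(α, β)` are calibrated in closed form from a target total-count
range.  Full details, parameter tables and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from countsim import (ModelConfig, PipelineConfig, run_recovery_cell,
                      tabulate_recovery)

model = ModelConfig(rho=0.4)                      # reference parameters
sage = PipelineConfig.sage(cov=0.05)              # 50K-100K tags/sample

rec = run_recovery_cell(model, sage, n=180, replicates=200, seed=7)
print(tabulate_recovery(rec))
```

prints (seed 7):

```
{'<8': 1.5, '8': 5.5, '9': 41.5, '10': 51.5}
```

i.e. with 180 training samples of SAGE-scale counts, t-test selection of
the top 10 features finds **all ten** true global markers in ~52% of
replicates, nine of them in ~42%, and fewer than eight in ~2%.  On the raw
expression data the all-ten rate at the same `n` is ~99.7%, and on deep
RNA-Seq (50M reads) ~81% — the count transformation, not the sample size,
is what destroys the rest.  A classification counterpart:

```python
from countsim import ClassifierSpec, replicate_rng, run_replicate

spec = ClassifierSpec(rule="LDA", d=10, selection="TTEST")
rec, err = run_replicate(model, sage, 60, [spec], n_t=3000,
                         rng_expr=replicate_rng(7, 101, 60, 0),
                         rng_pipe=replicate_rng(7, 202, 0, 60, 0))
print(rec, err)      # -> 5 {'LDA': 0.3167}
```

one replicate at `n = 60`: five of ten markers recovered, LDA true error
31.7% on a 3,000-sample independent test set (hold-out RMS bound
`1/(2√3000) ≈ 0.0091`).

There is also a CLI for scripted use (`countsim generate | transform |
run | tabulate | density`); `countsim run --config run.yml` executes a
full configured experiment and writes per-replicate records, recovery
tables, error densities and a manifest.

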