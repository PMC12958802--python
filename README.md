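# gpkern

Multi-kernel RKHS regression and feed-forward neural networks for genomic
prediction in multi-environment testcross trials — with a synthetic trial
generator so every stage is testable without external downloads.

## Who this is for

Quantitative geneticists and breeding-informatics developers who want to
compare kernel (gBLUP/RKHS) and neural-network prediction models *on
matched prediction problems*: breeding values, hybrid values, total genetic
values, phenotypes, or site means, each defined by the data modalities a
model is allowed to use.

## The models

**RKHS / gBLUP.** Phenotypes are modeled as

    y = 1·μ + Σ_k u_k + ε,   u_k ~ N(0, K_k σ²_k),   ε ~ N(0, I σ²_ε)

where each K_k is a similarity kernel: linear (K = XX′/(tr(XX′)/n), the
genomic-relationship matrix of gBLUP), Gaussian (k = exp(−h·d²/q), q the
median squared distance), or arc-cosine (the covariance of an
infinite-width ReLU network, with a layer recursion for depth). Composite
weather kernels combine per-variable kernels with inverse-hyperparameter
weights; genotype-by-environment kernels are Hadamard products of expanded
constituents. The model is fitted by Gibbs sampling in the eigenbasis of
each kernel (diagonal full conditionals; default chain 15,000/5,000/5).
Bandwidths and layer counts are chosen by spectral profile maximum
marginal likelihood.

**Networks.** Dense modules for genomic and soil inputs, a 1-D
convolutional module for daily weather, and a fusion module over
concatenated penultimate outputs — trained with Adam on RMSE, tuned by a
replicated random-search protocol with binned-loss configuration selection
and rolling-mean epoch selection.

**Evaluation.** Pearson's r and RMSE across and within environments, an
orthogonal three-part RMSE decomposition, an intercept-only baseline, and
one-sided Dunnett many-to-one tests over replicate seeds.

## Worked example

```python
import numpy as np
from gpkern.simulate import (SimConfig, simulate_inbred_panel,
    make_testcross_design, derive_hybrid_genotypes, simulate_environments,
    simulate_phenotypes, split_train_test)
from gpkern.codings import additive_code
from gpkern.kernels import linear_kernel, expand_kernel, design_matrix
from gpkern.rkhs import MultiKernelRKHS

cfg = SimConfig(n_inbreds=79, n_testers=4, n_snps=150, n_sites=4, n_years=1,
                variance_fractions={"additive": 0.5, "residual": 0.5}, seed=1)
panel = simulate_inbred_panel(cfg)
design = make_testcross_design(4, 75, 2, seed=1)
hybrids = derive_hybrid_genotypes(panel, design)
trial = simulate_environments(cfg)
table = split_train_test(simulate_phenotypes(hybrids, trial, cfg),
                         test_site_year_count=1, cap=None, seed=1)

A = additive_code(hybrids).values
Z = design_matrix(table.data["hybrid_id"], list(hybrids.individual_ids))
K = expand_kernel(linear_kernel(A, labels=list(hybrids.individual_ids)), Z,
                  labels=list(table.data.index))
y, train = table.data["y_std"].to_numpy(), table.train_mask()

model = MultiKernelRKHS(y, {"additive": K}, train_mask=train)
res = model.fit(n_iter=3000, burnin=1000, thin=2, seed=1)
pred = res.predict()
print("test r =", round(float(np.corrcoef(y[~train], pred[~train])[0, 1]), 3))
print(res.variance_components().round(3)[["mean", "proportion"]])
```

Output:

    test r = 0.662
                mean  proportion
    component
    additive   0.864       0.633
    residual   0.487       0.367

The test correlation is the accuracy of gBLUP for tested genotypes in an
untested environment. The posterior additive share lands above the
simulated 0.5 at this small scale: each hybrid repeats across the four
site-years, so the full-rank kernel can absorb part of the record-level
noise; the dedicated recovery checks (single records per hybrid, n = 500)
recover the simulated fractions with calibrated credible intervals.

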