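# Methods

This note documents the models, algorithms and design choices in `gpkern`,
in the spirit of a statistical-software methods appendix. Everything stated
here is computed by the package's tests or by `scripts/acceptance.py`;
nothing is quoted from external analyses.

## The prediction problem

Multi-environment testcross trials evaluate many candidate inbred lines by
crossing each to a small set of common testers and measuring hybrid grain
yield across site-years. Phenotypes are modeled as

    y = mu + a + d + i + (g x e) + e + eps

with additive (a), dominance (d) and epistatic (i) genetic effects, a
genotype-by-environment interaction, an environment main effect (e) and an
iid residual. Which of these components a model can capture depends on the
data modalities it is given, which motivates a five-problem taxonomy
(breeding values, hybrid values, total genetic values, phenotypes, and site
means) enforced by `gpkern.evaluate.run_taxonomy`: a model is only scored
inside a problem whose allowed modalities cover the model's inputs.

## Synthetic trial generator

`gpkern.simulate` is first-class, tested code, not a fixture. It emulates:

- **Inbred panel.** Homozygous calls in {0, 2}; per-locus reference-allele
  frequencies are uniform on a configurable minor-allele-frequency band
  (default 0.05–0.5), and loci whose *realized* MAF falls below the lower
  bound are redrawn, so the emitted panel respects the requested spectrum.
- **Testcross design.** Each line is paired with a configurable number of
  random testers; the hybrid incidence matrix M has exactly two 1s per row,
  and hybrid genotypes are the parental averages (1/2)MX.
- **Environments.** Soil is a site-level vector (21 variables by default,
  shared exactly by year replicates of a site). Weather is a daily grid for
  days −75..204 relative to planting (280 days, 19 variables by default):
  a site-specific seasonal sinusoid plus a year shift plus daily noise.
- **Phenotypes.** Components are built as: additive and dominance codings
  times iid normal effect vectors; additive-by-additive products at random
  locus pairs (the generator's operational definition of epistasis — the
  analysis only ever fits kernels, so any particular generating mechanism is
  a stand-in); a site-year main effect constructed from soil and
  season-average weather; a rank-1 genotype-by-environment interaction
  (per-hybrid additive score times a per-environment index), which is the
  simplest structure that makes interaction kernels identifiable; and iid
  noise. Every component is centered and rescaled so its realized variance
  equals its requested fraction *exactly*, giving downstream
  variance-component estimates a known truth. Yields are affine-mapped to a
  plausible bu/ac scale (mean 150, sd 25); models always operate on
  train-standardized values.
- **Splitting.** Whole site-years are held out for testing (tested
  genotypes in untested environments); any site-year with more than a cap
  (default 265) of records is down-sampled to the cap; the default number
  of held-out site-years is 16. Validation splits for network tuning
  sample site-years from the training set (default 10 splits of 16
  site-years). All splits are deterministic functions of (input, seed).

What the generator does *not* emulate: empirical maize linkage
disequilibrium (an optional block-copy mode approximates block structure
only), pedigree depth, heterosis mechanisms, or a real site network.
Passing tests therefore demonstrate the correctness and calibration of the
*methods* under a known generative model, not field performance on any real
trial dataset.

## Genomic codings and reduced predictor sets

Additive coding maps call c at locus l to c − 2p_l; dominance coding maps
(0, 1, 2) to (−2p², 2pq, −2q²) with q = 1 − p, so both have zero mean under
Hardy–Weinberg proportions. Allele frequencies are computed from the
training individuals. Monomorphic loci must be dropped before coding (a
dedicated error enforces this).

Principal components of the parental genotypes can be transferred to
hybrids either by averaging the two parents' scores or by projecting the
averaged genotypes onto the parental loadings; because each hybrid row of
(1/2)M sums to 1, the two paths are algebraically identical, and
`hybrid_gpcs` verifies the equality to 1e-10 when the genotype matrix is
supplied. The related covariance identity (1/4m)(MX)'(MX) =
(1/4m)X'(M'M)X, with M'M carrying progeny counts on its diagonal, is
exposed by `hybrid_covariance_identity`.

Reduced SNP sets are selected by a per-environment single-marker mixed-model
scan: the null model's variance ratio is estimated once per environment by
spectral profile maximum likelihood, each marker is then tested by
generalized least squares under that covariance, and per-locus p-values are
combined across environments by Fisher's method (statistic −2Σln p against
chi-square with 2k df; p-values are floored at 1e-300 with a warning before
taking logs). A fixed, configurable number of kinship PCs (default 0) can
enter as covariates; data-driven stepwise covariate selection is
deliberately out of scope, as the scan is plumbing rather than the analysis
target. Environments where a locus is untestable simply drop out of its
combination.

## Environmental features

Daily weather is summarized as means over consecutive non-overlapping
3-day windows. The 280-day season is not divisible by 3, so the trailing
1-day window is averaged over its available days — this is exactly what
makes the window count 94 (93 full windows + 1 partial). Which end of the
season carries the partial window is not identifiable from the target
configuration; the trailing choice is fixed here and is a documented
sensitivity point. All covariate columns (windowed weather and soil) are
centered and scaled by training-set statistics only, and the stored
statistics are reused on test rows, so no test information leaks into the
transformation.

## Kernels

- **Linear:** K = XX′/(tr(XX′)/n); trace is exactly n, and with additive
  codings this is the classical genomic-relationship similarity (gBLUP).
- **Gaussian:** k = exp(−h·d²/q) with q the median of the *off-diagonal*
  squared Euclidean distances (including the zero diagonal would bias q
  downward); the diagonal is set to exactly 1.
- **Arc-cosine:** layer 1 is k = (1/π)‖x‖‖x′‖ J(θ) with J(θ) = sin θ +
  (π−θ)cos θ and θ the angle between the inputs; this equals the
  covariance 2·E[relu(w·x)·relu(w·x′)] of an infinite-width
  single-hidden-layer ReLU network (verified against a Monte-Carlo
  random-feature oracle). Deeper layers recurse on the normalized angle.
  Floating-point overshoot of the arccos argument is clipped within 1e-12;
  larger violations raise. The kernel's non-unit diagonal is kept as the
  recursion produces it (optional cosine normalization is off by default).
- **Composite weather kernels** are built per variable and combined: plain
  sum then trace normalization for the linear kind (so all kernels enter
  the multi-kernel model on a common scale), and a weighted average with
  weights proportional to 1/h (or 1/layers), normalized to sum to 1, for
  the Gaussian/arc-cosine kinds — variables with stronger global similarity
  (small h) contribute more.
- **Interaction kernels** expand level-wise kernels to the record level
  with 0/1 design matrices and take the Hadamard product; a single data
  type expands against an identity kernel. The Schur product theorem
  guarantees the result is PSD.
- **Eigendecomposition** is exact and dense (desk scale), truncating
  eigenvalues below 1e-10 or beyond rank 7,500, whichever binds first; the
  retained variance fraction is recorded. The interface would admit an
  approximate backend for very large interaction kernels, which is out of
  scope here.

## Hyperparameter selection by marginal likelihood

Under y = g + eps with g ~ N(0, K·sig2_g), rotating by the eigenvectors of
K gives independent components with variances lam_j·sig2_g + sig2_e. The
residual variance is profiled analytically at each ratio sig2_g/sig2_e,
and the ratio itself is profiled by a bounded scalar search on the log
scale. Truncated bases are handled exactly by assigning the residual
response mass to zero-eigenvalue components. The Gaussian bandwidth is
then chosen by bounded scalar search over h in [0.05, 6.0] (box constraints
consistent with optimized values clustering at those ends in the target
configuration; configurable), and the arc-cosine layer count by exhaustive
grid over 1..l_max (default 50). Responses are centered with the training
mean before optimization, and fits pinned at a bound are flagged as not
converged (typical for pure-noise responses, whose profile is nearly
flat). The specific published routines this emulates are not reproduced
line-by-line anywhere accessible; the standard spectral Gaussian-process
profile likelihood above is this package's operational definition.

## The multi-kernel Bayesian model

The core model is y = 1·mu + Σ_k u_k + eps with u_k ~ N(0, K_k·sig2_k).
Writing u_k = U_k b_k in the (truncated) eigenbasis of K_k makes every
full conditional diagonal: the b_k block is sampled jointly from
independent Gaussians, which is what makes the Gibbs sampler efficient
(O(N·r_k) per kernel per sweep). Variances carry scaled-inverse-chi-square
priors with df = 5 and scales set so each prior mode equals
var(y_train)/(K+1) — a proper but weakly informative default chosen
because the upstream fitting software this emulates does not publish its
defaults; the mean has a flat prior. Default chain settings are 15,000
sweeps, 5,000 burn-in, thinning 5 (2,000 retained draws).

Kernels are built over all records (training and test) and the likelihood
conditions on training records only. This is implemented by data
augmentation: unobserved responses are imputed from their posterior
predictive each sweep, which preserves the diagonal conditionals and is
marginally equivalent to omitting them from the likelihood (a unit test
corrupts test responses and verifies training-record predictions are
bit-identical). Each kernel has its own named random stream, so kernel
dictionary order does not alter any kernel's noise sequence; predictions
under different orderings agree within Monte-Carlo error.

With a single linear kernel and fixed variances the posterior mean of g
equals the ridge/BLUP closed form K(K + λI)⁻¹y, and equivalently a marker-
effect ridge regression with the matched penalty (gBLUP ≡ rrBLUP); both
equalities are asserted within Monte-Carlo standard errors computed by
batch means. Because ~100 record-level checks at 3 MC SEs each cannot
jointly hold with certainty, the tests require ≥97% of records within 3
SEs and all within a familywise 4.5-SE bound.

## Networks

The network engine is a compact numpy implementation with manual
backpropagation: dense stacks (affine + activation + inverted dropout) for
genomic/soil/fusion modules, and valid 1-D convolutions with max/average
pooling for the weather series, all ending in one linear output unit.
Training is mini-batch Adam; the monitored loss is RMSE while the gradient
is that of the mean squared error (same minimizer, smooth at zero — pure
RMSE gradients have constant norm near the optimum and stall Adam at the
learning-rate scale). Replicate seeds control initialization and batch
shuffling; identical seeds reproduce training exactly on one platform,
and statistical (not bitwise) reproducibility is promised across
platforms. With the identity activation a single-layer network reduces to
linear regression and reaches ~1e-15 loss on noiseless linear data, which
serves as a correctness oracle.

The tuning protocol: random search over the declared space (default budget
40; the original proposal mechanism was a Bayesian optimizer, but the
selection/evaluation protocol, not the proposal distribution, is the
analysis-relevant computation, so the sampler is pluggable); each sampled
configuration trains on one randomly chosen training/validation pair with
early stopping (patience 7, up to 500 epochs); the 4 best by best-epoch
validation loss (the ranking statistic is not pinned down externally;
best-epoch loss is used and logged) retrain on all splits for the full
budget; the winner minimizes the binned loss (10 bins of 50 epochs, bin
loss = bin average of across-split mean + sd) in the most bins, with ties
broken by fewest parameters then lowest mean loss; the epoch count is the
earliest minimizer of the 20-epoch trailing rolling mean of the summed
validation loss. Both selectors are verified against brute-force
re-implementations on random trajectories. Fusion training sets are
assembled by sampling one trained replicate per modality and concatenating
penultimate-layer outputs, propagating single-model sampling variability
into the fusion stage.

Desk-scale defaults (`SearchSpace.desk`: ≤3 layers, ≤32 units, ≤16
filters, ≤100 epochs) shrink the full search ranges for simulated data;
the full ranges remain available via `SearchSpace.for_kind`.

## Evaluation

Pearson's r and RMSE are computed across environments and within each
environment having at least 3 test records (r for a zero-variance group is
recorded as missing with a warning). The MSE decomposes orthogonally as
(mean_p − mean_o)² + (sd_p − sd_o)² + 2·sd_p·sd_o·(1 − r), with the last
term set to 0 when either sd vanishes. The intercept-only baseline
(training mean predicted everywhere) is the RMSE floor any useful model
must beat. Replicate-aware many-to-one comparisons use Dunnett's max-T
procedure, one-sided (greater for r, less for RMSE), with adjusted
p-values by Monte-Carlo integration (4·10⁵ draws) of the multivariate-t
reference distribution under the classical equal-variance assumption; a
variance ratio above 4 across groups triggers a warning. With a single
comparison the procedure reduces to the two-sample t-test (verified within
MC tolerance 0.005). The grouping factor for comparisons is an explicit
argument, never guessed.

## Problem sizes used in the shipped checks

The automated checks run at desk scale by design: panels of ~80–130
inbreds, 150–200 SNPs, 150–500 hybrids, 3–8 site-years, Gibbs chains of
1,500–12,000 sweeps, and shrunk network search spaces. These sizes were
chosen so every check completes in seconds to a few minutes while keeping
each statistical contract (oracle equalities, calibration, recovery,
directional orderings) well-identified.

## Known limitations

- Independent loci by default; real LD structure is not emulated.
- The rank-1 G×E structure cannot represent crossover interactions of
  higher rank.
- Exact dense eigendecomposition bounds the feasible record count (~10⁴).
- The equal-variance Dunnett form relies on replicate seeds producing
  comparable group variances; a Welch-style variant is only warned about,
  not implemented.
- Network training is CPU-only and bitwise reproducibility across BLAS
  builds is not guaranteed.
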