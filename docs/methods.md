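# Methods

## Model and assumptions

The detector treats an expression profile from subtype `k` as an isotropic
Gaussian around a class template: `x ~ N(s_k, σ²I_N)` in the row-normalized
feature space. Under a linear projection `y = Φx` the class-conditional
density stays Gaussian, `y ~ N(Φs_k, σ²ΦΦᵀ)`, now on the M-dimensional
compressed space; its normalizer therefore uses the exponent `M/2`, which is
what makes the density integrate to one and keeps likelihoods comparable.
Classification follows ideal-observer decision theory: decide the class with
the largest expected utility `EU(l) = Σ_k U_{l|k} P_k p(y|k)`. With the
Kronecker-delta utility and equal priors this is exactly maximum likelihood
over the compressed Gaussians. All likelihood sums are computed in log space
with a common log-sum-exp shift; argmax ties break deterministically toward
the lowest class index.

The isotropic-Gaussian assumption is strong for real expression data
(features are correlated, noise is heteroscedastic and skewed); it is the
model hypothesis the whole pipeline is built on, and the synthetic generator
deliberately matches it so that recovery tests probe the matched-model
regime (see "What the generator does and does not emulate").

## Pipeline stages and the choices behind them

**Normalization.** Rows are min-max scaled to [0, 1]. Statistics are derived
from the training matrix only and stored with the model; test values outside
the training range are clipped. This avoids test-set leakage and lets a
fitted model score a single new sample. A `joint` mode (pooling train and
test before scaling) is provided for replicating workflows that normalized
both together. Constant training rows map to all-zeros — an uninformative
row is parked at the low end rather than mid-scale, and division by zero is
avoided.

**Feature scoring.** The five per-feature characteristics use sample
(`ddof=1`) standard deviations throughout, and the multi-class "correlation
with the class label" is defined as the mean and std, over classes, of the
absolute Pearson correlation between the feature and each one-vs-rest 0/1
indicator. This reduces to the familiar two-class construction, is symmetric
under class relabeling, and absolute values keep all components non-negative
before max-scaling. Correlations with a vanishing denominator (constant
feature) are defined as 0, so constant features profile to exactly
(0,0,0,0,0) and are never selected.

**Selection.** Rather than five coupled thresholds (one per characteristic,
with no principled way to set them jointly), selection uses a single
rank-sum composite: ascending ranks for the dispersion-type characteristics
(MeanStd, StdStd, StdCorr), descending for the separation-type ones
(StdMean, MeanCorr), ties averaged, final ties broken by feature position.
One interpretable knob (`M`), deterministic ordering, nested selections
(top-M is a prefix of top-(M+1)), and invariance to any positive rescaling
of a characteristic. A caveat observed in simulation: in designs where some
characteristics carry no class signal (e.g. StdStd/StdCorr in a two-class
problem), their ranks contribute pure noise and weakly discriminative
planted features can be displaced from the very top of the list; the
downstream classifier is insensitive to this because the displaced features
are replaced by similarly scored ones.

**Compress matrix.** `Φ` is learned on the full normalized training matrix
`S` with the selected rows as targets, one basis-pursuit problem per row.
The default solver is the exact LP formulation (positive/negative split,
HiGHS): deterministic, bit-stable, and tested against a brute-force vertex
enumeration oracle. The homotopy/LARS path (`solver="lars"`) is the fast
alternative used in the larger simulation experiments — roughly an order of
magnitude faster at N in the thousands; rare path degeneracies fall back to
the LP row-wise, and every accepted row must meet the same constraint
residual tolerance (`tol`, default 1e-6, on the l2 residual of `Sᵀφ = y`).
Because targets are rows of `S`, the unit selector row is always feasible
and learned rows satisfy `‖φ‖₁ ≤ 1 + tol`; solver reports (residual, l1
norm, iterations) are retained on the model for audit. Non-uniqueness of the
minimizer (possible when features are duplicated) is not actively detected;
determinism comes from the fixed solver configuration.

**Noise scale.** `σ` is not specified by the model alone, so the default
estimate is the pooled within-class sample standard deviation over the
selected features (one shared σ, matching the single-σ density); a
per-class mode is available. The estimate is floored at 1e-8 so that
degenerate noise-free training data yield a well-defined (sharply peaked)
density rather than a division by zero.

**Utility matrix.** Three estimators:

* `identity` (default) — the Kronecker delta; the ideal-detector utility,
  reducing the decision rule to maximum likelihood.
* `pairwise_br` — off-diagonal `U_{i|j} = 1 − BR(i,j)`, the two-class Bayes
  risk between the compressed class Gaussians evaluated in closed form along
  their Fisher discriminant direction (equal pair priors, midpoint
  boundary); coincident means give BR = 1/2.
* `mc_multiclass` — a seeded Monte-Carlo estimate of the decision
  probabilities `P(decide i | truth j)` under maximum-likelihood labeling of
  draws from each class (diagonal = 1 − class-conditional error). For
  well-separated classes this approaches the identity, which is the ideal
  detector's `δ_ij` characterization.

The default is the identity because a Bayes-risk-derived utility requires
the very densities the classifier is estimating; the alternatives are
provided for sensitivity analysis.

## Numerical details

* The compressed covariance `σ²ΦΦᵀ` is factored by Cholesky; no explicit
  inverse is ever formed. A relative ridge (`1e-10 · trace/M`) is added
  **only** when the eigenvalue ratio exceeds 1e12 (e.g. duplicated compress
  rows), so well-conditioned covariances are factored exactly; a covariance
  still beyond 1e12 after conditioning raises `SingularCovarianceError`.
* The two-class Bayes-risk quadrature integrates each tail over a geometric
  ladder of finite segments plus a far-field remainder; a single adaptive
  pass over a semi-infinite interval can miss a narrow mode far from the
  decision boundary. A Gaussian closed form is exposed alongside.
* The compressed dimension must satisfy `M ≤ c` for the compressed detector
  (each row of `Φ` solves a c-equation system); violating this raises a
  clear error. The `noncompressed` detector (the baseline without the
  learned projection: `Φ` is the plain selector of the chosen features,
  covariance `σ²I`) has no such constraint and can also run on all features.
* Entries of `Φ` below 1e-12 in magnitude are truncated to exact zeros for
  sparsity; models serialize to plain-text artifacts (JSON + TSV triplets)
  with `repr`-faithful floats so equal fits are byte-identical.

## The synthetic generator

`SyntheticConfig` defaults describe the emulated study: 4 subtypes, two
feature blocks of 150 and 2000 features (a small-RNA-sized and an
mRNA-array-sized block), 15 training and 14 testing samples per class, 10
planted discriminative features per class per block, effect size 4 in units
of the noise σ (default 0.1, around a baseline of 0.5 so raw values sit
roughly in [0, 1]). Planted sets are disjoint across classes within a block;
`block_signal_map` restricts which classes are separable in which block,
which is how the block-complementarity experiment (classes 1–2 separable
only in block A, classes 3–4 only in block B) is constructed. Noise is
Gaussian to match the classifier's model hypothesis; a mean-matched
log-normal mode provides a misspecification stress test.

What the generator does **not** emulate: correlation between features
(miRNA–mRNA regulatory structure), heteroscedastic platform noise, batch
effects, unbalanced class frequencies in training. Passing recovery tests
therefore demonstrates correctness of the pipeline under its own model
assumptions — not expected accuracy on real tumor data.

The simulation experiments (`mcsd.experiments`) use 20 independently seeded
replicates per condition and `M = 40` (the total number of planted features
per block set), with the homotopy solver; at these problem sizes
(N = 2150, c = 60) the full battery runs in well under a minute.

## Known limitations

* With `M` close to `c` the LP systems are still underdetermined but the
  compression is weak; the method's benefit shows when `N ≫ M`.
* The l1-minimal row frequently coincides with the unit selector when
  features are weakly correlated, in which case compression reduces to
  feature restriction; correlated features are what make `Φ` mix.
* `stability_experiment` refits the full pipeline per split; with the LP
  solver on large N this is the slowest path (use `solver="lars"`).
* Accuracy is the only built-in evaluation metric, mirroring the method's
  original evaluation; confusion-sensitive metrics can be derived from the
  prediction table.
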