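# mcsd — multi-class compressed-sensing detector for expression subtyping

`mcsd` classifies disease subtypes from one or more expression data types
(for example miRNA and mRNA expression measured on the same patients). Many
subtypes look alike in a single data type; stacking ("cascading") the
per-sample profiles of several data types into one tall vector and learning a
sparse compressive projection of it often separates them. The package is
aimed at computational biologists who want a small, fully reproducible
implementation of this pipeline, with a synthetic multi-omics generator so
every stage can be exercised without any external download.

## The method

Let `S ∈ R^{N×c}` be the cascaded, row-normalized training matrix (N
features, c samples, n subtypes).

1. **Feature scoring.** Every feature gets a five-component profile
   `V_i = (MeanStd, StdStd, StdMean, MeanCorr, StdCorr)`: the mean/std over
   classes of the within-class standard deviation, the std over classes of
   the class means, and the mean/std over classes of |Pearson r| between the
   feature and a one-vs-rest class indicator. Each component is scaled by its
   maximum into [0, 1]. Informative features have low MeanStd, StdStd,
   StdCorr and high StdMean, MeanCorr; the `M` best by a rank-sum composite
   are selected.
2. **Compress matrix.** With `Y ∈ R^{M×c}` the selected rows of `S`, the
   sparse compress matrix `Φ ∈ R^{M×N}` solves, row by row, the basis-pursuit
   problem

   ```
   (Φᵀ)_j = argmin ‖(Φᵀ)_j‖₁   subject to   Sᵀ(Φᵀ)_j = (Yᵀ)_j ,
   ```

   an underdetermined linear system solved exactly as a linear program
   (HiGHS) or by the homotopy/least-angle path. Because each target row is a
   row of `S`, the unit selector vector is always feasible, so every row of
   `Φ` has l1 norm ≤ 1.
3. **Ideal-observer classification.** Profiles are modelled as isotropic
   Gaussians `N(s_k, σ²I_N)` around the class mean; a compressed observation
   `y = Φx` is then `N(Φs_k, σ²ΦΦᵀ)`. A test sample is assigned to the class
   `l` maximizing the expected utility
   `EU(l) = Σ_k U_{l|k} P_k p(y | class k)`, where `U_{i|j}` is the utility
   of deciding `i` when the truth is `j` (Kronecker delta by default, which
   reduces the rule to maximum likelihood; Bayes-risk-derived and Monte-Carlo
   utilities are available) and `P_k` are class priors.

## Worked example

Simulate a balanced four-subtype, two-block dataset (blocks of 150 and 2000
features, 15 training and 14 testing samples per class, 10 planted
discriminative features per class per block, 4σ effect), train with 40
informative features, and classify the held-out samples:

```
$ mcsd simulate --config sim.yaml --out demo/data
dataset written to demo/data

$ mcsd train --blocks demo/data/train_block0.tsv --blocks demo/data/train_block1.tsv \
    --labels demo/data/train_labels.tsv --m 40 --solver lars --seed 7 --out demo/model
INFO mcsd: selected 40 features; sigma=[0.159926, ...]; phi row l1 norms max 1.000000
model written to demo/model

$ mcsd predict --model demo/model --blocks demo/data/test_block0.tsv \
    --blocks demo/data/test_block1.tsv --labels demo/data/test_labels.tsv --out demo/pred.tsv
predictions written to demo/pred.tsv
accuracy 100.0% (56/56)
```

All 56 test samples are labeled correctly: at a 4σ planted effect the four
classes are essentially separated in the compressed space, and `σ ≈ 0.16` is
the pooled within-class spread of the normalized selected features. The
predictions TSV lists, per sample, the winning subtype and the per-class
expected utilities (posterior probabilities under the identity utility).
`mcsd sweep --m-grid 10:200:10 ...` traces accuracy as a function of the
number of informative features.

The same pipeline is available as a library (`mcsd.fit`, `mcsd.predict`,
`mcsd.stability_experiment`, ...); see `docs/methods.md` for the model
details and design choices.

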