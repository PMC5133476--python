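# Methods

## Model and procedure

r2VIM selects variants associated with a continuous trait by combining
three ingredients: permutation importance from regression forests, an
empirical estimate of the null importance scale, and recurrency across
independently seeded runs.

A regression forest of `ntree` CART trees is grown on bootstrap samples of
the `n × p` predictor matrix (variant dosages 0/1/2 plus covariate
columns), with `mtry` candidate variables per split and a minimum leaf size
of `min_node_size`. For each tree the samples not drawn into its bootstrap
(out-of-bag, OOB) give an unbiased test set. The raw importance of variable
*j* is the per-tree percent change in OOB MSE after permuting column *j*
among that tree's OOB samples, averaged over all trees in the forest
(trees that never split on *j* contribute exactly 0, since permuting an
unused column cannot change the tree's predictions — the implementation
skips them, which is an exact optimisation, not an approximation).

Under the global null the VIMs scatter symmetrically around zero and the
lowest VIM is in practice negative; its absolute value estimates the null
importance scale. Dividing a run's VIMs by this estimate gives relative
importance scores (RIS) with minimum exactly −1 whenever the lowest VIM is
negative, comparable across runs; multiplying the estimate by integer
factors — equivalently thresholding RIS at 1, 2, 3, … — gives stricter
cutoffs. The forest is run `n_runs` times (5–10 conventionally) with seeds
`base_seed + 0 … n_runs − 1`, and per-variable RIS values are combined by
the minimum over runs. Selection keeps variants with `min.RIS` strictly
greater than the threshold; selections are therefore nested across
increasing thresholds, and `min.RIS` can only decrease as runs are added.

Covariates enter the forest as ordinary predictors and take part in the
per-run normalisation (their VIMs count toward `min VIM`) but are never
reported as selected variants. A covariate with missing values cannot enter
the forest at all (CART as used here does not handle missingness) and is
dropped from the forest inputs with a warning; the regression baseline
still uses it through per-variant complete-case analysis. This asymmetry —
typically affecting age — is deliberate: it reflects how the two methods
differ on real data.

The baseline is single-variant OLS, `y ~ dosage + covariates`, with the
two-sided t-test on the dosage coefficient. It is computed by residualising
the outcome and all dosage columns against the covariate block once (QR
projection; Frisch–Waugh–Lovell), which is algebraically identical to
fitting each full model and lets the scan run as one vectorised pass.
A dosage that is constant or collinear with the covariates gets an explicit
NaN marker rather than being dropped. Selection is Bonferroni
(`p < α / m`, `m` = variants with a defined p-value) or a fixed absolute
cutoff; the fixed mode exists because published analyses often quote a
round genome-wide constant (e.g. 5 × 10⁻⁷) rather than the exact `α/m`.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `ntree` | 500 | trees per forest; importance noise shrinks with more trees. Desk-scale default; exome-scale analyses use thousands. |
| `mtry` | `round(p/6)` | candidate variables per split; the ratio ≈ 1/6 follows the regime used for exome-scale runs of the method (60,000 of ~353k variables). Any explicit value in [1, p] is accepted. |
| `min_node_size` | 5 | minimum samples per leaf, the regression-forest convention. |
| `n_runs` | 5 | recurrency runs; values outside 5–10 warn but run. |
| thresholds | 0, 0.5, 1 | `min.RIS` cutoffs reported by the evaluation harness; factor thresholds > 1 are available via `factor_thresholds`. |
| `max_missing` | 0.05 | sample-level missingness cutoff (strict `>` drops). |
| PCs | 10 | principal components of the standardised dosage matrix used as stratification covariates. |

Seeding: run *r* uses seed `base_seed + r`; within a run, the permutation
for (tree *t*, variable *j*) comes from an independent stream keyed by
(seed, *t*, *j*), so importances are bit-reproducible and independent of
evaluation order and thread count.

## Degenerate cases and numerical choices

- A run whose lowest VIM is exactly 0 has no usable null estimate and is an
  error. A run with *no* negative VIM contradicts the symmetric-null
  assumption; `null_variance_estimate` returns the smallest positive VIM
  with a warning, while `run_r2vim` treats such a run as an error naming
  the offending seed unless `allow_positive_null=True`.
- A tree with zero OOB MSE (perfect OOB fit) has no defined percent change
  and contributes 0; a variable constant in a tree's OOB set is a
  permutation no-op and likewise contributes 0.
- Parameter tuning picks the grid element with the lowest forest OOB MSE,
  breaking exact ties toward smaller `ntree`, then smaller `mtry`.
- "Singleton" means minor-allele count exactly 1 across all samples
  (whichever allele is minor). Sample filters run before variant filters;
  PCA runs on the post-QC matrix with no LD pruning.
- PCA signs are fixed by making each component's largest-magnitude loading
  positive, so PC covariates are reproducible across runs.
- Threshold comparisons are strict (`min.RIS > t`, `p < cutoff`).

## Synthetic data: what it emulates and what it does not

The generator produces an exome-like dataset: independent binomial dosages
at MAFs drawn uniformly from a configurable range, variants partitioned
into contiguous gene blocks (default 5 variants per gene), a designated
functional subset with additive effects of configurable size, binary
covariates (sex, medication, smoking), a continuous age with ~1%
missingness, and Gaussian residual noise around an SBP-like intercept of
120. A permuted copy of the outcome serves as the negative control: it
keeps the trait's marginal distribution while destroying every
genotype–phenotype association. Truth annotation classifies each variant
as functional, functional-gene (same gene as a functional variant), or
neither, which the evaluation tables carry through.

The generating model is additive main effects only — interactions,
dominance, LD with ungenotyped causal sites, pedigree structure and
sequencing artefacts are not simulated (an optional Gaussian-copula mode
induces within-gene dosage correlation for studying how LD blurs the
true/false-positive distinction, but is off by default). Consequently,
passing tests show that the implementation ranks, normalises, and
thresholds correctly and that recurrency suppresses stochastic false
positives under realistic main-effect architectures; they do not show that
the method detects epistatic signals or survives confounding beyond what
10 PCs capture.

One point worth noting from the null analysis: because the permuted
phenotype is *fixed* across the recurrency runs, a variant that spuriously
correlates with it in-sample scores high in every run, so a handful of
false positives can survive recurrency. That is a property of the design
(and visible in real permuted-trait analyses), not an implementation
artefact; recurrency removes the run-to-run stochastic exceedances, which
is what the paired null simulations measure.

## Problem sizes used in the automated checks

The test suite runs the full method at n = 500 samples with p = 200–500
variants, 300-tree forests and 5 recurrency runs (50 replicates for the
power check, 20 paired replicates for the null check), and smaller
configurations elsewhere; these sizes give stable pass/fail behaviour on a
single CPU while preserving every property being tested. The exact
per-tree importance computation is additionally verified against a
brute-force reimplementation on a 30 × 5, 10-tree forest to 1e-10 relative
tolerance.

## Known limitations

- No missing-data handling inside the forest; inputs must be filtered or
  (externally) imputed first.
- Quantitative traits only; no classification forests, conditional
  importance variants, or mixed-model kinship adjustment.
- The choice of the final `min.RIS` threshold remains data-dependent;
  calibrating it against a permuted-phenotype null distribution is exposed
  via `null_analysis` but no automatic threshold selection is built in.
- Forests are fitted single-threaded; at biobank scale the method is
  embarrassingly parallel over trees and runs, which this implementation
  does not exploit.
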