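# Methods

## Model

`grexfine` fine-maps binary traits over the gene-tissue pairs of one genomic
region at a time. The observed case/control label is the sign of a latent
Gaussian liability,

    y_i = 1{z_i > 0},
    z_i = mu + Ghat_i' beta + X_i' alpha + C_i' xi + eps_i,   eps_i ~ N(0, 1),

with a unit residual variance fixed by the probit link. The design has four
blocks:

* **Ghat** (n × p): predicted GReX for every gene-tissue pair in the region,
  built as weighted dosage sums from per-pair SNP weight tables and then
  column-standardized. Zero-variance columns (e.g. pairs whose weights are
  all zero) are zeroed, flagged, and excluded from effect selection.
* **X** (n × s): all region SNPs, standardized, carrying horizontal
  pleiotropy — direct SNP effects not mediated by the modeled expression —
  under a ridge prior `alpha ~ N(0, sigma2_alpha I)`,
  `sigma2_alpha ~ IG(1, 1)`. The ridge absorbs polygenic background so the
  sparse selection machinery stays focused on the gene-tissue pairs.
* **C** (n × c): covariates, and the intercept `mu`, both under flat
  (improper) priors — equivalent to fixed effects.
* **beta**: a sum of L single effects, `beta = sum_l beta_l gamma_l`, each
  `gamma_l` selecting exactly one pair. L defaults to 10. The selection
  prior is hierarchical: first a gene, then a tissue within the gene,
  `pi_j = pi_g(j) * pi_t(j)|g(j)`, with `Dirichlet(1, ..., 1)` priors on the
  gene vector and on each per-gene tissue vector. This is what yields
  gene-level evidence separate from pair-level evidence.

## Inference

Mean-field coordinate-ascent variational Bayes over
`q(z) q(mu) q(alpha) q(xi) prod_l q(beta_l) q(gamma_l) q(pi_G) prod_g q(pi_T|g)`.
One sweep updates, in order: liabilities, each single effect l = 1..L,
pleiotropy, covariates/intercept, the Dirichlet posteriors, then the
hyperparameters. Each update is the exact conjugate optimum:

* `q(z_i)` is N(m_i, 1) truncated to the side dictated by y_i; moments use
  log-space Mills ratios (`scipy.special.log_ndtr`) and remain stable for
  |m_i| well past 40.
* Each single effect is a Gaussian single-effect regression of the current
  residual on every column with prior `N(0, sigma2_beta)`; selection
  probabilities combine the per-column log Bayes factor with the digamma
  expectation `E_q[log pi_j]` of the hierarchical prior (a `log E_q[pi_j]`
  variant is available as a sensitivity flag) and are normalized by
  log-sum-exp.
* `q(alpha)` has covariance `(X'X + I/sigma2_alpha)^-1`, computed through a
  cached eigendecomposition of X'X (identical to the direct solve to machine
  precision; the decomposition is reused as `sigma2_alpha` changes).
* The Dirichlet posteriors are conjugate pseudo-count updates,
  `delta_g = 1 + sum_l sum_{j in gene g} pi_lj` and analogously per tissue
  within gene.
* Empirical Bayes: `sigma2_beta` (shared across the L effects, the default)
  is refreshed each sweep at its ELBO-maximizing value, the mean posterior
  second moment of the L scalar effects, floored at 1e-8. `sigma2_alpha`
  maximizes its ELBO terms including the IG(1, 1) log-prior, giving
  `(1 + E[alpha'alpha]/2) / (s/2 + 2)` — the conjugate-posterior mode. The
  mode rather than the mean is used so the update is a true ascent step;
  the difference is O(1/s).

The reported ELBO accounts for the truncated-normal entropy against the
variational mean in force when the liabilities were last updated, all
Gaussian and Dirichlet KL terms, and the IG log-prior of `sigma2_alpha`
evaluated at its point estimate. Every update is an exact coordinate-ascent
step with respect to this objective, so the ELBO is non-decreasing across
sweeps; the test suite asserts this on every fit (50 seeded fixtures plus
all simulation fits). Convergence is declared at a relative ELBO change
below 1e-4 (default), with a 300-sweep cap; non-convergence returns a result
flagged `converged=False` rather than an error.

### Per-effect prior-variance variant

`FitConfig(sigma2_beta_mode="per_effect")` estimates one prior variance per
effect from its own posterior second moment, letting effects that carry no
signal shrink toward zero; fully collapsed effects revert to the prior
selection distribution and are excluded from PIPs and Dirichlet counts. The
shared mode is the default because it matches the single-`sigma2_beta`
parameterization of the model; the per-effect mode is useful when L greatly
exceeds the plausible number of signals in very small regions, where a
shared variance can shrink so far that the effects become near-identical
weak copies of one signal (see Limitations).

## Scoring

Pair PIP_j = 1 − prod_l (1 − pi_lj). Gene PIPs are the posterior mean of the
gene-selection Dirichlet, `delta_m / sum(delta)`; by construction they are
normalized selection probabilities over the region's genes and sum to 1 —
a different quantity from a per-gene non-zero-effect probability, and the
form used for gene-level ranking. For statistics that exist only at the pair
level, the independence combination `1 − prod_tissues (1 − PIP)` is provided
separately.

Significance: local FDR = 1 − PIP; sort ascending; the estimated FDR at rank
r is the mean of the first r local FDRs; everything up to the largest rank
with estimated FDR ≤ the target (default 0.05) is called. Ties are broken by
stable original-index order, which can only affect boundary calls. The
evaluation harness applies this rule pooled across a replicate group
(genome-wide pooling semantics); a per-region variant is what `fit` emits in
its result tables.

## Synthetic study generator

The generator reproduces a multi-tissue eQTL + case-control GWAS design on
synthetic genotypes:

* **Genotypes.** Biallelic dosages from two latent-Gaussian haplotypes with
  AR(1) within-block correlation `ld_rho^|j−j'|` (default rho = 0.9,
  mimicking strong local LD), thresholded at per-SNP MAFs drawn
  Uniform(0.05, 0.5). Blocks are independent; GWAS and eQTL panels are
  disjoint draws sharing MAFs and LD. Defaults: 50 blocks × 16 genes ×
  10 cis-SNPs (16 is the mean block size of the design being emulated;
  10 is its per-gene cis-SNP retention threshold), GWAS n = 50,000, eQTL
  n = 500.
* **Expression.** Half of all gene-tissue pairs (exactly) are cis-heritable.
  A heritable pair has 5 causal cis-SNPs — 3 shared across the gene's
  heritable tissues, 2 tissue-specific — each explaining an equal share of
  the cis-heritability PVE1 (default 10%); the genetic component is rescaled
  empirically so its variance is exactly PVE1, residual N(0, 1 − PVE1).
  Non-heritable pairs are pure N(0, 1) noise. A random 3–7 causal-SNP count
  is available as a flag.
* **Trait.** Deliberately a *logistic* model while the fitted model is
  probit — the generator preserves this link misspecification as a stress
  test. For each tissue k with weight w_k > 0, ng causal pairs (default 10)
  are drawn from its heritable pairs; the liability is
  `eta = u + sum_k sum_pairs sqrt(w_k * PVE2) * g_std + eps`,
  `eps ~ N(0, 1 − ng*PVE2)`, with `g_std` the standardized true (noiseless)
  genetic expression component in the GWAS panel and
  `v = sqrt(PVE2/PVE1)` the implied effect on the unstandardized component.
  Tissue weights act on the variance scale: each causal pair contributes
  `w_k * PVE2` of liability variance and the total genetic variance is
  `ng * PVE2` for any weight vector summing to 1 — the only bookkeeping
  consistent with the residual-variance formula, with a fixed total effect
  across causal-tissue settings, and with per-pair effects that shrink as
  causal tissues are added. The intercept u equals the expected
  log(case:control) ratio (u = 0 gives balanced data).
* **Pleiotropy mode.** Optionally, i.i.d. Gaussian effects over all block
  SNPs are added and scaled so SNP-mediated variance is 6% against a total
  genetic budget of 10% (4% through GReX), with residual variance reduced
  accordingly.
* **Weights.** Prediction weights come from a Gaussian sum-of-single-effects
  regression per pair on the eQTL panel (L = 5, matching the causal-SNP
  count; posterior-mean weights `sum_l alpha_l ⊙ mu_l`). Prior variances are
  per-effect, evidence-optimized, and collapse to zero unless the optimum
  beats the null by 0.5 nats — so non-heritable pairs get exactly-zero
  weight vectors, as a real pipeline's heritability screen would produce.

With a fixed seed the entire emitted study is byte-identical across runs.

### What the generator does not emulate

Real LD is block-diagonal only approximately and far more heterogeneous than
an AR(1) latent scheme; MAF spectra are skewed rather than uniform; gene
cis-windows overlap and genes per block vary; expression residuals are
non-Gaussian and correlated across tissues; there is no population structure
or relatedness. Passing tests on these data demonstrate the correctness and
calibration behavior of the machinery under the stated generative model, not
performance on real cohorts.

## Evaluation harness

Replicates are split into contiguous groups (default 5); statistics are
pooled within a group before thresholding; group means are reported.

* **True-FDR power**: scan every distinct statistic value as a cutoff, take
  the largest set with realized FDR ≤ the level, report TP / (all causal).
* **Estimated-FDR power**: apply the cumulative local-FDR rule per pooled
  group and report both power and the realized FDR of the call set (the
  calibration diagnostic).
* **Null false signals**: mean estimated-FDR-significant count per replicate
  under PVE2 = 0.

## Problem sizes used by the acceptance runs

`scripts/acceptance.py` and the acceptance tests run the baseline design at
GWAS n = 10,000 (null suite n = 5,000) with 10 LD blocks of 16 genes ×
3 tissues, eQTL n = 500, and 20 replicates in 5 groups — a deliberate
desk-scale choice of problem size. At this scale a causal pair's marginal
association is z ≈ 1.8 (per-pair liability variance 0.002, logistic-link
attenuation, prediction r ≈ 0.87), so absolute power at a true FDR of 0.05
is a few percent; a marginal-association oracle attains the same power on
identical data, i.e. the fitted model sits at the information ceiling of the
generated data. Calibration diagnostics (null false-signal counts, realized
FDR of estimated-FDR calls) are scale-stable and are the primary acceptance
checks; absolute power figures are not comparable across sample sizes.

## Numerical choices and degenerate inputs

* Standardization uses the population (divide-by-n) standard deviation;
  constant columns are zeroed and flagged, never an error.
* Missing dosages are mean-imputed before standardization; an all-missing
  SNP is an error.
* All-case or all-control phenotypes, p = 0 regions, singular covariate
  designs, and zero-variance expression are errors with actionable messages.
* s = 0 (no genotypes) and c = 0 (no covariates) are supported no-ops.
* Selection ties (e.g. duplicated GReX columns) are resolved by the softmax
  itself: indistinguishable predictors share probability rather than one
  being chosen arbitrarily.
* The intercept is initialized at the probit-transformed case fraction
  clipped to [−5, 5]; selection rows start uniform; effects start at zero.
* Per-replicate seeds derive deterministically from the base seed and stay
  below 2^31.

## Known limitations

* Individual-level data only; no summary-statistics mode (the probit
  augmentation requires per-individual liabilities).
* No credible sets; evidence is reported as PIPs and local FDRs.
* With L much larger than the number of true signals in a *very small*
  region (roughly p ≲ 15 candidate pairs), the shared empirical-Bayes
  `sigma2_beta` can shrink until the L effects become near-identical weak
  copies whose selection probabilities compound into inflated PIPs. At the
  region sizes the model is intended for (tens of pairs per region) the
  effect is negligible, and the `per_effect` mode provides a safeguard; for
  tiny custom regions, reduce L or use `sigma2_beta_mode="per_effect"`.
* Gene-level PIPs are region-normalized selection probabilities: they rank
  genes within and across regions but are not directly interpretable as
  per-gene posterior probabilities of non-zero effect, and their absolute
  scale depends on the number of genes in the region.
* The weight-panel / genotype-panel SNP harmonization (strand, alleles) is
  assumed done upstream; unresolvable SNPs are dropped with warnings.
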