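# Methods

## The problem

Some DNA methylation marks behave like alleles: they sit at one of a few
discrete levels in each person and are transmitted from parent to child.
In families ascertained for multiple cancer cases, such heritable marks
are candidate disease factors even when no causal DNA variant is known.
`mendelscan` implements a family-based screen for such marks from
methylation-array data: it asks, probe by probe, whether the pattern of
M-values across family members looks like the segregation of a rare
autosomal variant, and then tests the inferred carrier status for
association with disease.

## Models

For one CpG site let x₁…x_n be the M-values of the n typed individuals
(M = log2 β/(1−β); the logit scale makes within-group noise approximately
Gaussian). Three nested-or-parallel models are fitted:

* **Gaussian** — x_i ~ N(μ, σ²), iid. Closed-form MLE.
* **Independent mixture** — latent group labels y_i ∈ {0, 1} iid with
  P(y_i = 1) = α₁ fixed at 0.01, and x_i | y_i ~ N(μ_{y_i}, σ²_{y_i}).
  Fitted by the standard EM with fixed weights; only μ₀, μ₁, σ₀, σ₁ are
  estimated.
* **Pedigree-coupled ("Mendelian") mixture** — the same observation model,
  but y is the carrier-indicator vector of a rare autosomal variant
  segregating in the pedigrees: within a family the y_i are dependent,
  across families independent.

The screening statistic is Δl = l_Mendel − l_mix, the difference of the
maximised log-likelihoods. Both models estimate the same four free
parameters, so Δl is also half the AIC difference with the usual
AIC = 2k − 2l convention (and the BIC difference behaves identically);
either way the *ranking* of sites is the same, which is all the screen
uses. Large Δl means the site's bimodality clusters within families the
way Mendelian transmission would make it, over and above how bimodal the
site is marginally.

Two properties of Δl are worth keeping in mind when reading results:

* On families with several founders, the no-carrier configuration is
  cheaper under the segregation prior than under the iid Bernoulli prior,
  so unimodal (Gaussian) sites tend to have small *positive* Δl (≈ +1 to
  +5 at this cohort size) rather than 0. Truly Mendelian sites score far
  above this background; iid-mixture sites score strongly negative.
* Δl is a screening index, not a calibrated test statistic; no p-value is
  attached to it.

## Segregation model

The carrier prior assumes: (i) at most one founder per family introduces
the variant, and never as a homozygote — reasonable for a rare variant and
the assumption that keeps the state space linear in family size; (ii) a
heterozygous parent transmits to each child independently with probability
1/2; (iii) a child of two non-carriers is a non-carrier (no de novo
events). Founder configurations are weighted by the truncated binomial
{(1−α₁)^F, α₁(1−α₁)^(F−1)·F} renormalised, which keeps the founder
marginal ≈ α₁ for small α₁. Every parentless member counts as a founder,
including marry-in spouses.

Joint probabilities over any member subset are computed exactly by a
single downward pass over each founder's descent tree, marginalising
untracked members on the fly; cost is O(2^k) in the number k of *tracked*
members only. A deliberately naive full-enumeration implementation
(`brute_force_prior`, O(2^n)) is kept as an independent oracle and the two
are asserted equal to 1e−12 in the tests.

Consanguineous matings (both parents descending from the same founder) are
rejected rather than approximated: under the single-origin assumption such
a child could be homozygous, which the model excludes. The per-family
prior table over typed-member carrier vectors depends only on pedigree
structure and α₁ — not on the M-values or the Gaussian parameters — so it
is computed once and reused across all probes and EM iterations.

## The generalised EM

The E-step computes, family by family, the exact posterior over all 2^k
typed carrier vectors, P(y^f | x^f, θ) ∝ [∏ φ(x_i | μ_{y_i}, σ_{y_i})] ·
P(y^f), and the per-person carrier probabilities q_{i1} by marginalisation.
The M-step is the usual responsibility-weighted Gaussian update with the
group weights held fixed. The observed log-likelihood is non-decreasing
(checked to 1e−9/iteration in the tests).

Numerical choices:

* Initialisation: deterministic 1-D 2-means split of the site's values;
  both carrier orientations (rare group = upper or lower mode) are run and
  the higher-likelihood fit kept, exact ties going to "upper". The
  Mendelian fit is seeded with the mixture MLE (both orientations), which
  makes the two models coincide exactly on all-singleton cohorts.
* Convergence: relative log-likelihood change < 1e−8, max 500 iterations;
  non-convergence returns the best-so-far fit flagged `converged_=False`.
* Variance floor σ_min = 1e−3 M-units prevents singular likelihoods; a
  component whose total responsibility vanishes keeps its previous
  parameters (with a warning) instead of collapsing.
* All per-vector sums are done in log space; exact zero priors are kept as
  −∞ and drop out of the log-sum-exp.
* Probes with fewer than 4 distinct values are skipped with a recorded
  reason rather than fitted.

## Carrier probabilities

After fitting, each individual's posterior carrier probability is computed
at the plug-in MLE θ̂, with the site's Gaussian densities acting as the
penetrance function — no phenotype data enters. Typed members get the
E-step quantity directly. Untyped members (included by default, since the
association stage uses relatives' phenotypes) are handled by extending the
family's configuration sum with that one member and marginalising the
rest; a member of a family with no methylation data at all falls back to
the structural prior marginal. Posterior uncertainty in θ̂ is not
propagated.

## Association testing

Carrier probabilities for the top-k sites are tested against disease with
a Cox proportional-hazards model on the age time scale (event age for
affected, censoring age otherwise; no left truncation), covariate = q₁,
risk set = females by default (the transmission model still uses males).
Because the families are ascertained for multiple cases, hazard-ratio
estimates are biased and are flagged as such; inference is by the
likelihood-ratio test against the null model, whose p-values remain valid
under the null. Ties: Efron's approximation via lifelines by default; a
Breslow partial likelihood (internal one-covariate optimiser) is available
and doubles as an independent cross-check — with continuous ages the two
agree to ~1e−6. Significance uses a Bonferroni threshold of
family-wise α / k with k = the number of *tested* probes (0.05/1000 =
5×10⁻⁵ at the default screen size). Family-stratified partial likelihood
is available but off by default.

A caveat the simulations quantify: with family-constant covariates *and*
multiplex ascertainment the LRT is mildly conservative at 25 families
(empirical type-I error ≈ 0.033–0.034 at nominal 0.05 in 1000-replicate
null runs; the same code gives 0.052 for an iid covariate). Conditioning
every family on having ≥2 events equalises the between-family event
counts and so shrinks the true score variance relative to the model-based
information. Conservative means the p-values are still safe to report.

## SNP-proximity validation

Probes whose 50-mer target overlaps a common SNP behave like genotypes —
an artefact that makes them genuinely "Mendelian". The screen is therefore
validated by testing whether the fraction of probes within 10 bp of a
known SNP increases with Δl: logistic regression of the near-SNP indicator
on an orthogonalised polynomial in Δl (degree 3 by default; the basis is
the QR factor of the centred Vandermonde matrix), LRT against the
intercept-only model on `degree` degrees of freedom, plus decile-binned
proportions with Wilson 95% CIs for plotting.

## Probe filtering

Before screening: drop probes with SNP distance ≤ 10 bp (inclusive — "within
10 bp"), probes on X/Y, and probes failing detection. Detection filtering
excludes a probe when its detection p-value *exceeds* 0.05, with the
per-sample aggregation policy configurable (any-sample default; mean and
fraction>f also available) because array pipelines differ on this point.
Missing matrix values are an error — the EM weights assume complete data —
so imputation is deliberately not offered.

## Synthetic cohorts

The generator emulates the study design the screen targets:

* **Pedigrees** — 25 families, 3 generations, founder couple plus
  Poisson(2.5) offspring (clipped to 1–4), marry-in spouses with
  probability 0.7, ≥4 females per family (multiplex breast-cancer families
  are female-rich by construction), ~80% of members typed, capped at 12
  typed per family. This yields ≈ 210–250 typed members per cohort.
* **Variants** — dropped from the truncated-binomial founder prior with
  Mendelian transmission. The generative carrier frequency for simulated
  heritable sites is 0.20 — detected heritable marks segregate in a
  substantial fraction of families (often 10–50%), well above the rare
  screening prior α₁ = 0.01 that the fitted models keep. The analysis
  being robust to this mismatch is itself part of what the tests check.
* **Sites** — `mendelian` (x_i ~ N(μ_{y_i}, σ²) with pedigree-dropped y),
  `mixture` (iid labels, same marginal frequency), `gaussian` (one
  component). Default modes μ₀ = −3, μ₁ = 0 (β ≈ 0.11 vs 0.50, the
  hypo/hemi-methylated pair) with σ = 0.3 — a 10σ separation, as observed
  for array sites with Δβ > 0.3.
* **Phenotypes** — female ages at onset from a Weibull baseline (shape
  4.5, scale 120 ⇒ ~16% cumulative risk by 80, deliberately high to make
  multiplex ascertainment reachable) times a carrier hazard ratio (default
  3); censoring ages uniform on [40, 80]; families are ascertained for ≥2
  affected females by redrawing phenotypes (budget 1000/family) or
  discarding, with the policy recorded in the manifest because rejection
  sampling is exactly what biases the hazard ratios.
* Four independent random streams (structure, variant, methylation noise,
  phenotypes) so one component can vary with the others fixed; identical
  config + seed reproduces outputs byte-for-byte.

What the generator does *not* emulate: array technical noise and batch
structure, cell-composition variation, probe cross-reactivity, polygenic
familial aggregation, parent-of-origin effects, and linkage between sites.
Passing tests therefore show the *inference machinery* is correct under
the model's assumptions, not that real 450K data satisfies them.

## Problem sizes used in the shipped checks

The test suite fits cohorts at the full study scale (25 families, ~200
typed) with 20–50 replicates per property and 1000 replicates for the
null-calibration checks; the acceptance script uses 20 recovery
replicates, 5 screening replicates of 200 probes, 300 Cox null replicates
and 100 trend-test replicates, which reproduce the same quantities at
correspondingly wider Monte-Carlo error.

Association-stage *power* demonstrations (the end-to-end example and the
causal-site metrics in the acceptance script) use the strong-effect
design: carrier hazard ratio 5 on a high-risk familial baseline (Weibull
scale 65, most females eventually affected). This is deliberate: with a
family-constant covariate the Cox information is capped by the number of
segregating families (~15 of 25 at carrier frequency 0.2), so at hazard
ratio 3 the Bonferroni-level detection rate stays near 40% no matter how
many events accrue — a real design limitation of 25-family studies worth
knowing, not an implementation artefact. The null-calibration checks are
unaffected by this choice.

## Known limitations

* Consanguineous pedigrees are rejected, not approximated.
* α₁ is fixed, never estimated; the founder-configuration weighting under
  the ≤1-carrier restriction is a modelling choice (truncated binomial).
* Δl has no null distribution attached; it is a ranking device.
* Carrier posteriors are plug-in (no propagation of θ̂ uncertainty).
* The Cox stage assumes proportional hazards on the age scale and offers
  no frailty/random-effects correction for residual familial clustering.
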