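# Methods

## Fidelity composite

Fidelity for woman *i* combines three [0, 1] components: a coverage
indicator `C_i = 1{v_i >= 1}`, a frequency weight `min(v_i, 4)/4` (the
recommended schedule is four visits; extra visits earn no bonus), and a
content weight `k_i/17` over the 17-item FANC checklist. The default
composite is the **product** `C x freq x content`; an **equal-mean**
composite `(C + freq + content)/3` is retained as a documented switch. The
product is the default because it is the stricter reading of "implemented
as planned" — every shortfall discounts the score multiplicatively, a
non-attender scores exactly zero, and under survey-scale margins (coverage
0.84, visit mean 3, the published content margins) it yields cohort means
near 0.45–0.50, whereas the equal-mean composite sits near 0.68. For any
record the product never exceeds the equal mean (with coverage in {0, 1},
`f·w <= min(f, w) <= (1 + f + w)/3`), an invariant the tests assert.

Cohort estimates average the per-woman composite. The ALL stratum
denominates over *every* sampled woman, attenders and non-attenders — only
then does coverage shortfall drag fidelity down, which is the point of
including coverage in the composite. HEW and skilled strata denominate over
attenders with that provider. The CI on the mean is normal-theory
`mean ± z·SD/√n` (a t multiplier is a config switch), clipped to [0, 1].

The tetanus-toxoid checklist item is derived from the recorded dose count:
adequate iff ≥ 2 doses by default (the package schedule specifies two); a
threshold of 1 is configurable because survey tabulations separate TT1 from
TT2+ without stating which counts as received.

## Proportions

Binomial proportions use the Wald interval `p ± z·sqrt(p(1-p)/n)` with no
continuity correction, clipped to [0, 1] — the large-sample form that
matches published survey intervals at n in the hundreds. Degenerate
proportions (k = 0 or k = n) give zero-width intervals at the boundary.

## Random-intercept linear mixed model

`RandomInterceptLM` fits `y_ij = x_ij'β + u_j + e_ij` with
`u_j ~ N(0, σ_u²)`, `e_ij ~ N(0, σ_e²)` by ML (default) or REML. The
likelihood is profiled over the variance ratio λ = σ_u²/σ_e²: at a
candidate λ, each cluster's covariance `I + λ11'` inverts in closed form
(Sherman–Morrison), giving the GLS β, the residual scale, and the profiled
log-likelihood from per-cluster sufficient statistics in O(n p²). A
61-point log-spaced grid over λ ∈ [1e-8, 1e4] brackets the optimum; a
bounded scalar minimization (xatol 1e-12 in log λ) refines it. Solutions at
the lower bound are reported as the boundary σ_u² = 0 with ICC 0, where the
fit coincides with OLS. Tests verify the maximized log-likelihood against
an independent dense-matrix two-parameter Nelder–Mead search (agreement
1e-6), against closed-form ANOVA moment estimators on balanced one-way
layouts, and against statsmodels' MixedLM.

Numerical/design choices:

* **ML default** so AIC/BIC comparisons across specifications with
  different fixed effects are valid; REML likelihoods are not comparable
  across fixed-effect structures but are the right choice for variance
  components with a fixed mean structure (the intercept-only ICC, below).
* Parameter count for AIC/BIC is fixed effects + 2 variance components;
  BIC uses total observation count n.
* Fixed-effect CIs are Wald with the z multiplier, no degrees-of-freedom
  correction. With ~10 clusters this makes intervals on *cluster-level*
  coefficients slightly anti-conservative (simulated coverage ≈ 0.91–0.92
  versus 0.95 for woman-level terms); documented rather than corrected,
  matching common large-sample practice.
* Clusters of size 1 are allowed; a model where *every* cluster is a
  singleton leaves σ_u² unidentified and is returned flagged
  (`converged=False`) rather than raised.
* Rank-deficient designs raise immediately; constant covariate columns are
  dropped at design-build time with a logged warning.

The ICC is σ_u²/(σ_u²+σ_e²); the multilevel decision rule is ICC > 5%
(strict) on the intercept-only fit. The shipped model sequence is
null → level-1 (age, walk distance, maternal education, prior pregnancy
problems, partner education, abortions) → combined (prior problems, partner
education, cluster facilitation-strategy score), fitted on one common
complete-case row set so information criteria are comparable. Missing
covariates are never imputed; complete-case drops are logged. Categorical
covariates enter as treatment contrasts against no-formal-education /
no-prior-problems reference levels. The facilitation covariate is the
unweighted count of the 7 audited facilitation items, so its coefficient
reads "per additional implemented item".

A caveat carried deliberately: the fidelity response lives in [0, 1] but is
modelled with a Gaussian LMM, matching field practice for this outcome; no
transformation is applied.

## Synthetic-data generator

**What it emulates.** The nested survey: 898 women allocated near-equally
to 10 health-post clusters (real cluster sizes are unknown; near-equal is
assumed), attendance probability 0.837 with a cluster random effect
(SD 0.4 on the logit scale — a moderate between-post spread consistent with
a null ICC well above the 5% cutoff) and a positive association with prior
pregnancy problems (OR 1.8); the attendance intercept is solved by
Gauss–Hermite quadrature so the marginal coverage equals the configured
value exactly. Visit counts are zero-truncated Poisson on {1..10} with the
rate solved for mean 3 (implied SD ≈ 1.57, matching the reported 3 ± 1.6).
Content items are Bernoulli with a +0.35 log-odds-per-visit gradient
(content delivery rises with visit count); per-item intercepts are solved
so the *marginal* per-item probabilities among attenders equal the
configured survey margins exactly in expectation. Provider is 52.8% HEW
among attenders. Covariates: age N(30.96, 7.22²) clipped to 15–49, prior
problems 20.8%, partner formal education 35%, maternal formal education
28.6%, abortions Poisson(0.3), walking distance lognormal(3.50, 0.94)
(median ≈ 33 min, ~20% within 15 min, ~37% beyond 45 min), first visit
month N(4.14, 2²) rounded and clipped to 1–10. Facilitation items use
audit-like rates (weekly supervision 0.20, district supervision and
community/HDA support 0.31, onsite assistance 0.56, training 0.75, recent
refresher 0.125 — mean score ≈ 2.6 of 7).

**Linear mode** draws the same records but generates the response from the
mixed model with coefficients 0.09 (prior problems), 0.08 (partner formal
education), 0.04 (per facilitation item) and intercept 0.35 (placing the
mean response near 0.50 under the default covariate distributions — a
convenience, not a truth claim), truncated to [0, 1]. Variance components
are calibrated analytically so the *null-model* ICC on generated data hits
the 0.177 target at total response variance 0.0324 (SD 0.18): the
between-cluster share absorbs the facilitation covariate's variance
contribution `β_fac² Σ p(1-p)` and the residual share the woman-level
covariate contributions. Total SD 0.18 keeps [0, 1] truncation below ~1%
of draws (the truncation-bias warning fires above 10%); a survey-implied
response SD (~0.31) would clip over 10% of draws and visibly attenuate
recovery, so the generator trades marginal-variance realism for clean
recovery of the generating coefficients.

**What it does not emulate.** No spatial structure, no per-post workload,
no repeated pregnancies, no informative cluster sizes, no item-level
provider differences (the provider split calibrates only the per-woman
attribution), and the content gradient is a single global slope rather than
item-specific curves. Passing recovery tests therefore shows the estimators
are correct under the stated generating mechanism — not that the real
survey satisfies that mechanism.

## Measurement conventions in the recovery studies

Simulation studies run at full survey scale (n = 898, J = 10): coefficient
recovery uses 200 replicates (combined-model ML fits; mean estimates
compared against generating values at 2 Monte-Carlo SEs; pooled 95% Wald CI
coverage expected in [0.90, 0.99] given the cluster-level caveat above),
ICC recovery uses 100 replicates with **REML** intercept-only fits (ML's
between-cluster variance is biased low by roughly (J−1)/J, about −0.03 ICC
at J = 10; REML removes most of it, leaving a small residual shortfall from
truncation shrinkage), and structural calibration uses 50 replicates
(pooled coverage, visit mean, and product-composite cohort fidelity, which
lands near 0.45–0.46 under the default margins). These replicate counts
keep the full check suite within a few minutes on one CPU while holding
Monte-Carlo error well inside the tolerances tested.

## Known limitations

* Wald machinery throughout (proportions, fixed effects): no small-sample
  or boundary-respecting intervals.
* Only random intercepts: no random slopes, three-level nesting, or
  GLMM links.
* The equal-allocation, single-gradient generator cannot reproduce
  survey-specific features such as the published provider-stratum fidelity
  gap; stratum estimates on synthetic cohorts reflect the generator's
  provider-independent content mechanism.
* Complete-case analysis only; no imputation or missingness modelling.
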