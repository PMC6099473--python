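# Methods

`socped` analyses inbreeding, inbreeding depression and infidelity in a
cooperatively breeding, socially monogamous bird with very high female
infidelity — the superb fairy-wren social system.  It has two halves: a
set of pedigree/statistical methods that operate on real or synthetic
data tables, and an agent-based generator of synthetic study
populations with known ground truth, used to validate the methods by
parameter recovery.

## Pedigree quantities

All identity-by-descent quantities assume founders (individuals with no
recorded parents) are mutually unrelated and non-inbred; when only one
parent is recorded the unknown side contributes zero kinship, and such
individuals have f = 0 by convention.  This mirrors the field
convention for genetically assigned but boundary-open pedigrees, and it
means f and k are *lower bounds*: inbreeding through unrecorded
ancestry is invisible.  The completeness restriction
(`Pedigree.restrict`, counting known grandparents) exists precisely to
quantify that censoring.

* **Kinship** is computed by the Malecot recursion, decomposing the
  individual of higher generation rank onto its parents (the deeper
  individual can never be an ancestor of the shallower, so the
  recursion is well defined); results are memoized.  Self-kinship is
  (1 + f)/2.
* **Inbreeding for whole pedigrees** uses the ancestor-contribution
  identity f_i = Σ_a t_{s,a} t_{d,a} d_a / 2 (from A = T D T'), which is
  O(n · ancestors) and agrees with the pairwise recursion to 1e-12.
  All finite-pedigree values are dyadic rationals, so an "inbred"
  classification uses f > 1e-12 to absorb float noise conservatively.
* **The additive relationship matrix** A (A[i,j] = 2 k(i,j)) is built
  by the tabular method in topological order; its sparse inverse is
  assembled directly from the pedigree by Henderson's rules with the
  Quaas adjustment for inbred parents (Mendelian sampling variance
  d_i = 0.5 − 0.25(f_s + f_d)).
* **Gene drop**: a vectorized Monte Carlo transmission of founder-unique
  alleles down the ancestor closure of a pair, giving an independent,
  simulation-based kinship estimate with a binomial standard error.
  Used as a validation oracle for the exact recursions, never as the
  primary computation.
* **Relationship routes** (mother–son, half-sibs, grandmother–grandson,
  …) are labelled from the closest path among shared ancestors up to
  two generations; related pairs with no named route are
  `other_related`.  Kinship category bounds are half-open on the upper
  side: high ≥ 0.25, moderate [0.125, 0.25), low (0, 0.125).

## Mixed-model machinery

Two engines share one sparse design-matrix core:

* **Gaussian REML** (`LinearMixedModel`): restricted likelihood
  evaluated through Henderson's mixed-model equations,
  −2 l_R = log|R| + log|G| + log|C| + y′Py, with the residual variance
  profiled out and Powell's method over log variance ratios.  The
  additive-genetic ("animal") component uses the sparse A-inverse, so
  a pedigree of ~10⁴ individuals adds only ~3 nonzeros per row to the
  equations.  Fixed-effect covariances come from the corresponding
  block of C⁻¹; variance-component SEs from a central-difference
  Hessian of the restricted likelihood.  The engine reproduces
  statsmodels MixedLM to four decimals on iid random-intercept
  problems and matches a dense textbook REML evaluation on small
  pedigrees (both checks are in the test suite).
* **Binomial ML with Laplace approximation** (`BinomialMixedModel`):
  penalized IRLS to the joint mode of (b, u), marginal likelihood
  approximated with the log-determinant of the u-block Hessian, outer
  Powell search over log variances, Wald SEs from the joint-Hessian
  inverse.  Binomial (successes, failures) responses are expanded to
  Bernoulli rows (likelihood-equivalent).  Known limitation: with
  small clusters (brood size 3–5) and non-trivial latent variance the
  Laplace fit attenuates fixed effects and random-effect variances by
  roughly 5–10%; recovery tests therefore assert CI coverage and sign,
  not point equality.  Complete separation (e.g. an all-extra-pair
  stratum) is detected from the data and flagged, not raised.

Every fit returns a `MixedModelResults` with estimates, Wald SEs and
CIs, variance components, convergence flags and a `summary()` table.
Degenerate inputs (constant response, constant f, zero-variance clutch
sizes) yield flagged NaN fits rather than exceptions, so pipeline runs
always produce a complete, honest report.

## The analysis models

* **Brood-level infidelity** (`EPPModel`): binomial mixed model of the
  (EPO, WPO) split on social-pair kinship k_SOC, helper class (0/1/2+,
  0 as reference), and parental age classes (1-year-old reference),
  with mother, social-father, cohort *and brood* random intercepts.
  The brood intercept plays the role of the latent brood-level
  residual in overdispersed binomial mixed models; without it,
  unmodelled between-brood variation attenuates every other
  coefficient.  Fitted with and without mother–son social pairs; the
  contrast between the two fits is the analysis.
* **Selective disappearance**: clutch size ~ k_SOC (Gaussian, cohort
  intercept) and survival-to-measurement as a binomial on
  (brood size, clutch − brood) ~ k_SOC.  Null k_SOC effects are the
  no-bias condition.
* **Nestling mass** (`NestlingMassModel`): the animal model — fixed
  effects f, helper class, brood size, sex, measurement age (centred
  at day 7; in the centred basis the generating age slope 2.16/−0.09
  per day on raw age² becomes 0.90/−0.09), weighing-protocol era;
  random effects nest, cohort, hatch interval (12 two-week bins) and
  the additive genetic term.  Heritability is reported as
  V_A / ΣV with a delta-method SE.
* **Fledgling survival** (`FledglingSurvivalModel`): binomial mixed
  model of survival to independence with the same covariate block,
  optionally adding mass residualized to the day-7 / 1992+ scale
  (`mass_adjustment`, which corrects for measurement age and the era
  factor only).
* **Counterfactual**: the faithful pedigree replaces every assigned
  offspring's sire by its mother's social partner, for all generations
  simultaneously (descendants' kinship is then computed on the fully
  substituted pedigree).  A one-generation variant
  (`faithful_f_one_generation`) substitutes only the focal
  individual's sire, as a sensitivity analysis; the recursive mode is
  the default because the comparison is population-level.  Inbred
  (f > 1e-12) vs outbred counts are cross-tabulated observed vs
  faithful and WP vs EP, tested with two-sided Fisher's exact tests
  (scipy; a full hypergeometric-enumeration oracle backs it in the
  tests; the sample odds ratio is reported).
* **Hurdle model** (`InbreedingHurdleModel`): because f is zero for
  ~93% of offspring, stage 1 models inbred status (binomial on WP
  status, EP reference; nest and cohort intercepts) and stage 2 models
  natural-log f among the inbred only (Gaussian, same structure).
  Mother–son broods are excluded by default (their infidelity is
  structural); helper class is omitted because it is confounded with
  extra-pair rates, with an `include_helpers` flag for sensitivity.

## The synthetic-data generator

`simulate_population` is an agent-based model of ~75 territories on a
ring over 26 cohorts (1988–2013).  Each territory holds a dominant
pair and a queue of male helpers (retained sons, oldest first).  Per
year: 1–3 breeding attempts per female, whole-clutch predation with
probability 0.45, clutch sizes 3–5, per-nestling pre-measurement loss
0.08 (optionally f-dependent, for selective-disappearance power
checks).  Annual survival is 0.85 for males and 0.54 for females (the
female figure folds true mortality and permanent off-site dispersal
together); on a dominant male's death the oldest helper inherits the
territory — if the dominant female is his mother this creates a
mother–son social pair.  Surviving sons queue on the natal territory
with probability 0.8; daughters always disperse, settling within 2
territories of the natal one with probability 0.6 when a vacancy
exists, otherwise anywhere (immigrant females arrive at 1.4 per
territory-year; 65% of male vacancies without an heir go to immigrant
males — the study site is an open sample of a larger population).

Extra-pair paternity is per offspring with log-odds 0.47 (+0.53 with
one helper, +1.17 with 2+ helpers) plus a per-brood deviate (sd 0.7,
the between-brood overdispersion), forced to certainty in mother–son
pairs; mothers never produce offspring with their own sons in any
role.  Extra-pair sires are dominant males 3–30 territories away:
short female dispersal plus sessile male lines makes social partners
more related, on average, than these extra-group sires, which is what
generates the WP-vs-EP inbreeding contrast without any kin-targeted
mate choice.  Nestling mass is the linear predictor (defaults are the
published point estimates for this system) plus nest, cohort,
hatch-interval, additive-genetic and residual deviates; breeding
values transmit as midparent plus a Mendelian-sampling deviate with
variance (1 − (f_s + f_d)/2) V_A/2.  Survival to independence is
Bernoulli on a logistic model of adjusted mass (intercept −2.07, slope
0.33 per gram; no direct f effect by default, so any fitted direct
effect is a false positive).

Rates the source system does not pin down (survival, retention,
dispersal, immigration, nest failure) were set to realistic values for
this species and calibrated once so the defaults reproduce the
population's headline statistics — ~54% unassisted broods, ~4–6%
mother–son social pairs, ~66–70% extra-pair offspring, ~5–9% inbred
offspring at the one-grandparent restriction, rising to ~15–21% at
three — and were then frozen.

What the generator does *not* emulate: real territory geometry and
foray behaviour (the ring plus a distance window is a stand-in for an
unknown spatial kernel), within-season social changes (pairs are fixed
within a year), intra-annual variation in clutch initiation beyond the
uniform hatch-interval bins, kin-targeted extra-pair choice, and
selection on mass other than through the survival model.  A subtle
consequence of demographic feedback (survival → recruitment → future
pedigree) is that covariates in later cohorts depend on earlier
outcome draws; empirically this inflates the sampling variance of the
survival-model f coefficient by roughly two-fold relative to its
nominal SE, while the mass-model f coefficient is close to calibrated
(coverage tests in the suite hold the population fixed and redraw
masses to isolate estimator calibration from this feedback).  Passing
tests therefore demonstrate correct recovery under this generative
model, not under every process that could produce real field data.

## Problem sizes and numerical choices

The default simulated study has ~2000 broods and ~7000 measured
nestlings in a pedigree of ~10⁴ (about 5000 nestlings pass the
one-grandparent restriction); the full animal-model REML fit takes
about a minute on one core.  The test suite uses smaller populations
(24–30 territories, 10–14 years) for model unit tests, 30 null
replicates for the brood-model type-I-error check, and 40 mass
redraws for the f-coefficient coverage check; the acceptance script
fits the recovery model on every pedigree-complete nestling of one
default study (n ~ 4000-5500).  Variance components are floored at 1e-8 of the response variance
(1e-6 on the logistic scale); optimizer tolerances are 1e-4 on log
variance ratios.  Ties in topological order are broken by id, making
every computation deterministic for a given seed.
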