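# Methods notes

This note records the models, measurement conventions, numerical
choices and known limitations of the pipeline. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Ego networks from household rosters

Each analysed household contributes one ego network: the woman who
answered the infant-feeding questions (the ego) plus every other
listed member (her alters). The roster carries only each member's
relationship *to the household head*, so pairwise relatedness between
two non-head members is inferred by composing both members' pedigree
paths through the head. The default composition rules live in
`src/hhnet/data/kinship_rules.yaml` (users may pass their own file);
the assumptions that cannot be resolved from the codes alone are made
explicit there and in `hhnet.kinship`:

- the spouse is the parent of the head's children and grandparent of
  grandchildren; a son/daughter-in-law is the parent of grandchildren;
- a grandchild relates to any co-resident son/daughter at 0.25 (it may
  be their own child, 0.5; the conservative value changes no tie);
- two grandchildren default to 0.25 (siblings or first cousins);
- avuncular pairs are anchored at 0.125 throughout;
- `other_relative` relates only to the head (0.125): its relation to
  any other member is unknowable from the code, so those pairs carry
  no tie;
- `not_related` and `domestic_servant` tie to nobody, unconditionally.

Ties are binary (`r > 0`), never weighted by `r`, so the choice among
positive anchor values never changes a network. Affinal (marriage-
based) pairs — head–spouse, child–child-in-law, the head's parents as
a couple, and the adopted child's nuclear unit — have `r = 0` but are
tied by default (`include_affinal=True`, configurable). Without
affinal ties a nuclear family would not form the fully connected
network that maximises constraint, which is the behaviour the
constraint measure is meant to capture.

## Structural measures

With binary adjacency `z` over {ego} ∪ alters (ego tied to every
alter), proportional investments are `p_ij = z_ij / Σ_k z_ik`.

**Effective size** is implemented as `n − 2t/n` (n alters, t
alter–alter ties); the test suite proves this equal to Burt's general
redundancy formula on *every* binary alter graph up to n = 6
(exhaustive enumeration, 33 867 graphs, agreement to 1e-12) and
cross-checks both against `networkx.effective_size`.

**Constraint** is standard, un-normalised Burt constraint
`C = Σ_j (p_ej + Σ_{q≠e,j} p_eq p_qj)²`. Useful exact anchors, all
verified in the tests and cross-checked against `networkx.constraint`:
one alter gives exactly 1; n isolated alters give `1/n`; an n-alter
clique gives `(2n−1)²/n³` — 1.125 at n = 2 (the maximum over all ego
networks), 0.648 at n = 5. Survey reports sometimes describe
constraint as a 0–1 score with 0 for fully unrelated alters; standard
Burt yields `1/n` there, and no truncation, capping or whole-network
normalisation is applied here. Both conventions are stated so users
comparing against software that normalises (e.g. ego-network packages
with a percentage scale) know what to expect.

The effective-size band uses the fixed cut ≤3 vs >3 by default (values
at the threshold are "low"); a weighted-median rule is available.

## Compositional measures

Blau index `H = 1 − Σ P_i²` and `IQV = H/(1 − 1/r)` are computed over
the *alters only* (the ego's own attributes are excluded). Both are
evaluated in integer count arithmetic, `(n² − Σc_i²)·r / (n²(r−1))`,
so homogeneous sets give exactly 0 and an even spread over all r
categories exactly 1. The category count r is the codebook size for
sex (2) and education (3); for kinship type it defaults to the number
of distinct codes observed among alters in the cohort (configurable to
a fixed r). Members with missing education are left out of the
education IQV; the education IQV is dichotomised at the weighted
pooled median (at-median values are "low", matching the ≤/>
convention used for effective size). Age diversity is the sample SD
(n−1) of alter ages, 0 for a single alter. De jure / de facto
heterogeneity is reduced to two presence flags (≥1 absent usual
member; ≥1 visitor), which is how survey tables analyse them.

## Outcome and analysis units

The outcome is the WHO indicator: among infants aged 6–8 months with a
non-missing 24-hour recall, whether solid/semisolid/soft foods were
given. One analysis row per eligible child; households whose ego has
no alters are excluded with a logged reason, and rows with missing
model variables drop complete-case at the design-matrix stage.
Respondent type is "maternal" when the caregiver line equals the
child's mother line.

## Estimation

**Per-round models** maximise the survey-weighted log-likelihood
(statsmodels GLM with variance weights) with linearised sandwich
variance clustered on the primary sampling unit (no finite-population
or stratification terms). Crude = exposure only; adjusted adds the
fixed covariates (woman's age, education, residence, partner
co-residence, sex of head, wealth index, earnings type). Exposures are
analysed one at a time because the network measures are strongly
inter-correlated by construction.

**The pooled model** is a logistic random-intercept model with the
survey round as the grouping level and equal observation weights. It
is fitted by direct maximum likelihood: each group's integral over its
Gaussian intercept is evaluated by adaptive Gauss–Hermite quadrature
(the integrand's mode found by Newton iteration, probabilist-Hermite
nodes rescaled to its Laplace curvature; 12 nodes by default,
configurable), and the marginal likelihood is maximised by BFGS with
three-point numerical gradients from a Newton-fitted ordinary-logistic
start. Convergence requires max |gradient| ≤ 1e-2 after BFGS
termination at gtol 1e-7; the covariance is the inverse numerical
Hessian at the optimum. `fix_sigma=0` pins the variance and reduces
exactly to pooled ordinary logistic (verified to 1e-6 against
statsmodels); with a single round present the fit falls back to
ordinary logistic with a warning. An independent cross-check against
`lme4::glmer` (adaptive quadrature, same node count) runs in the test
suite. With only four groups the variance component is intrinsically
noisy and its ML estimate biased low — the recovery experiment
quantifies this rather than hiding it.

**Marginal effects.** For categorical/binary exposures, the mean
discrete change in predicted probability from the reference level with
all other columns at observed values; for continuous exposures the
mean of `β·p(1−p)`; both ×100 (percentage points) and averaged with
the model's estimation weights. CIs are delta-method with centred
numerical gradients. For multilevel fits the random intercept is
evaluated at zero by default; `re_treatment="integrate"` instead
averages over the fitted Gaussian by quadrature (both are reported
options because the population- vs cluster-averaged choice is a
genuine modelling decision). In a saturated single-binary-predictor
model the AME equals the weighted risk difference exactly (tested to
1e-10), and for unweighted fits it reproduces `statsmodels`
`get_margeff` point estimates and SEs.

No multiple-testing adjustment is applied (one exposure at a time at
p < 0.05); any non-estimable grid cell (zero-variance exposure,
separation, singular design) is flagged `converged=False` and the grid
continues.

## The synthetic cohort generator

The generator emulates the *structure* of a DHS household member
recode, not any real population: four rounds, cluster-level gamma
sampling weights (mean 1), households of up to 20 lines drawn from
four archetypes (nuclear 15%, extended 35%, with unrelated members
35%, female-headed 15% by default), visitors (12% of households),
absent usual members (12%), husbands away for work (8% of male-headed
households), a 90% maternal-respondent share, and round-specific
education distributions that improve over rounds. Each household
contains exactly one infant aged 6–8 months whose outcome is drawn
from a logistic model over the measured network and composition
variables plus covariates, with a Normal(0, 0.5²) intercept per round.
The default archetype mix and size distribution were chosen once so
the synthetic cohort's weighted medians (degree 5, effective size
≈2.6, constraint ≈0.53) sit in the range typical of East African
household surveys; the intercept (−1.152) was calibrated by
root-finding to a pooled prevalence of 0.50 at a zero round effect.
The coefficient preset (`src/hhnet/data/generator_presets.yaml`) is
synthetic and documented as such.

What passing tests therefore do and do not show: they demonstrate that
the measurement code is exact, that the estimators are unbiased,
calibrated and nominally covering *under this generating process* —
roster lines correctly coded, outcomes truly logistic in the measured
variables, weights independent of outcomes within clusters. They
cannot certify behaviour under real-survey pathologies (miscoded
relationships, informative weights, missing-not-at-random recall).

Determinism: all randomness flows through a single integer-seeded
numpy PCG64 generator; a fixed seed reproduces every file
byte-identically, which the tests assert.

## Simulation-study sizes

The recovery experiment runs 100 replicates (tests) / 30 replicates
(acceptance script) of 4 rounds × 1000 households with the
high-effective-size coefficient at −0.25 and round-intercept SD 0.5;
100 replicates make the 0.90–0.99 coverage band checkable at ~1%
resolution, which 20 replicates cannot resolve. Null calibration runs
200 replicates (tests) / 100 (script) of one round × 1000 households
with all coefficients zero, checking per-exposure rejection at
p < 0.05 against the 0.02–0.09 band.

## Known limitations

- Pairwise kinship beyond the head is inferred, not observed; the rule
  file makes the assumptions overridable but cannot recover the truth.
- The pooled model has only four groups; σ² estimates are noisy and
  the ML estimate biased toward zero.
- Sandwich variances use the large-cluster approximation (no
  small-cluster degrees-of-freedom correction).
- The generator's demography is stylised (e.g. grandchildren in young
  households are possible); it targets the distributions of the
  *measures*, not demographic realism.
- Marginal effects from the multilevel model condition on a zero round
  effect by default; the integrated alternative gives attenuated
  effects and is provided as an option, not a default.
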