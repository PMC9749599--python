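# hhnet — intra-household ego networks and the timing of complementary feeding

`hhnet` is an analysis pipeline for a question from infant-feeding
epidemiology: does the *structure* and *composition* of the household
around a young child's primary caregiver shape whether the child is
introduced to solid, semisolid or soft foods at the recommended 6–8
months of age (the WHO infant-and-young-child-feeding core indicator)?

It works from DHS-style household rosters — one line per member with a
relationship-to-head code, age, sex, education and co-residence flags —
and treats each woman respondent as the *ego* of a personal network
whose *alters* are her co-listed household members. Because such
microdata are access-restricted, the package ships a synthetic roster
generator with a fully known outcome process, so every stage of the
pipeline is testable end to end.

## What it computes

**Ties.** Two alters are tied when their coefficient of relatedness
`r`, inferred from their relationship-to-head codes under documented
pedigree defaults (`r = 0.5` parents/children and full siblings, `0.25`
grandparent–grandchild, `0.125` niece/nephew, `0` for any pair
involving a non-related member), is positive — optionally also when the
pair is affinal (e.g. head–spouse). Ties are binary; the ego is tied to
every alter by construction.

**Structure** (Burt's structural-hole measures on the ego network):

- degree: number of alters, `n`;
- effective size: nonredundant contacts, which for a binary symmetric
  ego network reduces to `n − 2t/n` with `t` the number of alter–alter
  ties (range 1 … n); dichotomised `≤3` vs `>3`;
- constraint: `C = Σ_j (p_ej + Σ_q p_eq p_qj)²` over alters `j`, with
  `p` the proportional tie investments — larger when the ego's contacts
  are mutually related.

**Composition** (heterogeneity of the alters): Blau index
`H = 1 − Σ P_i²` and its normalisation, the index of qualitative
variation `IQV = H / (1 − 1/r)` (0 = homogeneous, 1 = evenly spread
over all `r` categories), applied to sex, kinship type and education;
the SD of alter ages; and two membership flags — at least one usual
(de jure) member who slept elsewhere, and at least one visitor
(de facto only).

**Inference.** Each exposure is analysed in its own logistic model
(crude, and adjusted for the woman's age, education, residence, partner
co-residence, sex of head, wealth and earnings type): per survey round
with sampling weights and cluster-robust (primary-sampling-unit)
variance, and pooled across rounds with a multilevel random-intercept
logistic model (survey round as the grouping level, likelihood by
adaptive Gauss–Hermite quadrature, equal observation weights). Pooled
fits are converted to average marginal effects in percentage points,
with delta-method confidence intervals.

## Worked example

The numbered scripts under `analysis/` run the full study on a
synthetic four-round cohort (seed 42, 500 households per round, one
eligible 6–8-month-old per household; raw cohort files go under
`scratch/`, aggregate tables under `results/`):

```sh
python analysis/01_simulate.py     # roster.csv, children.csv, truth.json
python analysis/02_measures.py     # per-child analysis table
python analysis/03_descriptives.py # weighted Table-1-style summary
python analysis/04_fit_models.py   # model grid + marginal effects
```

`03_descriptives.py` prints the weighted cohort summary:

```
pooled weighted medians of the network measures:
  degree: 5.00
  effective_size: 2.60
  constraint: 0.53
  ...
weighted % of infants 6-8 months given solid/semisolid/soft foods:
  2000: 52.7%
  2005: 34.5%
  2011: 61.1%
  2016: 63.2%
```

— the typical ego lives with five other people of whom about 2.6 are
nonredundant contacts, and about half the infants were started on
solids on time, varying by round because each round draws its own
random intercept. `04_fit_models.py` then prints the pooled estimates,
e.g.:

```
  effective_size_band[high]: AOR 0.70 (0.58, 0.85) *   [generating OR 0.78]
  effective_size_band[high]: ME -8.73 pp (-13.36, -4.09) *
  age_sd: AOR 1.05 (1.04, 1.07) *
  age_sd: ME +1.25 pp (+0.85, +1.65) *
```

Read: children of women whose household network has effective size
above 3 are 8.7 percentage points less likely to have been introduced
to solids on time, holding covariates at observed values; the adjusted
odds ratio 0.70 brackets the generating value 0.78 (= e^−0.25) used to
simulate this cohort. A `*` marks p < 0.05. The full grid (per-round
crude/adjusted ORs, pooled ORs and MEs per exposure) is in
`results/results.csv`.

The same workflow is available as a CLI:
`hhnet simulate|measures|fit|all` (see `hhnet --help`); every output
directory receives the resolved configuration and input checksums.

## Layout

```
src/hhnet/        library: roster I/O, kinship rules, network measures,
                  composition, pipeline assembly, inference, simulator, CLI
src/hhnet/data/   default kinship rule table and generator preset (YAML)
analysis/         numbered study drivers (thin wrappers over the library)
tests/            pytest suite incl. oracle and simulation-based checks
scripts/          acceptance script
docs/methods.md   model and design notes
```
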