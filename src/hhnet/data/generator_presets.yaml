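# Default synthetic outcome-model preset.
#
# These coefficients are SYNTHETIC: they define the known generating
# process for the simulated cohorts (log-odds scale), chosen to mirror
# the qualitative pattern expected of household networks (a negative
# high-effective-size effect, a positive age-diversity effect). They
# are not estimates from any survey. The intercept is calibrated by
# root-finding so the pooled outcome prevalence under the default
# archetype mix is ~0.50.
intercept: -1.152
round_intercept_sd: 0.5
coefficients:
  effective_size_band_high: -0.25
  constraint: 0.30
  age_sd: 0.04
  iqv_sex: -0.20
  iqv_kinship: 0.30
  iqv_education_band_high: 0.06
  defacto_diversity: 0.12
  dejure_diversity: 0.08
  mother_age_c: 0.010
  mother_education_primary: 0.15
  mother_education_secondary_plus: 0.30
  residence_urban: 0.20
  coresidence_stays_elsewhere: -0.10
  head_sex_female: -0.05
  wealth_middle: 0.10
  wealth_rich: 0.20
  earnings_working_unpaid: 0.05
  earnings_paid: 0.10
  respondent_nonmaternal: -0.10
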