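"""Assemble the per-child analysis table from roster and child files.

One row per eligible child (aged 6-8 months with a non-missing feeding
recall): the respondent's structural measures (degree, effective size,
constraint), the alters' compositional measures (IQV of sex, kinship
and education, age SD, membership-diversity flags), the respondent and
household covariates, and the binary outcome.

Cohort-level steps happen after the per-household pass: the effective-
size band (fixed <=3 / >3 by default) and the education-IQV band (split
at the weighted pooled median by default, values at the median going to
"low"). The IQV of kinship is normalised by the number of relationship
codes observed among alters in the cohort ("observed" policy, the
default) or by a fixed r.

Households whose ego has no alters are excluded with a logged reason,
as are ineligible or response-missing children.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from hhnet.codes import CODE_INDEX, EDUCATION_LEVELS, RELATIONSHIP_CODES
from hhnet.errors import HHNetError
from hhnet.kinship import RelatednessRules, TieOptions, default_rules
from hhnet.measures import dichotomise_effective_size
from hhnet.stats import weighted_quantile

_EDU_INDEX = {lvl: i for i, lvl in enumerate(EDUCATION_LEVELS)}
_HEAD = CODE_INDEX["head"]
_SPOUSE = CODE_INDEX["spouse"]


@dataclasses.dataclass
class PipelineOptions:
    """Measurement policies for the analysis-table build."""

    include_affinal: bool = True
    rules: RelatednessRules | None = None
    kinship_r: int | str = "observed"
    es_band_rule: str = "fixed"  # "fixed" | "weighted_median"
    es_band_threshold: float = 3.0
    education_band_rule: str = "weighted_median"  # or "fixed"
    education_band_threshold: float = 0.5

    def tie_options(self) -> TieOptions:
        return TieOptions(include_affinal=self.include_affinal, rules=self.rules)


def _blau_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return np.nan
    p = counts / n
    return 1.0 - float(p @ p)


def household_measures_arrays(
    codes: np.ndarray,
    ages: np.ndarray,
    female: np.ndarray,
    edu: np.ndarray,
    de_jure: np.ndarray,
    de_facto: np.ndarray,
    ego_pos: int,
    rules: RelatednessRules,
    include_affinal: bool,
) -> dict:
    """Measure one household from raw arrays (the fast kernel).

    ``codes`` are indices into RELATIONSHIP_CODES, ``edu`` indices into
    EDUCATION_LEVELS with -1 for missing, ``ages`` float with NaN for
    missing. Returns per-household measures; Blau indices are returned
    un-normalised (the cohort pass fixes the kinship r).
    """
    n_members = len(codes)
    alt = np.ones(n_members, dtype=bool)
    alt[ego_pos] = False
    acodes = codes[alt]
    n = n_members - 1
    if n < 1:
        raise HHNetError("ego has no alters")

    tie = rules.r[np.ix_(acodes, acodes)] > 0
    if include_affinal:
        tie |= rules.affinal[np.ix_(acodes, acodes)]
    np.fill_diagonal(tie, False)
    t = int(tie.sum()) // 2

    eff_size = n - 2.0 * t / n

    # Burt constraint on {ego} + alters, ego node 0
    z = np.zeros((n + 1, n + 1))
    z[0, 1:] = z[1:, 0] = 1.0
    z[1:, 1:] = tie
    deg = z.sum(axis=1)
    p = z / deg[:, None]
    inner = p[0] + p[0] @ p
    constraint = float(np.sum(inner[1:] ** 2))

    # compositional measures over alters
    sex_counts = np.array([np.sum(~female[alt]), np.sum(female[alt])])
    blau_sex = _blau_from_counts(sex_counts)
    kin_counts = np.bincount(acodes, minlength=len(RELATIONSHIP_CODES))
    blau_kin = _blau_from_counts(kin_counts)
    aedu = edu[alt]
    edu_counts = np.bincount(aedu[aedu >= 0], minlength=len(EDUCATION_LEVELS))
    blau_edu = _blau_from_counts(edu_counts)
    aages = ages[alt]
    aages = aages[~np.isnan(aages)]
    age_sd = float(np.std(aages, ddof=1)) if aages.size > 1 else 0.0

    defacto_div = bool(np.any(de_jure & ~de_facto))
    dejure_div = bool(np.any(de_facto & ~de_jure))

    # partner coresidence: the ego's spouse is the head when she is the
    # spouse, or a spouse line when she heads the household
    ego_code = codes[ego_pos]
    if ego_code == _SPOUSE:
        partner = np.flatnonzero(codes == _HEAD)
    elif ego_code == _HEAD:
        partner = np.flatnonzero(codes == _SPOUSE)
    else:
        partner = np.empty(0, dtype=int)
    partner_present = bool(partner.size and np.any(de_facto[partner]))

    head_rows = np.flatnonzero(codes == _HEAD)
    head_female = bool(head_rows.size and female[head_rows[0]])

    return {
        "degree": n,
        "t_ties": t,
        "effective_size": eff_size,
        "constraint": constraint,
        "blau_sex": blau_sex,
        "blau_kinship": blau_kin,
        "blau_education": blau_edu,
        "observed_kin_codes": frozenset(np.flatnonzero(kin_counts)),
        "age_sd": age_sd,
        "defacto_diversity": defacto_div,
        "dejure_diversity": dejure_div,
        "coresidence_partner": "living_with_woman" if partner_present else "stays_elsewhere",
        "head_sex": "female" if head_female else "male",
    }


def build_analysis_table(
    roster: pd.DataFrame,
    children: pd.DataFrame,
    options: PipelineOptions | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-eligible-child analysis table.

    Returns ``(analysis, exclusions)``; exclusions is a tidy table of
    (household_id, reason) for every unit left out (ego without alters,
    child outside 6-8 months, missing feeding response).
    """
    options = options or PipelineOptions()
    rules = options.rules if options.rules is not None else default_rules()

    hh_codes, hh_index = pd.factorize(roster["household_id"], sort=False)
    order = np.argsort(hh_codes, kind="stable")

    codes = roster["relationship_code"].map(CODE_INDEX).to_numpy(dtype=int)[order]
    ages = roster["age_years"].to_numpy(dtype=float)[order]
    female = (roster["sex"] == "female").to_numpy()[order]
    edu = roster["education"].map(_EDU_INDEX).fillna(-1).to_numpy(dtype=int)[order]
    de_jure = roster["de_jure"].to_numpy(dtype=bool)[order]
    de_facto = roster["de_facto"].to_numpy(dtype=bool)[order]
    resp = roster["is_respondent"].to_numpy(dtype=bool)[order]
    sorted_codes = hh_codes[order]
    starts = np.searchsorted(sorted_codes, np.arange(len(hh_index)))
    stops = np.append(starts[1:], len(sorted_codes))

    hh_first = {}  # household_id -> index of first (sorted) row
    measures: dict[str, dict] = {}
    exclusions: list[tuple[str, str]] = []
    for g, hh_id in enumerate(hh_index):
        lo, hi = starts[g], stops[g]
        ego_pos = int(np.flatnonzero(resp[lo:hi])[0])
        if hi - lo < 2:
            exclusions.append((str(hh_id), "ego_without_alters"))
            continue
        m = household_measures_arrays(
            codes[lo:hi], ages[lo:hi], female[lo:hi], edu[lo:hi],
            de_jure[lo:hi], de_facto[lo:hi], ego_pos, rules,
            options.include_affinal,
        )
        m["mother_age"] = ages[lo:hi][ego_pos]
        e = edu[lo:hi][ego_pos]
        m["mother_education"] = EDUCATION_LEVELS[e] if e >= 0 else np.nan
        measures[str(hh_id)] = m
        hh_first[str(hh_id)] = lo

    # cohort-level kinship r
    if options.kinship_r == "observed":
        observed = set()
        for m in measures.values():
            observed |= m["observed_kin_codes"]
        kin_r = max(2, len(observed))
    else:
        kin_r = int(options.kinship_r)
        if kin_r < 2:
            raise HHNetError("kinship_r must be >= 2")

    hh_meta = roster.iloc[order].drop_duplicates("household_id").set_index("household_id")

    rows = []
    for _, ch in children.iterrows():
        hh_id = str(ch["household_id"])
        if not (6 <= ch["age_months"] <= 8):
            exclusions.append((hh_id, "child_outside_6_8_months"))
            continue
        if pd.isna(ch["given_solids_yesterday"]):
            exclusions.append((hh_id, "missing_feeding_response"))
            continue
        if hh_id not in measures:
            continue  # already excluded (degenerate household)
        m = measures[hh_id]
        meta = hh_meta.loc[hh_id]
        maternal = (not pd.isna(ch["mother_line"])) and int(ch["mother_line"]) == int(ch["caregiver_line"])
        rows.append(
            {
                "household_id": hh_id,
                "child_line": int(ch["child_line"]),
                "survey_round": str(meta["survey_round"]),
                "cluster_id": str(meta["cluster_id"]),
                "weight": float(meta["weight"]),
                "outcome_introduced": int(ch["given_solids_yesterday"]),
                "child_age_months": int(ch["age_months"]),
                "degree": m["degree"],
                "effective_size": m["effective_size"],
                "constraint": m["constraint"],
                "age_sd": m["age_sd"],
                "iqv_sex": min(1.0, m["blau_sex"] / (1 - 1 / 2)) if not np.isnan(m["blau_sex"]) else np.nan,
                "iqv_kinship": min(1.0, m["blau_kinship"] / (1 - 1 / kin_r)),
                "iqv_education": (
                    min(1.0, m["blau_education"] / (1 - 1 / len(EDUCATION_LEVELS)))
                    if not np.isnan(m["blau_education"]) else np.nan
                ),
                "defacto_diversity": int(m["defacto_diversity"]),
                "dejure_diversity": int(m["dejure_diversity"]),
                "coresidence_partner": m["coresidence_partner"],
                "respondent_type": "maternal" if maternal else "nonmaternal",
                "mother_age": m["mother_age"],
                "mother_education": m["mother_education"],
                "head_sex": m["head_sex"],
                "residence": meta["residence"],
                "wealth_index": meta["wealth_index"],
                "earnings_type": meta["earnings_type"],
            }
        )

    analysis = pd.DataFrame(rows)
    exclusions_df = pd.DataFrame(exclusions, columns=["household_id", "reason"])
    if analysis.empty:
        return analysis, exclusions_df

    w = analysis["weight"].to_numpy()
    bands, es_thr = dichotomise_effective_size(
        analysis["effective_size"].to_numpy(),
        rule=options.es_band_rule,
        threshold=options.es_band_threshold,
        weights=w,
    )
    analysis["effective_size_band"] = bands
    if options.education_band_rule == "weighted_median":
        vals = analysis["iqv_education"].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        edu_thr = weighted_quantile(vals[ok], 0.5, w[ok])
    else:
        edu_thr = float(options.education_band_threshold)
    analysis["iqv_education_band"] = np.where(
        analysis["iqv_education"] <= edu_thr, "low", "high"
    )
    analysis.loc[analysis["iqv_education"].isna(), "iqv_education_band"] = np.nan
    analysis.attrs["effective_size_threshold"] = es_thr
    analysis.attrs["iqv_education_threshold"] = edu_thr
    return analysis, exclusions_df
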