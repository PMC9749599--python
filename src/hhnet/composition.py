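"""Compositional diversity measures and the feeding outcome.

Heterogeneity of the alters on a categorical attribute is summarised by
the Blau index H = 1 - sum_i P_i^2 and its normalisation, the index of
qualitative variation IQV = H / (1 - 1/r), where P_i are category
proportions among the alters and r is the number of codebook categories.
IQV runs from 0 (all alters in one category) to 1 (alters spread evenly
over all r categories).

Membership diversity reduces de jure / de facto status to two presence
flags, matching how household surveys tabulate them: at least one usual
member who slept elsewhere (de facto diversity) and at least one visitor
(de jure diversity).

The outcome is the WHO infant-feeding core indicator: among infants aged
6-8 months, whether solid, semisolid or soft foods were given in the
previous 24 hours.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from hhnet.errors import HHNetError
from hhnet.stats import weighted_mean_se, weighted_quantile, weighted_share


def _count_stats(categories) -> tuple[int, int]:
    """(n, sum of squared category counts) for a multiset."""
    cats = list(categories)
    if not cats:
        raise HHNetError("diversity of an empty multiset is undefined")
    sumsq = sum(c * c for c in Counter(cats).values())
    return len(cats), sumsq


def blau_index(categories) -> float:
    """Blau heterogeneity index H = 1 - sum_i P_i^2 of a multiset."""
    n, sumsq = _count_stats(categories)
    return 1.0 - sumsq / (n * n)


def iqv(categories, r: int) -> float:
    """Index of qualitative variation: Blau index normalised by its
    maximum given ``r`` codebook categories.

    Evaluated in integer arithmetic, (n^2 - sum_i c_i^2) r / (n^2 (r-1)),
    so that homogeneous multisets give exactly 0 and an even spread over
    all r categories exactly 1.
    """
    if r < 2:
        raise HHNetError("IQV normaliser undefined for r < 2")
    n, sumsq = _count_stats(categories)
    value = ((n * n - sumsq) * r) / (n * n * (r - 1))
    if value > 1.0 + 1e-12:
        raise HHNetError(f"IQV {value} exceeds 1: more observed categories than r={r}?")
    return min(value, 1.0)


def age_diversity(ages) -> float:
    """Sample standard deviation (n-1 denominator) of alter ages, in
    years; 0 by convention for a single alter."""
    ages = np.asarray(list(ages), dtype=float)
    if ages.size == 0:
        raise HHNetError("age diversity of an empty list is undefined")
    if ages.size == 1:
        return 0.0
    return float(np.std(ages, ddof=1))


def membership_diversity(members: pd.DataFrame) -> tuple[bool, bool]:
    """Presence flags for membership heterogeneity in a household.

    Returns ``(defacto_diversity, dejure_diversity)``: whether at least
    one usual (de jure) member slept elsewhere last night, and whether
    at least one visitor (de facto only) was present.
    """
    dj = members["de_jure"].to_numpy(dtype=bool)
    df_ = members["de_facto"].to_numpy(dtype=bool)
    return bool(np.any(dj & ~df_)), bool(np.any(df_ & ~dj))


def derive_outcome(age_months, given_solids_yesterday) -> tuple[bool, object]:
    """Eligibility and value of the complementary-feeding indicator.

    A child contributes to the indicator only when aged 6-8 months with
    a non-missing 24-hour recall response. Returns ``(eligible,
    introduced)``; ``introduced`` is None when ineligible.
    """
    response_missing = given_solids_yesterday is None or (
        isinstance(given_solids_yesterday, float) and np.isnan(given_solids_yesterday)
    )
    eligible = (6 <= age_months <= 8) and not response_missing
    return eligible, (bool(given_solids_yesterday) if eligible else None)


# how each analysis-table variable is summarised in descriptive output
DESCRIPTIVE_SPEC: dict[str, str] = {
    "outcome_introduced": "percent",
    "degree": "median",
    "effective_size": "median",
    "constraint": "median",
    "age_sd": "median",
    "iqv_sex": "median",
    "iqv_kinship": "median",
    "iqv_education": "median",
    "effective_size_band": "percent",
    "iqv_education_band": "percent",
    "defacto_diversity": "percent",
    "dejure_diversity": "percent",
    "coresidence_partner": "percent",
    "respondent_type": "percent",
    "mother_age": "mean",
    "mother_education": "percent",
    "residence": "percent",
    "head_sex": "percent",
    "wealth_index": "percent",
    "earnings_type": "percent",
}


def weighted_descriptives(
    units: pd.DataFrame,
    weights=None,
    by_round: bool = True,
    spec: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Survey-weighted descriptive summary in tidy long format.

    Categorical variables get weighted percentages per level, symmetric
    continuous variables a weighted mean with linearised SE, and skewed
    continuous variables the weighted median with Q1/Q3 — per survey
    round and pooled. Output columns: variable, level, round,
    statistic, value.
    """
    if units.empty:
        raise HHNetError("cannot describe an empty table")
    w = units["weight"].to_numpy(dtype=float) if weights is None else np.asarray(weights, float)
    if w.sum() <= 0:
        raise HHNetError("zero total weight")
    spec = spec or {k: v for k, v in DESCRIPTIVE_SPEC.items() if k in units.columns}

    groups: list[tuple[str, np.ndarray]] = [("pooled", np.ones(len(units), dtype=bool))]
    if by_round and "survey_round" in units.columns:
        for rnd in sorted(units["survey_round"].astype(str).unique()):
            groups.append((rnd, (units["survey_round"].astype(str) == rnd).to_numpy()))

    rows = []
    for var, kind in spec.items():
        col = units[var]
        for rnd, mask in groups:
            ok = mask & col.notna().to_numpy()
            if not ok.any():
                continue
            v, wg = col[ok], w[ok]
            if kind == "percent":
                for level in sorted(v.astype(str).unique()):
                    share = weighted_share((v.astype(str) == level).to_numpy(), wg)
                    rows.append((var, level, rnd, "percent", 100.0 * share))
            elif kind == "mean":
                m, se = weighted_mean_se(v.to_numpy(dtype=float), wg)
                rows.append((var, "", rnd, "mean", m))
                rows.append((var, "", rnd, "se", se))
            elif kind == "median":
                x = v.to_numpy(dtype=float)
                for stat, q in (("median", 0.5), ("q1", 0.25), ("q3", 0.75)):
                    rows.append((var, "", rnd, stat, weighted_quantile(x, q, wg)))
            else:
                raise HHNetError(f"unknown descriptive kind {kind!r} for {var!r}")
    return pd.DataFrame(rows, columns=["variable", "level", "round", "statistic", "value"])
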