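"""Synthetic DHS-like household rosters with a known outcome process.

The generator emulates the *structure* of a household-survey member
recode — up to 20 roster lines per household, nuclear / extended /
with-unrelated / female-headed archetypes, visitors (de facto only),
absent usual members (de jure only), four survey rounds with
cluster-level sampling weights — and attaches to every household one
infant aged 6-8 months whose feeding outcome is drawn from a logistic
model over the very measures the pipeline computes:

    P(introduced) = expit(b0 + u_round + sum_k b_k x_k),
    u_round ~ Normal(0, round_intercept_sd^2).

Because the truth (coefficients, round intercepts, per-unit
probabilities) is recorded, the whole pipeline is testable: parameter
recovery, null calibration and coverage experiments all run against
known values. The default coefficient preset is synthetic — a negative
high-effective-size effect and positive age-diversity effect of
plausible sign and size — and is documented as such, never as a
reproduction of any survey estimate.

All randomness flows through one integer-seeded numpy PCG64 generator,
so a fixed seed reproduces the cohort byte-identically.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import expit

from hhnet.errors import ConfigError
from hhnet.pipeline import PipelineOptions, build_analysis_table

ARCHETYPES = ("nuclear", "extended", "with_unrelated", "female_headed")

#: synthetic coefficient preset (log-odds); signs chosen to mirror the
#: qualitative pattern expected of household networks (larger effective
#: size harmful, related/age-diverse households helpful)
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "effective_size_band_high": -0.25,
    "constraint": 0.30,
    "age_sd": 0.04,
    "iqv_sex": -0.20,
    "iqv_kinship": 0.30,
    "iqv_education_band_high": 0.06,
    "defacto_diversity": 0.12,
    "dejure_diversity": 0.08,
    "mother_age_c": 0.010,
    "mother_education_primary": 0.15,
    "mother_education_secondary_plus": 0.30,
    "residence_urban": 0.20,
    "coresidence_stays_elsewhere": -0.10,
    "head_sex_female": -0.05,
    "wealth_middle": 0.10,
    "wealth_rich": 0.20,
    "earnings_working_unpaid": 0.05,
    "earnings_paid": 0.10,
    "respondent_nonmaternal": -0.10,
}

#: intercept calibrated by root-finding so the pooled outcome
#: prevalence under the default mix is ~0.50 (see calibrate_intercept)
DEFAULT_INTERCEPT = -1.152

_EDU_BY_ROUND = {
    "2000": (0.75, 0.18, 0.07),
    "2005": (0.65, 0.24, 0.11),
    "2011": (0.55, 0.30, 0.15),
    "2016": (0.45, 0.35, 0.20),
}
_EDU_DEFAULT = (0.60, 0.27, 0.13)

_EXTENDED_POOL = (
    ("parent", 0.10),
    ("parent_in_law", 0.12),
    ("sibling", 0.12),
    ("niece_nephew", 0.12),
    ("grandchild", 0.12),
    ("son_daughter_in_law", 0.12),
    ("other_relative", 0.30),
)

_AGE_RANGES = {
    "parent": (45, 70),
    "parent_in_law": (45, 68),
    "sibling": (10, 40),
    "niece_nephew": (2, 20),
    "grandchild": (0, 12),
    "son_daughter_in_law": (16, 35),
    "other_relative": (5, 50),
    "not_related": (10, 50),
    "domestic_servant": (12, 40),
}


class GeneratorConfig(BaseModel):
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    n_households_per_round: int = Field(500, ge=1)
    rounds: list[str] = ["2000", "2005", "2011", "2016"]
    n_clusters_per_round: int = Field(35, ge=1)
    archetype_mix: dict[str, float] = {
        "nuclear": 0.15,
        "extended": 0.35,
        "with_unrelated": 0.35,
        "female_headed": 0.15,
    }
    household_size_mean: float = Field(5.6, gt=2.0, le=20.0)
    visitor_prob: float = Field(0.12, ge=0.0, le=1.0)
    absent_member_prob: float = Field(0.12, ge=0.0, le=1.0)
    #: probability the (male) head sleeps elsewhere — the "husband
    #: stays elsewhere" pattern of labour migration
    partner_absent_prob: float = Field(0.08, ge=0.0, le=1.0)
    maternal_prob: float = Field(0.90, ge=0.0, le=1.0)
    urban_cluster_prob: float = Field(0.20, ge=0.0, le=1.0)
    intercept: float = DEFAULT_INTERCEPT
    coefficients: dict[str, float] = dict(DEFAULT_COEFFICIENTS)
    round_intercept_sd: float = Field(0.5, ge=0.0)
    weight_gamma_shape: float = Field(4.0, gt=0.0)
    #: the DGP's fixed dichotomisation cuts (the analysis step may
    #: re-derive data-driven cuts; the generating process uses these)
    effective_size_cut: float = 3.0
    education_iqv_cut: float = 0.5

    @field_validator("archetype_mix")
    @classmethod
    def _known_archetypes(cls, v):
        unknown = set(v) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype(s): {sorted(unknown)}")
        return v

    @model_validator(mode="after")
    def _mix_sums_to_one(self):
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_mix must sum to 1, got {total}")
        if any(p < 0 for p in self.archetype_mix.values()):
            raise ValueError("archetype proportions must be non-negative")
        return self


@dataclasses.dataclass
class CohortData:
    """A generated cohort: files-in-memory plus the generating truth."""

    roster: pd.DataFrame
    children: pd.DataFrame
    analysis: pd.DataFrame  # measured table with outcomes filled in
    truth: dict

    def write(self, outdir):
        """Write roster.csv / children.csv / truth.json under outdir."""
        from pathlib import Path

        from hhnet.roster import write_analysis_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_analysis_table(self.roster, outdir / "roster.csv")
        write_analysis_table(self.children, outdir / "children.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)
        return outdir / "roster.csv", outdir / "children.csv", outdir / "truth.json"


def _edu_probs(round_label: str):
    return _EDU_BY_ROUND.get(str(round_label), _EDU_DEFAULT)


def _draw_education(rng, age, probs):
    if age < 5:
        return "none"
    return ("none", "primary", "secondary_plus")[rng.choice(3, p=probs)]


def generate_household(
    rng: np.random.Generator,
    config: GeneratorConfig,
    archetype: str,
    round_label: str,
    household_id: str,
):
    """Generate one household's roster lines plus its child record.

    Returns ``(rows, child)`` where rows is a list of member dicts
    (without survey context) and child the infant's record dict.
    The respondent is the head's spouse (or the head in female-headed
    households); the infant aged 6-8 months is always listed.
    """
    if archetype not in ARCHETYPES:
        raise ConfigError(f"unknown archetype {archetype!r}")
    eprobs = _edu_probs(round_label)
    size = 2 + rng.poisson(max(config.household_size_mean - 2.0, 0.1))
    min_size = 2 if archetype == "female_headed" else 3
    if archetype in ("extended", "with_unrelated"):
        min_size = 4
    size = int(np.clip(size, min_size, 19))  # one line kept free for a visitor

    rows = []

    def add(code, age, sex, respondent=False, de_jure=1, de_facto=1):
        rows.append(
            {
                "line_number": len(rows) + 1,
                "relationship_code": code,
                "age_years": int(age),
                "sex": sex,
                "education": _draw_education(rng, age, eprobs),
                "de_jure": de_jure,
                "de_facto": de_facto,
                "is_respondent": int(respondent),
            }
        )

    ego_age = int(rng.integers(16, 46))
    if archetype == "female_headed":
        add("head", ego_age, "female", respondent=True)
        n_extra = size - 2
        pool = ("son_daughter", "sibling", "parent", "other_relative")
        pp = (0.6, 0.15, 0.1, 0.15)
        for _ in range(n_extra):
            code = pool[rng.choice(4, p=pp)]
            lo, hi = _AGE_RANGES.get(code, (1, 16))
            age = rng.integers(lo, hi + 1) if code != "son_daughter" else rng.integers(1, 17)
            sex = "female" if rng.random() < 0.5 else "male"
            add(code, age, sex)
    else:
        add("head", ego_age + int(rng.integers(2, 9)), "male")
        add("spouse", ego_age, "female", respondent=True)
        n_extra = size - 3
        force_pool = archetype in ("extended", "with_unrelated")
        for k in range(n_extra):
            if archetype == "nuclear":
                code = "son_daughter"
            elif force_pool and k == 0:
                codes, probs = zip(*_EXTENDED_POOL)
                code = codes[rng.choice(len(codes), p=probs)]
            else:
                if rng.random() < 0.25:
                    code = "son_daughter"
                else:
                    codes, probs = zip(*_EXTENDED_POOL)
                    code = codes[rng.choice(len(codes), p=probs)]
            if code == "son_daughter":
                age = rng.integers(1, 17)
            else:
                lo, hi = _AGE_RANGES[code]
                age = rng.integers(lo, hi + 1)
            sex = "female" if rng.random() < 0.5 else "male"
            add(code, age, sex)
    if archetype == "with_unrelated":
        for _ in range(int(rng.integers(1, 4))):
            if len(rows) >= 18:
                break
            code = "domestic_servant" if rng.random() < 0.4 else "not_related"
            lo, hi = _AGE_RANGES[code]
            sex = "female" if rng.random() < 0.5 else "male"
            add(code, rng.integers(lo, hi + 1), sex)

    # the infant whose feeding outcome is analysed (age in completed
    # years is 0); listed as a child of the head
    infant_sex = "female" if rng.random() < 0.5 else "male"
    add("son_daughter", 0, infant_sex)
    infant_line = len(rows)

    # labour migration: the woman's husband (the head) away from home
    if archetype != "female_headed" and rng.random() < config.partner_absent_prob:
        rows[0]["de_facto"] = 0

    # an absent usual member (de jure only): never the ego or infant
    if rng.random() < config.absent_member_prob:
        ego_line = next(r["line_number"] for r in rows if r["is_respondent"])
        candidates = [r for r in rows if r["line_number"] not in (ego_line, infant_line)]
        if candidates:
            pick = candidates[int(rng.integers(len(candidates)))]
            pick["de_facto"] = 0

    # a visitor (de facto only)
    if rng.random() < config.visitor_prob and len(rows) < 20:
        code = "other_relative" if rng.random() < 0.5 else "not_related"
        lo, hi = _AGE_RANGES[code]
        sex = "female" if rng.random() < 0.5 else "male"
        add(code, rng.integers(lo, hi + 1), sex, de_jure=0, de_facto=1)

    ego_line = next(r["line_number"] for r in rows if r["is_respondent"])
    maternal = bool(rng.random() < config.maternal_prob)
    child = {
        "household_id": household_id,
        "child_line": infant_line,
        "age_months": int(rng.integers(6, 9)),
        "caregiver_line": ego_line,
        "mother_line": ego_line if maternal else None,
    }
    for r in rows:
        r["household_id"] = household_id
    return rows, child


def linear_predictor(analysis: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Fixed-effect part of the outcome model for measured units.

    Encodes the analysis-table columns exactly as the coefficient keys
    name them (bands from the DGP's fixed cuts, mother age centred at
    28 years).
    """
    b = config.coefficients
    n = len(analysis)
    eta = np.full(n, config.intercept, dtype=float)

    def add(key, x):
        if key in b and b[key] != 0.0:
            eta[:] += b[key] * np.asarray(x, dtype=float)

    add("effective_size_band_high", analysis["effective_size"].to_numpy() > config.effective_size_cut)
    add("constraint", analysis["constraint"])
    add("age_sd", analysis["age_sd"])
    add("iqv_sex", analysis["iqv_sex"].fillna(0.0))
    add("iqv_kinship", analysis["iqv_kinship"])
    add("iqv_education_band_high", analysis["iqv_education"].fillna(0.0).to_numpy() > config.education_iqv_cut)
    add("defacto_diversity", analysis["defacto_diversity"])
    add("dejure_diversity", analysis["dejure_diversity"])
    add("mother_age_c", analysis["mother_age"].to_numpy(dtype=float) - 28.0)
    add("mother_education_primary", analysis["mother_education"] == "primary")
    add("mother_education_secondary_plus", analysis["mother_education"] == "secondary_plus")
    add("residence_urban", analysis["residence"] == "urban")
    add("coresidence_stays_elsewhere", analysis["coresidence_partner"] == "stays_elsewhere")
    add("head_sex_female", analysis["head_sex"] == "female")
    add("wealth_middle", analysis["wealth_index"] == "middle")
    add("wealth_rich", analysis["wealth_index"] == "rich")
    add("earnings_working_unpaid", analysis["earnings_type"] == "working_unpaid")
    add("earnings_paid", analysis["earnings_type"] == "paid")
    add("respondent_nonmaternal", analysis["respondent_type"] == "nonmaternal")
    return eta


def generate_outcome(
    eta_fixed: np.ndarray, round_intercepts: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli outcomes from the logistic model; returns (y, p)."""
    p = expit(eta_fixed + round_intercepts)
    return (rng.random(len(p)) < p).astype(int), p


def generate_cohort(config: GeneratorConfig) -> CohortData:
    """Generate a full multi-round cohort with outcomes and truth.

    The in-memory roster/children frames are exactly what
    ``roster.csv`` / ``children.csv`` round-trip through
    :mod:`hhnet.roster`.
    """
    rng = np.random.default_rng(config.seed)
    mix_names = list(config.archetype_mix)
    mix_probs = np.array([config.archetype_mix[a] for a in mix_names])

    all_rows: list[dict] = []
    all_children: list[dict] = []
    round_intercepts = {
        r: float(rng.normal(0.0, config.round_intercept_sd)) for r in config.rounds
    }
    for rnd in config.rounds:
        cluster_weights = rng.gamma(config.weight_gamma_shape, 1.0 / config.weight_gamma_shape,
                                    size=config.n_clusters_per_round)
        cluster_urban = rng.random(config.n_clusters_per_round) < config.urban_cluster_prob
        archetypes = rng.choice(len(mix_names), size=config.n_households_per_round, p=mix_probs)
        clusters = rng.integers(0, config.n_clusters_per_round, size=config.n_households_per_round)
        for h in range(config.n_households_per_round):
            hh_id = f"{rnd}-{h:05d}"
            rows, child = generate_household(rng, config, mix_names[archetypes[h]], rnd, hh_id)
            c = clusters[h]
            wealth = ("poor", "middle", "rich")[rng.choice(3)]
            earnings = ("not_working", "working_unpaid", "paid")[rng.choice(3, p=(0.5, 0.2, 0.3))]
            ctx = {
                "survey_round": rnd,
                "cluster_id": f"{rnd}-c{c:03d}",
                "weight": round(float(cluster_weights[c]), 6),
                "residence": "urban" if cluster_urban[c] else "rural",
                "wealth_index": wealth,
                "earnings_type": earnings,
            }
            for r in rows:
                r.update(ctx)
            all_rows.extend(rows)
            all_children.append(child)

    roster = pd.DataFrame(all_rows)
    from hhnet.roster import CHILD_COLUMNS, ROSTER_COLUMNS

    roster = roster[ROSTER_COLUMNS]
    children = pd.DataFrame(all_children)
    children["given_solids_yesterday"] = 0  # placeholder until drawn
    children = children[CHILD_COLUMNS]
    children["mother_line"] = children["mother_line"].astype("Int64")

    # measure with the DGP's fixed cuts, then draw outcomes
    opts = PipelineOptions(
        es_band_rule="fixed",
        es_band_threshold=config.effective_size_cut,
        education_band_rule="fixed",
        education_band_threshold=config.education_iqv_cut,
    )
    analysis, _ = build_analysis_table(roster, children, opts)
    eta = linear_predictor(analysis, config)
    u = analysis["survey_round"].map(round_intercepts).to_numpy(dtype=float)
    y, p = generate_outcome(eta, u, rng)
    analysis = analysis.copy()
    analysis["outcome_introduced"] = y

    key = children["household_id"].astype(str)
    outcome_map = dict(zip(analysis["household_id"], y))
    children["given_solids_yesterday"] = key.map(outcome_map).astype("Int64")

    truth = {
        "config": json.loads(config.model_dump_json()),
        "round_intercepts": round_intercepts,
        "coefficients": dict(config.coefficients),
        "intercept": config.intercept,
        "n_units": int(len(analysis)),
        "mean_probability": float(np.mean(p)),
        "probabilities": [round(float(v), 6) for v in p],
    }
    return CohortData(roster=roster, children=children, analysis=analysis, truth=truth)


def calibrate_intercept(
    config: GeneratorConfig, target_prevalence: float = 0.5, n_households: int = 4000
) -> float:
    """Root-find the intercept giving the target pooled prevalence.

    Simulates one large cohort's fixed-effect linear predictor (with
    the round intercepts integrated out at their realised draws) and
    solves mean(expit(b0 + eta - b0_current)) = target.
    """
    from scipy.optimize import brentq

    probe = config.model_copy(
        update={"n_households_per_round": max(1, n_households // len(config.rounds))}
    )
    cohort = generate_cohort(probe)
    eta = linear_predictor(cohort.analysis, probe) - probe.intercept
    u = cohort.analysis["survey_round"].map(
        {r: 0.0 for r in probe.rounds}
    ).to_numpy()  # evaluate at the population (zero) round effect

    def gap(b0):
        return float(np.mean(expit(b0 + eta + u))) - target_prevalence

    return float(brentq(gap, -10.0, 10.0))
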