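"""Kin relatedness between roster members and ego-network construction.

Each household member carries only a relationship-to-head code, so the
relatedness between two *non-head* members must be inferred by composing
their paths to the head under default pedigree assumptions (the spouse
is the parent of the head's children, the head's parent is the
grandparent of the head's children, and so on). The resulting pairwise
coefficient-of-relatedness table is restricted to the conventional
anchor values {0, 0.125, 0.25, 0.5} and ships as a documented,
user-overridable YAML file (``data/kinship_rules.yaml``).

Ties are binary: an alter-alter tie is present when the pair's
relatedness is positive, or when the pair is affinal (marriage-based)
and ``include_affinal`` is on. The relatedness value itself is never
used as an edge weight.

Default pedigree assumptions worth stating explicitly, because the
roster cannot distinguish the alternatives:

* a grandchild is taken to be the child of a co-resident
  son/daughter-in-law couple, hence r=0.5 to ``son_daughter_in_law``
  and (conservatively) r=0.25 to any ``son_daughter``;
* two grandchildren may be full siblings or first cousins; the default
  is 0.25;
* a niece/nephew is anchored at the value used for avuncular pairs
  throughout the table (0.125 to the head);
* ``other_relative`` is distant blood kin of the head (r=0.125 to the
  head only): its pedigree path runs through the head, so its relation
  to any *other* member cannot be established from the code alone and
  those pairs stay untied;
* ``adopted_foster`` children have zero genetic relatedness but are
  socially part of the nuclear unit, so their ties to head, spouse and
  the head's children are affinal;
* ``not_related`` and ``domestic_servant`` are tied to nobody.
"""

from __future__ import annotations

import dataclasses
import importlib.resources

import numpy as np
import pandas as pd
import yaml

from hhnet.codes import CODE_INDEX, RELATIONSHIP_CODES, UNRELATED_CODES
from hhnet.errors import DegenerateNetworkError, HHNetError

N_CODES = len(RELATIONSHIP_CODES)

# relatedness of each code to the head under the default pedigree
_R_TO_HEAD = {
    "head": 1.0,
    "spouse": 0.0,
    "son_daughter": 0.5,
    "son_daughter_in_law": 0.0,
    "grandchild": 0.25,
    "parent": 0.5,
    "parent_in_law": 0.0,
    "sibling": 0.5,
    "niece_nephew": 0.125,
    "other_relative": 0.125,
    "adopted_foster": 0.0,
    "not_related": 0.0,
    "domestic_servant": 0.0,
}

# pairwise relatedness between non-head member types, composed through
# the head's pedigree; only positive entries are listed, everything else
# defaults to 0
_R_PAIRS = {
    ("spouse", "son_daughter"): 0.5,
    ("spouse", "grandchild"): 0.25,
    ("spouse", "parent_in_law"): 0.5,
    ("son_daughter", "son_daughter"): 0.5,
    ("son_daughter", "grandchild"): 0.25,
    ("son_daughter", "parent"): 0.25,
    ("son_daughter", "parent_in_law"): 0.25,
    ("son_daughter", "sibling"): 0.125,
    ("son_daughter", "niece_nephew"): 0.125,
    ("son_daughter_in_law", "grandchild"): 0.5,
    ("grandchild", "grandchild"): 0.25,
    ("grandchild", "parent"): 0.125,
    ("grandchild", "parent_in_law"): 0.125,
    ("grandchild", "sibling"): 0.125,
    ("grandchild", "niece_nephew"): 0.125,
    ("parent", "sibling"): 0.5,
    ("parent", "niece_nephew"): 0.25,
    ("sibling", "sibling"): 0.5,
    ("sibling", "niece_nephew"): 0.25,
    ("niece_nephew", "niece_nephew"): 0.25,
}

# marriage-based pairs (relatedness 0, tied only when include_affinal)
_AFFINAL_PAIRS = {
    ("head", "spouse"),
    ("head", "son_daughter_in_law"),
    ("head", "parent_in_law"),
    ("head", "adopted_foster"),
    ("spouse", "parent"),
    ("spouse", "son_daughter_in_law"),
    ("spouse", "adopted_foster"),
    ("son_daughter", "son_daughter_in_law"),
    ("son_daughter", "adopted_foster"),
    ("parent", "parent"),
    ("parent_in_law", "parent_in_law"),
    ("adopted_foster", "adopted_foster"),
}


@dataclasses.dataclass(frozen=True)
class RelatednessRules:
    """Symmetric pairwise relatedness and affinal-link tables.

    ``r[i, j]`` is the coefficient of relatedness between relationship
    codes ``i`` and ``j`` (indices into :data:`RELATIONSHIP_CODES`);
    ``affinal[i, j]`` marks marriage-based pairs whose tie presence is
    governed by the ``include_affinal`` option.
    """

    r: np.ndarray
    affinal: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.r, self.r.T):
            raise HHNetError("relatedness table must be symmetric")
        if not np.array_equal(self.affinal, self.affinal.T):
            raise HHNetError("affinal table must be symmetric")
        allowed = {0.0, 0.125, 0.25, 0.5, 1.0}
        if not set(np.unique(self.r)) <= allowed:
            raise HHNetError(f"relatedness values must be in {sorted(allowed)}")


def default_rules() -> RelatednessRules:
    """Build the default rule table from the pedigree assumptions above."""
    r = np.zeros((N_CODES, N_CODES))
    aff = np.zeros((N_CODES, N_CODES), dtype=bool)
    for code, val in _R_TO_HEAD.items():
        i = CODE_INDEX[code]
        r[CODE_INDEX["head"], i] = r[i, CODE_INDEX["head"]] = val
    for (a, b), val in _R_PAIRS.items():
        i, j = CODE_INDEX[a], CODE_INDEX[b]
        r[i, j] = r[j, i] = val
    for a, b in _AFFINAL_PAIRS:
        i, j = CODE_INDEX[a], CODE_INDEX[b]
        aff[i, j] = aff[j, i] = True
    # the nonrelated rule overrides everything
    for code in UNRELATED_CODES:
        i = CODE_INDEX[code]
        r[i, :] = r[:, i] = 0.0
        aff[i, :] = aff[:, i] = False
    return RelatednessRules(r=r, affinal=aff)


def rules_to_records(rules: RelatednessRules) -> list[dict]:
    """Flatten a rule table to the YAML record layout (upper triangle)."""
    recs = []
    for i in range(N_CODES):
        for j in range(i, N_CODES):
            if rules.r[i, j] > 0 or rules.affinal[i, j]:
                recs.append(
                    {
                        "code_a": RELATIONSHIP_CODES[i],
                        "code_b": RELATIONSHIP_CODES[j],
                        "relatedness": float(rules.r[i, j]),
                        "affinal": bool(rules.affinal[i, j]),
                    }
                )
    return recs


def save_rules(rules: RelatednessRules, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(rules_to_records(rules), fh, sort_keys=False)


def load_rules(path=None) -> RelatednessRules:
    """Load a rule table from YAML; with no path, the packaged default."""
    if path is None:
        ref = importlib.resources.files("hhnet.data") / "kinship_rules.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    records = yaml.safe_load(text) or []
    r = np.zeros((N_CODES, N_CODES))
    aff = np.zeros((N_CODES, N_CODES), dtype=bool)
    for rec in records:
        try:
            i, j = CODE_INDEX[rec["code_a"]], CODE_INDEX[rec["code_b"]]
        except KeyError as exc:
            raise HHNetError(f"unknown relationship code in rules file: {exc}") from exc
        r[i, j] = r[j, i] = float(rec["relatedness"])
        aff[i, j] = aff[j, i] = bool(rec.get("affinal", False))
    return RelatednessRules(r=r, affinal=aff)


def relatedness(a: str, b: str, rules: RelatednessRules | None = None) -> float:
    """Coefficient of relatedness between two relationship codes.

    Symmetric deterministic lookup; any pair involving a nonrelated
    code (``not_related``, ``domestic_servant``) returns 0.
    """
    if rules is None:
        rules = default_rules()
    try:
        i, j = CODE_INDEX[a], CODE_INDEX[b]
    except KeyError as exc:
        raise HHNetError(f"unknown relationship code: {exc}") from exc
    return float(rules.r[i, j])


@dataclasses.dataclass(frozen=True)
class TieOptions:
    """Options governing alter-alter tie construction.

    include_affinal
        Treat marriage-based pairs (head-spouse, child-child-in-law,
        the adopted child's nuclear unit, ...) as tied even though
        their genetic relatedness is 0. On by default: with alters
        restricted to consanguineal kin only, a nuclear family would
        not form the fully connected (maximum-constraint) network that
        motivates the constraint measure.
    """

    include_affinal: bool = True
    rules: RelatednessRules | None = None

    def resolved_rules(self) -> RelatednessRules:
        return self.rules if self.rules is not None else default_rules()


def tie_matrix(code_idx: np.ndarray, rules: RelatednessRules, include_affinal: bool) -> np.ndarray:
    """Binary symmetric alter-alter tie matrix for an array of code indices."""
    r = rules.r[np.ix_(code_idx, code_idx)]
    tie = r > 0
    if include_affinal:
        tie |= rules.affinal[np.ix_(code_idx, code_idx)]
    np.fill_diagonal(tie, False)
    return tie


@dataclasses.dataclass
class EgoNetwork:
    """The respondent (ego), her alters and the alter-alter tie matrix.

    The ego is implicitly tied to every alter (alters are defined by
    co-listing on the roster); only alter-alter ties vary.
    """

    ego: pd.Series
    alters: pd.DataFrame
    tie: np.ndarray

    @property
    def n_alters(self) -> int:
        return len(self.alters)

    @property
    def t_ties(self) -> int:
        return int(np.triu(self.tie, k=1).sum())

    def adjacency(self) -> np.ndarray:
        """Full binary adjacency over {ego} + alters (ego is node 0)."""
        n = self.n_alters
        z = np.zeros((n + 1, n + 1), dtype=float)
        z[0, 1:] = z[1:, 0] = 1.0
        z[1:, 1:] = self.tie.astype(float)
        return z


def build_ego_network(household: pd.DataFrame, options: TieOptions | None = None) -> EgoNetwork:
    """Build the respondent's ego network from one household's roster rows.

    Raises :class:`DegenerateNetworkError` when the ego has no alters
    (structural measures are undefined there and such households are
    excluded from analysis), and :class:`HHNetError` when the household
    does not contain exactly one respondent.
    """
    options = options or TieOptions()
    resp = household["is_respondent"].astype(bool)
    if resp.sum() != 1:
        raise HHNetError(
            f"household {household['household_id'].iloc[0]!r} has "
            f"{int(resp.sum())} respondents; exactly one required"
        )
    ego = household.loc[resp].iloc[0]
    alters = household.loc[~resp].reset_index(drop=True)
    if len(alters) == 0:
        raise DegenerateNetworkError(
            f"household {ego['household_id']!r}: ego has no alters"
        )
    rules = options.resolved_rules()
    code_idx = np.array([CODE_INDEX[c] for c in alters["relationship_code"]])
    tie = tie_matrix(code_idx, rules, options.include_affinal)
    return EgoNetwork(ego=ego, alters=alters, tie=tie)
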