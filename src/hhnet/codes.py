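"""Enumerations for the household-roster codebook.

Relationship-to-head codes follow the standard DHS household member
recode categories. Codes are stored as plain strings in files and as
integer indices (position in :data:`RELATIONSHIP_CODES`) in the fast
numeric kernels.
"""

from __future__ import annotations

RELATIONSHIP_CODES: tuple[str, ...] = (
    "head",
    "spouse",
    "son_daughter",
    "son_daughter_in_law",
    "grandchild",
    "parent",
    "parent_in_law",
    "sibling",
    "niece_nephew",
    "other_relative",
    "adopted_foster",
    "not_related",
    "domestic_servant",
)

CODE_INDEX: dict[str, int] = {c: i for i, c in enumerate(RELATIONSHIP_CODES)}

#: codes that carry no kin tie to anyone (paper rule: "zero for any
#: combination of nonrelated household members")
UNRELATED_CODES: frozenset[str] = frozenset({"not_related", "domestic_servant"})

SEXES: tuple[str, ...] = ("male", "female")

#: ordered education levels; "secondary_plus" pools secondary and higher
EDUCATION_LEVELS: tuple[str, ...] = ("none", "primary", "secondary_plus")

RESIDENCE_LEVELS: tuple[str, ...] = ("rural", "urban")
WEALTH_LEVELS: tuple[str, ...] = ("poor", "middle", "rich")
EARNINGS_LEVELS: tuple[str, ...] = ("not_working", "working_unpaid", "paid")

#: maximum roster lines per household in the DHS household questionnaire
MAX_ROSTER_LINES = 20
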