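"""ICD-10-style code handling: normalisation, range tests, category mapping.

Diagnosis and external-cause codes are matched on their normalised form
(dots stripped, upper-case).  Range tests such as the injury principal-
diagnosis block S00-T89 compare the 3-character category lexicographically,
ignoring 4th and later characters, which is the usual convention for
administrative range definitions.

Mechanism-of-injury (9 categories) and nature-of-injury (13 categories)
groupings are externalised in ``config/code_categories.yaml`` so a licensed
classification could be dropped in without code change.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

__all__ = [
    "normalize_code",
    "category3",
    "in_range3",
    "is_injury_code",
    "load_category_config",
    "mechanism_of",
    "nature_of",
    "MECHANISMS",
    "NATURES",
    "AGE_GROUPS",
    "CCI_GROUPS",
    "TRAUMA_LEVELS",
]

INJURY_LO = "S00"
INJURY_HI = "T89"

AGE_GROUPS = ("0-16", "17-24", "25-44", "45-64", "65-79", "80+")
AGE_BREAKS = (0, 17, 25, 45, 65, 80)  # lower bound of each group
CCI_GROUPS = ("0", "1-2", "3-4", "5+")
TRAUMA_LEVELS = ("level1", "regional", "other")


def normalize_code(code: str) -> str:
    """Strip dots and whitespace and upper-case an ICD-10-style code."""
    if code is None:
        return ""
    return str(code).replace(".", "").replace(" ", "").upper()


def category3(code: str) -> str:
    """Three-character category of a (possibly dotted) code."""
    return normalize_code(code)[:3]


def in_range3(code: str, lo: str, hi: str) -> bool:
    """True if the code's 3-character category lies in [lo, hi] inclusive."""
    cat = category3(code)
    return bool(cat) and lo <= cat <= hi


def is_injury_code(code: str) -> bool:
    """True for codes in the injury principal-diagnosis block S00-T89."""
    return in_range3(code, INJURY_LO, INJURY_HI)


@lru_cache(maxsize=1)
def load_category_config() -> dict:
    text = resources.files("icisskit.config").joinpath("code_categories.yaml").read_text()
    return yaml.safe_load(text)


def _ranges_match(code: str, rule: dict) -> bool:
    cat = category3(code)
    for pref in rule.get("prefixes", []) or []:
        if normalize_code(code).startswith(normalize_code(pref)):
            return True
    for rng in rule.get("ranges", []) or []:
        lo, hi = rng.split("-")
        if lo <= cat <= hi:
            return True
    return False


@lru_cache(maxsize=1)
def _mechanism_rules() -> list[dict]:
    return load_category_config()["mechanism"]


@lru_cache(maxsize=1)
def _nature_rules() -> list[dict]:
    return load_category_config()["nature"]


MECHANISMS = tuple(r["name"] for r in yaml.safe_load(
    resources.files("icisskit.config").joinpath("code_categories.yaml").read_text()
)["mechanism"])
NATURES = tuple(r["name"] for r in yaml.safe_load(
    resources.files("icisskit.config").joinpath("code_categories.yaml").read_text()
)["nature"])


def mechanism_of(external_cause: str) -> str:
    """Map an external-cause code to one of the 9 mechanism categories.

    Unmatched or missing codes fall through to the 'Other and unspecified'
    category (the last rule, which has no ranges).
    """
    for rule in _mechanism_rules():
        if rule.get("fallback"):
            fallback = rule["name"]
        elif _ranges_match(external_cause, rule):
            return rule["name"]
    return fallback


# In the S-block the third character encodes the type of injury within a body
# region (0 superficial, 1 open wound, 2 fracture, ...).  S06/S26/S27/S36/S37
# break the matrix (internal-organ injuries) and are listed explicitly.
_S_MATRIX = {
    "0": "Superficial injuries",
    "1": "Open wound",
    "2": "Fracture",
    "3": "Dislocations, sprains & strains",
    "4": "Injury to nerves and spinal cord",
    "5": "Injury to blood vessels",
    "6": "Injury to muscle, fascia and tendon",
}


def nature_of(principal_dx: str) -> str:
    """Map a principal injury diagnosis to one of the 13 nature categories."""
    code = normalize_code(principal_dx)
    fallback = "Other and unspecified injuries"
    for rule in _nature_rules():
        if rule.get("fallback"):
            fallback = rule["name"]
        elif _ranges_match(code, rule):
            return rule["name"]
    if code.startswith("S") and len(code) >= 3 and code[2] in _S_MATRIX:
        return _S_MATRIX[code[2]]
    return fallback


def age_group_of(age_years) -> str:
    """Band an age in years into the six analysis age groups."""
    try:
        a = float(age_years)
    except (TypeError, ValueError):
        return "missing"
    if a != a or a < 0:  # NaN or negative
        return "missing"
    for lo, name in zip(reversed(AGE_BREAKS), reversed(AGE_GROUPS)):
        if a >= lo:
            return name
    return "missing"


def cci_group_of(score: int) -> str:
    """Bin a Charlson score: 0 / 1-2 / 3-4 / 5+."""
    s = int(score)
    if s < 0:
        raise ValueError("Charlson score cannot be negative")
    if s == 0:
        return "0"
    if s <= 2:
        return "1-2"
    if s <= 4:
        return "3-4"
    return "5+"
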