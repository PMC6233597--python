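"""Charlson comorbidity index and condition flags from diagnosis history.

Conditions are detected over a 12-month lookback window before the index
admission, plus (by default) the diagnoses recorded during the index period
itself, since administrative comorbidity capture typically includes them;
the inclusion is switchable.  Each of the 17 Charlson conditions counts at
most once; the score is the sum of the present conditions' weights (1-6),
binned into the analysis groups 0 / 1-2 / 3-4 / 5+.

Three additional condition flags relevant to injury risk and recovery are
derived from fixed code lists: mental health conditions (F20-F50), alcohol
misuse and dependence (F10, Y90, Y91, Z50.2, Z71.4, Z72.1) and drug-related
dependence (F11-F16, F19, Z50.3, Z71.5, Z72.2).

The condition-to-code mapping ships as a YAML config (the Quan et al. ICD-10
coding algorithm by default) and is fully replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources


import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .codes import cci_group_of, normalize_code
from .exceptions import ConfigError

__all__ = [
    "CharlsonMap",
    "ComorbidityProfile",
    "load_charlson_map",
    "charlson_profile",
    "condition_flags",
    "CharlsonEncoder",
    "attach_comorbidity",
]

FLAG_DEFS = {
    "mental_health": {"ranges": [("F20", "F50")], "prefixes": []},
    "alcohol": {"ranges": [], "prefixes": ["F10", "Y90", "Y91", "Z502", "Z714", "Z721"]},
    "drug": {"ranges": [("F11", "F16"), ("F19", "F19")], "prefixes": ["Z503", "Z715", "Z722"]},
}


@dataclass(frozen=True)
class CharlsonMap:
    """One Charlson condition: name, prefix patterns / category ranges, weight."""

    condition: str
    prefixes: tuple
    ranges: tuple
    weight: int


@dataclass(frozen=True)
class ComorbidityProfile:
    cci_score: int
    cci_group: str
    mental_health: bool
    alcohol: bool
    drug: bool


@lru_cache(maxsize=4)
def load_charlson_map(path: str | None = None) -> tuple[CharlsonMap, ...]:
    if path is None:
        text = resources.files("icisskit.config").joinpath("charlson_quan10.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    conds = raw.get("conditions") or []
    if not conds:
        raise ConfigError("Charlson mapping is empty")
    out = []
    for c in conds:
        w = int(c["weight"])
        if not 1 <= w <= 6:
            raise ConfigError(f"weight {w} for {c['name']} outside 1..6")
        out.append(CharlsonMap(
            condition=c["name"],
            prefixes=tuple(normalize_code(p) for p in c.get("prefixes", []) or []),
            ranges=tuple(tuple(r.split("-")) for r in c.get("ranges", []) or []),
            weight=w,
        ))
    return tuple(out)


def _matches(norm_code: str, entry: CharlsonMap) -> bool:
    if any(norm_code.startswith(p) for p in entry.prefixes):
        return True
    cat = norm_code[:3]
    return any(lo <= cat <= hi for lo, hi in entry.ranges)


def _flag_hit(norm_code: str, spec: dict) -> bool:
    if any(norm_code.startswith(p) for p in spec["prefixes"]):
        return True
    cat = norm_code[:3]
    return any(lo <= cat <= hi for lo, hi in spec["ranges"])


def _history_codes(person_history: pd.DataFrame, index_date, lookback_days: int,
                   include_index_period: bool) -> list[str]:
    h = person_history.copy()
    h["admit_date"] = pd.to_datetime(h["admit_date"])
    index_date = pd.Timestamp(index_date)
    lo = index_date - pd.Timedelta(days=lookback_days)
    keep = (h["admit_date"] >= lo) & (h["admit_date"] < index_date)
    if include_index_period:
        keep |= h["admit_date"] >= index_date
    codes = []
    for row in h.loc[keep].itertuples(index=False):
        if isinstance(row.principal_dx, str) and row.principal_dx:
            codes.append(row.principal_dx)
        other = getattr(row, "other_dx", "")
        if isinstance(other, str) and other:
            codes += [c for c in other.split(";") if c]
    return [normalize_code(c) for c in codes]


def charlson_profile(person_history: pd.DataFrame, index_date,
                     mapping: tuple[CharlsonMap, ...] | None = None,
                     lookback_days: int = 365,
                     include_index_period: bool = True) -> ComorbidityProfile:
    """Charlson score/group and condition flags for one person's history."""
    if mapping is None:
        mapping = load_charlson_map()
    if not mapping:
        raise ConfigError("Charlson mapping is empty")
    codes = _history_codes(person_history, index_date, lookback_days, include_index_period)
    present = {e.condition: e.weight for e in mapping if any(_matches(c, e) for c in codes)}
    score = sum(present.values())
    mh, alc, drg = (any(_flag_hit(c, FLAG_DEFS[f]) for c in codes)
                    for f in ("mental_health", "alcohol", "drug"))
    return ComorbidityProfile(score, cci_group_of(score), mh, alc, drg)


def condition_flags(person_history: pd.DataFrame, index_date,
                    lookback_days: int = 365,
                    include_index_period: bool = True) -> tuple[bool, bool, bool]:
    """(mental_health, alcohol, drug) flags from the stated code lists."""
    codes = _history_codes(person_history, index_date, lookback_days, include_index_period)
    return tuple(any(_flag_hit(c, FLAG_DEFS[f]) for c in codes)
                 for f in ("mental_health", "alcohol", "drug"))


class CharlsonEncoder(BaseEstimator, TransformerMixin):
    """Append comorbidity columns to a periods table.

    Parameters
    ----------
    episodes : DataFrame
        The full episode table the diagnosis history is read from.
    lookback_days : int
        Length of the pre-index window searched for diagnoses (default 365).
    include_index_period : bool
        Whether the index period's own diagnoses also count (default True).
    mapping_path : str or None
        Alternative Charlson mapping YAML; None uses the shipped algorithm.
    """

    def __init__(self, episodes=None, lookback_days=365,
                 include_index_period=True, mapping_path=None):
        self.episodes = episodes
        self.lookback_days = lookback_days
        self.include_index_period = include_index_period
        self.mapping_path = mapping_path

    def fit(self, X, y=None):
        self.mapping_ = load_charlson_map(self.mapping_path)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "mapping_"):
            self.fit(X)
        return attach_comorbidity(X, self.episodes, self.mapping_,
                                  self.lookback_days, self.include_index_period)


def attach_comorbidity(periods: pd.DataFrame, episodes: pd.DataFrame,
                       mapping: tuple[CharlsonMap, ...] | None = None,
                       lookback_days: int = 365,
                       include_index_period: bool = True) -> pd.DataFrame:
    """Vectorised batch version of :func:`charlson_profile` over all periods."""
    if mapping is None:
        mapping = load_charlson_map()
    if not mapping:
        raise ConfigError("Charlson mapping is empty")

    eps = episodes[["person_id", "episode_id", "admit_date", "principal_dx", "other_dx"]].copy()
    eps["admit_date"] = pd.to_datetime(eps["admit_date"])

    # candidate history: lookback-window episodes plus (optionally) the
    # period's own episodes
    per = periods[["person_id", "period_id", "index_admit_date"]].copy()
    per["index_admit_date"] = pd.to_datetime(per["index_admit_date"])
    cand = per.merge(eps, on="person_id", how="left")
    delta = (cand["index_admit_date"] - cand["admit_date"]).dt.days
    in_window = (delta > 0) & (delta <= lookback_days)
    if include_index_period:
        own = periods[["period_id", "episode_ids"]].explode("episode_ids").rename(
            columns={"episode_ids": "episode_id"})
        own["own"] = True
        cand = cand.merge(own, on=["period_id", "episode_id"], how="left")
        in_window |= cand["own"].notna()
    cand = cand.loc[in_window, ["period_id", "principal_dx", "other_dx"]]

    codes = pd.concat([
        cand[["period_id", "principal_dx"]].rename(columns={"principal_dx": "code"}),
        cand.assign(code=cand["other_dx"].str.split(";"))[["period_id", "code"]].explode("code"),
    ])
    codes = codes.dropna(subset=["code"])
    codes = codes[codes["code"] != ""]
    codes["code"] = codes["code"].map(normalize_code)
    codes = codes.drop_duplicates()

    norm = codes["code"]
    cat = norm.str.slice(0, 3)
    weight_hits = pd.DataFrame(index=codes.index)
    for entry in mapping:
        hit = pd.Series(False, index=codes.index)
        for p in entry.prefixes:
            hit |= norm.str.startswith(p)
        for lo, hi in entry.ranges:
            hit |= (cat >= lo) & (cat <= hi)
        weight_hits[entry.condition] = hit

    flags = pd.DataFrame(index=codes.index)
    for f, spec in FLAG_DEFS.items():
        hit = pd.Series(False, index=codes.index)
        for p in spec["prefixes"]:
            hit |= norm.str.startswith(p)
        for lo, hi in spec["ranges"]:
            hit |= (cat >= lo) & (cat <= hi)
        flags[f] = hit

    wmap = {e.condition: e.weight for e in mapping}
    by_period_cond = weight_hits.groupby(codes["period_id"]).any()
    score = by_period_cond.mul(pd.Series(wmap)).sum(axis=1).astype(int)
    by_period_flag = flags.groupby(codes["period_id"]).any()

    out = periods.copy()
    out["cci_score"] = out["period_id"].map(score).fillna(0).astype(int)
    out["cci_group"] = out["cci_score"].map(cci_group_of)
    for f in FLAG_DEFS:
        out[f] = out["period_id"].map(by_period_flag[f]).fillna(False).astype(bool) \
            if f in by_period_flag else False
    return out
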