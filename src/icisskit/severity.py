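"""Survival risk ratios (SRRs) and the ICD-based injury severity score.

The SRR of a diagnosis code is the fraction of index admissions carrying
that code whose patient did not die (here: survived to 90 days from the
index admission, the study outcome; switchable).  Each admission contributes
once to every distinct injury code it carries; duplicate codes within a
period — typically an artifact of repeated coding across transfer episodes —
are collapsed before counting and before taking the product.

Two severity scores are derived per period:

* multiplicative ICISS — the product of the SRRs of all distinct injury
  diagnoses, and
* single worst-injury ICISS — the lowest SRR alone (ties broken towards the
  lexicographically smallest code).

The product of values <= 1 can never exceed its smallest factor, so
``iciss_mult <= iciss_worst`` holds for every period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigError, EmptyDataError

__all__ = [
    "estimate_srr",
    "score_period",
    "score_periods",
    "IcissScores",
    "SurvivalRiskRatioScorer",
]


@dataclass(frozen=True)
class IcissScores:
    iciss_mult: float
    iciss_worst: float
    worst_dx: str


def _exploded(periods: pd.DataFrame) -> pd.DataFrame:
    dx = periods["all_injury_dx"]
    if dx.map(lambda v: isinstance(v, str)).any():
        dx = dx.map(lambda v: [c for c in v.split(";") if c] if isinstance(v, str) else v)
    long = pd.DataFrame({
        "row": np.repeat(np.arange(len(periods)), dx.map(len)),
        "code": [c for lst in dx for c in lst],
    })
    return long.drop_duplicates()  # one contribution per distinct code per period


def estimate_srr(periods: pd.DataFrame, outcome_field: str = "death90",
                 min_count: int = 1) -> pd.DataFrame:
    """SRR table (dx_code, n_total, n_survived, srr) from index admissions.

    ``srr = n_survived / n_total`` exactly; codes with fewer than
    ``min_count`` carriers are dropped (default keeps every code).
    """
    if len(periods) == 0:
        raise EmptyDataError("cannot estimate SRRs from zero periods")
    long = _exploded(periods.reset_index(drop=True))
    died = periods.reset_index(drop=True)[outcome_field].astype(bool).to_numpy()
    long["died"] = died[long["row"].to_numpy()]
    g = long.groupby("code")["died"].agg(n_total="count", n_died="sum")
    table = pd.DataFrame({
        "dx_code": g.index,
        "n_total": g["n_total"].to_numpy(),
        "n_survived": (g["n_total"] - g["n_died"]).to_numpy(),
    }).reset_index(drop=True)
    table["srr"] = table["n_survived"] / table["n_total"]
    if min_count > 1:
        table = table[table["n_total"] >= min_count].reset_index(drop=True)
    return table


def score_period(codes, srr_table: pd.DataFrame,
                 missing_policy: str = "ones") -> IcissScores:
    """ICISS scores for one period's injury code list."""
    lookup = srr_table.set_index("dx_code")["srr"] if isinstance(srr_table, pd.DataFrame) else srr_table
    if isinstance(codes, str):
        codes = [c for c in codes.split(";") if c]
    distinct = sorted(set(codes))
    if not distinct:
        return IcissScores(1.0, 1.0, "")
    srrs = []
    for c in distinct:
        if c in lookup.index:
            srrs.append(float(lookup[c]))
        elif missing_policy == "ones":
            srrs.append(1.0)
        else:
            raise KeyError(f"code {c!r} absent from SRR table")
    srrs = np.asarray(srrs)
    k = int(np.argmin(srrs))  # ties -> first in sorted order = smallest code
    return IcissScores(float(np.prod(srrs)), float(srrs[k]), distinct[k])


def score_periods(periods: pd.DataFrame, srr_table: pd.DataFrame,
                  missing_policy: str = "ones") -> pd.DataFrame:
    """Vectorised scoring: appends iciss_mult, iciss_worst, worst_dx columns.

    Returns a copy; the number of code occurrences not found in the table is
    recorded in ``result.attrs['srr_missing_codes']``.
    """
    if missing_policy not in ("ones", "error"):
        raise ConfigError(f"unknown missing_policy {missing_policy!r}")
    out = periods.reset_index(drop=True).copy()
    long = _exploded(out)
    lookup = srr_table.set_index("dx_code")["srr"]
    vals = long["code"].map(lookup)
    n_missing = int(vals.isna().sum())
    if n_missing and missing_policy == "error":
        missing = sorted(long.loc[vals.isna(), "code"].unique())
        raise KeyError(f"{n_missing} code occurrences absent from SRR table, e.g. {missing[:5]}")
    vals = vals.fillna(1.0)
    long = long.assign(srr=vals.to_numpy())
    long = long.sort_values(["row", "srr", "code"], kind="mergesort")
    grp = long.groupby("row", sort=True)
    mult = grp["srr"].prod()
    worst = grp["srr"].first()
    worst_dx = grp["code"].first()
    idx = np.arange(len(out))
    out["iciss_mult"] = mult.reindex(idx).fillna(1.0).to_numpy()
    out["iciss_worst"] = worst.reindex(idx).fillna(1.0).to_numpy()
    out["worst_dx"] = worst_dx.reindex(idx).fillna("").to_numpy()
    out.attrs["srr_missing_codes"] = n_missing
    return out


class SurvivalRiskRatioScorer(BaseEstimator, TransformerMixin):
    """Learn an SRR table from index admissions and score periods with it.

    ``fit`` tabulates per-code survival against the configured outcome;
    ``transform`` appends the two ICISS variants.  Composes with sklearn
    pipelines (the fitted table lives in ``srr_table_``).

    Parameters
    ----------
    outcome : str
        Column defining "did not die" (default ``death90``).
    min_count : int
        Minimum carriers for a code to enter the table (default 1: keep all,
        accepting that rare codes yield noisy ratios).
    missing_policy : {'ones', 'error'}
        Treatment of codes absent from the fitted table at transform time.
    """

    def __init__(self, outcome: str = "death90", min_count: int = 1,
                 missing_policy: str = "ones"):
        self.outcome = outcome
        self.min_count = min_count
        self.missing_policy = missing_policy

    def fit(self, X: pd.DataFrame, y=None):
        self.srr_table_ = estimate_srr(X, self.outcome, self.min_count)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return score_periods(X, self.srr_table_, self.missing_policy)
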