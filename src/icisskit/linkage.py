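"""Episode-to-period linkage for administrative hospital data.

A *period of care* is the chain of hospital episodes belonging to one injury
event, including inter-hospital transfers, treated as a single analysis unit.
Episodes join the current period when the prior episode separated in transfer
mode and the next admission starts within a configurable window (default one
day) of the prior separation; overlapping episodes of the same person are
merged with a warning count.  The treating hospital of a period is the one
providing the majority of care by length of stay (same-day episodes count as
one day; ties go to the hospital of the later episode, which is typically
the higher level of care a patient was transferred to).

Index injury admissions are the periods whose index-episode principal
diagnosis falls in the S00-T89 injury block, and 90-day mortality is flagged
from the index admission date (day 90 itself counts as within the window;
deaths recorded before the admission are ignored and logged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import age_group_of, is_injury_code, mechanism_of, nature_of, normalize_code

__all__ = [
    "build_periods",
    "select_index_admissions",
    "assign_treating_hospital",
    "flag_death90",
    "LinkageLog",
]


@dataclass
class LinkageLog:
    """Warning counters accumulated during a linkage run."""

    overlapping_episodes_merged: int = 0
    deaths_before_admission: int = 0
    notes: list = field(default_factory=list)


def _split_codes(principal, other) -> list[str]:
    codes = [principal] if isinstance(principal, str) and principal else []
    if isinstance(other, str) and other:
        codes += [c for c in other.split(";") if c]
    return codes


def episode_los_days(admit, sep) -> int:
    """Length of stay in days, with same-day episodes counting as one day."""
    try:
        d = (sep - admit).days
    except TypeError:
        d = (pd.Timestamp(sep) - pd.Timestamp(admit)).days
    return max(int(d), 1)


def assign_treating_hospital(period_episodes: pd.DataFrame) -> tuple[str, str]:
    """Hospital (and its trauma level) with the maximal summed LOS.

    ``period_episodes`` must carry admit_date, sep_date, hospital_id and
    trauma_level, in episode order.  Ties are broken in favour of the
    hospital of the later episode.
    """
    rows = list(period_episodes.itertuples(index=False))
    return _treating_hospital(rows)


def _treating_hospital(rows) -> tuple[str, str]:
    los: dict[str, int] = {}
    last_seen: dict[str, int] = {}
    level: dict[str, str] = {}
    for pos, row in enumerate(rows):
        h = row.hospital_id
        los[h] = los.get(h, 0) + episode_los_days(row.admit_date, row.sep_date)
        last_seen[h] = pos
        level[h] = row.trauma_level
    best = max(los, key=lambda h: (los[h], last_seen[h]))
    return best, level[best]


def build_periods(episodes: pd.DataFrame, transfer_window_days: int = 1,
                  log: LinkageLog | None = None) -> pd.DataFrame:
    """Collapse per-hospital episodes into periods of care.

    Episodes are grouped per person in admission order; a new period starts
    whenever the prior separation mode is not 'transfer' or the gap from the
    prior separation to the next admission exceeds ``transfer_window_days``.
    Every episode lands in exactly one period.
    """
    if log is None:
        log = LinkageLog()
    eps = episodes.copy()
    eps["admit_date"] = pd.to_datetime(eps["admit_date"])
    eps["sep_date"] = pd.to_datetime(eps["sep_date"])
    eps = eps.sort_values(["person_id", "admit_date", "sep_date"], kind="mergesort")

    window = pd.Timedelta(days=transfer_window_days)
    records = []
    pid_counter = 0
    current: list = []
    cur_person = None
    prev_sep = None
    prev_mode = None
    for row in eps.itertuples(index=False):
        if current and row.person_id == cur_person:
            overlap = row.admit_date < prev_sep
            chained = (prev_mode == "transfer" and row.admit_date <= prev_sep + window)
            if overlap and not chained:
                log.overlapping_episodes_merged += 1
            if not (chained or overlap):
                records.append(_close_period(cur_person, pid_counter, current))
                pid_counter += 1
                current = []
        elif current:
            records.append(_close_period(cur_person, pid_counter, current))
            pid_counter += 1
            current = []
        if not current:
            cur_person = row.person_id
            prev_sep = row.sep_date
        else:
            prev_sep = max(prev_sep, row.sep_date)
        current.append(row)
        prev_mode = row.sep_mode
    if current:
        records.append(_close_period(cur_person, pid_counter, current))

    periods = pd.DataFrame.from_records(records)
    periods.attrs["linkage_log"] = log
    return periods


def _close_period(person_id, pid_counter, rows) -> dict:
    first = rows[0]
    injury = []
    seen = set()
    for r in rows:
        for c in _split_codes(r.principal_dx, r.other_dx):
            norm = normalize_code(c)
            if is_injury_code(norm) and norm not in seen:
                seen.add(norm)
                injury.append(norm)
    hosp, level = _treating_hospital(rows)
    return {
        "person_id": person_id,
        "period_id": f"{person_id}-{pid_counter:03d}",
        "episode_ids": [r.episode_id for r in rows],
        "index_admit_date": first.admit_date,
        "final_sep_date": max(r.sep_date for r in rows),
        "treating_hospital": hosp,
        "treating_trauma_level": level,
        "all_injury_dx": injury,
        "principal_dx": normalize_code(first.principal_dx),
        "mechanism": mechanism_of(first.external_cause),
        "nature": nature_of(first.principal_dx),
        "icu_any": bool(any(r.icu_flag for r in rows)),
        "age_years": first.age_years,
        "age_group": age_group_of(first.age_years),
        "sex": first.sex,
        "n_episodes": len(rows),
    }


def select_index_admissions(periods: pd.DataFrame, study_start, study_end) -> pd.DataFrame:
    """Keep periods whose index principal diagnosis is in S00-T89 and whose
    index admission falls inside the study window (both bounds inclusive)."""
    admit = pd.to_datetime(periods["index_admit_date"])
    in_block = periods["principal_dx"].map(is_injury_code)
    in_window = (admit >= pd.Timestamp(study_start)) & (admit <= pd.Timestamp(study_end))
    return periods.loc[in_block & in_window].reset_index(drop=True)


def flag_death90(periods: pd.DataFrame, deaths: pd.DataFrame,
                 window_days: int = 90, log: LinkageLog | None = None) -> pd.Series:
    """Boolean flag: a registered death within ``window_days`` of the index
    admission (0 <= death - admission <= window, day 90 inclusive)."""
    if log is None:
        log = periods.attrs.get("linkage_log") or LinkageLog()
    d = deaths.copy()
    d["death_date"] = pd.to_datetime(d["death_date"])
    merged = periods[["person_id", "index_admit_date"]].reset_index().merge(
        d, on="person_id", how="left")
    delta = (merged["death_date"] - pd.to_datetime(merged["index_admit_date"])).dt.days
    log.deaths_before_admission += int((delta < 0).sum())
    merged["hit"] = (delta >= 0) & (delta <= window_days)
    flag = merged.groupby("index")["hit"].any()
    return flag.reindex(np.arange(len(periods)), fill_value=False).rename("death90")
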