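"""Shared fixtures: seeded synthetic runs at two scales, linked and scored.

The 50,000-person run reproduces the default study conditions (calibrated
marginals, ~1.9% 90-day mortality) and backs the parameter-recovery and
calibration checks; the 4,000-person run backs cheaper integration tests.
"""

import warnings

import pandas as pd
import pytest

from icisskit.comorbidity import attach_comorbidity
from icisskit.linkage import LinkageLog, build_periods, flag_death90, select_index_admissions
from icisskit.severity import SurvivalRiskRatioScorer
from icisskit.synth import default_config, generate


def link_and_score(cfg, out):
    """Generator output -> comorbidity-annotated, ICISS-scored index periods."""
    log = LinkageLog()
    periods = build_periods(out.episodes, log=log)
    idx = select_index_admissions(periods, cfg.study_start, cfg.study_end)
    idx["death90"] = flag_death90(idx, out.deaths, log=log).to_numpy()
    idx = attach_comorbidity(idx, out.episodes)
    idx = idx.rename(columns={"icu_any": "icu", "treating_trauma_level": "trauma_level"})
    idx.attrs["linkage_log"] = log
    scorer = SurvivalRiskRatioScorer(outcome="death90").fit(idx)
    scored = scorer.transform(idx)
    scored.attrs["linkage_log"] = log
    return idx, scorer, scored


@pytest.fixture(scope="session")
def run50k():
    cfg = default_config(n_persons=50_000, seed=20)
    out = generate(cfg)
    idx, scorer, scored = link_and_score(cfg, out)
    return {"cfg": cfg, "out": out, "index_periods": idx,
            "scorer": scorer, "scored": scored}


@pytest.fixture(scope="session")
def small_run():
    cfg = default_config(n_persons=4_000, seed=7)
    out = generate(cfg)
    idx, scorer, scored = link_and_score(cfg, out)
    return {"cfg": cfg, "out": out, "index_periods": idx,
            "scorer": scorer, "scored": scored}


@pytest.fixture(autouse=True)
def _quiet_quasi_separation():
    """Sparse category cells in small fits emit quasi-separation warnings;
    they are expected behaviour, not test failures."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*quasi-complete separation.*")
        warnings.filterwarnings("ignore", message=".*Hosmer-Lemeshow group.*")
        yield


def make_episodes(rows):
    """Hand-built episode table from compact tuples:
    (person, episode, admit, sep, hospital, level, principal, other, ext,
    icu, mode, age, sex)."""
    cols = ["person_id", "episode_id", "admit_date", "sep_date", "hospital_id",
            "trauma_level", "principal_dx", "other_dx", "external_cause",
            "icu_flag", "sep_mode", "age_years", "sex"]
    df = pd.DataFrame(rows, columns=cols)
    df["admit_date"] = pd.to_datetime(df["admit_date"])
    df["sep_date"] = pd.to_datetime(df["sep_date"])
    return df
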