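"""Synthetic linked hospitalisation + mortality data with known ground truth.

Emulates a state-wide administrative extract of injury admissions: per-person
hospital episodes (up to 50 ICD-10-style diagnosis codes, external cause,
ICU flag, separation mode), a death registry, inter-hospital transfer chains,
and a 12-month pre-index comorbidity history — with every event's true
severity score and outcome probabilities recorded so downstream estimation
can be checked against truth.

The data-generating process:

* diagnosis counts per admission follow a shifted negative binomial
  (1 + NB, so every admission has at least one code) capped at 43 codes,
  with parameters solved numerically to hit mean 1.74 / SD 1.46;
* each event's 90-day death risk is logistic in the log survival-risk-ratio
  of the worst (lowest-SRR) injury code plus age/sex/comorbidity effects;
  ICU risk is logistic in the log of the multiplicative score by default
  (each is switchable to the other variant);
* demographic and injury-category marginals default to published state-wide
  injury-hospitalisation descriptors (55.6% male, 35.6% falls, 79.7% with no
  Charlson comorbidity, 1.9% 90-day deaths, 3.1% ICU, ...), with plausible
  age x mechanism and mechanism x nature dependence reconciled to those
  marginals by iterative proportional fitting.

Because death risk depends on the worst code *and* covariates, the marginal
survival of carriers of a code (the estimand of SRR estimation) is not the
raw per-code severity parameter; ``generate`` therefore also returns a
``srr_truth`` table holding the exact model-implied survival per code,
computed from the realised per-person event probabilities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .codes import AGE_GROUPS, MECHANISMS, NATURES, TRAUMA_LEVELS
from .exceptions import ConfigError

__all__ = [
    "GeneratorConfig",
    "OutcomeCoefs",
    "default_config",
    "generate",
    "truncated_count_sampler",
    "SynthOutput",
]

# ---------------------------------------------------------------------------
# Diagnosis-count distribution


@lru_cache(maxsize=16)
def _solve_shifted_nb(mean: float, sd: float, lo: int, hi: int) -> np.ndarray:
    """Probability vector on lo..hi of a shifted (lo + NB) negative binomial
    with the requested truncated mean and SD; parameters solved numerically.

    The shift guarantees support starting at ``lo`` while allowing more
    overdispersion than a zero-truncated NB can reach (the zero-truncated
    family cannot exceed its logarithmic-series boundary, SD ~1.34 at mean
    1.74, so it cannot match the target SD of 1.46)."""
    ks = np.arange(lo, hi + 1)

    def trunc_moments(x):
        r = np.exp(x[0])
        p = expit(x[1])
        w = stats.nbinom.pmf(ks - lo, r, p)
        tot = w.sum()
        if tot <= 0:
            return np.array([1e6, 1e6])
        w = w / tot
        m = float(w @ ks)
        v = float(w @ (ks - m) ** 2)
        return np.array([m - mean, np.sqrt(max(v, 0.0)) - sd])

    best = None
    for guess in ((np.log(0.4), logit(0.35)), (np.log(0.8), logit(0.5)),
                  (np.log(2.0), logit(0.7)), (np.log(0.1), logit(0.15))):
        sol = optimize.root(trunc_moments, np.array(guess), method="hybr")
        resid = np.max(np.abs(trunc_moments(sol.x)))
        if best is None or resid < best[0]:
            best = (resid, sol.x)
        if resid < 1e-9:
            break
    resid, x = best
    if resid > 1e-6:
        raise ConfigError(
            f"count distribution with mean {mean}, sd {sd} on [{lo},{hi}] "
            "is unattainable (moment solver did not converge)"
        )
    r, p = np.exp(x[0]), expit(x[1])
    w = stats.nbinom.pmf(ks - lo, r, p)
    return w / w.sum()


DEFAULT_DX_COUNT_DIST = {"kind": "shifted_nb", "mean": 1.74, "sd": 1.46, "min": 1, "max": 43}


def count_pmf(dist_spec: dict) -> tuple[np.ndarray, np.ndarray]:
    """(support, probabilities) for a count distribution spec."""
    kind = dist_spec.get("kind")
    if kind == "point":
        v = int(dist_spec["value"])
        return np.array([v]), np.array([1.0])
    if kind == "pmf":
        ks = np.asarray(dist_spec["values"], dtype=int)
        ps = np.asarray(dist_spec["probs"], dtype=float)
        if np.any(ps < 0) or not np.isclose(ps.sum(), 1.0):
            raise ConfigError("pmf probabilities must be non-negative and sum to 1")
        return ks, ps
    if kind == "shifted_nb":
        lo = int(dist_spec.get("min", 1))
        hi = int(dist_spec.get("max", 43))
        mean = float(dist_spec["mean"])
        sd = float(dist_spec["sd"])
        if not (lo < mean < hi):
            raise ConfigError(f"target mean {mean} outside attainable support [{lo},{hi}]")
        return np.arange(lo, hi + 1), _solve_shifted_nb(mean, sd, lo, hi)
    raise ConfigError(f"unknown count distribution kind {kind!r}")


def truncated_count_sampler(dist_spec: dict, n: int, seed) -> np.ndarray:
    """Sample ``n`` diagnosis counts from a bounded count distribution."""
    ks, ps = count_pmf(dist_spec)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(ks, size=n, p=ps)


# ---------------------------------------------------------------------------
# Iterative proportional fitting for plausible joint category structure


def ipf(row_marg: np.ndarray, col_marg: np.ndarray, tilt: np.ndarray,
        tol: float = 1e-12, max_iter: int = 500) -> np.ndarray:
    """Joint table with given margins, as close as possible to ``tilt``."""
    row_marg = np.asarray(row_marg, float)
    col_marg = np.asarray(col_marg, float)
    j = np.outer(row_marg, col_marg) * np.asarray(tilt, float)
    for _ in range(max_iter):
        j *= (row_marg / j.sum(axis=1))[:, None]
        j *= col_marg / j.sum(axis=0)
        if np.max(np.abs(j.sum(axis=1) - row_marg)) < tol:
            break
    return j


# ---------------------------------------------------------------------------
# Ground-truth outcome model


@dataclass(frozen=True)
class OutcomeCoefs:
    """Logistic coefficients of a ground-truth outcome model.

    The linear predictor is
    ``intercept + b_log_iciss * log(ICISS) + age + sex + cci`` where ICISS is
    the variant named by ``iciss_variant`` ('worst' or 'mult').
    """

    intercept: float
    b_log_iciss: float
    iciss_variant: str = "worst"
    age: dict = field(default_factory=dict)
    sex: dict = field(default_factory=dict)
    cci: dict = field(default_factory=dict)

    @classmethod
    def flat(cls, intercept: float) -> "OutcomeCoefs":
        """All-zero coefficients except the intercept (constant risk)."""
        return cls(intercept=intercept, b_log_iciss=0.0)

    def linear_predictor(self, log_iciss_worst, log_iciss_mult,
                         age_group, sex, cci_group) -> np.ndarray:
        log_iciss = log_iciss_worst if self.iciss_variant == "worst" else log_iciss_mult
        eta = self.intercept + self.b_log_iciss * np.asarray(log_iciss, float)
        if self.age:
            eta = eta + np.array([self.age.get(a, 0.0) for a in age_group])
        if self.sex:
            eta = eta + np.array([self.sex.get(s, 0.0) for s in sex])
        if self.cci:
            eta = eta + np.array([self.cci.get(c, 0.0) for c in cci_group])
        return eta


# Intercepts calibrated once (large-sample logit-shift root solve) so default
# prevalences sit near 1.9% 90-day mortality and 3.1% ICU admission.
DEATH_INTERCEPT = -6.1458
ICU_INTERCEPT = -3.8896

DEFAULT_DEATH_COEFS = OutcomeCoefs(
    intercept=DEATH_INTERCEPT,
    b_log_iciss=-10.0,
    iciss_variant="worst",
    age={"0-16": -1.5, "17-24": -0.7, "25-44": 0.0, "45-64": 0.6,
         "65-79": 1.8, "80+": 2.9},
    sex={"male": 0.0, "female": -0.1},
    cci={"0": 0.0, "1-2": 0.6, "3-4": 1.1, "5+": 1.6},
)

DEFAULT_ICU_COEFS = OutcomeCoefs(
    intercept=ICU_INTERCEPT,
    b_log_iciss=-8.0,
    iciss_variant="mult",
    age={"0-16": -0.5, "17-24": 0.3, "25-44": 0.4, "45-64": 0.3,
         "65-79": 0.0, "80+": -0.5},
    sex={"male": 0.0, "female": -0.15},
    cci={"0": 0.0, "1-2": 0.4, "3-4": 0.7, "5+": 0.9},
)


# ---------------------------------------------------------------------------
# Synthetic code vocabulary

# Category stems and a per-category hazard scale (typical 1 - SRR magnitude).
_NATURE_STEMS = {
    "Superficial injuries": (["S00", "S30", "S40", "S50", "S60", "S70", "S80", "S90"], 0.002),
    "Open wound": (["S01", "S11", "S21", "S31", "S41", "S51", "S61", "S71", "S81", "S91"], 0.004),
    "Fracture": (["S02", "S12", "S22", "S32", "S42", "S52", "S62", "S72", "S82", "S92"], 0.025),
    "Dislocations, sprains & strains": (["S03", "S13", "S23", "S33", "S43", "S53", "S63", "S73", "S83", "S93"], 0.003),
    "Injury to nerves and spinal cord": (["S04", "S14", "S24", "S34", "S44", "S54", "S64", "S74", "S84", "S94"], 0.05),
    "Injury to blood vessels": (["S15", "S25", "S35", "S45", "S75", "S85"], 0.07),
    "Injury to muscle, fascia and tendon": (["S16", "S46", "S56", "S66", "S76", "S86", "S96"], 0.003),
    "Injury to internal organs": (["S06", "S26", "S27", "S36", "S37"], 0.08),
    "Foreign body entering through natural orifice": (["T15", "T17", "T18"], 0.004),
    "Burns": (["T21", "T24", "T29", "T31"], 0.04),
    "Poisoning by drugs, medicaments and biological substances": (["T39", "T42", "T43", "T50"], 0.02),
    "Toxic effects of substances chiefly nonmedicinal as to source": (["T51", "T58", "T60"], 0.03),
    "Other and unspecified injuries": (["S09", "S19", "S29", "S39", "T07", "T14", "T79"], 0.01),
}

_MECH_CODES = {
    "Land transport incidents": ["V43.5", "V03.1", "V28.4"],
    "Falls": ["W01.0", "W06.8", "W18.3"],
    "Inanimate mechanical forces": ["W22.8", "W25.0", "W31.2"],
    "Drowning and submersion and other threats to breathing": ["W65.2", "W74.9"],
    "Smoke, fire and flames, heat and hot substances": ["X00.0", "X10.1"],
    "Poisoning": ["X42.1", "X44.8"],
    "Intentional self-harm": ["X70.3", "X61.0", "X80.8"],
    "Assault": ["X95.9", "Y04.0"],
    "Other and unspecified injury mechanism": ["X58.9", "W55.1", "Y34.9"],
}

# Representative codes for emitting comorbidity history episodes; each maps to
# exactly one Charlson condition under the shipped coding algorithm.
CONDITION_CODES = {
    "myocardial_infarction": "I21.4",
    "congestive_heart_failure": "I50.0",
    "peripheral_vascular_disease": "I70.2",
    "cerebrovascular_disease": "I63.9",
    "dementia": "F00.1",
    "chronic_pulmonary_disease": "J44.9",
    "rheumatic_disease": "M05.9",
    "peptic_ulcer_disease": "K25.9",
    "mild_liver_disease": "K70.3",
    "diabetes_without_complication": "E11.9",
    "diabetes_with_complication": "E11.2",
    "hemiplegia_paraplegia": "G81.9",
    "renal_disease": "N18.5",
    "any_malignancy": "C34.9",
    "moderate_severe_liver_disease": "K72.9",
    "metastatic_solid_tumour": "C78.7",
    "aids_hiv": "B20",
}
_W1 = ["myocardial_infarction", "congestive_heart_failure", "peripheral_vascular_disease",
       "cerebrovascular_disease", "dementia", "chronic_pulmonary_disease", "rheumatic_disease",
       "peptic_ulcer_disease", "mild_liver_disease", "diabetes_without_complication"]
_W2 = ["diabetes_with_complication", "hemiplegia_paraplegia", "renal_disease", "any_malignancy"]
_W3 = ["moderate_severe_liver_disease"]
_W6 = ["metastatic_solid_tumour", "aids_hiv"]

_FLAG_CODES = {
    "mental_health": ["F32.1", "F20.0", "F41.2"],
    "alcohol": ["F10.2", "Z72.1"],
    "drug": ["F11.2", "Z72.2"],
}


def build_vocabulary(seed: int = 20100101) -> pd.DataFrame:
    """Synthetic injury-code vocabulary: code, nature, sampling weight,
    per-code severity parameter (worst-case excess death probability)."""
    rng = np.random.default_rng(seed)
    rows = []
    nature_marg = DEFAULT_MARGINALS["nature"]
    for nature, (stems, scale) in _NATURE_STEMS.items():
        zipf = 1.0 / np.arange(1, len(stems) + 1)
        zipf /= zipf.sum()
        for stem, z in zip(stems, zipf):
            code = f"{stem}.{rng.integers(0, 10)}"
            sev = float(np.clip(scale * rng.lognormal(0.0, 0.6), 5e-4, 0.5))
            rows.append((code, nature, nature_marg[nature] * z, sev))
    vocab = pd.DataFrame(rows, columns=["code", "nature", "weight", "severity"])
    vocab["weight"] /= vocab["weight"].sum()
    return vocab


# ---------------------------------------------------------------------------
# Default marginal targets (published state-wide descriptors)

DEFAULT_MARGINALS = {
    "age_group": dict(zip(AGE_GROUPS, (0.147, 0.110, 0.215, 0.208, 0.151, 0.169))),
    "sex": {"male": 0.556, "female": 0.444},
    "trauma_level": dict(zip(TRAUMA_LEVELS, (0.278, 0.179, 0.543))),
    "mechanism": dict(zip(MECHANISMS, (0.101, 0.356, 0.120, 0.002, 0.010,
                                       0.016, 0.048, 0.031, 0.316))),
    "nature": dict(zip(NATURES, (0.039, 0.014, 0.013, 0.055, 0.009,
                                 0.050, 0.121, 0.341, 0.047, 0.010,
                                 0.004, 0.039, 0.258))),
    # any Charlson condition, by age stratum (<65 vs >=65); chosen so the
    # overall rate is ~20.3% while ~45.3% of those 65+ carry a comorbidity
    "charlson_any_under65": 0.0853,
    "charlson_any_65plus": 0.453,
    # split of the non-zero Charlson groups (1-2 / 3-4 / 5+)
    "charlson_group_split": (0.645, 0.197, 0.158),
    "mental_health": 0.095,
    "alcohol": 0.072,
    "drug": 0.036,
}

# age x mechanism plausibility tilt (falls skew old, transport/self-harm young)
_AGE_MECH_TILT = np.array([
    # transport falls  mech   drown  fire   poison selfh  assault other
    [0.8,      0.80,   1.2,   2.0,   1.2,   0.8,   0.3,   0.3,    1.0],  # 0-16
    [2.2,      0.35,   1.5,   1.0,   1.0,   1.5,   2.5,   2.5,    1.0],  # 17-24
    [1.6,      0.40,   1.4,   1.0,   1.2,   1.5,   2.0,   2.0,    1.0],  # 25-44
    [1.0,      0.80,   1.1,   0.8,   1.0,   1.0,   1.0,   0.8,    1.0],  # 45-64
    [0.6,      2.20,   0.6,   0.8,   0.8,   0.6,   0.3,   0.2,    1.0],  # 65-79
    [0.3,      3.50,   0.4,   0.6,   0.7,   0.4,   0.1,   0.1,    1.0],  # 80+
])

# mechanism x nature plausibility tilt (poisoning mechanism -> poisoning
# nature, burns <- fire, fractures <- falls, ...)
_MECH_NATURE_TILT = np.ones((9, 13))


def _set_tilt(mech, nature, value):
    _MECH_NATURE_TILT[MECHANISMS.index(mech), NATURES.index(nature)] = value


for _n in NATURES:
    _set_tilt("Poisoning", _n, 0.03)
    _set_tilt("Smoke, fire and flames, heat and hot substances", _n, 0.05)
_set_tilt("Poisoning", "Poisoning by drugs, medicaments and biological substances", 80.0)
_set_tilt("Poisoning", "Toxic effects of substances chiefly nonmedicinal as to source", 10.0)
_set_tilt("Smoke, fire and flames, heat and hot substances", "Burns", 100.0)
_set_tilt("Intentional self-harm", "Poisoning by drugs, medicaments and biological substances", 8.0)
_set_tilt("Intentional self-harm", "Open wound", 2.0)
_set_tilt("Falls", "Fracture", 2.5)
_set_tilt("Falls", "Superficial injuries", 1.3)
_set_tilt("Falls", "Poisoning by drugs, medicaments and biological substances", 0.02)
_set_tilt("Falls", "Toxic effects of substances chiefly nonmedicinal as to source", 0.05)
_set_tilt("Falls", "Burns", 0.02)
_set_tilt("Land transport incidents", "Injury to internal organs", 2.5)
_set_tilt("Land transport incidents", "Fracture", 1.8)
_set_tilt("Land transport incidents", "Injury to nerves and spinal cord", 2.0)
_set_tilt("Land transport incidents", "Poisoning by drugs, medicaments and biological substances", 0.02)
_set_tilt("Assault", "Open wound", 3.0)
_set_tilt("Assault", "Superficial injuries", 2.0)
_set_tilt("Inanimate mechanical forces", "Open wound", 3.0)
_set_tilt("Inanimate mechanical forces", "Foreign body entering through natural orifice", 2.0)
_set_tilt("Drowning and submersion and other threats to breathing", "Other and unspecified injuries", 8.0)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class GeneratorConfig:
    n_persons: int = 50_000
    study_start: date = date(2010, 1, 1)
    study_end: date = date(2014, 6, 30)
    lookback_start: date = date(2009, 1, 1)
    death_followup_end: date = date(2015, 3, 31)
    vocabulary: pd.DataFrame = None
    dx_count_dist: dict = field(default_factory=lambda: dict(DEFAULT_DX_COUNT_DIST))
    death_coefs: OutcomeCoefs = DEFAULT_DEATH_COEFS
    icu_coefs: OutcomeCoefs = DEFAULT_ICU_COEFS
    transfer_prob: float = 0.10
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    late_death_prob: float = 0.015
    missing_sex_prob: float = 1.5e-4
    missing_age_prob: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.vocabulary is None:
            self.vocabulary = build_vocabulary()
        if not (self.lookback_start < self.study_start < self.study_end
                <= self.death_followup_end):
            raise ConfigError("dates must satisfy lookback < start < end <= follow-up end")
        for p in (self.transfer_prob, self.late_death_prob,
                  self.missing_sex_prob, self.missing_age_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        srr = self.true_srr
        if any(not (0.0 < s <= 1.0) for s in srr.values()):
            raise ConfigError("true SRR values must lie in (0, 1]")
        count_pmf(self.dx_count_dist)  # validates the spec eagerly

    @property
    def true_srr(self) -> dict:
        """Per-code severity parameters expressed as survival ratios."""
        return dict(zip(self.vocabulary["code"], 1.0 - self.vocabulary["severity"]))


def default_config(n_persons: int = 50_000, seed: int = 0, **overrides) -> GeneratorConfig:
    return dataclasses.replace(GeneratorConfig(n_persons=n_persons, seed=seed), **overrides) \
        if overrides else GeneratorConfig(n_persons=n_persons, seed=seed)


@dataclass
class SynthOutput:
    episodes: pd.DataFrame
    deaths: pd.DataFrame
    truth: pd.DataFrame
    srr_truth: pd.DataFrame

    def __iter__(self):  # (episodes, deaths, truth) unpacking per the API
        return iter((self.episodes, self.deaths, self.truth))


# ---------------------------------------------------------------------------
# Generation


def _hospital_pools():
    return {
        "level1": [f"TL1-{i:02d}" for i in range(1, 11)],
        "regional": [f"TRC-{i:02d}" for i in range(1, 11)],
        "other": [f"OTH-{i:03d}" for i in range(1, 41)],
    }


def generate(config: GeneratorConfig) -> SynthOutput:
    """Simulate linked episode and death tables plus the ground-truth table.

    Bit-reproducible for a fixed config seed.  Returns a :class:`SynthOutput`
    whose ``truth`` frame holds, per simulated injury event, the true ICISS
    values, true outcome probabilities and drawn labels, and whose
    ``srr_truth`` frame holds the model-implied survival ratio per code.
    """
    rng = np.random.default_rng(config.seed)
    n = int(config.n_persons)
    marg = config.marginals
    vocab = config.vocabulary
    codes_arr = vocab["code"].to_numpy()
    sev = vocab["severity"].to_numpy()
    weight = (vocab["weight"] / vocab["weight"].sum()).to_numpy()
    code_index = {c: i for i, c in enumerate(codes_arr)}

    # --- demographics ------------------------------------------------------
    age_p = np.array([marg["age_group"][a] for a in AGE_GROUPS], float)
    age_p /= age_p.sum()
    age_idx = rng.choice(len(AGE_GROUPS), size=n, p=age_p)
    age_lo = np.array([0, 17, 25, 45, 65, 80])
    age_hi = np.array([16, 24, 44, 64, 79, 100])
    age_years = rng.integers(age_lo[age_idx], age_hi[age_idx] + 1)
    age_group = np.array(AGE_GROUPS)[age_idx]

    sex = np.where(rng.random(n) < marg["sex"]["male"] / (marg["sex"]["male"] + marg["sex"]["female"]),
                   "male", "female")
    sex = np.where(rng.random(n) < config.missing_sex_prob, "missing", sex)
    age_missing = rng.random(n) < config.missing_age_prob

    trauma_p = np.array([marg["trauma_level"][t] for t in TRAUMA_LEVELS], float)
    trauma_p /= trauma_p.sum()
    trauma_level = np.array(TRAUMA_LEVELS)[rng.choice(3, size=n, p=trauma_p)]

    # mechanism | age and nature | mechanism via IPF-reconciled joints
    mech_p = np.array([marg["mechanism"][m] for m in MECHANISMS], float)
    mech_p /= mech_p.sum()
    joint_am = ipf(age_p, mech_p, _AGE_MECH_TILT)
    cond_mech = joint_am / joint_am.sum(axis=1, keepdims=True)
    mech_idx = np.array([rng.choice(9, p=cond_mech[a]) for a in age_idx])
    nature_p = np.array([marg["nature"][v] for v in NATURES], float)
    nature_p /= nature_p.sum()
    joint_mn = ipf(mech_p, nature_p, _MECH_NATURE_TILT)
    cond_nat = joint_mn / joint_mn.sum(axis=1, keepdims=True)
    nat_idx = np.array([rng.choice(13, p=cond_nat[m]) for m in mech_idx])
    mechanism = np.array(MECHANISMS)[mech_idx]
    nature = np.array(NATURES)[nat_idx]

    # --- comorbidity ground truth -----------------------------------------
    older = age_idx >= 4
    p_any = np.where(older, marg["charlson_any_65plus"], marg["charlson_any_under65"])
    has_charlson = rng.random(n) < p_any
    split = np.asarray(marg["charlson_group_split"], float)
    split /= split.sum()
    grp_nonzero = rng.choice(np.array(["1-2", "3-4", "5+"]), size=n, p=split)
    cci_group = np.where(has_charlson, grp_nonzero, "0")
    mental = rng.random(n) < marg["mental_health"]
    alcohol = rng.random(n) < marg["alcohol"]
    drug = rng.random(n) < marg["drug"]

    conditions, cci_score = _draw_conditions(rng, cci_group)

    # --- diagnosis codes ---------------------------------------------------
    m_codes = truncated_count_sampler(config.dx_count_dist, n, rng)
    principal = np.empty(n, dtype=object)
    nat_codes = {v: np.flatnonzero((vocab["nature"] == v).to_numpy()) for v in NATURES}
    for v, idxs in nat_codes.items():
        mask = nature == v
        if mask.any():
            w = weight[idxs] / weight[idxs].sum()
            principal[mask] = codes_arr[idxs[rng.choice(len(idxs), size=int(mask.sum()), p=w)]]
    n_extra = m_codes - 1
    extra_flat = rng.choice(len(codes_arr), size=int(n_extra.sum()), p=weight)
    splits = np.cumsum(n_extra)[:-1]
    extras = np.split(extra_flat, splits)
    dx_lists = []
    s_worst = np.empty(n)
    s_mult = np.empty(n)
    worst_code = np.empty(n, dtype=object)
    for i in range(n):
        lst = [principal[i]] + [codes_arr[j] for j in extras[i]]
        dx_lists.append(lst)
        distinct = {code_index[c] for c in lst}
        s_vals = 1.0 - sev[list(distinct)]
        k = int(np.argmin(s_vals))
        s_worst[i] = s_vals[k]
        s_mult[i] = float(np.prod(s_vals))
        worst_code[i] = codes_arr[list(distinct)[k]]

    # --- outcomes ----------------------------------------------------------
    log_w = np.log(s_worst)
    log_m = np.log(s_mult)
    p_death = expit(config.death_coefs.linear_predictor(log_w, log_m, age_group, sex, cci_group))
    p_icu = expit(config.icu_coefs.linear_predictor(log_w, log_m, age_group, sex, cci_group))
    death90 = rng.random(n) < p_death
    icu = rng.random(n) < p_icu

    # --- episode chains ----------------------------------------------------
    study_days = (config.study_end - config.study_start).days
    admit_off = rng.integers(0, study_days + 1, size=n)
    transfer = rng.random(n) < config.transfer_prob
    n_chain = np.where(transfer, np.where(rng.random(n) < 0.7, 2, 3), 1)
    los_last = 1 + rng.poisson(1.5 + 25.0 * (1.0 - s_worst))
    los_last = np.minimum(los_last, 60)
    los_prev1 = np.minimum(1 + rng.poisson(1.0, size=n), 14)
    los_prev2 = np.minimum(1 + rng.poisson(1.0, size=n), 14)
    # destination stay strictly dominates so the LOS rule recovers the drawn
    # treating trauma level exactly
    prev_max = np.where(n_chain >= 2, np.where(n_chain == 3, np.maximum(los_prev1, los_prev2), los_prev1), 0)
    los_last = np.maximum(los_last, prev_max + 1)
    single = n_chain == 1
    los_last = np.where(single & (rng.random(n) < 0.25), np.maximum(los_last - 1, 0), los_last)

    pools = _hospital_pools()
    dest_hosp = np.empty(n, dtype=object)
    dest_pool_idx = {}
    for lvl in TRAUMA_LEVELS:
        mask = trauma_level == lvl
        picks = rng.integers(0, len(pools[lvl]), size=int(mask.sum()))
        dest_hosp[mask] = np.array(pools[lvl], dtype=object)[picks]
        dest_pool_idx[lvl] = picks
    other_pool = np.array(pools["other"], dtype=object)
    send1 = other_pool[rng.integers(0, len(other_pool), size=n)]
    send2 = other_pool[rng.integers(0, len(other_pool), size=n)]
    clash1 = (send1 == dest_hosp)
    send1[clash1] = other_pool[(np.searchsorted(other_pool, send1[clash1]) + 1) % len(other_pool)]
    clash2 = (send2 == dest_hosp) | (send2 == send1)
    send2[clash2] = other_pool[(np.searchsorted(other_pool, send2[clash2]) + 2) % len(other_pool)]

    # death timing
    dd = np.minimum(np.round(rng.exponential(20.0, size=n)).astype(int), 90)
    chain_pre = np.where(n_chain == 3, los_prev1 + los_prev2, np.where(n_chain == 2, los_prev1, 0))
    dd = np.where(death90, np.maximum(dd, chain_pre), dd)  # cannot die before reaching the last hospital
    total_los = chain_pre + los_last
    died_inhosp = death90 & (dd <= total_los)
    sep_last_off = np.where(died_inhosp, dd, total_los)

    late = (~death90) & (rng.random(n) < config.late_death_prob)
    late_dd = 91 + np.round(rng.exponential(100.0, size=n)).astype(int)

    person_id = np.array([f"P{i:06d}" for i in range(n)])
    start = np.datetime64(config.study_start)
    admit_date = start + admit_off.astype("timedelta64[D]")

    dx_str = np.array([";".join(l[1:]) for l in dx_lists], dtype=object)
    ext_cause = np.array([
        _MECH_CODES[m][k] for m, k in zip(mechanism, rng.integers(0, 3, size=n) % np.array([len(_MECH_CODES[m]) for m in mechanism]))
    ], dtype=object)

    age_out = age_years.astype(float)
    age_out[age_missing] = np.nan

    blocks = []
    # first episode of each chain
    first_sep_off = np.where(n_chain == 1, sep_last_off, los_prev1)
    first_mode = np.where(n_chain > 1, "transfer",
                          np.where(died_inhosp, "died_in_hospital", "discharge"))
    blocks.append(pd.DataFrame({
        "person_id": person_id,
        "episode_seq": 0,
        "admit_date": admit_date,
        "sep_date": admit_date + first_sep_off.astype("timedelta64[D]"),
        "hospital_id": np.where(n_chain == 1, dest_hosp, send1),
        "principal_dx": principal,
        "other_dx": dx_str,
        "external_cause": ext_cause,
        "icu_flag": np.where(n_chain == 1, icu, False),
        "sep_mode": first_mode,
        "age_years": age_out,
        "sex": sex,
    }))
    # middle episode (3-chains)
    mid = n_chain == 3
    if mid.any():
        a = admit_date[mid] + los_prev1[mid].astype("timedelta64[D]")
        blocks.append(pd.DataFrame({
            "person_id": person_id[mid],
            "episode_seq": 1,
            "admit_date": a,
            "sep_date": a + los_prev2[mid].astype("timedelta64[D]"),
            "hospital_id": send2[mid],
            "principal_dx": principal[mid],
            "other_dx": "",
            "external_cause": ext_cause[mid],
            "icu_flag": False,
            "sep_mode": "transfer",
            "age_years": age_out[mid],
            "sex": sex[mid],
        }))
    # final episode (2- and 3-chains)
    fin = n_chain > 1
    if fin.any():
        a = admit_date[fin] + chain_pre[fin].astype("timedelta64[D]")
        blocks.append(pd.DataFrame({
            "person_id": person_id[fin],
            "episode_seq": 2,
            "admit_date": a,
            "sep_date": admit_date[fin] + sep_last_off[fin].astype("timedelta64[D]"),
            "hospital_id": dest_hosp[fin],
            "principal_dx": principal[fin],
            "other_dx": "",
            "external_cause": ext_cause[fin],
            "icu_flag": icu[fin],
            "sep_mode": np.where(died_inhosp[fin], "died_in_hospital", "discharge"),
            "age_years": age_out[fin],
            "sex": sex[fin],
        }))

    # comorbidity history episodes in the 12-month lookback window
    pre_rows = _history_episodes(rng, person_id, admit_date, conditions,
                                 mental, alcohol, drug, age_out, sex, other_pool)
    if pre_rows is not None:
        blocks.append(pre_rows)

    episodes = pd.concat(blocks, ignore_index=True)
    episodes = episodes.sort_values(["person_id", "admit_date", "episode_seq"],
                                    kind="mergesort").reset_index(drop=True)
    episodes.insert(1, "episode_id", [f"E{i:07d}" for i in range(len(episodes))])
    # per-episode hospital trauma level
    lvl_of = {}
    for lvl, hs in pools.items():
        for h in hs:
            lvl_of[h] = lvl
    episodes["trauma_level"] = episodes["hospital_id"].map(lvl_of)
    episodes = episodes.drop(columns=["episode_seq"])

    # --- deaths ------------------------------------------------------------
    death_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    death_date[death90] = (admit_date[death90].astype("datetime64[D]")
                           + dd[death90].astype("timedelta64[D]"))
    death_date[late] = (admit_date[late].astype("datetime64[D]")
                        + late_dd[late].astype("timedelta64[D]"))
    fu_end = np.datetime64(config.death_followup_end)
    has_death = (death90 | late) & (death_date <= fu_end)
    deaths = pd.DataFrame({
        "person_id": person_id[has_death],
        "death_date": pd.to_datetime(death_date[has_death]),
    }).reset_index(drop=True)

    # --- truth -------------------------------------------------------------
    truth = pd.DataFrame({
        "person_id": person_id,
        "index_admit_date": pd.to_datetime(admit_date),
        "n_dx": m_codes,
        "true_iciss_worst": s_worst,
        "true_iciss_mult": s_mult,
        "worst_dx": worst_code,
        "p_death90": p_death,
        "p_icu": p_icu,
        "death90": death90,
        "icu": icu,
        "age_group": age_group,
        "sex": sex,
        "trauma_level": trauma_level,
        "mechanism": mechanism,
        "nature": nature,
        "cci_score": cci_score,
        "cci_group": cci_group,
        "mental_health": mental,
        "alcohol": alcohol,
        "drug": drug,
        "n_episodes": n_chain,
    })

    long = pd.DataFrame({
        "code": [c for lst in dx_lists for c in set(lst)],
        "p_death": np.repeat(p_death, [len(set(l)) for l in dx_lists]),
    })
    g = long.groupby("code")["p_death"].agg(["count", "mean"])
    srr_truth = pd.DataFrame({
        "code": g.index,
        "n_carriers": g["count"].to_numpy(),
        "implied_srr": 1.0 - g["mean"].to_numpy(),
    }).reset_index(drop=True)
    srr_truth["severity_param_srr"] = srr_truth["code"].map(config.true_srr)

    return SynthOutput(episodes, deaths, truth, srr_truth)


def _draw_conditions(rng, cci_group):
    """Charlson condition sets realising each person's target score group."""
    n = len(cci_group)
    conditions = [[] for _ in range(n)]
    weights = {c: 1 for c in _W1} | {c: 2 for c in _W2} | {c: 3 for c in _W3} | {c: 6 for c in _W6}
    combos_34 = [("w3",), ("w2", "w1"), ("w2", "w2"), ("w1", "w1", "w1")]
    combos_5p = [("w6",), ("w3", "w2"), ("w6", "w1"), ("w2", "w2", "w1")]
    pools = {"w1": _W1, "w2": _W2, "w3": _W3, "w6": _W6}
    score = np.zeros(n, dtype=int)
    for i, grp in enumerate(cci_group):
        if grp == "0":
            continue
        if grp == "1-2":
            cls = "w1" if rng.random() < 0.7 else "w2"
            picks = [pools[cls][rng.integers(0, len(pools[cls]))]]
        else:
            combos = combos_34 if grp == "3-4" else combos_5p
            combo = combos[rng.choice(len(combos), p=[0.3, 0.4, 0.15, 0.15] if grp == "3-4" else [0.4, 0.3, 0.2, 0.1])]
            picks = []
            for cls in combo:
                pool = [c for c in pools[cls] if c not in picks]
                picks.append(pool[rng.integers(0, len(pool))])
        conditions[i] = picks
        score[i] = sum(weights[c] for c in picks)
    return conditions, score


def _history_episodes(rng, person_id, admit_date, conditions,
                      mental, alcohol, drug, age_out, sex, other_pool):
    """Pre-index admissions carrying comorbidity and condition-flag codes."""
    rows = {k: [] for k in ("person_id", "episode_seq", "admit_date", "sep_date",
                            "hospital_id", "principal_dx", "other_dx", "external_cause",
                            "icu_flag", "sep_mode", "age_years", "sex")}
    n = len(person_id)
    for i in range(n):
        codes = [CONDITION_CODES[c] for c in conditions[i]]
        for flag, present in (("mental_health", mental[i]), ("alcohol", alcohol[i]),
                              ("drug", drug[i])):
            if present:
                opts = _FLAG_CODES[flag]
                codes.append(opts[rng.integers(0, len(opts))])
        if not codes:
            continue
        back = 7 + int(rng.integers(0, 351))
        a = admit_date[i] - np.timedelta64(back, "D")
        rows["person_id"].append(person_id[i])
        rows["episode_seq"].append(-1)
        rows["admit_date"].append(a)
        rows["sep_date"].append(a + np.timedelta64(int(1 + rng.poisson(3.0)), "D"))
        rows["hospital_id"].append(other_pool[rng.integers(0, len(other_pool))])
        rows["principal_dx"].append(codes[0])
        rows["other_dx"].append(";".join(codes[1:]))
        rows["external_cause"].append("")
        rows["icu_flag"].append(False)
        rows["sep_mode"].append("discharge")
        rows["age_years"].append(age_out[i])
        rows["sex"].append(sex[i])
    if not rows["person_id"]:
        return None
    df = pd.DataFrame(rows)
    df["admit_date"] = pd.to_datetime(df["admit_date"])
    df["sep_date"] = pd.to_datetime(df["sep_date"])
    return df


# ---------------------------------------------------------------------------
# CSV output


def write_outputs(out: SynthOutput, out_dir) -> dict:
    """Write episodes/deaths/truth/srr_truth CSVs (ISO-8601 dates)."""
    import pathlib

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("episodes", out.episodes), ("deaths", out.deaths),
                     ("truth", out.truth), ("srr_truth", out.srr_truth)):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, date_format="%Y-%m-%d")
        paths[name] = str(p)
    (out_dir / "data_dictionary.md").write_text(DATA_DICTIONARY)
    paths["data_dictionary"] = str(out_dir / "data_dictionary.md")
    return paths


DATA_DICTIONARY = """\
# Synthetic linked data dictionary

## episodes.csv — one row per hospital episode
| column | meaning |
|---|---|
| person_id | person identifier (links episodes and deaths) |
| episode_id | unique episode identifier |
| admit_date, sep_date | admission / separation dates (ISO-8601) |
| hospital_id | treating hospital of the episode |
| trauma_level | trauma-service level of that hospital: level1, regional, other |
| principal_dx | principal diagnosis (dotted ICD-10-style) |
| other_dx | additional diagnoses, ';'-separated (up to 49) |
| external_cause | external-cause code of the injury ('' for non-injury episodes) |
| icu_flag | ICU admission during the episode |
| sep_mode | discharge, transfer, or died_in_hospital |
| age_years | age at admission (blank if missing) |
| sex | male, female, or missing |

## deaths.csv — death registry
person_id, death_date (ISO-8601).

## truth.csv — per simulated injury event
True ICISS values (worst / multiplicative), worst code, true outcome
probabilities, drawn outcome labels, demographics, Charlson score/group and
condition flags, number of diagnosis codes and chain length.

## srr_truth.csv — per diagnosis code
n_carriers; implied_srr = 1 - mean true death probability of carriers (the
estimand of survival-risk-ratio estimation); severity_param_srr = the raw
per-code severity parameter that drives the generating model.
"""
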