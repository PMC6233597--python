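"""Discrimination, fit and calibration statistics with bootstrap optimism
correction.

Implements the four model-assessment statistics from first principles:

* c-statistic — probability a randomly chosen event outranks a randomly
  chosen non-event (ties count one half); equals the area under the ROC
  curve, computed here from rank sums in O(n log n);
* AIC — ``-2 loglik + 2 k`` with ``k`` counting every estimated coefficient
  including the intercept;
* Nagelkerke R² — the Cox-Snell pseudo-R² rescaled to a maximum of one:
  ``[1 - exp((2/n)(ll0 - ll))] / [1 - exp((2/n) ll0)]``;
* Hosmer-Lemeshow — risk-decile chi-square ``sum (O-E)^2 / (E (1 - E/n_g))``
  over equal-count groups of predicted risk (ties kept together; degenerate
  groups skipped with a warning counter).

Internal validation follows the optimism-bootstrap: fit the model on the
full data (apparent statistics); for each of B replicates resample periods
of care with replacement, refit, evaluate on the resample and on the
original data, and take the difference as that replicate's optimism; the
mean optimism is subtracted from the apparent statistics, with percentile
confidence intervals over the per-replicate corrected values.  A time-based
split-sample alternative (train before a cut date, test on or after) is
provided for comparison.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .exceptions import (ConfigError, ConvergenceError, DegenerateStatisticError,
                         EmptyDataError, IcissError, SeparationError)
from .models import FitResult, IcissLogisticRegression, ModelSpec
from .severity import SurvivalRiskRatioScorer

__all__ = [
    "FitStats",
    "ValidationReport",
    "CalibrationCurve",
    "c_statistic",
    "aic",
    "nagelkerke_r2",
    "hosmer_lemeshow",
    "calibration_curve",
    "bootstrap_optimism",
    "confidence_intervals",
    "split_sample_validation",
    "evaluate_predictions",
]

_FIELDS = ("aic", "r2_nagelkerke", "hl_statistic", "c_statistic")


@dataclass(frozen=True)
class FitStats:
    aic: float
    r2_nagelkerke: float
    hl_statistic: float
    c_statistic: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _FIELDS], float)

    @classmethod
    def from_array(cls, a) -> "FitStats":
        return cls(*[float(v) for v in a])

    def __sub__(self, other: "FitStats") -> "FitStats":
        return FitStats.from_array(self.as_array() - other.as_array())

    def to_dict(self) -> dict:
        return {f: float(getattr(self, f)) for f in _FIELDS}


@dataclass
class ValidationReport:
    apparent: FitStats
    optimism: FitStats
    adjusted: FitStats
    ci_lower: FitStats
    ci_upper: FitStats
    n_replicates: int
    seed: int
    n_failed: int = 0
    spec: ModelSpec | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k).to_dict()
             for k in ("apparent", "optimism", "adjusted", "ci_lower", "ci_upper")}
        d["n_replicates"] = self.n_replicates
        d["seed"] = self.seed
        d["n_failed"] = self.n_failed
        if self.spec is not None:
            d["model"] = {"outcome": self.spec.outcome, "variant": self.spec.iciss_variant,
                          "label": self.spec.label, "covariates": list(self.spec.covariates)}
        return d


@dataclass
class CalibrationCurve:
    bins: pd.DataFrame  # mean_predicted, observed_rate, n
    rule: str

    @property
    def n_total(self) -> int:
        return int(self.bins["n"].sum())


# ---------------------------------------------------------------------------
# Statistics


def _check_binary(y, p):
    y = np.asarray(y, int)
    p = np.asarray(p, float)
    if y.shape != p.shape:
        raise ConfigError("y and p must have the same length")
    n1 = int(y.sum())
    if n1 == 0 or n1 == len(y):
        raise DegenerateStatisticError("both outcome classes must be present")
    return y, p, n1, len(y) - n1


def c_statistic(y, p) -> float:
    """Concordance: fraction of (event, non-event) pairs ranked correctly,
    ties counted one half.  Equals the area under the ROC curve."""
    y, p, n1, n0 = _check_binary(y, p)
    ranks = rankdata(p)  # average ranks handle ties as 1/2 automatically
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _loglik_bernoulli(y, p) -> float:
    p = np.clip(np.asarray(p, float), 1e-300, 1.0 - 1e-16)
    y = np.asarray(y, float)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def aic(fit, k: int | None = None) -> float:
    """Akaike information criterion, ``-2 loglik + 2 k`` (lower is better)."""
    if isinstance(fit, FitResult):
        return -2.0 * fit.loglik + 2.0 * fit.k
    return -2.0 * float(fit) + 2.0 * int(k)


def nagelkerke_r2(fit, loglik_null: float | None = None, n: int | None = None) -> float:
    """Nagelkerke's rescaled pseudo R² in [0, 1]."""
    if isinstance(fit, FitResult):
        ll, ll0, n = fit.loglik, fit.loglik_null, fit.n
    else:
        ll, ll0 = float(fit), float(loglik_null)
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll0 - ll))
    max_cs = 1.0 - np.exp((2.0 / n) * ll0)
    if max_cs <= 0:
        raise DegenerateStatisticError("null log-likelihood of zero: R² undefined")
    return float(cox_snell / max_cs)


def hosmer_lemeshow(y, p, n_groups: int = 10, return_table: bool = False):
    """Hosmer-Lemeshow chi-square over equal-count groups of predicted risk.

    Groups are deciles of ``p`` (ties kept in one group); groups whose
    expected count is 0 or n_g are skipped (counts available in the table
    via ``return_table=True``)."""
    if n_groups < 2:
        raise ConfigError("n_groups must be at least 2")
    y, p, _, _ = _check_binary(y, p)
    if len(y) < n_groups:
        raise ConfigError("need at least one observation per group")
    labels = pd.qcut(pd.Series(p).rank(method="average"), q=n_groups, duplicates="drop")
    df = pd.DataFrame({"y": y, "p": p, "g": labels.to_numpy()})
    rows = []
    stat = 0.0
    skipped = 0
    for _, grp in df.groupby("g", observed=True, sort=True):
        n_g = len(grp)
        obs = float(grp["y"].sum())
        exp = float(grp["p"].sum())
        if exp <= 0.0 or exp >= n_g:
            skipped += 1
            warnings.warn("Hosmer-Lemeshow group with degenerate expected count skipped")
            contrib = np.nan
        else:
            contrib = (obs - exp) ** 2 / (exp * (1.0 - exp / n_g))
            stat += contrib
        rows.append({"n": n_g, "observed": obs, "expected": exp, "contribution": contrib})
    if return_table:
        return float(stat), pd.DataFrame(rows)
    return float(stat)


def calibration_curve(y, p, n_bins: int = 10) -> CalibrationCurve:
    """Equal-width bins on predicted probability [0, 1]; empty bins omitted."""
    y = np.asarray(y, int)
    p = np.asarray(p, float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        rows.append({"bin": b, "mean_predicted": float(p[mask].mean()),
                     "observed_rate": float(y[mask].mean()), "n": int(mask.sum())})
    return CalibrationCurve(pd.DataFrame(rows),
                            rule=f"{n_bins} equal-width bins on [0, 1]")


def evaluate_predictions(y, p, k: int) -> FitStats:
    """All four statistics for predictions ``p`` of binary ``y`` from a model
    with ``k`` estimated coefficients (log-likelihood recomputed from p)."""
    y = np.asarray(y, int)
    ll = _loglik_bernoulli(y, p)
    n = len(y)
    n1 = int(y.sum())
    base = n1 / n
    ll0 = _loglik_bernoulli(y, np.full(n, base))
    return FitStats(
        aic=aic(ll, k),
        r2_nagelkerke=nagelkerke_r2(ll, ll0, n),
        hl_statistic=hosmer_lemeshow(y, p),
        c_statistic=c_statistic(y, p),
    )


# ---------------------------------------------------------------------------
# Bootstrap optimism correction


def _resample_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    """n-out-of-n resample with replacement (seam for tests)."""
    return rng.integers(0, n, size=n)


def _evaluate_estimator(est: IcissLogisticRegression, periods: pd.DataFrame) -> FitStats:
    design, y = est.design_and_outcome(periods)
    p = expit(design.to_numpy() @ est.result_.params)
    return evaluate_predictions(y, p, k=len(est.result_.params))


def bootstrap_optimism(periods: pd.DataFrame, spec: ModelSpec, B: int = 200,
                       seed: int = 0, iciss_form: str = "linear",
                       reestimate_srr: bool = False,
                       srr_outcome: str = "death90",
                       max_failed_frac: float = 0.05) -> ValidationReport:
    """Optimism-corrected fit statistics for one model specification.

    The resampling unit is the period of care.  Replicate b draws its own
    generator seeded ``seed + b`` so results are invariant to execution
    order.  By default the SRR table (hence the ICISS columns already on
    ``periods``) is held fixed across replicates — the model, not the
    severity table, is what is bootstrapped; ``reestimate_srr=True`` rebuilds
    the SRR table inside each replicate for the stricter variant.
    """
    periods = periods.reset_index(drop=True)
    if reestimate_srr:
        scorer = SurvivalRiskRatioScorer(outcome=srr_outcome).fit(periods)
        full = scorer.transform(periods)
    else:
        full = periods
    est = IcissLogisticRegression.from_spec(spec, iciss_form).fit(full)
    apparent = FitStats(
        aic=aic(est.result_),
        r2_nagelkerke=nagelkerke_r2(est.result_),
        hl_statistic=hosmer_lemeshow(est.design_and_outcome(full)[1], est.result_.fitted_p),
        c_statistic=c_statistic(est.design_and_outcome(full)[1], est.result_.fitted_p),
    )

    n = len(periods)
    optimisms = []
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng(seed + b)
        idx = _resample_indices(rng, n)
        boot = periods.iloc[idx].reset_index(drop=True)
        try:
            if reestimate_srr:
                sc_b = SurvivalRiskRatioScorer(outcome=srr_outcome).fit(boot)
                boot_scored = sc_b.transform(boot)
                orig_scored = sc_b.transform(periods)
            else:
                boot_scored, orig_scored = boot, full
            est_b = IcissLogisticRegression.from_spec(spec, iciss_form).fit(boot_scored)
            boot_stats = _evaluate_estimator(est_b, boot_scored)
            test_stats = _evaluate_estimator(est_b, orig_scored)
        except (ConvergenceError, SeparationError, DegenerateStatisticError):
            n_failed += 1
            continue
        optimisms.append((boot_stats - test_stats).as_array())
    if B > 0 and n_failed / B > max_failed_frac:
        raise IcissError(f"{n_failed}/{B} bootstrap replicates failed")
    if not optimisms:
        raise IcissError("no successful bootstrap replicates")
    opt = np.vstack(optimisms)
    mean_opt = FitStats.from_array(opt.mean(axis=0))
    adjusted = apparent - mean_opt
    corrected = apparent.as_array()[None, :] - opt
    lo, hi = confidence_intervals(corrected)
    return ValidationReport(
        apparent=apparent, optimism=mean_opt, adjusted=adjusted,
        ci_lower=lo, ci_upper=hi, n_replicates=len(optimisms),
        seed=seed, n_failed=n_failed, spec=spec,
    )


def confidence_intervals(corrected: np.ndarray, level: float = 0.95):
    """Percentile bounds over per-replicate optimism-corrected statistics.

    ``corrected`` is (B, 4) in field order (aic, R², H-L, c)."""
    if not 0.0 < level < 1.0:
        raise ConfigError("confidence level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(corrected, 100 * alpha, axis=0)
    hi = np.percentile(corrected, 100 * (1 - alpha), axis=0)
    return FitStats.from_array(lo), FitStats.from_array(hi)


# ---------------------------------------------------------------------------
# Split-sample alternative


def split_sample_validation(periods: pd.DataFrame, spec: ModelSpec, split_date,
                            iciss_form: str = "linear",
                            srr_outcome: str = "death90",
                            min_count: int = 1) -> FitStats:
    """Time-based split-sample validation: SRRs and model fitted on
    admissions before ``split_date``, statistics computed on or after it."""
    periods = periods.reset_index(drop=True)
    admit = pd.to_datetime(periods["index_admit_date"])
    cut = pd.Timestamp(split_date)
    train = periods.loc[admit < cut]
    test = periods.loc[admit >= cut]
    if len(train) == 0 or len(test) == 0:
        raise EmptyDataError("both halves of the split must be non-empty")
    for half, name in ((train, "training"), (test, "test")):
        s = half[spec.outcome].astype(bool)
        if s.all() or not s.any():
            raise DegenerateStatisticError(f"{name} half lacks one outcome class")
    scorer = SurvivalRiskRatioScorer(outcome=srr_outcome, min_count=min_count).fit(train)
    est = IcissLogisticRegression.from_spec(spec, iciss_form).fit(scorer.transform(train))
    return _evaluate_estimator(est, scorer.transform(test))
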