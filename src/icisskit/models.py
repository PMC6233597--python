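"""Nested logistic model suites for 90-day mortality and ICU admission.

Each model enters one ICISS variant (multiplicative or single worst-injury)
as a continuous term together with an incremental covariate set drawn from
age group, sex, Charlson group, the three condition flags, trauma-service
level, injury mechanism and nature of injury.  The registry mirrors the
standard suite: eight nested specifications for 90-day mortality and seven
for ICU admission, labelled M1..M8.

Categorical covariates are expanded to treatment-coded indicators against
fixed reference levels (age 25-44, male, Charlson 0, other hospital, and the
'Other and unspecified' mechanism/nature categories); references affect only
coefficient labels, not fit statistics.  Rows with missing age or sex are
dropped listwise and counted.  Maximum likelihood is obtained by Newton /
iteratively-reweighted least squares with step halving; non-convergence and
perfect separation raise explicit errors, while quasi-complete separation in
a sparse covariate cell converges with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .codes import AGE_GROUPS, CCI_GROUPS, MECHANISMS, NATURES, TRAUMA_LEVELS
from .exceptions import ConfigError, ConvergenceError, SeparationError

__all__ = [
    "ModelSpec",
    "FitResult",
    "model_registry",
    "encode_design",
    "fit_logistic",
    "IcissLogisticRegression",
]

CATEGORICALS: dict[str, tuple[tuple, str]] = {
    "age_group": (AGE_GROUPS, "25-44"),
    "sex": (("male", "female"), "male"),
    "cci_group": (CCI_GROUPS, "0"),
    "trauma_level": (TRAUMA_LEVELS, "other"),
    "mechanism": (MECHANISMS, "Other and unspecified injury mechanism"),
    "nature": (NATURES, "Other and unspecified injuries"),
}
BOOLEANS = ("mental_health", "alcohol", "drug")

_MORTALITY_SUITE = [
    ("M1", ("age_group", "sex")),
    ("M2", ("age_group", "sex", "cci_group")),
    ("M3", ("age_group", "sex", "cci_group", "mental_health", "drug", "alcohol")),
    ("M4", ("age_group", "sex", "cci_group", "mental_health", "drug", "alcohol",
            "trauma_level")),
    ("M5", ("age_group", "sex", "cci_group", "mechanism", "nature")),
    ("M6", ("age_group", "sex", "cci_group", "mechanism", "trauma_level")),
    ("M7", ("age_group", "sex", "cci_group", "mechanism", "nature", "trauma_level")),
    ("M8", ("age_group", "sex", "cci_group", "mental_health", "drug", "alcohol",
            "mechanism", "nature", "trauma_level")),
]
_ICU_SUITE = [
    ("M1", ("age_group", "sex")),
    ("M2", ("age_group", "sex", "cci_group")),
    ("M3", ("age_group", "sex", "cci_group", "mental_health", "drug", "alcohol")),
    ("M4", ("age_group", "sex", "cci_group", "mechanism")),
    ("M5", ("age_group", "sex", "cci_group", "nature")),
    ("M6", ("age_group", "sex", "cci_group", "mechanism", "nature")),
    ("M7", ("age_group", "sex", "cci_group", "mental_health", "drug", "alcohol",
            "mechanism", "nature")),
]


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    iciss_variant: str
    covariates: tuple
    label: str

    @property
    def iciss_column(self) -> str:
        return {"mult": "iciss_mult", "worst": "iciss_worst"}[self.iciss_variant]


@dataclass
class FitResult:
    coefficients: dict
    params: np.ndarray
    columns: list
    loglik: float
    loglik_null: float
    n: int
    k: int
    fitted_p: np.ndarray
    n_dropped: int = 0
    spec: ModelSpec | None = None


def model_registry(outcome: str, iciss_variant: str = "worst") -> list[ModelSpec]:
    """The nested model suite for one outcome and ICISS variant
    (8 specifications for death90, 7 for icu)."""
    if outcome == "death90":
        suite = _MORTALITY_SUITE
    elif outcome == "icu":
        suite = _ICU_SUITE
    else:
        raise ConfigError(f"unknown outcome {outcome!r}")
    if iciss_variant not in ("mult", "worst"):
        raise ConfigError(f"unknown ICISS variant {iciss_variant!r}")
    return [ModelSpec(outcome, iciss_variant, covs, label) for label, covs in suite]


def _iciss_term(values: pd.Series, form: str) -> np.ndarray:
    v = np.asarray(values, float)
    if form == "linear":
        return v
    if form == "log":
        return np.log(np.clip(v, 1e-12, None))
    if form == "logit":
        return logit(np.clip(v, 1e-9, 1.0 - 1e-9))
    raise ConfigError(f"unknown ICISS functional form {form!r}")


def encode_design(periods: pd.DataFrame, spec: ModelSpec,
                  iciss_form: str = "linear"):
    """(X, y, n_dropped): treatment-coded design matrix with intercept.

    Categorical covariates are expanded against the registry's fixed level
    lists; an unseen level raises an error naming it.  Covariate names not
    in the registry are passed through as numeric columns.  Rows with
    missing age or sex (and rows missing any requested column) are dropped
    listwise and counted.
    """
    df = periods.reset_index(drop=True)
    keep = pd.Series(True, index=df.index)
    if "sex" in df.columns:
        keep &= df["sex"].isin(("male", "female"))
    if "age_group" in df.columns:
        keep &= df["age_group"].isin(AGE_GROUPS)
    n_dropped = int((~keep).sum())
    df = df.loc[keep]

    cols = {"const": np.ones(len(df))}
    cols["iciss"] = _iciss_term(df[spec.iciss_column], iciss_form)
    for cov in spec.covariates:
        if cov in CATEGORICALS:
            levels, ref = CATEGORICALS[cov]
            vals = df[cov]
            unknown = set(vals.unique()) - set(levels)
            if unknown:
                raise ConfigError(f"unknown level(s) {sorted(unknown)} in covariate {cov!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{cov}[{lev}]"] = (vals == lev).to_numpy(dtype=float)
        elif cov in BOOLEANS:
            cols[cov] = df[cov].astype(float).to_numpy()
        else:
            cols[cov] = pd.to_numeric(df[cov]).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    y = df[spec.outcome].astype(int)
    return X, y, n_dropped


def _null_loglik(y: np.ndarray) -> float:
    n = len(y)
    n1 = int(np.sum(y))
    n0 = n - n1
    ll = 0.0
    if n1:
        ll += n1 * np.log(n1 / n)
    if n0:
        ll += n0 * np.log(n0 / n)
    return float(ll)


def _bernoulli_loglik(y, p) -> float:
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def fit_logistic(X: pd.DataFrame, y, spec: ModelSpec | None = None,
                 n_dropped: int = 0, maxiter: int = 100,
                 score_tol: float = 1e-8, loglik_tol: float = 1e-10) -> FitResult:
    """Maximum-likelihood logistic fit by Newton / iteratively-reweighted
    least squares with step halving.

    Convergence: max absolute score below ``score_tol`` or relative
    log-likelihood change below ``loglik_tol``.  Perfect separation (deviance
    collapsing to zero with diverging coefficients) raises
    :class:`SeparationError`; quasi-complete separation — e.g. a sparse
    indicator with no events, where the likelihood converges while that one
    coefficient drifts — is reported as a warning, matching how mainstream
    GLM fitters treat it.  Non-convergence raises :class:`ConvergenceError`
    carrying the last iterate.
    """
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome is single-class; model is degenerate")
    if len(y) <= X.shape[1]:
        raise ConfigError(f"n={len(y)} not greater than parameter count {X.shape[1]}")
    A = np.asarray(X, float)
    n, k = A.shape
    beta = np.zeros(k)
    beta[0] = logit(np.clip(y.mean(), 1e-12, 1 - 1e-12))  # stable start at the base rate
    p = expit(A @ beta)
    ll = _bernoulli_loglik(y, p)
    converged = False
    for _ in range(maxiter):
        score = A.T @ (y - p)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (A * w[:, None]).T @ A
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.trace(H) / k * np.eye(k), score)
        new_ll = -np.inf
        for _half in range(40):
            cand = beta + step
            new_ll = _bernoulli_loglik(y, expit(A @ cand))
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        p = expit(A @ beta)
        rel_change = abs(new_ll - ll) / (abs(ll) + 1e-12)
        ll = new_ll
        if rel_change < loglik_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations", last_params=beta)
    if np.max(np.abs(beta)) > 30:
        if np.mean(np.abs(y - p)) < 1e-6:
            raise SeparationError("perfect separation: fitted probabilities are 0/1")
        warnings.warn("quasi-complete separation: a coefficient diverged while the "
                      "likelihood converged (sparse covariate cell)", stacklevel=2)
    return FitResult(
        coefficients=dict(zip(X.columns, beta)),
        params=beta,
        columns=list(X.columns),
        loglik=ll,
        loglik_null=_null_loglik(y.astype(int)),
        n=n,
        k=k,
        fitted_p=p,
        n_dropped=n_dropped,
        spec=spec,
    )


class IcissLogisticRegression(BaseEstimator):
    """Logistic outcome model for one ICISS variant plus covariates.

    sklearn-style estimator: ``fit(periods)`` encodes the design and fits by
    maximum likelihood; ``predict_proba(periods)`` scores new periods with
    the same encoding.  The fitted :class:`FitResult` lives in ``result_``.

    Parameters
    ----------
    outcome : {'death90', 'icu'}
    iciss_variant : {'worst', 'mult'}
    covariates : tuple of covariate names (registry categoricals, the three
        boolean flags, or numeric passthrough columns)
    iciss_form : {'linear', 'log', 'logit'}
        Functional form of the ICISS term (default linear: the score enters
        untransformed).
    label : str, informational tag (e.g. 'M8')
    """

    def __init__(self, outcome="death90", iciss_variant="worst",
                 covariates=("age_group", "sex"), iciss_form="linear",
                 label=""):
        self.outcome = outcome
        self.iciss_variant = iciss_variant
        self.covariates = covariates
        self.iciss_form = iciss_form
        self.label = label

    @classmethod
    def from_spec(cls, spec: ModelSpec, iciss_form="linear"):
        return cls(outcome=spec.outcome, iciss_variant=spec.iciss_variant,
                   covariates=spec.covariates, iciss_form=iciss_form,
                   label=spec.label)

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.outcome, self.iciss_variant,
                         tuple(self.covariates), self.label)

    def fit(self, X: pd.DataFrame, y=None):
        design, yy, n_dropped = encode_design(X, self.spec, self.iciss_form)
        self.result_ = fit_logistic(design, yy, self.spec, n_dropped)
        self.coef_ = self.result_.params
        self.n_features_in_ = design.shape[1]
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        design, _, _ = encode_design(X, self.spec, self.iciss_form)
        eta = design.to_numpy() @ self.result_.params
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def design_and_outcome(self, X: pd.DataFrame):
        """Encoded design and outcome for external evaluation (e.g. on a
        bootstrap resample or held-out periods)."""
        design, yy, _ = encode_design(X, self.spec, self.iciss_form)
        return design, np.asarray(yy, int)
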