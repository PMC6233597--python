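"""One-command orchestration: generate -> link -> comorbidity -> SRR/ICISS ->
model suites -> bootstrap validation, with a run manifest and a descriptive
summary panel (counts and percents by demographic and injury category).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import platform


import pandas as pd

from . import __version__
from .comorbidity import attach_comorbidity
from .linkage import LinkageLog, build_periods, flag_death90, select_index_admissions
from .models import IcissLogisticRegression, model_registry
from .severity import SurvivalRiskRatioScorer
from .synth import GeneratorConfig, default_config, generate, write_outputs
from .validation import aic, bootstrap_optimism, calibration_curve, nagelkerke_r2

__all__ = ["run_all", "describe", "percents_from_counts", "periods_to_csv", "periods_from_csv"]

_LIST_COLS = ("episode_ids", "all_injury_dx")


def periods_to_csv(periods: pd.DataFrame, path):
    df = periods.copy()
    for c in _LIST_COLS:
        if c in df.columns:
            df[c] = df[c].map(lambda v: ";".join(v) if isinstance(v, (list, tuple)) else v)
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


def periods_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["index_admit_date", "final_sep_date"])
    for c in _LIST_COLS:
        if c in df.columns:
            df[c] = df[c].fillna("").map(lambda v: [x for x in str(v).split(";") if x])
    return df


def _table_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode()
    ).hexdigest()[:16]


def run_all(config: GeneratorConfig | None = None, out_dir="iciss_run",
            b_replicates: int = 200, validate: bool = True,
            iciss_form: str = "linear", seed: int | None = None) -> dict:
    """Run the full pipeline and write all artefacts to ``out_dir``.

    Returns the run manifest (also written as ``manifest.json``).  Bootstrap
    validation covers the best mortality model (worst-injury ICISS, M8) and
    the best ICU model (multiplicative ICISS, M7).
    """
    if config is None:
        config = default_config(seed=0 if seed is None else seed)
    elif seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    synth_out = generate(config)
    write_outputs(synth_out, out_dir)
    episodes, deaths = synth_out.episodes, synth_out.deaths

    log = LinkageLog()
    periods = build_periods(episodes, log=log)
    n_periods_all = len(periods)
    index_periods = select_index_admissions(periods, config.study_start, config.study_end)
    n_index = len(index_periods)
    index_periods["death90"] = flag_death90(index_periods, deaths, log=log).to_numpy()
    index_periods = index_periods.rename(columns={"icu_any": "icu"})
    index_periods = attach_comorbidity(index_periods, episodes)
    index_periods = index_periods.rename(columns={"treating_trauma_level": "trauma_level"})

    scorer = SurvivalRiskRatioScorer(outcome="death90").fit(index_periods)
    scored = scorer.transform(index_periods)
    scorer.srr_table_.to_csv(out_dir / "srr_table.csv", index=False)
    periods_to_csv(scored, out_dir / "periods.csv")

    describe(scored).to_csv(out_dir / "describe.csv", index=False)

    fits = []
    with open(out_dir / "model_fits.jsonl", "w") as fh:
        for outcome in ("death90", "icu"):
            for variant in ("mult", "worst"):
                for spec in model_registry(outcome, variant):
                    est = IcissLogisticRegression.from_spec(spec, iciss_form).fit(scored)
                    rec = {
                        "outcome": outcome, "variant": variant, "label": spec.label,
                        "covariates": list(spec.covariates),
                        "n": est.result_.n, "k": est.result_.k,
                        "n_dropped": est.result_.n_dropped,
                        "loglik": est.result_.loglik,
                        "aic": aic(est.result_),
                        "r2_nagelkerke": nagelkerke_r2(est.result_),
                        "coefficients": {k: float(v) for k, v in est.result_.coefficients.items()},
                    }
                    fh.write(json.dumps(rec) + "\n")
                    fits.append(rec)

    reports = {}
    if validate:
        for outcome, variant, label in (("death90", "worst", "M8"), ("icu", "mult", "M7")):
            spec = next(s for s in model_registry(outcome, variant) if s.label == label)
            rep = bootstrap_optimism(scored, spec, B=b_replicates,
                                     seed=config.seed, iciss_form=iciss_form)
            reports[f"{outcome}_{variant}_{label}"] = rep.to_dict()
            est = IcissLogisticRegression.from_spec(spec, iciss_form).fit(scored)
            _, y = est.design_and_outcome(scored)
            curve = calibration_curve(y, est.result_.fitted_p)
            curve.bins.to_csv(out_dir / f"calibration_{outcome}_{label}.csv", index=False)
        with open(out_dir / "validation.json", "w") as fh:
            json.dump(reports, fh, indent=2)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_persons": config.n_persons,
        "stages": {
            "episodes_generated": len(episodes),
            "deaths_generated": len(deaths),
            "periods_built": n_periods_all,
            "index_periods": n_index,
            "excluded_non_index": n_periods_all - n_index,
            "srr_codes": len(scorer.srr_table_),
            "models_fitted": len(fits),
        },
        "warnings": {
            "overlapping_episodes_merged": log.overlapping_episodes_merged,
            "deaths_before_admission": log.deaths_before_admission,
        },
        "hashes": {
            "episodes": _table_hash(episodes),
            "periods": _table_hash(scored.drop(columns=list(_LIST_COLS))),
            "srr_table": _table_hash(scorer.srr_table_),
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# Descriptive panel


def percents_from_counts(block_counts: dict, denominator: int | None = None) -> dict:
    """Percent (one decimal) of each level within a block of counts.

    The denominator defaults to the block total, i.e. the non-missing count.
    """
    total = denominator if denominator is not None else sum(block_counts.values())
    if total <= 0:
        return {k: float("nan") for k in block_counts}
    return {k: round(100.0 * v / total, 1) for k, v in block_counts.items()}


_BLOCKS = (
    ("sex", ("male", "female")),
    ("age_group", None),
    ("cci_group", None),
    ("trauma_level", None),
    ("mechanism", None),
    ("nature", None),
)
_FLAG_ROWS = ("mental_health", "alcohol", "drug", "icu", "death90")


def describe(periods: pd.DataFrame) -> pd.DataFrame:
    """Counts and percents by sex, age group, Charlson group, condition
    flags, trauma level, mechanism, nature, ICU admission and 90-day death.

    Percents use non-missing denominators within each block; missing counts
    are reported as their own rows (footnote style).
    """
    n_total = len(periods)
    rows = []
    for block, keep in _BLOCKS:
        if block not in periods.columns:
            continue
        vals = periods[block].astype(str)
        missing_mask = vals.isin(("missing", "nan", "None", ""))
        counts = vals[~missing_mask].value_counts()
        if keep is not None:
            counts = counts.reindex(keep, fill_value=0)
        pct = percents_from_counts(counts.to_dict())
        for level, cnt in counts.items():
            rows.append({"block": block, "level": level, "count": int(cnt),
                         "percent": pct[level]})
        n_miss = int(missing_mask.sum())
        if n_miss:
            rows.append({"block": block, "level": "(missing)", "count": n_miss,
                         "percent": float("nan")})
    for flag in _FLAG_ROWS:
        col = flag if flag in periods.columns else \
            ("icu_any" if flag == "icu" and "icu_any" in periods.columns else None)
        if col is None:
            continue
        cnt = int(periods[col].astype(bool).sum())
        rows.append({"block": flag, "level": "yes", "count": cnt,
                     "percent": round(100.0 * cnt / n_total, 1)})
    return pd.DataFrame(rows)
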