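"""Assessment statistics against exhaustive oracles, and the optimism
bootstrap: exact identities, degenerate cases, overfitting direction, and
behaviour for a correctly specified model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import icisskit.validation as vmod
from icisskit.exceptions import ConfigError, DegenerateStatisticError, EmptyDataError
from icisskit.models import ModelSpec, model_registry
from icisskit.validation import (FitStats, aic, bootstrap_optimism, c_statistic,
                                 calibration_curve, confidence_intervals,
                                 hosmer_lemeshow, nagelkerke_r2,
                                 split_sample_validation)


def brute_force_c(y, p):
    """O(n^2) pairwise concordance count."""
    events = p[y == 1]
    nonevents = p[y == 0]
    num = 0.0
    for pe in events:
        for pn in nonevents:
            num += 1.0 if pe > pn else (0.5 if pe == pn else 0.0)
    return num / (len(events) * len(nonevents))


class TestCStatistic:
    def test_perfect_ranking(self):
        assert c_statistic([0, 1], [0.2, 0.7]) == 1.0

    def test_all_ties_give_half(self):
        assert c_statistic([0, 1, 0, 1], [0.3] * 4) == 0.5

    @pytest.mark.parametrize("seed,n", [(0, 60), (1, 120), (2, 200)])
    def test_equals_exhaustive_pair_count(self, seed, n):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        y[0], y[1] = 0, 1  # guarantee both classes
        p = rng.choice(np.linspace(0, 1, 17), size=n)  # many ties
        assert c_statistic(y, p) == pytest.approx(brute_force_c(y, p), abs=1e-12)

    def test_agrees_with_reference_auc(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 500)
        p = rng.random(500)
        assert c_statistic(y, p) == pytest.approx(sk.roc_auc_score(y, p), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(DegenerateStatisticError):
            c_statistic([1, 1, 1], [0.2, 0.5, 0.9])

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.floats(0, 1, allow_nan=False)),
                    min_size=4, max_size=60))
    def test_pairwise_property(self, pairs):
        y = np.array([a for a, _ in pairs])
        p = np.array([b for _, b in pairs])
        if y.sum() in (0, len(y)):
            return
        assert c_statistic(y, p) == pytest.approx(brute_force_c(y, p), abs=1e-12)


class TestAic:
    def test_formula(self):
        assert aic(-100.0, 3) == 206.0

    def test_better_loglik_same_k_gives_lower_aic(self):
        assert aic(-90.0, 3) < aic(-100.0, 3)

    def test_intercept_only_closed_form(self):
        ll = 3 * np.log(0.3) + 7 * np.log(0.7)
        assert aic(ll, 1) == pytest.approx(14.217, abs=5e-4)


class TestNagelkerke:
    def test_zero_when_model_equals_null(self):
        assert nagelkerke_r2(-6.73, -6.73, n=10) == 0.0

    def test_one_at_perfect_fit(self):
        assert nagelkerke_r2(0.0, -6.73, n=10) == pytest.approx(1.0)

    def test_plug_in_arithmetic(self):
        # independent plug-in: [1-exp((2/10)(-6.7301+4))]/[1-exp((2/10)(-6.7301))]
        assert nagelkerke_r2(-4.0, -6.7301, n=10) == pytest.approx(0.568791, abs=1e-5)


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups_score_zero(self):
        p = np.array([0.2] * 10 + [0.6] * 10)
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0] + [1] * 6 + [0] * 4)
        assert hosmer_lemeshow(y, p, n_groups=2) == pytest.approx(0.0, abs=1e-12)

    def test_two_group_hand_fixture(self):
        p = np.array([0.1] * 10 + [0.3] * 10)
        y = np.array([1, 1] + [0] * 8 + [1] * 4 + [0] * 6)
        # group 1: O=2, E=1, n=10 -> 1/(1*0.9); group 2: O=4, E=3, n=10 -> 1/(3*0.7)
        expected = 1 / 0.9 + 1 / 2.1
        assert hosmer_lemeshow(y, p, n_groups=2) == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        y = (rng.random(100) < p).astype(int)
        stat = hosmer_lemeshow(y, p)
        perm = rng.permutation(100)
        assert hosmer_lemeshow(y[perm], p[perm]) == pytest.approx(stat, abs=1e-10)

    def test_miscalibration_increases_statistic(self):
        p = np.array([0.2] * 10 + [0.6] * 10)
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0] + [1] * 6 + [0] * 4)
        drifted = np.clip(p + 0.15, 0, 1)
        assert hosmer_lemeshow(y, drifted, n_groups=2) > hosmer_lemeshow(y, p, n_groups=2)

    def test_input_guards(self):
        with pytest.raises(ConfigError):
            hosmer_lemeshow([0, 1], [0.1, 0.9], n_groups=1)
        with pytest.raises(ConfigError):
            hosmer_lemeshow([0, 1, 1], [0.1, 0.9, 0.8], n_groups=10)


class TestCalibrationCurve:
    def test_perfect_predictions_on_diagonal(self):
        y = np.array([0] * 50 + [1] * 50)
        p = y.astype(float) * 0.999
        curve = calibration_curve(y, p)
        for _, row in curve.bins.iterrows():
            assert row["observed_rate"] == pytest.approx(row["mean_predicted"], abs=0.01)

    def test_empty_bins_omitted_and_counts_partition(self):
        y = np.array([0, 1, 0, 1])
        p = np.array([0.05, 0.06, 0.95, 0.96])
        curve = calibration_curve(y, p, n_bins=10)
        assert len(curve.bins) == 2
        assert curve.n_total == 4

    def test_hand_tabulation(self):
        y = np.array([0, 1, 1, 0, 1])
        p = np.array([0.12, 0.18, 0.55, 0.58, 0.52])
        curve = calibration_curve(y, p, n_bins=10).bins.set_index("bin")
        assert curve.loc[1, "n"] == 2
        assert curve.loc[1, "observed_rate"] == pytest.approx(0.5)
        assert curve.loc[5, "n"] == 3
        assert curve.loc[5, "mean_predicted"] == pytest.approx(0.55)


class TestConfidenceIntervals:
    def test_constant_replicates_zero_width(self):
        corrected = np.tile([100.0, 0.3, 5.0, 0.9], (20, 1))
        lo, hi = confidence_intervals(corrected)
        assert lo.as_array() == pytest.approx(hi.as_array())

    def test_level_monotone(self):
        rng = np.random.default_rng(0)
        corrected = rng.normal(size=(200, 4))
        lo95, hi95 = confidence_intervals(corrected, 0.95)
        lo50, hi50 = confidence_intervals(corrected, 0.50)
        assert (lo50.as_array() >= lo95.as_array()).all()
        assert (hi50.as_array() <= hi95.as_array()).all()

    def test_invalid_level(self):
        with pytest.raises(ConfigError):
            confidence_intervals(np.zeros((5, 4)), level=1.5)


def _noise_periods(n=2000, p_noise=30, seed=0):
    """Pure-noise covariates: any apparent skill is overfitting."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({f"z{i}": rng.normal(size=n) for i in range(p_noise)})
    df["iciss_worst"] = rng.uniform(0.85, 1.0, n)
    df["iciss_mult"] = df["iciss_worst"]
    df["death90"] = rng.integers(0, 2, n)
    return df


class TestBootstrapOptimism:
    def test_identity_resample_gives_zero_optimism(self, small_run, monkeypatch):
        monkeypatch.setattr(vmod, "_resample_indices", lambda rng, n: np.arange(n))
        spec = model_registry("death90", "worst")[0]
        rep = bootstrap_optimism(small_run["scored"], spec, B=2, seed=0)
        assert rep.optimism.as_array() == pytest.approx(np.zeros(4), abs=1e-9)
        assert rep.adjusted.as_array() == pytest.approx(rep.apparent.as_array(), abs=1e-9)

    def test_adjusted_equals_apparent_minus_mean_optimism(self, small_run):
        spec = model_registry("death90", "worst")[1]
        rep = bootstrap_optimism(small_run["scored"], spec, B=8, seed=3)
        assert rep.adjusted.as_array() == pytest.approx(
            rep.apparent.as_array() - rep.optimism.as_array(), abs=0)
        assert rep.n_replicates == 8

    def test_noise_covariates_shrink_adjusted_c(self):
        df = _noise_periods()
        spec = ModelSpec("death90", "worst", tuple(f"z{i}" for i in range(30)), "noise")
        rep = bootstrap_optimism(df, spec, B=15, seed=1)
        assert rep.adjusted.c_statistic < rep.apparent.c_statistic
        assert rep.optimism.c_statistic > 0.005

    def test_true_model_has_small_optimism(self, run50k):
        """A correctly specified, modestly parameterised model fitted at
        n=50,000 is barely optimistic."""
        spec = model_registry("death90", "worst")[1]  # M2
        rep = bootstrap_optimism(run50k["scored"], spec, B=15, seed=4)
        assert abs(rep.optimism.c_statistic) < 0.01

    def test_replicate_order_invariance(self, small_run):
        """Per-replicate seeds are derived as seed+b, so a subset of
        replicates reproduces regardless of execution order."""
        spec = model_registry("death90", "worst")[0]
        r1 = bootstrap_optimism(small_run["scored"], spec, B=3, seed=9)
        r2 = bootstrap_optimism(small_run["scored"], spec, B=3, seed=9)
        assert r1.adjusted.as_array() == pytest.approx(r2.adjusted.as_array(), abs=0)

    def test_report_serialisable(self, small_run):
        import json
        spec = model_registry("death90", "worst")[0]
        rep = bootstrap_optimism(small_run["scored"], spec, B=2, seed=0)
        js = json.dumps(rep.to_dict())
        assert "adjusted" in js and "ci_lower" in js


class TestSplitSample:
    def test_empty_half_rejected(self, small_run):
        spec = model_registry("death90", "worst")[0]
        with pytest.raises(EmptyDataError):
            split_sample_validation(small_run["index_periods"], spec, "1990-01-01")

    def test_midpoint_split_close_to_bootstrap_adjusted(self, run50k):
        """Both the time-based split-sample and the optimism bootstrap
        estimate out-of-sample discrimination, so their c-statistics agree
        to within Monte Carlo error on large synthetic data."""
        spec = model_registry("death90", "worst")[1]
        idx = run50k["index_periods"]
        mid = pd.to_datetime(idx["index_admit_date"]).quantile(0.5)
        split_stats = split_sample_validation(idx, spec, mid)
        rep = bootstrap_optimism(run50k["scored"], spec, B=15, seed=2)
        assert abs(split_stats.c_statistic - rep.adjusted.c_statistic) < 0.02


def test_fitstats_fieldwise_arithmetic():
    a = FitStats(100.0, 0.3, 5.0, 0.9)
    b = FitStats(90.0, 0.25, 4.0, 0.88)
    d = a - b
    assert d.aic == pytest.approx(10.0) and d.c_statistic == pytest.approx(0.02)
    assert FitStats.from_array(a.as_array()) == a
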