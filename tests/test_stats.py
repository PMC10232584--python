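import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stresseeg.stats import (
    ConvergenceError,
    apply_exclusions,
    bayes_factor_bic,
    bf01_from_bic,
    enumerate_tests,
    fdr_correct,
    fit_condition_model,
    fit_gamma_glmm,
    fit_linear_mixed,
    fit_measure_table,
    inclusion_filter,
    jeffreys_label,
    sex_covariate_check,
)


def _records(n=30, delta=0.0, mean=5.0, tau=1.0, sigma=1.0, seed=0, sex=False):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n):
        b = rng.normal(0, tau)
        for cond, shift in (("control", 0.0), ("negative", delta)):
            row = {
                "participant": f"P{p:03d}",
                "condition": cond,
                "value": mean + b + shift + rng.normal(0, sigma),
            }
            if sex:
                row["sex"] = "F" if p % 2 == 0 else "M"
            rows.append(row)
    return pd.DataFrame(rows)


class TestInclusionFilter:
    def _counts(self, pairs):
        rows = []
        for pid, (c, n) in pairs.items():
            rows.append({"participant": pid, "condition": "control", "n_epochs": c})
            rows.append({"participant": pid, "condition": "negative", "n_epochs": n})
        return pd.DataFrame(rows)

    def test_boundary_inclusive(self):
        assert inclusion_filter(self._counts({"a": (15, 15)})) == ["a"]

    def test_one_condition_below_excludes(self):
        assert inclusion_filter(self._counts({"a": (14, 40)})) == []

    def test_empty_report(self):
        assert inclusion_filter(pd.DataFrame()) == []

    def test_missing_condition_excludes(self):
        df = pd.DataFrame(
            [{"participant": "a", "condition": "control", "n_epochs": 30}]
        )
        assert inclusion_filter(df) == []


class TestApplyExclusions:
    def test_printed_count_bookkeeping(self):
        # 83 recruited − 2 incomplete − 8 insufficient quality → 73
        rows = [{"participant": f"S{i:02d}", "exclusion_reason": None} for i in range(83)]
        for i in range(2):
            rows[i]["exclusion_reason"] = "incomplete data"
        for i in range(2, 10):
            rows[i]["exclusion_reason"] = "insufficient EEG quality"
        out = apply_exclusions(pd.DataFrame(rows))
        assert len(out) == 73


class TestLinearMixed:
    def test_recovers_known_contrast(self):
        df = _records(n=60, delta=-1.0, seed=1)
        fit = fit_linear_mixed(df)
        assert fit.beta == pytest.approx(-1.0, abs=0.4)
        assert fit.family == "linear"
        assert fit.p < 0.05

    def test_aic_bic_relationship(self):
        df = _records(n=30, seed=2)
        fit = fit_linear_mixed(df)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.llf)
        assert fit.bic == pytest.approx(fit.n_params * np.log(fit.nobs) - 2 * fit.llf)

    def test_refit_reproducible(self):
        df = _records(n=25, delta=0.3, seed=3)
        a, b = fit_linear_mixed(df), fit_linear_mixed(df)
        assert a.beta == b.beta
        assert a.llf == b.llf

    def test_unknown_condition_label_rejected(self):
        df = _records(n=5)
        df.loc[0, "condition"] = "sham"
        with pytest.raises(ValueError, match="condition"):
            fit_linear_mixed(df)


class TestGammaGLMM:
    def test_recovers_known_contrast(self):
        rng = np.random.default_rng(7)
        rows = []
        for p in range(73):
            b = rng.normal(0, 1.0)
            for cond, shift in (("control", 0.0), ("negative", -1.0)):
                mu = max(5.0 + b + shift, 0.3)
                rows.append(
                    {
                        "participant": f"P{p}",
                        "condition": cond,
                        "value": rng.gamma(10.0, mu / 10.0),
                    }
                )
        fit = fit_gamma_glmm(pd.DataFrame(rows))
        assert fit.family == "gamma-identity"
        assert fit.beta == pytest.approx(-1.0, abs=0.4)
        assert fit.se > 0

    def test_nonpositive_values_rejected(self):
        df = _records(n=10, mean=0.0, seed=4)
        with pytest.raises(ValueError, match="positive"):
            fit_gamma_glmm(df)

    def test_gamma_preferred_on_skewed_data(self):
        # strongly skewed gamma data → gamma candidate wins the AIC race
        rng = np.random.default_rng(8)
        rows = []
        for p in range(60):
            b = np.exp(rng.normal(0, 0.3))
            for cond in ("control", "negative"):
                rows.append(
                    {
                        "participant": f"P{p}",
                        "condition": cond,
                        "value": rng.gamma(1.5, 2.0 * b),
                    }
                )
        res = fit_condition_model(pd.DataFrame(rows), "skewed")
        assert res.aic_gamma < res.aic_linear


class TestFitConditionModel:
    def test_aic_minimal_family_selected(self):
        df = _records(n=40, delta=0.5, seed=5)
        res = fit_condition_model(df, "m")
        chosen = "gamma-identity" if res.aic_gamma < res.aic_linear else "linear"
        assert res.family == chosen

    def test_negative_values_force_linear(self):
        df = _records(n=20, mean=0.0, seed=6)
        assert (df["value"] <= 0).any()
        res = fit_condition_model(df, "m")
        assert res.family == "linear"
        assert res.aic_gamma is None

    def test_identical_values_contrast_zero(self):
        df = pd.DataFrame(
            {
                "participant": ["a", "a", "b", "b"],
                "condition": ["control", "negative"] * 2,
                "value": [5.0, 5.0, 7.0, 7.0],
            }
        )
        res = fit_condition_model(df, "m")
        assert res.beta == pytest.approx(0.0, abs=1e-5)

    def test_ci_contains_point_estimate(self):
        res = fit_condition_model(_records(n=30, delta=0.4, seed=7), "m")
        lo, hi = res.ses_ci
        assert lo <= res.ses <= hi

    def test_too_few_participants_rejected(self):
        df = _records(n=1)
        with pytest.raises(ValueError, match="two participants"):
            fit_condition_model(df, "m")


class TestSexCovariate:
    def test_single_sex_skipped_with_warning(self):
        df = _records(n=10, sex=True, seed=8)
        df["sex"] = "F"
        with pytest.warns(UserWarning, match="skipped"):
            retained, p = sex_covariate_check(df)
        assert retained is False and np.isnan(p)

    def test_strong_sex_effect_retained(self):
        df = _records(n=40, sex=True, seed=9)
        df.loc[df["sex"] == "M", "value"] += 3.0
        retained, p = sex_covariate_check(df)
        assert retained and p < 0.001

    def test_null_sex_effect_usually_dropped(self):
        df = _records(n=40, sex=True, seed=10)
        retained, p = sex_covariate_check(df)
        assert p > 0.05 and not retained


class TestBayesFactor:
    def test_equal_bic_gives_one(self):
        assert bf01_from_bic(10.0, 10.0) == 1.0

    def test_delta_two_gives_e(self):
        assert bf01_from_bic(12.0, 10.0) == pytest.approx(np.e)

    def test_strong_effect_favours_alternative(self):
        df = _records(n=73, delta=-1.5, seed=11)
        bf = bayes_factor_bic(df, family="linear")
        assert bf < 1.0 / 3.0

    def test_null_data_favours_null(self):
        df = _records(n=73, delta=0.0, seed=12)
        assert bayes_factor_bic(df, family="linear") > 1.0

    def test_jeffreys_labels(self):
        assert "moderate" in jeffreys_label(6.4)
        assert "anecdotal" in jeffreys_label(1.24)
        assert "H1" in jeffreys_label(0.01)


def _bh_oracle(p, q=0.05):
    """Step-up Benjamini–Hochberg, spelled out for cross-checking."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.03]), [0.03])

    def test_hand_applied_step_up(self):
        # p·m/rank = (.04, .04, .04, .04) after the running minimum
        np.testing.assert_allclose(
            fdr_correct([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_correct([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])

    @given(
        ps=hst.lists(
            hst.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=67
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_independent_oracle(self, ps):
        np.testing.assert_allclose(fdr_correct(ps), _bh_oracle(ps), atol=1e-12)

    @given(
        ps=hst.lists(hst.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=30)
    )
    @settings(max_examples=30, deadline=None)
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = fdr_correct(ps)
        p = np.asarray(ps)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestEnumerateTests:
    def test_full_family_67(self):
        from stresseeg.connectivity import PRECUNEUS_REGIONS, ROICatalog, enumerate_connections

        cat = ROICatalog()
        fc = enumerate_connections(cat, ("alpha", "beta"), anchor=PRECUNEUS_REGIONS)
        ids = enumerate_tests(source_regions=cat.regions, fc_connections=fc)
        assert len(ids) == 67
        assert len(set(ids)) == 67

    def test_sensor_only_3(self):
        assert len(enumerate_tests()) == 3

    def test_empty_design_zero(self):
        assert enumerate_tests(sensor_bands=()) == []


class TestFitMeasureTable:
    def test_family_order_and_fdr_column(self):
        measures = {
            "a": _records(n=12, delta=1.5, seed=13),
            "b": _records(n=12, delta=0.0, seed=14),
        }
        out = fit_measure_table(measures, ["a", "b"])
        assert list(out["measure"]) == ["a", "b"]
        assert (out["p_fdr"] >= out["p_raw"] - 1e-12).all()

    def test_missing_measure_reported_not_fitted(self):
        out = fit_measure_table({}, ["ghost"])
        assert out["p_raw"].isna().all()
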