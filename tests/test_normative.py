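"""Quantile-regression fitting, ULN prediction, and presence classification."""

import numpy as np
import pandas as pd
import pytest

from spiroprm import normative, simulate
from spiroprm.normative import (
    QuantileModel,
    build_design,
    classify_presence,
    disease_flags,
    fit_normative,
    fit_quantile,
    pinball_loss,
    predict_uln,
)


class TestFitQuantile:
    def test_intercept_only_equals_order_statistic_lower_endpoint(self):
        y = np.arange(1.0, 101.0)
        model = fit_quantile(np.ones((100, 1)), y, 0.95)
        # minimizers form the interval [95, 96]; lower endpoint reported
        assert model.coef_array[0] == pytest.approx(95.0)
        assert model.n_below <= 95
        assert model.n_above <= 5

    def test_gaussian_synthetic_uln_recovery(self):
        rng = np.random.default_rng(42)
        n, sigma = 2000, 2.0
        age = rng.uniform(40, 80, n)
        y = 1.0 + 0.1 * age + rng.normal(0, sigma, n)
        X = np.column_stack([np.ones(n), age])
        model = fit_quantile(X, y, 0.95, column_names=["intercept", "age"])
        beta = model.coef_array
        for a in (45.0, 60.0, 75.0):
            true_uln = 1.0 + 0.1 * a + 1.645 * sigma
            assert beta[0] + beta[1] * a == pytest.approx(true_uln, abs=0.5)

    def test_lp_beats_coarse_grid_search(self):
        rng = np.random.default_rng(3)
        n = 200
        x = rng.uniform(0, 1, n)
        y = 2.0 + 1.5 * x + rng.exponential(1.0, n)
        X = np.column_stack([np.ones(n), x])
        model = fit_quantile(X, y, 0.9)
        ours = pinball_loss(y, X @ model.coef_array, 0.9)
        best = np.inf
        for b0 in np.linspace(0, 8, 60):
            for b1 in np.linspace(-1, 4, 60):
                best = min(best, pinball_loss(y, b0 + b1 * x, 0.9))
        assert ours <= best + 1e-9

    def test_matches_statsmodels_quantreg_loss(self):
        # independent implementation cross-check (not used in the package path)
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 400
        X = np.column_stack([np.ones(n), rng.uniform(0, 10, n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.5, -0.8]) + rng.standard_t(5, n)
        for tau in (0.5, 0.95):
            ours = fit_quantile(X, y, tau)
            sm_fit = sm.QuantReg(y, X).fit(q=tau)
            loss_ours = pinball_loss(y, X @ ours.coef_array, tau)
            loss_sm = pinball_loss(y, X @ sm_fit.params, tau)
            assert loss_ours <= loss_sm + 1e-7
            np.testing.assert_allclose(ours.coef_array, sm_fit.params, atol=0.05)

    def test_subgradient_conditions_hold_on_random_fits(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = int(rng.integers(60, 300))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = X @ rng.normal(size=3) + rng.exponential(1.0, n)
            tau = float(rng.uniform(0.1, 0.95))
            m = fit_quantile(X, y, tau)
            assert m.n_below <= tau * n + 1e-9
            assert m.n_above <= (1 - tau) * n + 1e-9

    def test_shift_equivariance(self):
        rng = np.random.default_rng(8)
        n = 150
        X = np.column_stack([np.ones(n), rng.uniform(size=n)])
        y = rng.normal(size=n)
        b0 = fit_quantile(X, y, 0.95).coef_array
        b1 = fit_quantile(X, y + 7.5, 0.95).coef_array
        assert b1[0] - b0[0] == pytest.approx(7.5, abs=1e-6)
        assert b1[1] == pytest.approx(b0[1], abs=1e-6)

    def test_no_quantile_crossing_at_training_points(self):
        rng = np.random.default_rng(21)
        n = 500
        age = rng.uniform(40, 80, n)
        X = np.column_stack([np.ones(n), age])
        y = 0.5 + 0.05 * age + rng.exponential(2.0, n)
        hi = fit_quantile(X, y, 0.95).coef_array
        med = fit_quantile(X, y, 0.50).coef_array
        assert np.all(X @ hi >= X @ med - 1e-9)

    def test_rank_deficiency_names_collinear_columns(self):
        n = 60
        x = np.linspace(0, 1, n)
        X = pd.DataFrame({"intercept": 1.0, "a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            fit_quantile(X, np.random.default_rng(0).normal(size=n), 0.9)

    def test_poorly_identified_quantile_warns(self):
        with pytest.warns(UserWarning, match="poorly"):
            fit_quantile(np.ones((8, 1)), np.arange(8.0), 0.05)


class TestNormativeModel:
    def test_fit_on_reference_bed_recovers_truth_surface(self, normative_bed):
        model = fit_normative(normative_bed, "pct_fsad")
        uln = predict_uln(model, normative_bed)
        err = uln - normative_bed["uln_pct_fsad_true"].to_numpy()
        assert np.abs(np.mean(err)) < 1.0
        assert np.mean(np.abs(err)) < 2.5

    def test_training_set_positive_fraction_bounded(self, normative_bed):
        model = fit_normative(normative_bed, "pct_emphysema", tau=0.95)
        uln = predict_uln(model, normative_bed)
        frac = np.mean(normative_bed["pct_emphysema"].to_numpy() > uln)
        k = len(model.coef)
        assert frac <= 0.05 + k / model.n_train

    def test_intercept_only_prediction_is_constant(self):
        model = QuantileModel(
            tau=0.95, outcome_name="pct_emphysema",
            coef={"intercept": 3.2}, n_train=100, covariates=("intercept",),
        )
        df = pd.DataFrame({"age": [40, 70], "bmi": [22, 30]})
        np.testing.assert_allclose(predict_uln(model, df), [3.2, 3.2])

    def test_negative_linear_predictor_floors_at_zero(self):
        model = QuantileModel(
            tau=0.95, outcome_name="pct_emphysema",
            coef={"intercept": -2.0, "age": 0.01}, n_train=100,
            covariates=("intercept", "age"),
        )
        df = pd.DataFrame({"age": [40.0]})
        assert predict_uln(model, df)[0] == 0.0

    def test_unseen_scanner_raises_unless_fallback(self, normative_bed):
        model = fit_normative(normative_bed, "pct_fsad")
        cov = normative_bed.head(3).copy()
        cov["scanner"] = "scanner_X"
        with pytest.raises(ValueError, match="scanner"):
            predict_uln(model, cov)
        uln = predict_uln(model, cov, strict_scanners=False)
        assert np.all(np.isfinite(uln))

    def test_json_round_trip(self, tmp_path, normative_bed):
        model = fit_normative(normative_bed, "pct_emphysema")
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = QuantileModel.from_json(path)
        assert loaded == model

    def test_design_contains_expected_columns(self, normative_bed):
        design, levels, ref = build_design(normative_bed)
        assert "intercept" in design.columns and "male" in design.columns
        assert len(levels) == 4 and ref == levels[0]
        assert design.shape[1] == 3 + 1 + 3  # intercept, age, bmi, male, 3 one-hots


class TestPresence:
    @pytest.mark.parametrize(
        "observed,uln,expected",
        [(5.0, 3.2, True), (3.2, 3.2, False), (0.0, 0.0, False)],
    )
    def test_strict_comparison(self, observed, uln, expected):
        assert classify_presence(observed, uln) is expected

    def test_disease_flags_truth_table(self):
        either, both = disease_flags([True, False, True, False], [False, False, True, True])
        np.testing.assert_array_equal(either, [True, False, True, True])
        np.testing.assert_array_equal(both, [False, False, True, False])

    def test_cohort_counts_match_recount(self, rng):
        e = rng.random(500) < 0.3
        f = rng.random(500) < 0.2
        either, both = disease_flags(e, f)
        n_either = sum(1 for a, b in zip(e, f) if a or b)
        n_both = sum(1 for a, b in zip(e, f) if a and b)
        assert either.sum() == n_either
        assert both.sum() == n_both

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            classify_presence(np.nan, 1.0)


class TestReferenceBedGeneration:
    def test_zero_noise_fit_is_exact(self):
        truth = simulate.NormativeTruth(
            emph=simulate.OutcomeTruth(
                name="pct_emphysema", intercept=1.0, age_coef=0.03,
                male_coef=0.2, bmi_coef=0.01, noise="gaussian", noise_scale=0.0,
            ),
            fsad=simulate.OutcomeTruth(
                name="pct_fsad", intercept=15.0, age_coef=0.2,
                male_coef=1.0, bmi_coef=0.05, noise="gaussian", noise_scale=0.0,
            ),
        )
        bed = simulate.generate_normative_truth(400, truth=truth, seed=5)
        model = fit_normative(bed, "pct_fsad")
        np.testing.assert_allclose(
            predict_uln(model, bed), bed["uln_pct_fsad_true"], atol=1e-6
        )

    def test_different_seeds_differ_but_both_recover(self):
        for seed in (1, 2):
            bed = simulate.generate_normative_truth(2000, seed=seed)
            model = fit_normative(bed, "pct_fsad")
            err = predict_uln(model, bed) - bed["uln_pct_fsad_true"].to_numpy()
            assert np.abs(err).mean() < 2.5
        b1 = simulate.generate_normative_truth(200, seed=1)
        b2 = simulate.generate_normative_truth(200, seed=2)
        assert not b1.equals(b2)
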