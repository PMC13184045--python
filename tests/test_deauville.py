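import numpy as np
import pandas as pd
import pytest

from petbias.deauville import (
    FitResult,
    deauville_score,
    fit_suvr_regression,
    misclassification_probability,
    prediction_distribution,
    risk_curve,
    risk_flag,
    score_change_table,
    suvr,
    suvr_table,
)


class TestSuvr:
    def test_median_ratio(self):
        # lesion and liver cohort medians give ~1.979
        assert suvr(5.68, 2.87) == pytest.approx(1.979, abs=1e-3)

    def test_unity(self):
        assert suvr(2.5, 2.5) == 1.0

    def test_nonpositive_reference(self):
        with pytest.raises(ValueError):
            suvr(5.0, 0.0)


class TestDeauvilleScore:
    @pytest.mark.parametrize(
        "sa,sl,expected",
        [
            (0.9, 0.7, 2),
            (1.2, 0.96, 3),
            (1.0, 1.0, 2),  # inclusive boundary maps down
            (1.5, 1.2, 4),
            (1.0, 0.99, 2),
            (1.0001, 1.0, 3),
            (0.9, 1.1, 4),  # liver clause takes precedence as written
        ],
    )
    def test_rule(self, sa, sl, expected):
        assert deauville_score(sa, sl) == expected

    def test_scores_1_and_5_never_emitted(self):
        rng = np.random.default_rng(0)
        scores = {
            deauville_score(a, b)
            for a, b in zip(rng.uniform(0.01, 5, 500), rng.uniform(0.01, 5, 500))
        }
        assert scores <= {2, 3, 4}

    def test_monotone_in_both_ratios(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            sa, sl = rng.uniform(0.2, 3, 2)
            base = deauville_score(sa, sl)
            assert deauville_score(sa * 1.3, sl) >= base
            assert deauville_score(sa, sl * 1.3) >= base

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            deauville_score(0.0, 1.0)


class TestFit:
    def test_identity_data(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_suvr_regression(x, x)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.slope == pytest.approx(1.0)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-12)

    def test_three_point_closed_form(self):
        fit = fit_suvr_regression([1, 2, 3], [1.1, 2.0, 3.0])
        assert fit.slope == pytest.approx(0.95)
        assert fit.intercept == pytest.approx(0.13333, abs=1e-5)
        assert fit.resid_sd == pytest.approx(0.040825, abs=1e-5)
        assert fit.x_mean == pytest.approx(2.0)
        assert fit.sxx == pytest.approx(2.0)

    def test_against_polyfit_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.5, 4, 40)
        y = 0.2 + 0.9 * x + rng.normal(0, 0.15, 40)
        fit = fit_suvr_regression(x, y)
        slope_ref, intercept_ref = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(slope_ref)
        assert fit.intercept == pytest.approx(intercept_ref)
        resid = y - (intercept_ref + slope_ref * x)
        assert fit.resid_sd == pytest.approx(np.sqrt((resid**2).sum() / 38))

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_suvr_regression([2, 2, 2], [1, 2, 3])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_suvr_regression([1, 2], [1, 2])

    def test_parameter_recovery(self):
        a_true, b_true, s_true = 0.1, 0.95, 0.2
        slopes, intercepts = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.5, 5, 200)
            y = a_true + b_true * x + rng.normal(0, s_true, 200)
            fit = fit_suvr_regression(x, y)
            slopes.append(fit.slope)
            intercepts.append(fit.intercept)
        assert np.mean(slopes) == pytest.approx(b_true, abs=0.02)
        assert np.mean(intercepts) == pytest.approx(a_true, abs=0.05)


def _fit(intercept=0.0, slope=1.0, s=0.1, n=1_000_000, x_mean=1.0, sxx=1e12):
    # huge n and sxx make the prediction sd collapse to the residual sd
    return FitResult(intercept, slope, s, n, x_mean, sxx)


class TestPredictionDistribution:
    def test_identity_zero_residual(self):
        fit = _fit(s=0.0)
        mean, sd = prediction_distribution(fit, 1.0)
        assert (mean, sd) == (1.0, 0.0)

    def test_sd_minimum_at_x_mean(self):
        fit = FitResult(0.0, 1.0, 0.3, 20, 1.5, 4.0)
        _, sd0 = prediction_distribution(fit, 1.5)
        assert sd0 == pytest.approx(0.3 * np.sqrt(1 + 1 / 20))
        grid = np.linspace(0.1, 3.0, 25)
        sds = [prediction_distribution(fit, r)[1] for r in grid]
        # strictly increasing in |r - x_mean|
        dist = np.abs(grid - 1.5)
        order = np.argsort(dist)
        assert all(np.diff(np.array(sds)[order]) > -1e-15)

    def test_confidence_narrower_than_prediction(self):
        fit = FitResult(0.0, 1.0, 0.3, 20, 1.5, 4.0)
        _, sp = prediction_distribution(fit, 1.0, "prediction")
        _, sc = prediction_distribution(fit, 1.0, "confidence")
        assert sc < sp

    def test_unknown_interval(self):
        with pytest.raises(ValueError):
            prediction_distribution(_fit(), 1.0, "bootstrap")


class TestMisclassification:
    def test_half_at_threshold_limit(self):
        fit = _fit()  # mean(1) = 1
        assert misclassification_probability(fit, 1.0 + 1e-12) == pytest.approx(0.5)

    def test_published_aorta_boundary_pair(self):
        # mean(1) = 1 + 1.96 sd -> false upgrade 2.5%, false downgrade 97.5%
        s = 0.1
        fit = _fit(intercept=1.96 * s, slope=1.0, s=s)
        up = misclassification_probability(fit, 1.0 + 1e-12)
        down = misclassification_probability(fit, 1.0 - 1e-12)
        assert up == pytest.approx(0.025, abs=1e-4)
        assert down == pytest.approx(0.975, abs=1e-4)

    def test_boundary_complementarity(self):
        for intercept, s in [(0.02, 0.05), (-0.1, 0.3), (0.0, 0.01)]:
            fit = _fit(intercept=intercept, s=s)
            up = misclassification_probability(fit, 1.0 + 1e-12)
            down = misclassification_probability(fit, 1.0 - 1e-12)
            assert up + down == pytest.approx(1.0, abs=1e-9)

    def test_monotone_away_from_threshold(self):
        fit = FitResult(0.05, 0.95, 0.15, 66, 2.0, 100.0)
        above = np.linspace(1.001, 3, 50)
        probs = [misclassification_probability(fit, r) for r in above]
        assert all(np.diff(probs) <= 1e-12)
        below = np.linspace(0.2, 0.999, 50)
        probs = [misclassification_probability(fit, r) for r in below]
        assert all(np.diff(probs) >= -1e-12)

    def test_monte_carlo_oracle(self):
        fit = FitResult(0.03, 0.97, 0.2, 66, 2.1, 150.0)
        rng = np.random.default_rng(17)
        for r in (0.7, 0.95, 1.05, 1.6):
            mean, sd = prediction_distribution(fit, r)
            draws = rng.normal(mean, sd, 100_000)
            mc = (draws <= 1.0).mean() if r > 1.0 else (draws > 1.0).mean()
            assert misclassification_probability(fit, r) == pytest.approx(mc, abs=0.005)

    def test_at_threshold_rejected(self):
        with pytest.raises(ValueError):
            misclassification_probability(_fit(), 1.0)

    def test_degenerate_sd_deterministic(self):
        fit = _fit(intercept=0.1, s=0.0)  # mean(r) = r + 0.1
        assert misclassification_probability(fit, 1.01) == 0.0  # mean 1.11 > 1
        assert misclassification_probability(fit, 0.95) == 1.0  # mean 1.05 > 1
        # zero spread with the mean pinned exactly at the threshold is undefined
        flat = FitResult(1.0, 0.0, 0.0, 10, 1.0, 1.0)
        with pytest.raises(ValueError):
            misclassification_probability(flat, 1.5)


class TestRiskFlag:
    def test_below_alpha(self):
        s = 0.1
        fit = _fit(intercept=1.96 * s, s=s)  # P = 0.025 just above 1
        assert risk_flag(fit, 1.0 + 1e-12) is False

    def test_liver_boundary_value_flags(self):
        # mean(1) = 1 + z_{0.84} sd -> false upgrade ~16%
        s = 0.1
        from scipy.stats import norm

        fit = _fit(intercept=norm.ppf(0.84) * s, s=s)
        p = misclassification_probability(fit, 1.0 + 1e-12)
        assert p == pytest.approx(0.16, abs=1e-3)
        assert risk_flag(fit, 1.0 + 1e-12) is True

    def test_alpha_one_never_flags(self):
        assert risk_flag(_fit(), 1.2, alpha=1.0) is False


class TestRiskCurve:
    def test_grid_skips_threshold(self):
        fit = _fit()
        curve = risk_curve(fit, [0.5, 1.0, 1.5])
        assert len(curve) == 2
        assert set(curve["direction"]) == {"upgrade", "downgrade"}

    def test_probabilities_in_unit_interval(self):
        fit = FitResult(0.02, 0.98, 0.25, 66, 2.0, 120.0)
        curve = risk_curve(fit, np.linspace(0.1, 3, 100))
        assert curve["probability"].between(0, 1).all()


def _records(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "lesion_id", "recon", "suvr_aorta", "suvr_liver", "score"]
    )


class TestScoreChangeTable:
    def test_no_changes(self):
        rows = []
        for recon in ("AC", "CE"):
            rows.append(("P1", "L1", recon, 0.8, 0.6, 2))
            rows.append(("P1", "L2", recon, 1.5, 1.2, 4))
        changes = score_change_table(_records(rows))
        assert changes.n_upgraded == changes.n_downgraded == 0
        assert changes.changed.empty

    def test_borderline_upgrade(self):
        # aorta ratio crosses 1 between reconstructions -> 2 becomes 3
        rows = [
            ("P1", "L1", "AC", 0.98, 0.8, deauville_score(0.98, 0.8)),
            ("P1", "L1", "CE", 1.02, 0.85, deauville_score(1.02, 0.85)),
        ]
        changes = score_change_table(_records(rows))
        assert changes.n_upgraded == 1
        assert changes.changed.iloc[0]["score_ac"] == 2
        assert changes.changed.iloc[0]["score_ce"] == 3

    def test_ratio_below_one_only_downgrades(self):
        # construct a cohort where every CE ratio is a shrunk AC ratio
        rng = np.random.default_rng(2)
        rows = []
        for k in range(30):
            sa = rng.uniform(0.5, 2.5)
            sl = sa * 0.66
            shrink = rng.uniform(0.85, 0.99)
            rows.append(("P1", f"L{k}", "AC", sa, sl, deauville_score(sa, sl)))
            rows.append(
                ("P1", f"L{k}", "CE", sa * shrink, sl * shrink, deauville_score(sa * shrink, sl * shrink))
            )
        changes = score_change_table(_records(rows))
        assert changes.n_upgraded == 0
        assert changes.n_downgraded >= 1

    def test_missing_pair_rejected(self):
        rows = [("P1", "L1", "AC", 0.9, 0.8, 2)]
        with pytest.raises(ValueError):
            score_change_table(_records(rows))


class TestSuvrTable:
    def test_from_measurements(self):
        meas = pd.DataFrame(
            [
                ("P1", "P1:aorta", "aorta", "AC", 2.0, 1.6),
                ("P1", "P1:aorta", "aorta", "CE", 2.2, 1.76),
                ("P1", "P1:liver", "liver", "AC", 2.5, 2.0),
                ("P1", "P1:liver", "liver", "CE", 2.7, 2.16),
                ("P1", "P1:lesion1", "lesion", "AC", 5.0, 3.3),
                ("P1", "P1:lesion1", "lesion", "CE", 5.2, 3.4),
            ],
            columns=["patient_id", "unit_id", "unit_type", "recon", "suv_max", "suv_mean"],
        )
        tbl = suvr_table(meas)
        ac = tbl[tbl["recon"] == "AC"].iloc[0]
        assert ac["suvr_aorta"] == pytest.approx(2.5)
        assert ac["suvr_liver"] == pytest.approx(2.0)
        assert ac["score"] == 4

    def test_mean_reference_mode(self):
        meas = pd.DataFrame(
            [
                ("P1", "P1:aorta", "aorta", "AC", 2.0, 1.0),
                ("P1", "P1:liver", "liver", "AC", 2.5, 1.25),
                ("P1", "P1:lesion1", "lesion", "AC", 5.0, 3.3),
            ],
            columns=["patient_id", "unit_id", "unit_type", "recon", "suv_max", "suv_mean"],
        )
        tbl = suvr_table(meas, reference_metric="suv_mean")
        assert tbl.iloc[0]["suvr_aorta"] == pytest.approx(5.0)

    def test_missing_reference_rejected(self):
        meas = pd.DataFrame(
            [("P1", "P1:lesion1", "lesion", "AC", 5.0, 3.3)],
            columns=["patient_id", "unit_id", "unit_type", "recon", "suv_max", "suv_mean"],
        )
        with pytest.raises(ValueError):
            suvr_table(meas)


class TestFitResultInvariants:
    def test_bad_fields(self):
        with pytest.raises(ValueError):
            FitResult(0, 1, -0.1, 10, 1, 1)
        with pytest.raises(ValueError):
            FitResult(0, 1, 0.1, 2, 1, 1)
        with pytest.raises(ValueError):
            FitResult(0, 1, 0.1, 10, 1, 0)
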