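"""Anchored prediction, national aggregation, and fit evaluation."""

import dataclasses

import numpy as np
import pytest

import proxysdm as px
from proxysdm.inference import evaluate_fit, national_aggregate, predict_monthly

from conftest import make_toy_panel


def noiseless(params):
    return dataclasses.replace(params, sigma2=0.0)


class TestPredictMonthly:
    def test_intercept_only_constant_prediction(self):
        panel = make_toy_panel(n=2, T=3, survey=np.full((2, 3), 0.42))
        Wseq = px.build_population_distance_W(
            panel.populations, px.pairwise_distance(panel.centroids)
        )
        p = px.ModelParameters(alpha_H=0.42)
        pred = predict_monthly(p, panel, Wseq, include_national=False)
        np.testing.assert_allclose(pred.monthly, 0.42, atol=1e-14)

    def test_hand_recursion_with_anchor_switch(self):
        # 1 unit, 3 years, tau only: every value is tau * its 12-month lag,
        # and each October's lag is the previous October's survey value
        T = 3
        survey = np.array([[0.4, 0.9, 0.5]])
        panel = make_toy_panel(n=1, T=T, survey=survey)
        Wseq = px.null_W(1, T)
        tau = 0.5
        p = px.ModelParameters(tau=tau)
        pred = predict_monthly(p, panel, Wseq, include_national=False)
        y = np.empty(36)
        for m in range(36):
            if m < 12:
                lag = 0.4  # burn-in: first survey year's value
            elif m % 12 == 9:
                lag = survey[0, m // 12 - 1]  # October anchor
            else:
                lag = y[m - 12]
            y[m] = tau * lag
        np.testing.assert_allclose(pred.monthly[0], y, atol=1e-14)

    def test_one_survey_anchor_per_year_after_burn_in(self, small_bundle):
        b = small_bundle
        pred = predict_monthly(
            noiseless(b["true_params"]), b["panel"], b["weights"],
            include_national=False,
        )
        sources = [s for _, s in pred.anchors_used]
        assert sources[0] == "burnin"
        assert sources[1:] == ["survey"] * (b["panel"].T - 1)

    def test_missing_anchor_falls_back_to_model(self, small_bundle, caplog):
        panel = small_bundle["panel"]
        survey = panel.survey_Y.copy()
        survey[0, 2] = np.nan  # anchor feeding the 4th year's October
        broken = px.StatePanel(
            panel.unit_ids, list(panel.years), list(panel.months),
            panel.X1, panel.X2, survey, panel.populations,
            panel.centroids, panel.response_class,
        )
        with caplog.at_level("WARNING"):
            pred = predict_monthly(
                noiseless(small_bundle["true_params"]), broken,
                small_bundle["weights"], include_national=False,
            )
        sources = dict(pred.anchors_used)
        assert sources[panel.years[3]] == "model"
        assert "missing survey anchor" in caplog.text

    def test_self_consistency_with_simulator(self, small_bundle):
        b = small_bundle
        panel = b["panel"]
        params = noiseless(b["true_params"])
        y0 = panel.survey_Y[:, 0]
        Y_init = np.tile(y0[:, None], (1, 12))
        Ysim, october = px.simulate_panel(
            params, b["weights"], panel.X1, panel.X2, Y_init,
            high_mask=panel.high_mask(),
        )
        consistent = px.StatePanel(
            panel.unit_ids, list(panel.years), list(panel.months),
            panel.X1, panel.X2, october, panel.populations,
            panel.centroids, panel.response_class,
        )
        pred = predict_monthly(
            params, consistent, b["weights"], include_national=False,
            Y_init=Y_init,
        )
        assert np.max(np.abs(pred.monthly - Ysim)) < 1e-10
        ev = evaluate_fit(pred, october)
        assert ev.sse == 0.0 and ev.mse == 0.0

    def test_unit_reordering_invariance(self, small_bundle):
        b = small_bundle
        params = noiseless(b["true_params"])
        pred = predict_monthly(params, b["panel"], b["weights"],
                               include_national=False)
        order = np.array([3, 0, 9, 1, 7, 2, 8, 5, 4, 6])
        panel2 = b["panel"].reorder_units(order)
        W2 = px.WeightMatrixSequence(
            b["weights"].matrices[:, order][:, :, order],
            list(b["weights"].year_index),
        )
        pred2 = predict_monthly(params, panel2, W2, include_national=False)
        np.testing.assert_allclose(pred2.monthly, pred.monthly[order], atol=1e-12)


class TestNationalAggregate:
    def test_single_unit_equals_state_series(self):
        panel = make_toy_panel(n=1, T=3, survey=np.array([[0.3, 0.32, 0.31]]))
        Wseq = px.null_W(1, 3)
        p = px.ModelParameters(tau=0.4, phi1_H=5.0, phi2_H=0.2, alpha_H=0.05)
        state = predict_monthly(p, panel, Wseq, include_national=False).monthly[0]
        national = national_aggregate(panel, p, Wseq)
        np.testing.assert_allclose(national, state, atol=1e-12)

    def test_equal_units_give_common_value(self):
        survey = np.full((2, 3), 0.35)
        panel = make_toy_panel(n=2, T=3, survey=survey)
        Wseq = px.build_population_distance_W(
            panel.populations, px.pairwise_distance(panel.centroids)
        )
        # identical proxies and survey in both units; national proxies are
        # the population-weighted averages of identical series
        p = px.ModelParameters(tau=0.3, phi1_H=4.0, phi2_H=0.1, alpha_H=0.1)
        national = national_aggregate(panel, p, Wseq)
        single = make_toy_panel(n=1, T=3, survey=survey[:1])
        expected = predict_monthly(
            p, single, px.null_W(1, 3), include_national=False
        ).monthly[0]
        np.testing.assert_allclose(national, expected, atol=1e-12)

    def test_check_count_aggregation_arithmetic(self):
        # national rate = (c1+c2)/(p1+p2) when counts are rate*population
        panel = make_toy_panel(n=2, T=2)
        panel.X1[0, :] = 0.004
        panel.X1[1, :] = 0.008
        pops = panel.populations[:, 0]
        expected_rate = (0.004 * pops[0] + 0.008 * pops[1]) / pops.sum()
        Wseq = px.null_W(2, 2)
        p = px.ModelParameters(phi1_H=1.0)  # output = lagged national X1
        national = national_aggregate(panel, p, Wseq)
        assert national[5] == pytest.approx(expected_rate, rel=1e-12)

    def test_zero_total_suicides_rejected(self):
        panel = make_toy_panel(n=2, T=2)
        counts = np.ones((2, 24))
        counts[:, 3] = 0.0
        with pytest.raises(ValueError, match="zero total suicides"):
            national_aggregate(
                panel, px.ModelParameters(), px.null_W(2, 2),
                suicide_counts=counts,
            )


class TestEvaluateFit:
    def test_identical_gives_zero(self):
        pred = px.PredictionResult(monthly=np.full((2, 24), 0.3))
        survey = np.full((2, 2), 0.3)
        ev = evaluate_fit(pred, survey)
        assert ev.sse == 0.0 and ev.mse == 0.0

    def test_constant_error_arithmetic(self):
        # constant error 0.1 over 20 Octobers in one unit: SSE=0.2, MSE=0.01
        monthly = np.full((1, 240), 0.3)
        survey = np.full((1, 20), 0.4)
        ev = evaluate_fit(px.PredictionResult(monthly=monthly), survey)
        assert ev.sse == pytest.approx(0.2)
        assert ev.mse == pytest.approx(0.01)
        assert ev.mse == pytest.approx(ev.sse / 20)

    def test_no_overlap_rejected(self):
        pred = px.PredictionResult(monthly=np.zeros((1, 24)))
        with pytest.raises(ValueError, match="overlap"):
            evaluate_fit(pred, np.full((1, 2), np.nan))

    def test_per_unit_table(self, small_bundle):
        b = small_bundle
        pred = predict_monthly(noiseless(b["true_params"]), b["panel"],
                               b["weights"], include_national=False)
        ev = evaluate_fit(pred, b["panel"].survey_Y, b["panel"])
        table = ev.per_unit_table()
        assert len(table) == b["panel"].n
        assert ev.sse == pytest.approx(table["sse"].sum())
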