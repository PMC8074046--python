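import math
from functools import partial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meronat import (AgreementReport, DosingRegimen, PopPKModel,
                     TDMObservation, ValidationError, ccc_confidence,
                     ccc_with_ci, compare_risk_methods, concentration,
                     individual_parameters, lins_ccc, mcbride_grade,
                     prediction_errors, risk_regression, success_criterion)


class TestTDMObservation:
    def test_time_after_last_dose(self):
        obs = TDMObservation("p1", [(1000, 0.5, 0.0), (1000, 0.5, 8.0)],
                             sample_time=14.2, concentration=5.0)
        assert obs.time_after_last_dose == pytest.approx(6.2)

    def test_sample_before_first_dose_rejected(self):
        with pytest.raises(ValidationError, match="predates"):
            TDMObservation("p1", [(1000, 0.5, 4.0)], sample_time=2.0,
                           concentration=5.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            TDMObservation("p1", [(1000, 0.5, 0.0)], sample_time=6.0,
                           concentration=-1.0)


class TestPredictionErrors:
    @pytest.fixture
    def setup(self, pk_model_novar, median_patient, rng):
        ip = individual_parameters(pk_model_novar, median_patient, rng)
        history = [(1000.0, 0.5, 0.0), (1000.0, 0.5, 8.0)]
        times = [6.0, 14.0]
        true_c = [float(concentration(ip, history, t)) for t in times]
        return pk_model_novar, median_patient, history, times, true_c

    def test_perfect_predictions_give_zero_bias_and_interval(self, setup, rng):
        model, patient, history, times, true_c = setup
        obs = [TDMObservation(patient.id, history, t, c)
               for t, c in zip(times, true_c)]
        rep = prediction_errors(obs, {patient.id: patient}, model,
                                n_replicates=20, rng=rng, with_residual=False)
        assert rep.bias_abs == pytest.approx(0.0, abs=1e-9)
        assert rep.pe_interval_50 == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_hand_computed_median_and_sign_conventions(self, setup, rng):
        model, patient, history, times, true_c = setup
        # observed = predicted - delta with deltas (-2, +1):
        obs = [TDMObservation(patient.id, history, times[0], true_c[0] + 2.0),
               TDMObservation(patient.id, history, times[1], true_c[1] - 1.0)]
        rep = prediction_errors(obs, {patient.id: patient}, model,
                                n_replicates=20, rng=rng, with_residual=False)
        # default: PE = predicted - observed -> (-2, +1), median -0.5
        assert sorted(rep.per_sample["pe_mg_l"]) == pytest.approx([-2.0, 1.0])
        assert rep.bias_abs == pytest.approx(-0.5)
        rep2 = prediction_errors(obs, {patient.id: patient}, model,
                                 n_replicates=20, rng=rng, with_residual=False,
                                 sign_convention="observed_minus_predicted")
        assert rep2.bias_abs == pytest.approx(0.5)

    def test_underprediction_yields_negative_bias(self, setup, rng):
        model, patient, history, times, true_c = setup
        obs = [TDMObservation(patient.id, history, t, c * 1.3)
               for t, c in zip(times, true_c)]  # observed above predictions
        rep = prediction_errors(obs, {patient.id: patient}, model,
                                n_replicates=20, rng=rng, with_residual=False)
        assert rep.bias_abs < 0

    def test_order_invariance(self, setup, rng):
        model, patient, history, times, true_c = setup
        obs = [TDMObservation(patient.id, history, t, c * 1.1)
               for t, c in zip(times, true_c)]
        r1 = prediction_errors(obs, {patient.id: patient}, model,
                               n_replicates=20, rng=np.random.default_rng(1),
                               with_residual=False)
        r2 = prediction_errors(obs[::-1], {patient.id: patient}, model,
                               n_replicates=20, rng=np.random.default_rng(1),
                               with_residual=False)
        assert r1.bias_abs == pytest.approx(r2.bias_abs)
        assert r1.pe_interval_50 == pytest.approx(r2.pe_interval_50)

    def test_quartiles_bracket_median(self, pk_model, median_patient, rng):
        history = [(1000.0, 0.5, 0.0)]
        obs = [TDMObservation(median_patient.id, history, 6.0, c)
               for c in (2.0, 5.0, 9.0, 14.0, 20.0)]
        rep = prediction_errors(obs, {median_patient.id: median_patient}, pk_model,
                                n_replicates=200, rng=rng)
        p25, p75 = rep.pe_interval_50
        assert p25 <= rep.bias_abs <= p75

    def test_unknown_patient_rejected(self, pk_model, median_patient, rng):
        obs = [TDMObservation("ghost", [(1000.0, 0.5, 0.0)], 6.0, 5.0)]
        with pytest.raises(ValidationError, match="ghost"):
            prediction_errors(obs, {median_patient.id: median_patient}, pk_model,
                              n_replicates=10, rng=rng)


class TestLinsCCC:
    def test_hand_derived_value(self):
        assert lins_ccc([1.0, 2.0, 3.0], [2.0, 4.0, 6.0]) == pytest.approx(8.0 / 22.0)

    def test_perfect_concordance(self, rng):
        x = rng.normal(size=50)
        assert lins_ccc(x, x) == pytest.approx(1.0)

    def test_reversal_is_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = -x + 2.0 * x.mean()
        assert lins_ccc(x, y) < 0

    def test_symmetry_and_reorder_invariance(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert lins_ccc(x, y) == pytest.approx(lins_ccc(y, x))
        perm = rng.permutation(30)
        assert lins_ccc(x[perm], y[perm]) == pytest.approx(lins_ccc(x, y))

    def test_penalizes_scale_and_location_shift(self, rng):
        x = rng.normal(size=100)
        assert lins_ccc(x, x * 2.0) < 1.0
        assert lins_ccc(x, x + 1.0) < 1.0
        assert lins_ccc(x, x * 1.5 + 0.5) < lins_ccc(x, x)

    def test_bounded_by_pearson_r(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(scale=rng.uniform(0.1, 2.0), size=n) \
                + rng.uniform(-2.0, 2.0)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(lins_ccc(x, y)) <= abs(r) + 1e-12

    def test_degenerate_cases(self):
        assert lins_ccc([3.0, 3.0], [3.0, 3.0]) == 1.0
        assert lins_ccc([3.0, 3.0], [4.0, 4.0]) == 0.0
        with pytest.raises(ValidationError):
            lins_ccc([1.0], [1.0])
        with pytest.raises(ValidationError):
            lins_ccc([1.0, np.inf], [1.0, 2.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20),
           st.data())
    def test_always_in_unit_ball(self, x, data):
        y = data.draw(st.lists(st.floats(-100, 100), min_size=len(x),
                               max_size=len(x)))
        assert -1.0 - 1e-9 <= lins_ccc(x, y) <= 1.0 + 1e-9


class TestCCCConfidence:
    def test_interval_orders_around_point(self):
        lo, hi = ccc_confidence(0.9, 50)
        assert lo < 0.9 < hi
        (lo1,) = ccc_confidence(0.9, 50, sided="lower")
        assert lo1 < 0.9

    def test_limits_tighten_with_n(self):
        lo_small, hi_small = ccc_confidence(0.9, 20)
        lo_big, hi_big = ccc_confidence(0.9, 20000)
        assert hi_big - lo_big < hi_small - lo_small
        assert lo_big == pytest.approx(0.9, abs=0.005)

    def test_degenerate_ccc_returns_point_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert ccc_confidence(1.0, 50) == (1.0, 1.0)
        assert "degenerate" in caplog.text

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            ccc_confidence(0.9, 3)

    def test_two_sided_coverage_on_bivariate_normal(self):
        """Fisher-z interval with Lin's variance covers the population CCC
        ~95% of the time (n=50 pairs, 2000 replicates)."""
        rng = np.random.default_rng(42)
        rho, s1, s2, d = 0.9, 1.0, 1.2, 0.3
        pop_ccc = 2 * rho * s1 * s2 / (s1**2 + s2**2 + d**2)
        cov = [[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]]
        hits = 0
        reps = 2000
        for _ in range(reps):
            xy = rng.multivariate_normal([0.0, d], cov, size=50)
            res = ccc_with_ci(xy[:, 0], xy[:, 1])
            hits += res.lower <= pop_ccc <= res.upper
        assert hits / reps == pytest.approx(0.95, abs=0.02)


class TestMcBride:
    @pytest.mark.parametrize("value,grade", [
        (0.50, "poor"),
        (0.8999, "poor"),
        (0.90, "moderate"),
        (0.94, "moderate"),
        (0.95, "substantial"),
        (0.983, "substantial"),
        (0.99, "substantial"),
        (0.991, "almost_perfect"),
        (0.999, "almost_perfect"),
    ])
    def test_bands(self, value, grade):
        assert mcbride_grade(value) == grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            mcbride_grade(1.5)


class TestCompareRiskMethods:
    def test_self_agreement_is_perfect(self, patient_factory, reg_model,
                                       pk_model, rng):
        """Replacing the PK engine by the regression engine itself yields
        CCC = 1 for every MIC."""
        patients = [patient_factory(c, pid=f"p{i}")
                    for i, c in enumerate((40.0, 70.0, 86.4, 120.0, 180.0))]
        report = compare_risk_methods(
            patients, reg_model, pk_model, rng=rng,
            pk_risk_factory=lambda p: partial(risk_regression, reg_model,
                                              p.resolve_clcr()))
        per_mic = report.table[report.table["stratum"] == "all"]
        assert np.allclose(per_mic["ccc"], 1.0)
        assert report.pooled["all"].ccc == pytest.approx(1.0)

    def test_constant_offset_lowers_ccc_increasingly(self, patient_factory,
                                                     reg_model, pk_model, rng):
        patients = [patient_factory(c, pid=f"p{i}")
                    for i, c in enumerate((40.0, 70.0, 86.4, 120.0, 180.0))]

        def offset_factory(delta):
            def factory(p):
                base = partial(risk_regression, reg_model, p.resolve_clcr())
                return lambda mic: min(base(mic) + delta, 1.0)
            return factory

        cccs = [
            compare_risk_methods(patients, reg_model, pk_model, rng=rng,
                                 pk_risk_factory=offset_factory(d)).pooled["all"].ccc
            for d in (0.0, 0.05, 0.15)
        ]
        assert cccs[0] > cccs[1] > cccs[2]

    def test_report_structure_and_strata(self, patient_factory, reg_model,
                                         pk_model, rng):
        patients = [patient_factory(c, pid=f"p{i}")
                    for i, c in enumerate((40.0, 48.0, 86.4, 120.0, 180.0))]
        report = compare_risk_methods(patients, reg_model, pk_model,
                                      n_replicates=300, rng=rng)
        assert isinstance(report, AgreementReport)
        assert set(report.paired.columns) >= {"patient_id", "clcr", "mic",
                                              "risk_regression", "risk_pk"}
        assert len(report.paired) == 5 * 8
        strata = set(report.table["stratum"])
        assert strata == {"all", "clcr_gt_50"}
        # stratum rows use only the 3 patients above 50 mL/min
        pooled_stratum = report.pooled["clcr_gt_50"]
        assert pooled_stratum.n == 3 * 8

    def test_empty_stratum_omitted_with_warning(self, patient_factory, reg_model,
                                                pk_model, rng, caplog):
        patients = [patient_factory(40.0)]
        with caplog.at_level("WARNING"):
            report = compare_risk_methods(
                patients, reg_model, pk_model, n_replicates=100, rng=rng,
                strata={"clcr_gt_200": lambda c: c > 200.0})
        assert "clcr_gt_200" not in report.pooled
        assert "empty" in caplog.text


class TestSuccessCriterion:
    def _report_with_lower(self, lower):
        from meronat import CCCResult
        res = CCCResult(ccc=0.99, lower=lower, upper=0.999,
                        lower_one_sided=lower, n=100, grade="substantial")
        import pandas as pd
        return AgreementReport(paired=pd.DataFrame(), table=pd.DataFrame(),
                               pooled={"all": res}, mic_grid=(0.125, 16.0))

    def test_true_above_threshold(self):
        assert success_criterion(self._report_with_lower(0.98)) is True

    def test_boundary_is_strict(self):
        assert success_criterion(self._report_with_lower(0.95)) is False

    def test_missing_pooled_is_error(self):
        import pandas as pd
        report = AgreementReport(paired=pd.DataFrame(), table=pd.DataFrame(),
                                 pooled={}, mic_grid=(0.125, 16.0))
        with pytest.raises(ValidationError):
            success_criterion(report)
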