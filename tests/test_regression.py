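"""OLS/CPD machinery, decision-model regressions, derivative estimation and
orthogonalisation, cross-checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pfcdyn import regression as reg, synthetic as syn
from pfcdyn.containers import SpikeRaster


class TestBinRates:
    def test_count_over_width(self):
        ras = SpikeRaster(spikes=[np.array([10.0, 150.0])], window_ms=(0, 1000))
        rates = reg.bin_rates(ras, bin_width_ms=200.0, step_ms=200.0)
        assert rates.bin_centers_ms[0] == pytest.approx(100.0)
        assert rates.rates[0, 0] == pytest.approx(10.0)  # 2 spikes / 0.2 s
        assert not rates.rates[0, 1:].any()

    def test_empty_raster_all_zero(self):
        ras = SpikeRaster(spikes=[np.array([])] * 3, window_ms=(-500, 1000))
        rates = reg.bin_rates(ras)
        assert not rates.rates.any()

    def test_homogeneous_poisson_recovers_rate(self, trials500):
        model = syn.SpikeModel(
            baseline_hz=20.0, dv_weight_hz=0, choice_weight_hz=0, cv_weight_hz=0
        )
        rasters, _ = syn.gen_spikes(trials500, model, None, n_units=1, seed=5)
        rates = reg.bin_rates(rasters[0])
        # mean across trials and bins ~ 20 Hz within sampling error
        assert rates.rates.mean() == pytest.approx(20.0, abs=0.5)

    def test_nonpositive_width_rejected(self):
        ras = SpikeRaster(spikes=[np.array([])], window_ms=(0, 1000))
        with pytest.raises(ValueError):
            reg.bin_rates(ras, bin_width_ms=0.0)


class TestOls:
    def test_exact_line(self):
        x = np.arange(5.0)
        y = 2 * x + 1
        fit = reg.ols(y, np.column_stack([np.ones(5), x]))
        assert np.allclose(fit.coef[0], [1.0, 2.0])
        assert fit.sse[0] == pytest.approx(0.0, abs=1e-20)

    def test_orthogonal_regressor_gets_zero_slope(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        fit = reg.ols(y, np.column_stack([np.ones(4), x]))
        assert fit.coef[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels(self):
        """Coefficients, classical SEs and t/Z stats agree with the
        statsmodels OLS implementation on a random system."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 2))])
        y = X @ [1.0, 0.5, -2.0] + rng.normal(size=50)
        fit = reg.ols(y, X)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(fit.coef[0], ref.params, atol=1e-10)
        assert np.allclose(fit.se[0], ref.bse, atol=1e-10)
        assert np.allclose(fit.z[0], ref.tvalues, atol=1e-8)
        assert fit.sse[0] == pytest.approx(ref.ssr, abs=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = reg.ols(y, X)
        assert np.allclose(fit.coef[0], beta, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            reg.ols(np.zeros(10), X, names=["const", "x", "dup"])


class TestCpd:
    def test_hand_worked_example(self):
        """y = [1..4] on {intercept, x=[1..4]}: dropping x leaves SSE 5,
        the full model fits exactly, so CPD = 1."""
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), np.arange(1.0, 5.0)])
        assert reg.cpd(y, X, [1])[0] == pytest.approx(1.0)
        # and the reduced-model SSE is indeed 5
        assert reg.ols(y, X[:, :1]).sse[0] == pytest.approx(5.0)

    def test_irrelevant_factor_near_zero(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        assert reg.cpd(y, X, [1])[0] < 0.01

    def test_equals_two_independent_fits(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        y = rng.normal(size=30)
        got = reg.cpd(y, X, [2])[0]
        sse_full = np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        Xr = X[:, [0, 1, 3]]
        sse_red = np.sum((y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]) ** 2)
        assert got == pytest.approx(1 - sse_full / sse_red, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equals_squared_partial_correlation(self, seed):
        """For a single-column factor, CPD equals the squared partial
        correlation of y and the factor given the other regressors."""
        rng = np.random.default_rng(seed)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = X @ rng.normal(size=4) + rng.normal(size=n)
        Z = X[:, [0, 1, 2]]
        ry = reg.orthogonalize(y, Z[:, 1:])
        rx = reg.orthogonalize(X[:, 3], Z[:, 1:])
        partial_r2 = np.corrcoef(ry, rx)[0, 1] ** 2
        assert reg.cpd(y, X, [3])[0] == pytest.approx(partial_r2, abs=1e-10)

    def test_perfect_reduced_fit_flagged_nan(self):
        """If the reduced model already fits exactly the CPD is undefined
        and returned as NaN."""
        y = np.full(6, 3.0)
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        assert np.isnan(reg.cpd(y, X, [1])[0])

    def test_null_cpd_mean_near_chance_level(self):
        """On task-independent data the per-bin CPD of one regressor
        averages ~ 1/(n - p) (Monte-Carlo)."""
        rng = np.random.default_rng(4)
        n, p = 60, 4
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        Y = rng.normal(size=(n, 400))
        cpds = reg.cpd(Y, X, [1])
        assert cpds.mean() == pytest.approx(1.0 / (n - p), rel=0.3)


class TestUnitDecisionModel:
    def test_constant_rates_give_chance_cpd(self, trials500):
        model = syn.SpikeModel(
            baseline_hz=15.0, dv_weight_hz=0, choice_weight_hz=0, cv_weight_hz=0
        )
        rasters, _ = syn.gen_spikes(trials500, model, None, n_units=1, seed=6)
        rates = reg.bin_rates(rasters[0])
        res = reg.unit_decision_model(rates, trials500)
        for factor, tc in res.cpd.items():
            assert tc.mean() < 3 * res.chance_cpd

    def test_perfect_value_difference_coding(self, trials500):
        X, names, factors = reg.decision_design(trials500)
        dv = X[:, names.index("value_diff")]
        Y = np.tile(dv[:, None], (1, 3))
        res = reg.regression_result(Y, X, names, factors, np.arange(3))
        assert np.allclose(res.cpd["value_diff"], 1.0)

    def test_early_dv_to_late_choice_transition(self, trials500):
        """Generated units switch from value-difference to chosen-action
        coding: the CPD peaks are ordered in time accordingly."""
        model = syn.SpikeModel(baseline_hz=20.0, cv_weight_hz=0.0, gain_sd=0.0)
        rasters, _ = syn.gen_spikes(trials500, model, None, n_units=3, seed=7)
        peaks = []
        for ras in rasters:
            res = reg.unit_decision_model(reg.bin_rates(ras), trials500)
            peaks.append(
                (
                    res.bin_centers_ms[np.argmax(res.cpd["value_diff"])],
                    res.bin_centers_ms[np.argmax(res.cpd["choice"])],
                )
            )
        assert all(t_dv < t_ch for t_dv, t_ch in peaks)

    def test_early_dv_selectivity_predicts_late_choice_selectivity(self, trials500):
        """Across units whose action-frame drives share a preferred side by
        construction, the Z-statistic for value difference at 300 ms
        correlates positively with the Z-statistic for choice at 700 ms."""
        rasters, _ = syn.gen_spikes(trials500, None, None, n_units=25, seed=17)
        z300, z700 = [], []
        for ras in rasters:
            rates = reg.bin_rates(ras, step_ms=50.0)
            res = reg.unit_decision_model(rates, trials500)
            i300 = np.argmin(np.abs(res.bin_centers_ms - 300))
            i700 = np.argmin(np.abs(res.bin_centers_ms - 700))
            z300.append(res.z[i300, res.factor_names.index("value_diff")])
            z700.append(res.z[i700, res.factor_names.index("choice")])
        assert np.corrcoef(z300, z700)[0, 1] > 0.5

    def test_single_trial_type_drops_constant(self, trials500):
        tr = trials500.copy()
        tr["trial_type"] = "effort"
        with pytest.warns(UserWarning, match="dropping constant"):
            X, names, _ = reg.decision_design(tr)
        assert "const_delay" not in names


class TestLfpValueRegression:
    def test_null_calibration(self, trials500):
        """Value-free LFP: ~5% of |Z| > 2 across timepoints/electrodes."""
        model = syn.ErpModel(amp_gain=0, latency_gain=0, latency_error=0)
        arrays, _ = syn.gen_lfp(trials500, model, 4, ("DLPFC",), seed=8)
        z, _, _, _ = reg.lfp_value_regression(arrays, trials500)
        frac = (np.abs(z) > 2).mean()
        assert 0.01 < frac < 0.10

    def test_early_value_sum_coding_same_sign(self, trials500, lfp_default):
        arrays, _ = lfp_default
        _, mean_z, _, t = reg.lfp_value_regression(arrays, trials500)
        early = (t >= 50) & (t <= 250)
        i = np.argmax(np.abs(mean_z[early, 0]))
        zc, zu = mean_z[early][i]
        assert np.sign(zc) == np.sign(zu)

    def test_value_coefficients_peak_on_the_ramp(self, trials500, lfp_default):
        """Latency-driven value coding peaks where the ERP derivative is
        large, not at the ERP peak."""
        arrays, _ = lfp_default
        _, mean_z, _, t = reg.lfp_value_regression(arrays, trials500)
        mean_erp = np.mean([a.data.mean(axis=0) for a in arrays], axis=0)
        deriv = reg.erp_derivative(mean_erp, t)
        late = t >= 250
        t_peak_z = t[late][np.argmax(np.abs(mean_z[late, 0]))]
        t_peak_erp = t[late][np.argmax(mean_erp[late])]
        slope_at_z = abs(deriv[np.argmin(np.abs(t - t_peak_z))])
        slope_at_erp = abs(deriv[np.argmin(np.abs(t - t_peak_erp))])
        assert slope_at_z > slope_at_erp
        assert abs(t_peak_z - t_peak_erp) > 50


class TestErpDerivative:
    def test_constant_and_ramp(self):
        t = np.arange(0, 1000, 10.0)
        assert np.allclose(reg.erp_derivative(np.ones_like(t), t), 0.0)
        ramp = 0.3 * t
        d = reg.erp_derivative(ramp, t)
        assert np.allclose(d[5:-5], 0.3, atol=1e-9)

    def test_sinusoid_within_smoothing_attenuation(self):
        f = 2.0  # Hz
        t = np.arange(0, 2000, 10.0)
        wave = np.sin(2 * np.pi * f * t / 1000.0)
        d = reg.erp_derivative(wave, t, smooth_window_ms=80.0)
        omega = 2 * np.pi * f / 1000.0
        atten = np.sinc(f * 0.08)  # boxcar attenuation at 80 ms
        expect = omega * atten * np.cos(omega * t)
        assert np.allclose(d[20:-20], expect[20:-20], atol=0.05 * omega)

    def test_short_window_rejected(self):
        t = np.arange(0, 100, 10.0)
        with pytest.raises(ValueError):
            reg.erp_derivative(np.zeros_like(t), t, smooth_window_ms=10.0)


class TestOrthogonalize:
    def test_unchanged_when_orthogonal(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        Z = np.array([1.0, 1.0, -1.0, -1.0])
        assert np.allclose(reg.orthogonalize(x, Z), x)

    def test_zero_when_in_span(self):
        Z = np.arange(10.0)
        assert np.allclose(reg.orthogonalize(3 * Z + 2, Z), 0.0, atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_residual_orthogonal_to_every_column(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        Z = rng.normal(size=(30, 3))
        r = reg.orthogonalize(x, Z)
        assert np.max(np.abs(r @ Z)) < 1e-8
        assert abs(r.sum()) < 1e-8  # intercept included


class TestPcWeightRegression:
    def test_null_weights_no_spurious_effects(self, trials500):
        rng = np.random.default_rng(9)
        hits = 0
        for rep in range(30):
            tab = reg.pc_weight_regression(rng.normal(size=len(trials500)), trials500)
            hits += (tab.z.drop("intercept").abs() > 2).sum()
        assert hits / (30 * 3) < 0.12

    def test_latency_component_value_and_error_signs(self, decomposition, trials500):
        """Higher chosen value and error trials both push the latency
        component's weights positive (earlier waveform)."""
        from pfcdyn import pca

        d, _, _ = decomposition
        lc = pca.latency_component(d)
        trials_rows = trials500.set_index("trial_id").loc[d.row_index.trial_id].reset_index()
        tab = reg.pc_weight_regression(d.U[:, lc], trials_rows)
        assert tab.loc["chosen_value", "z"] > 2
        assert tab.loc["error", "z"] > 2

    def test_rt_coefficient_negative_on_meg_data(self):
        from pfcdyn import pca

        arrays, trials, truth = syn.gen_meg_subjects(
            n_subjects=6, trials_per_subject=150, seed=10
        )
        signs = pca.align_subject_signs(arrays)
        for arr, s in zip(arrays, signs):
            arr.data = s * arr.data
        st_ = pca.stack(arrays)
        d = pca.decompose(st_, k=6)
        lc = pca.latency_component(d)
        rows = trials.iloc[
            [
                i
                for sid, a in zip(range(len(arrays)), arrays)
                for i in np.flatnonzero((trials.subject_id == a.subject_id).to_numpy())
            ]
        ]
        # row order of the stack follows (session=subject, electrode) sorted
        tab = reg.pc_weight_regression(d.U[:, lc], rows.reset_index(), include_rt=True)
        assert tab.loc["rt", "coef"] < 0
        assert tab.loc["chosen_value", "coef"] > 0
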