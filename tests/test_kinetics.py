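"""FRAP normalization, exponential fitting, model selection, actin half-times."""

import numpy as np
import pytest
from scipy import stats

from slbphase import (
    FrapGenParams,
    KineticTrace,
    actin_halftime,
    actin_halftimes,
    fit_decay,
    fit_recovery,
    gen_actin_timecourse,
    gen_frap_trace,
    normalize_frap,
    select_model,
)
from slbphase.kinetics import ExpFit, detect_bleach_frame


def _trace(times, values, **kw):
    return KineticTrace(times=np.asarray(times, float), values=np.asarray(values, float), **kw)


class TestNormalizeFrap:
    def test_identity_without_bleach_or_decay(self):
        tr = _trace(np.arange(10), np.full(10, 250.0), n_prebleach=4)
        out = normalize_frap(tr)
        assert np.allclose(out.values, 1.0)

    def test_direct_arithmetic_with_background(self):
        # pre-bleach 100, background 10, reference constant 100, first
        # post-bleach value 40 -> (40-10)/(100-10) = 1/3
        values = np.array([100.0, 100.0, 100.0, 40.0, 50.0])
        ref = np.full(5, 100.0)
        tr = _trace(np.arange(5), values, n_prebleach=3, reference=ref, background=10.0)
        out = normalize_frap(tr)
        assert out.values[3] == pytest.approx(1.0 / 3.0)
        assert out.values[:3].mean() == pytest.approx(1.0)

    def test_undoes_generator_acquisition_bleaching(self):
        p = FrapGenParams(
            tau_values=(20.0,), bleach_depth=0.7, acq_bleach_tau=300.0,
            frame_interval=1.0, duration=120.0, noise_sd=0.0,
        )
        trace, _ = gen_frap_trace(p)
        out = normalize_frap(trace)
        t, y = out.postbleach()
        expected = 0.3 + 0.7 * (1 - np.exp(-t / 20.0))
        assert np.allclose(y, expected, atol=1e-9)

    def test_requires_prebleach_points(self):
        with pytest.raises(ValueError, match="pre-bleach"):
            normalize_frap(_trace([0, 1, 2], [1, 0.4, 0.5], n_prebleach=1))

    def test_reference_at_background_rejected(self):
        tr = _trace([0, 1, 2, 3], [5, 5, 2, 3], n_prebleach=2,
                    reference=np.array([5.0, 5.0, 1.0, 5.0]), background=1.0)
        with pytest.raises(ValueError, match="reference"):
            normalize_frap(tr)


class TestDetectBleachFrame:
    def test_finds_first_big_drop(self, rng):
        values = np.concatenate([1 + 0.001 * rng.standard_normal(8), [0.3, 0.5, 0.7]])
        tr = _trace(np.arange(11), values)
        assert detect_bleach_frame(tr, n_baseline=8) == 8

    def test_no_bleach_raises(self):
        tr = _trace(np.arange(10), np.ones(10) + 1e-6 * np.arange(10))
        with pytest.raises(ValueError, match="no bleach"):
            detect_bleach_frame(tr)


class TestFitRecovery:
    def test_noiseless_single_exponential_exact(self):
        p = FrapGenParams(
            tau_values=(1.3,), bleach_depth=0.8, frame_interval=0.05,
            duration=15.0, noise_sd=0.0,
        )
        trace, _ = gen_frap_trace(p)
        fit = fit_recovery(normalize_frap(trace), n_components=1)
        assert fit.taus[0] == pytest.approx(1.3, rel=1e-4)
        assert fit.plateau == pytest.approx(1.0, rel=1e-4)

    def test_noiseless_biexponential_exact(self):
        p = FrapGenParams(
            tau_values=(86.0, 526.0), fractions=(0.76, 0.24), bleach_depth=0.8,
            frame_interval=2.0, duration=2000.0, noise_sd=0.0,
        )
        trace, _ = gen_frap_trace(p)
        fit = fit_recovery(normalize_frap(trace), n_components=2)
        assert fit.taus[0] == pytest.approx(86.0, rel=1e-3)
        assert fit.taus[1] == pytest.approx(526.0, rel=1e-3)
        assert fit.amplitudes[0] == pytest.approx(0.76, abs=1e-3)

    def test_flat_trace_rejected(self):
        tr = _trace(np.arange(40), np.ones(40), n_prebleach=5)
        with pytest.raises(ValueError, match="flat"):
            fit_recovery(tr, n_components=1)

    def test_time_shift_and_scale_invariance(self):
        p = FrapGenParams(
            tau_values=(10.0,), bleach_depth=0.6, frame_interval=0.5,
            duration=80.0, noise_sd=0.005, seed=4,
        )
        trace, _ = gen_frap_trace(p)
        norm = normalize_frap(trace)
        fit_a = fit_recovery(norm, n_components=1)
        shifted = KineticTrace(
            times=norm.times + 137.0, values=norm.values, n_prebleach=norm.n_prebleach
        )
        fit_b = fit_recovery(shifted, n_components=1)
        assert fit_a.taus[0] == pytest.approx(fit_b.taus[0], rel=1e-9)
        # global intensity scaling of the raw trace is removed by normalization
        raw_scaled = KineticTrace(
            times=trace.times, values=500.0 * trace.values,
            n_prebleach=trace.n_prebleach, reference=trace.reference,
        )
        fit_c = fit_recovery(normalize_frap(raw_scaled), n_components=1)
        assert fit_c.taus[0] == pytest.approx(fit_a.taus[0], rel=1e-9)

    def test_parameter_recovery_within_ci_coverage(self):
        """Fitted (tau_i, fractions) cover truth at ~95% CI level."""
        taus_true = (2.6, 43.0)
        fracs_true = (0.37, 0.63)
        inside = np.zeros(3)
        n_seeds = 40
        for seed in range(n_seeds):
            p = FrapGenParams(
                tau_values=taus_true, fractions=fracs_true, bleach_depth=0.8,
                frame_interval=0.25, duration=300.0, noise_sd=0.01, seed=seed,
            )
            trace, _ = gen_frap_trace(p)
            fit = fit_recovery(normalize_frap(trace), n_components=2)
            truth = [taus_true[0], taus_true[1], fracs_true[0]]
            half = [fit.ci95[0], fit.ci95[1], fit.ci95_fractions[0]]
            est = [fit.taus[0], fit.taus[1], fit.amplitudes[0]]
            for k in range(3):
                if abs(est[k] - truth[k]) <= half[k]:
                    inside[k] += 1
        assert np.all(inside / n_seeds >= 0.9)


class TestSelectModel:
    @staticmethod
    def _fit(ss, df, n):
        return ExpFit(
            n_components=1, taus=(1.0,), amplitudes=(1.0,), plateau=1.0,
            bleach_floor=0.0, ss_residual=ss, df=df, n_points=n,
        )

    def test_no_improvement_prefers_single(self):
        choice = select_model(self._fit(5.0, 100, 103), self._fit(5.0, 98, 103))
        assert choice.F_stat == 0.0
        assert choice.preferred == "single"

    def test_textbook_formula(self):
        choice = select_model(self._fit(10.0, 100, 103), self._fit(5.0, 98, 103))
        assert choice.F_stat == pytest.approx(49.0)
        assert choice.df_num == 2 and choice.df_den == 98
        assert choice.preferred == "double"

    def test_perfect_double_fit(self):
        choice = select_model(self._fit(10.0, 100, 103), self._fit(0.0, 98, 103))
        assert choice.p_value == 0.0
        assert choice.preferred == "double"

    def test_df_violation_rejected(self):
        with pytest.raises(ValueError):
            select_model(self._fit(10.0, 98, 103), self._fit(5.0, 100, 103))

    def test_power_on_well_separated_biexponential(self):
        """tau ratio >= 10 with both fractions >= 20%: double wins."""
        n_double = 0
        for seed in range(20):
            p = FrapGenParams(
                tau_values=(5.0, 80.0), fractions=(0.4, 0.6), bleach_depth=0.8,
                frame_interval=0.5, duration=400.0, noise_sd=0.01, seed=100 + seed,
            )
            trace, _ = gen_frap_trace(p)
            norm = normalize_frap(trace)
            choice = select_model(
                fit_recovery(norm, n_components=1), fit_recovery(norm, n_components=2)
            )
            n_double += choice.preferred == "double"
        assert n_double >= 19


class TestFitDecay:
    def test_noiseless_dissociation_constant(self):
        t = np.arange(0, 6001, 60.0)
        tr = _trace(t, 1.0 * np.exp(-t / 2080.0) + 0.02)
        fit = fit_decay(tr)
        assert fit.taus[0] == pytest.approx(2080.0, rel=1e-4)
        assert fit.plateau == pytest.approx(0.02, abs=1e-5)

    def test_noisy_recovery_within_5_percent(self):
        t = np.arange(0, 6001, 60.0)
        rng = np.random.default_rng(8)
        tr = _trace(t, np.exp(-t / 2080.0) + rng.normal(0, 0.01, t.size))
        fit = fit_decay(tr)
        assert fit.taus[0] == pytest.approx(2080.0, rel=0.05)

    def test_flat_trace_flagged(self):
        with pytest.raises(ValueError, match="flat"):
            fit_decay(_trace(np.arange(10.0), np.full(10, 3.0)))


class TestActinHalftimes:
    def test_step_trace_halftime_is_step_frame(self):
        values = np.array([0.0, 0.0, 0.0, 5.0, 5.0, 5.0])
        t_half = actin_halftime(_trace(np.arange(6.0) * 3, values), window=27.0)
        assert t_half == pytest.approx(9.0)

    def test_linear_ramp_halftime_is_midpoint(self):
        t = np.linspace(0, 10, 11)
        tr = _trace(t, t)  # 0 -> max over [0, 10]
        assert actin_halftime(tr, window=27.0, n_baseline=1) == pytest.approx(5.0)

    def test_no_assembly_flagged(self):
        tr = _trace(np.arange(10.0), np.full(10, 1.0) + 1e-3)
        with pytest.raises(ValueError, match="no assembly"):
            actin_halftime(tr)

    def test_stochastic_lags_uncorrelated_with_area(self, rng):
        traces = gen_actin_timecourse(
            n_clusters=50, lag_range_min=(6.0, 15.0), noise_sd=0.002, seed=11
        )
        features = [
            {"area": float(a), "receptor_intensity": float(i)}
            for a, i in zip(rng.uniform(0.5, 5, 50), rng.uniform(100, 400, 50))
        ]
        res = actin_halftimes(traces, features)
        assert not res["undefined"].any()
        rho, p = res["spearman_area"]
        assert abs(rho) < 0.4
        assert p > 0.05
        lags = res["t_half"]
        assert lags.min() >= 6.0
        assert lags.max() <= 15.0 + 5.0  # half-rise occurs shortly after lag
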