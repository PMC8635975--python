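"""Filtering, baseline subtraction, dF/F0, charge, fits, voltage curves."""

import numpy as np
import pytest

from vsdquench import (
    ExponentialFit,
    SweepRecording,
    VoltageProtocol,
    average_sweeps,
    bessel_lowpass,
    boltzmann_fit,
    build_voltage_curve,
    cole_moore_tau,
    compute_dFF0,
    fit_exponential,
    integrate_charge,
)
from vsdquench.analysis import pulse_onset


def make_step_sweep(f0=1000.0, step=-5.0, drift=0.0, noise_sd=0.0, seed=0,
                    baseline_ms=10.0, pulse_ms=20.0, tail_ms=5.0, dt=0.05):
    proto = VoltageProtocol(
        ((baseline_ms, -120.0), (pulse_ms, 80.0), (tail_ms, -120.0)),
        -120.0,
        dt,
    )
    t = proto.times()
    f = np.full(t.size, f0) + drift * t
    in_pulse = (t >= baseline_ms) & (t < baseline_ms + pulse_ms)
    f[in_pulse] += step
    if noise_sd > 0:
        f = f + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return SweepRecording(proto, 1.0 / dt, f)


class TestBesselLowpass:
    def test_dc_gain_unity(self):
        x = np.full(2000, 3.7)
        y = bessel_lowpass(x, sample_rate=50.0, cutoff=1.0)
        assert np.max(np.abs(y - 3.7)) < 1e-9

    def test_stopband_attenuation_30db(self):
        fs, fc = 50.0, 1.0  # kHz
        t = np.arange(0, 50.0, 1 / fs)  # ms
        x = np.sin(2 * np.pi * 10.0 * t)  # 10x the cutoff
        y = bessel_lowpass(x, fs, fc)
        settled = y[t > 10.0]
        assert np.max(np.abs(settled)) < 10 ** (-30 / 20)

    def test_white_noise_variance_reduced(self):
        x = np.random.default_rng(1).normal(0, 1, 50_000)
        y = bessel_lowpass(x, 50.0, 1.0)
        assert np.var(y[1000:]) < 0.2 * np.var(x)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bessel_lowpass(np.zeros(100), 10.0, 5.0)


class TestAverageSweeps:
    def test_self_average_identity(self):
        s = make_step_sweep()
        avg = average_sweeps([s, s])
        assert np.array_equal(avg.fluorescence, s.fluorescence)
        assert avg.n_averaged == 2

    def test_mismatched_rates_rejected(self):
        a = make_step_sweep(dt=0.05)
        b = make_step_sweep(dt=0.1)
        with pytest.raises(ValueError, match="protocol and sample rate"):
            average_sweeps([a, b])

    def test_noise_sd_halves_with_four_sweeps(self):
        rng_sd = []
        sweeps = [make_step_sweep(noise_sd=1.0, seed=s, baseline_ms=50.0) for s in range(4)]
        avg = average_sweeps(sweeps)
        t = avg.times
        base = avg.fluorescence[t < 50.0] - 1000.0
        assert np.std(base) == pytest.approx(0.5, rel=0.1)


class TestComputeDFF0:
    def test_noiseless_step_exact(self):
        s = make_step_sweep(f0=1000.0, step=-5.0)
        dff0 = compute_dFF0(s, (0.0, 10.0), (25.0, 30.0))
        assert dff0 == pytest.approx(-0.5, abs=1e-12)

    def test_pure_drift_removed(self):
        proto = VoltageProtocol(((10.0, -120.0), (20.0, 80.0), (5.0, -120.0)), -120.0, 0.05)
        t = proto.times()
        s = SweepRecording(proto, 20.0, 1000.0 + 2.5 * t)
        dff0 = compute_dFF0(s, (0.0, 10.0), (25.0, 30.0))
        assert abs(dff0) < 1e-9

    def test_scale_invariance(self):
        s = make_step_sweep()
        s2 = SweepRecording(s.protocol, s.sample_rate, 7.3 * s.fluorescence)
        a = compute_dFF0(s, (0.0, 10.0), (25.0, 30.0))
        b = compute_dFF0(s2, (0.0, 10.0), (25.0, 30.0))
        assert a == pytest.approx(b, rel=1e-12)

    def test_ci_contains_truth(self):
        sweeps = [make_step_sweep(noise_sd=0.5, seed=s) for s in range(20)]
        avg = average_sweeps(sweeps)
        val, (lo, hi) = compute_dFF0(avg, (0.0, 10.0), (25.0, 30.0), with_ci=True)
        assert lo < -0.5 < hi

    def test_consistency_under_averaging(self):
        """RMS error of dF/F0 shrinks as more sweeps are averaged."""
        truth = -0.5
        rms = {}
        rng = np.random.default_rng(0)
        proto_sweep = make_step_sweep()
        for n in (4, 16, 64):
            errs = []
            for _ in range(30):
                noise = rng.normal(0, 2.0, proto_sweep.fluorescence.size) / np.sqrt(n)
                s = SweepRecording(
                    proto_sweep.protocol,
                    proto_sweep.sample_rate,
                    proto_sweep.fluorescence + noise,
                    n_averaged=n,
                )
                errs.append(compute_dFF0(s, (0.0, 10.0), (25.0, 30.0)) - truth)
            rms[n] = np.sqrt(np.mean(np.square(errs)))
        assert rms[64] < rms[16] < rms[4]

    def test_baseline_after_onset_rejected(self):
        s = make_step_sweep()
        with pytest.raises(ValueError, match="onset"):
            compute_dFF0(s, (5.0, 15.0), (25.0, 30.0))

    def test_nonpositive_f0_rejected(self):
        s = make_step_sweep(f0=0.0, step=-5.0)
        with pytest.raises(ValueError, match="F0"):
            compute_dFF0(s, (0.0, 10.0), (25.0, 30.0))

    def test_degenerate_baseline_rejected(self):
        s = make_step_sweep()
        with pytest.raises(ValueError, match="2 samples|empty window"):
            compute_dFF0(s, (0.0, 0.05), (25.0, 30.0))


class TestIntegrateCharge:
    def test_rectangular_pulse_exact(self):
        fs = 10.0  # kHz
        t = np.arange(0, 15.0, 1 / fs)
        x = np.where((t >= 5.0) & (t < 10.0), 2.0, 0.0)
        q = integrate_charge(x, fs, [(0.0, 4.0), (12.0, 15.0)], (4.0, 11.0))
        assert q == pytest.approx(10.0, rel=1e-12)

    def test_noise_only_statistical_bound(self):
        fs, T = 10.0, 50.0
        rng = np.random.default_rng(4)
        sd = 0.3
        x = rng.normal(0, sd, int(T * fs))
        q = integrate_charge(x, fs, [(0.0, 10.0), (40.0, 50.0)])
        assert abs(q) < 3 * sd * np.sqrt(T / fs)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            integrate_charge(np.zeros(100), 10.0, [(0.0, 5.0)], (5.0, 100.0))


class TestFitExponential:
    def test_exact_single_exponential(self):
        t = np.linspace(0, 50, 500)
        y = 2.0 + 5.0 * np.exp(-t / 10.0)
        fit = fit_exponential(y, t, order=1)
        assert fit.taus[0] == pytest.approx(10.0, rel=1e-6)
        assert fit.weighted_tau == fit.taus[0]

    def test_weighted_tau_equal_amplitudes(self):
        fit = ExponentialFit(2, (1.0, 1.0), (2.0, 8.0), 0.0, 0.0)
        assert fit.weighted_tau == pytest.approx(5.0)

    def test_order_two_collapses_on_single_exponential_truth(self):
        t = np.linspace(0, 60, 600)
        y = 1.0 + 4.0 * np.exp(-t / 7.0)
        fit = fit_exponential(y, t, order=2)
        assert fit.weighted_tau == pytest.approx(7.0, rel=0.01)

    def test_noisy_recovery_median_error(self):
        t = np.linspace(0, 50, 200)
        truth = 10.0
        errors = []
        for seed in range(200):
            y = 5.0 * np.exp(-t / truth) + np.random.default_rng(seed).normal(0, 0.5, t.size)
            fit = fit_exponential(y, t, order=1)
            errors.append(abs(fit.taus[0] - truth) / truth)
        assert np.median(errors) < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            fit_exponential(np.ones(5), np.arange(5.0), order=1)


class TestVoltageCurves:
    def test_minmax_normalization(self):
        vals = [(-80.0, 0.0, "a"), (-40.0, 1.0, "a"), (0.0, 2.0, "a"), (40.0, 4.0, "a")]
        curve = build_voltage_curve(vals, "QV")
        assert np.allclose(curve.values, [0.0, 0.25, 0.5, 1.0])

    def test_scale_factor_invariance(self):
        base = [(-80.0, 0.0), (-40.0, 1.0), (0.0, 2.0), (40.0, 4.0)]
        vals = [(v, y, "a") for v, y in base] + [(v, 3.5 * y, "b") for v, y in base]
        curve = build_voltage_curve(vals, "QV")
        assert np.allclose(curve.values, [0.0, 0.25, 0.5, 1.0])
        assert np.allclose(curve.sem, 0.0)

    def test_zero_span_rejected(self):
        vals = [(-80.0, 1.0, "a"), (0.0, 1.0, "a")]
        with pytest.raises(ValueError, match="span"):
            build_voltage_curve(vals, "QV")

    def test_boltzmann_round_trip(self):
        kT = 25.4
        v = np.arange(-120.0, 41.0, 10.0)
        q = 1.0 / (1.0 + np.exp(-2.0 * (v - (-40.0)) / kT))
        curve = build_voltage_curve([(vv, qq, "a") for vv, qq in zip(v, q)], "QV", normalize=False)
        vhalf, z = boltzmann_fit(curve, kT=kT)
        assert vhalf == pytest.approx(-40.0, abs=0.1)
        assert z == pytest.approx(2.0, abs=0.01)

    def test_left_shift_detected(self):
        kT = 25.4
        v = np.arange(-120.0, 41.0, 10.0)

        def make(vh):
            q = 1.0 / (1.0 + np.exp(-2.0 * (v - vh) / kT))
            c = build_voltage_curve([(vv, qq, "a") for vv, qq in zip(v, q)], "QV", normalize=False)
            return boltzmann_fit(c, kT=kT)[0]

        assert make(-60.0) < make(-40.0)

    def test_too_few_points_rejected(self):
        curve = build_voltage_curve(
            [(-80.0, 0.0, "a"), (0.0, 0.5, "a"), (80.0, 1.0, "a")], "QV"
        )
        with pytest.raises(ValueError, match="4 points"):
            boltzmann_fit(curve)


class TestColeMooreTau:
    def _sweep(self, prepulse_ms, tau=5.0, amp=3.0):
        proto = VoltageProtocol(
            ((10.0, -120.0), (prepulse_ms, -160.0), (40.0, 80.0), (10.0, -120.0)),
            -120.0,
            0.1,
        )
        t = proto.times()
        onset = 10.0 + prepulse_ms
        f = np.full(t.size, 100.0)
        m = (t >= onset) & (t < onset + 40.0)
        f[m] += amp * (1 - np.exp(-(t[m] - onset) / tau))
        return SweepRecording(proto, 10.0, f)

    def test_identical_recordings_identical_tau(self):
        groups = {
            (-160.0, 80.0): [self._sweep(80.0)],
            (-160.0, 1000.0): [self._sweep(1000.0)],
        }
        res = cole_moore_tau(groups)
        taus = [tau for _, _, tau in res.entries]
        assert taus[0] == pytest.approx(taus[1], rel=1e-3)
        assert taus[0] == pytest.approx(5.0, rel=0.02)

    def test_inconsistent_test_pulses_rejected(self):
        a = self._sweep(80.0)
        proto_b = VoltageProtocol(
            ((10.0, -120.0), (80.0, -160.0), (60.0, 80.0), (10.0, -120.0)),
            -120.0,
            0.1,
        )
        b = SweepRecording(proto_b, 10.0, np.full(proto_b.n_samples, 100.0))
        with pytest.raises(ValueError, match="differ"):
            cole_moore_tau({(-160.0, 80.0): [a], (-160.0, 81.0): [b]})


def test_pulse_onset_derived_from_protocol():
    proto = VoltageProtocol(((12.0, -120.0), (20.0, 80.0), (5.0, -120.0)), -120.0, 0.1)
    assert pulse_onset(proto) == 12.0
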