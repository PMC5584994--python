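"""Trace metrics: ΔF/F, noise, SNR, bleach correction, fits, propagation."""

import numpy as np
import pytest

import gevitrace as gt
from gevitrace.errors import (
    FitError,
    InvalidArgumentError,
    InvalidReferenceError,
    InvalidTraceError,
    UndefinedSNRError,
    UndefinedVelocityError,
    WindowTooShortError,
)
from gevitrace.trace import Event, Trace

from conftest import annotate, average_trials


def make_counts_trace(values, frame_rate=1000.0, **events):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.size) / frame_rate
    tr = Trace(times=times, values=values, kind="counts", frame_rate=frame_rate)
    return annotate(tr, **events)


class TestComputeDff:
    def test_simple_arithmetic(self):
        """Baseline mean 100 and a dip to 85 give a −0.15 peak."""
        vals = np.full(400, 100.0)
        vals[250] = 85.0
        tr = make_counts_trace(vals, spike_trigger=0.200)
        dff = gt.compute_dff(tr)
        assert dff.meta["f0"] == pytest.approx(100.0)
        assert dff.values.min() == pytest.approx(-0.15)

    def test_constant_trace_gives_zero(self):
        tr = make_counts_trace(np.full(400, 50.0), spike_trigger=0.200)
        assert np.allclose(gt.compute_dff(tr).values, 0.0)

    def test_round_trip_with_stored_f0(self):
        rng = np.random.default_rng(0)
        tr = make_counts_trace(rng.poisson(80.0, 400).astype(float), spike_trigger=0.2)
        back = gt.dff_to_counts(gt.compute_dff(tr))
        assert np.allclose(back.values, tr.values, atol=1e-12)

    def test_nonpositive_baseline_rejected(self):
        tr = make_counts_trace(np.zeros(400), spike_trigger=0.200)
        with pytest.raises(InvalidTraceError, match="positive"):
            gt.compute_dff(tr)

    def test_window_before_trace_rejected(self):
        tr = make_counts_trace(np.full(100, 10.0), spike_trigger=0.05)
        with pytest.raises(WindowTooShortError):
            gt.compute_dff(tr)

    def test_simulated_ap_peak_matches_forward_model(self, ap_dff_asap2s, ap_onset):
        """Trial-averaged single-voxel ASAP2s AP response at 925 Hz recovers
        the forward model's peak amplitude."""
        sched = gt.ScanSchedule(n_voxels=20)
        trials = [
            gt.simulate_photon_counts(ap_dff_asap2s, 500.0, sched, seed=s)
            for s in range(60)
        ]
        avg = annotate(average_trials(trials), spike_trigger=ap_onset)
        dff = gt.compute_dff(avg, trigger=ap_onset)
        amp, _ = gt.peak_amplitude(dff, trigger=ap_onset, search_ms=30.0)
        model_peak = float(np.abs(ap_dff_asap2s.values).max())
        assert amp == pytest.approx(model_peak, rel=0.1)


class TestNoiseAndSnr:
    def test_constant_trace_has_zero_noise(self):
        tr = make_counts_trace(np.full(500, 1.0), frame_rate=1000.0, stimulus_onset=0.3)
        dff = tr.with_values(np.zeros(500), kind="dff")
        assert gt.baseline_noise(dff, 0.3) == 0.0

    def test_poisson_noise_matches_coefficient_of_variation(self):
        """ΔF/F noise of Poisson counts at rate λ is ≈ 1/√λ."""
        rng = np.random.default_rng(3)
        lam, n = 100.0, 4000
        counts = rng.poisson(lam, n).astype(float)
        tr = make_counts_trace(counts, frame_rate=1000.0,
                               spike_trigger=3.5, stimulus_onset=3.5)
        dff = gt.compute_dff(tr, trigger=3.5)
        noise = gt.baseline_noise(dff, 3.5, window_ms=3000.0)
        se = (1 / np.sqrt(lam)) / np.sqrt(2 * 3000)
        assert noise == pytest.approx(1 / np.sqrt(lam), abs=3 * se)

    def test_short_prestimulus_window_rejected(self):
        tr = make_counts_trace(np.full(400, 10.0), stimulus_onset=0.150)
        dff = tr.with_values(np.zeros(400), kind="dff")
        with pytest.raises(WindowTooShortError, match="short by"):
            gt.baseline_noise(dff, 0.150)

    def test_snr_arithmetic(self):
        vals = np.zeros(600)
        vals[400] = -0.15
        rng = np.random.default_rng(1)
        vals[:300] = rng.normal(0.0, 0.03, 300)
        tr = Trace(times=np.arange(600) / 1000.0, values=vals, kind="dff",
                   events=[Event("spike_trigger", 0.35), Event("stimulus_onset", 0.3)])
        measured_noise = gt.baseline_noise(tr, 0.3)
        assert gt.snr(tr) == pytest.approx(0.15 / measured_noise)

    def test_zero_noise_is_undefined_snr(self):
        vals = np.zeros(600)
        vals[400] = -0.15
        tr = Trace(times=np.arange(600) / 1000.0, values=vals, kind="dff",
                   events=[Event("spike_trigger", 0.35), Event("stimulus_onset", 0.3)])
        with pytest.raises(UndefinedSNRError):
            gt.snr(tr)


class TestAdditiveBleachCorrection:
    def test_pure_exponential_pinned_at_reference(self):
        """f(t) = 100·e^(−t/10 s), rest everywhere, reference 1 s →
        corrected ≡ 100·e^(−0.1)."""
        t = np.arange(0.0, 5.0, 1e-3)
        tr = Trace(times=t, values=100.0 * np.exp(-t / 10.0), kind="counts")
        out = gt.bleach_correct_additive(tr, [(0.0, 5.0)], reference_time=1.0)
        assert np.allclose(out.values, 100.0 * np.exp(-0.1), atol=1e-6)

    def test_bleach_free_trace_unchanged(self):
        t = np.arange(0.0, 2.0, 1e-3)
        tr = Trace(times=t, values=np.full_like(t, 42.0), kind="counts")
        out = gt.bleach_correct_additive(tr, [(0.0, 2.0)], reference_time=0.5)
        assert np.allclose(out.values, 42.0, atol=1e-9)

    def test_spike_height_preserved_exactly(self):
        """An added transient of height h keeps height h after correction
        when the rest fit is exact (additivity of the correction)."""
        t = np.arange(0.0, 4.0, 1e-3)
        g = 200.0 * np.exp(-t / 8.0)
        h = -30.0
        spike = np.where((t >= 2.0) & (t < 2.02), h, 0.0)
        tr = Trace(times=t, values=g + spike, kind="counts")
        out = gt.bleach_correct_additive(
            tr, [(0.0, 1.9), (2.3, 4.0)], reference_time=2.0
        )
        rest_level = 200.0 * np.exp(-2.0 / 8.0)
        in_spike = (t >= 2.0) & (t < 2.02)
        assert np.allclose(out.values[in_spike] - rest_level, h, atol=1e-6)
        assert np.allclose(out.values[~in_spike], rest_level, atol=1e-6)

    def test_empty_rest_segments_rejected(self):
        t = np.arange(0.0, 1.0, 1e-3)
        tr = Trace(times=t, values=np.full_like(t, 5.0), kind="counts")
        with pytest.raises(InvalidArgumentError):
            gt.bleach_correct_additive(tr, [], reference_time=0.5)


class TestDivisiveBleachCorrection:
    def test_pure_double_exponential_maps_to_zero(self):
        t = np.arange(0.0, 30.0, 0.02)
        f = 60.0 * np.exp(-t / 3.0) + 40.0 * np.exp(-t / 40.0)
        tr = Trace(times=t, values=f, kind="counts")
        out = gt.bleach_correct_divisive(tr)
        assert out.kind == "dff"
        assert np.allclose(out.values, 0.0, atol=1e-6)

    def test_multiplicative_modulation_recovered(self):
        """decay × (1 + 0.1·sin) yields ΔF/F oscillating at amplitude ≈ 0.1."""
        t = np.arange(0.0, 30.0, 0.02)
        envelope = 60.0 * np.exp(-t / 5.0) + 40.0 * np.exp(-t / 60.0)
        f = envelope * (1.0 + 0.1 * np.sin(2 * np.pi * 1.3 * t))
        out = gt.bleach_correct_divisive(Trace(times=t, values=f, kind="counts"))
        # the envelope fit absorbs a little of the modulation at early times
        assert np.abs(out.values).max() == pytest.approx(0.1, abs=0.02)
        assert np.abs(out.values).mean() == pytest.approx(0.2 / np.pi, rel=0.15)

    def test_constant_trace_maps_to_zero(self):
        t = np.arange(0.0, 10.0, 0.02)
        tr = Trace(times=t, values=np.full_like(t, 25.0), kind="counts")
        out = gt.bleach_correct_divisive(tr)
        assert np.allclose(out.values, 0.0, atol=1e-8)


class TestExponentialFits:
    def test_monoexponential_decay_recovery(self):
        """A·e^(−t/24 ms) recovers τ = 24 ms within 1%."""
        t = np.arange(0.0, 0.2, 1e-4)
        tr = Trace(times=t, values=-0.15 * np.exp(-t / 0.024), kind="dff")
        tau, r2 = gt.fit_monoexponential_decay(tr, peak_time=0.0)
        assert tau == pytest.approx(0.024, rel=0.01)
        assert r2 > 0.999

    def test_flat_decay_flagged_infinite(self):
        t = np.arange(0.0, 0.2, 1e-3)
        tr = Trace(times=t, values=np.full_like(t, -0.1), kind="dff")
        tau, r2 = gt.fit_monoexponential_decay(tr, peak_time=0.0)
        assert np.isinf(tau)

    def test_noisy_decay_recovery_within_5_percent(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 1.0, 1e-4)  # 10^4 points
        a = 1.0
        y = a * np.exp(-t / 0.1) + rng.normal(0.0, a / 100.0, t.size)
        tr = Trace(times=t, values=y, kind="dff")
        tau, _ = gt.fit_monoexponential_decay(tr, peak_time=0.0)
        assert tau == pytest.approx(0.1, rel=0.05)

    def test_too_few_points_rejected(self):
        t = np.arange(4) / 1000.0
        tr = Trace(times=t, values=np.exp(-t), kind="dff")
        with pytest.raises(FitError, match="need at least 5"):
            gt.fit_monoexponential_decay(tr, peak_time=0.0)

    def test_biexponential_spot_recovery(self, asap2s):
        """Noiseless ASAP2s depolarisation step response → τ_fast 5.2 ms ± 2%.
        (The full four-regime × three-indicator grid runs in the acceptance
        suite.)"""
        wf = gt.make_step_waveform(-70.0, 30.0, 0.0, duration=400.0, dt=0.05)
        out = gt.simulate_dff(asap2s, wf)
        fit = gt.fit_biexponential((out.times, out.values))
        assert fit.tau_fast == pytest.approx(5.2, rel=0.02)
        assert fit.tau_slow == pytest.approx(63.0, rel=0.02)
        assert fit.fraction_fast == pytest.approx(0.56, rel=0.02)

    def test_single_exponential_input_degenerates_cleanly(self):
        t = np.arange(0.0, 0.5, 1e-4)
        y = -0.3 * np.exp(-t / 0.05)
        fit = gt.fit_biexponential((t, y), with_offset=False)
        eff_tau = 0.05 * 1e3
        # either one amplitude vanishes or the two rates collapse (flagged)
        one_term = min(abs(fit.a), abs(fit.c)) < 0.01 * max(abs(fit.a), abs(fit.c))
        assert one_term or fit.near_degenerate
        if one_term:
            dominant_tau = fit.tau_fast if abs(fit.a) < abs(fit.c) else fit.tau_slow
            taus = [fit.tau_fast, fit.tau_slow]
            assert any(abs(tau - eff_tau) / eff_tau < 0.02 for tau in taus)
        else:
            assert fit.tau_fast == pytest.approx(eff_tau, rel=0.1)


class TestPeakMetrics:
    def test_gaussian_pulse_fwhm(self):
        """σ = 1.699 ms Gaussian has FWHM 2√(2 ln 2)σ ≈ 4.0 ms."""
        t = np.arange(0.0, 0.1, 1e-4)
        y = -0.2 * np.exp(-0.5 * ((t - 0.05) / 1.699e-3) ** 2)
        tr = Trace(times=t, values=y, kind="dff",
                   events=[Event("spike_trigger", 0.03)])
        m = gt.peak_metrics(tr)
        assert m.fwhm == pytest.approx(4.0e-3, abs=1e-4)
        assert m.a_max == pytest.approx(0.2)
        assert m.t_peak == pytest.approx(0.05, abs=1e-4)

    def test_boundary_peak_has_no_fwhm(self):
        t = np.arange(0.0, 0.1, 1e-3)
        y = -t  # extremum at the last sample
        tr = Trace(times=t, values=y, kind="dff",
                   events=[Event("spike_trigger", 0.0)])
        m = gt.peak_metrics(tr)
        assert m.fwhm is None
        assert m.flags.get("fwhm_absent")

    def test_simulated_asap2s_ap_shape(self, ap_dff_asap2s, ap_onset):
        """Model-level AP response shape: time-to-peak ≈ 6 ms and
        FWHM ≈ 21 ms within 20%."""
        tr = ap_dff_asap2s.with_values(ap_dff_asap2s.values.copy())
        tr.events = [Event("spike_trigger", ap_onset)]
        m = gt.peak_metrics(tr, search_ms=50.0)
        assert m.time_to_peak == pytest.approx(6.0e-3, rel=0.2)
        assert m.fwhm == pytest.approx(21.1e-3, rel=0.2)


class TestBinning:
    def test_counts_are_summed(self):
        tr = make_counts_trace([3, 1, 2, 4, 5, 0, 1, 2])
        out = gt.bin_timepoints(tr, 4)
        assert out.values.tolist() == [10.0, 8.0]
        assert out.frame_rate == pytest.approx(tr.frame_rate / 4)

    def test_k1_is_identity(self):
        tr = make_counts_trace([3, 1, 2, 4])
        out = gt.bin_timepoints(tr, 1)
        assert np.array_equal(out.values, tr.values)

    def test_dff_is_averaged_and_remainder_dropped(self):
        tr = Trace(times=np.arange(7) / 1000.0,
                   values=np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6]),
                   kind="dff")
        out = gt.bin_timepoints(tr, 3)
        assert np.allclose(out.values, [0.1, 0.4])

    def test_invalid_k_rejected(self):
        tr = make_counts_trace([1, 2, 3])
        with pytest.raises(InvalidArgumentError):
            gt.bin_timepoints(tr, 0)

    def test_effective_dwell_scales(self, ap_dff_asap2s):
        sched = gt.ScanSchedule(n_voxels=20)
        tr = gt.simulate_photon_counts(ap_dff_asap2s, 500.0, sched, seed=0)
        out = gt.bin_timepoints(tr, 4)
        assert out.meta["schedule"]["dwell_time_us"] == pytest.approx(200.0)


class TestPropagationSummaries:
    def test_conduction_velocity_two_points(self):
        """150 µm arriving 1.1 ms later → 0.136 m/s."""
        v, pairwise = gt.conduction_velocity([(0.0, 0.010), (150.0, 0.0111)])
        assert v == pytest.approx(150e-6 / 1.1e-3, rel=1e-6)
        assert pairwise[0] == pytest.approx(0.13636, rel=1e-3)

    def test_zero_delays_undefined(self):
        with pytest.raises(UndefinedVelocityError):
            gt.conduction_velocity([(0.0, 0.01), (100.0, 0.01)])

    def test_missing_soma_reference_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gt.conduction_velocity([(50.0, 0.01), (100.0, 0.011)])

    def test_attenuation_profile_paper_arithmetic(self):
        """Soma 0.15, dendrite 0.0936 at 144 µm → 37.6% reduction."""
        prof = dict(gt.attenuation_profile([(0.0, 0.15), (144.0, 0.0936)]))
        assert prof[144.0] == pytest.approx(37.6, abs=0.05)
        assert prof[0.0] == 0.0

    def test_uniform_amplitudes_zero_reduction(self):
        prof = gt.attenuation_profile([(0.0, 0.1), (50.0, 0.1), (100.0, 0.1)])
        assert all(p == pytest.approx(0.0) for _, p in prof)

    def test_zero_soma_amplitude_rejected(self):
        with pytest.raises(InvalidReferenceError):
            gt.attenuation_profile([(0.0, 0.0), (50.0, 0.1)])

    def test_percent_improvement_values(self):
        assert gt.percent_improvement(-38.7, -23.3) == pytest.approx(66.09, abs=0.01)
        assert gt.percent_improvement(-15.0, -8.4) == pytest.approx(78.57, abs=0.01)
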