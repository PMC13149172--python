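import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiomap.io import Trace
from cardiomap.synth import RhythmScript, SimulationConfig, simulate_trace, solve_template
from cardiomap.transients import (
    analyze_trace,
    detect_beats,
    fridericia_correct,
    iso_response,
    measure_beat,
    preprocess_trace,
    spontaneous_frequency,
)


class TestPreprocess:
    def test_identity_when_disabled(self, noisy_wt_trace):
        tr, _ = noisy_wt_trace
        out = preprocess_trace(tr, smooth_window_s=None, detrend=False)
        np.testing.assert_array_equal(out.values, tr.values)

    def test_constant_trace_unchanged(self):
        tr = Trace(values=np.full(500, 3.2), frame_rate=100.0)
        out = preprocess_trace(tr, smooth_window_s=0.05, detrend=True)
        np.testing.assert_allclose(out.values, 3.2, atol=1e-9)

    def test_detrend_removes_linear_drift(self, wt_voltage_template):
        """Detrending a drifting trace should restore the driftless twin
        to within 1% of the transient amplitude."""
        base = SimulationConfig(
            duration=10.0,
            waveform=wt_voltage_template,
            rhythm=RhythmScript(base_frequency=0.67),
            noise_sd=0.0,
            seed=2,
        )
        clean, _ = simulate_trace(base)
        drift = 0.01 * clean.times  # 0.01 a.u./s linear drift
        drifting = clean.copy_with(clean.values + drift)
        out = preprocess_trace(drifting, smooth_window_s=None, detrend=True)
        dev = np.abs(out.values - out.values.mean() - (clean.values - clean.values.mean()))
        assert dev.max() < 0.01 * wt_voltage_template.amplitude

    def test_window_longer_than_trace_errors(self):
        tr = Trace(values=np.zeros(20), frame_rate=100.0)
        with pytest.raises(ValueError, match="window"):
            preprocess_trace(tr, smooth_window_s=1.0)


class TestDetectBeats:
    def test_noiseless_beats_within_one_frame(self, clean_wt_trace):
        tr, truth = clean_wt_trace
        times = detect_beats(tr)
        true_mid = truth.beats["time"].to_numpy() + tr.frame_rate ** -1  # near upstroke
        assert len(times) == len(truth.beats)
        # detection fires at the derivative peak, i.e. mid-upstroke
        np.testing.assert_allclose(
            times, truth.beats["time"] + 0.01, atol=0.010
        )

    def test_flat_trace_empty(self):
        tr = Trace(values=np.zeros(1000), frame_rate=100.0)
        assert detect_beats(tr).size == 0

    def test_pure_noise_empty(self):
        rng = np.random.default_rng(0)
        tr = Trace(values=rng.normal(0, 0.05, 2000), frame_rate=100.0)
        assert detect_beats(tr).size == 0

    def test_snr20_cohort_sensitivity_and_specificity(self, wt_voltage_template):
        """At SNR 20, >=99% of scripted beats are found within 2 frames
        and spurious detections average zero per recording."""
        matched = total = spurious = 0
        for seed in range(20):
            cfg = SimulationConfig(
                duration=30.0,
                waveform=wt_voltage_template,
                rhythm=RhythmScript(base_frequency=1.0, jitter_cv=0.05),
                seed=seed,
            )
            tr, truth = simulate_trace(cfg)
            times = detect_beats(tr)
            true_times = truth.beats["time"].to_numpy()
            total += true_times.size
            for t in true_times:
                if times.size and np.min(np.abs(times - t - 0.01)) <= 0.02:
                    matched += 1
            for t in times:
                if np.min(np.abs(true_times + 0.01 - t)) > 0.02:
                    spurious += 1
        assert matched / total >= 0.99
        assert spurious == 0


class TestMeasureBeat:
    def test_square_pulse_geometry(self):
        fs = 100.0
        t = np.arange(0, 2.0, 1 / fs)
        v = np.where((t >= 0.5) & (t < 0.8), 1.0, 0.0)
        m = measure_beat(Trace(values=v, frame_rate=fs), 0.5)
        assert m.amplitude == pytest.approx(1.0, abs=0.01)
        assert m.baseline == pytest.approx(0.0, abs=1e-9)
        assert m.d80 == pytest.approx(0.30, abs=0.011)
        assert m.triangulation == pytest.approx(0.0, abs=0.011)

    def test_recovers_published_calcium_configuration(self, wt_calcium_template):
        """Templates configured at the WT calcium values (baseline 0.46,
        CaTD80 0.74 s) are recovered from a noiseless trace."""
        cfg = SimulationConfig(
            duration=30.0,
            modality="calcium",
            waveform=wt_calcium_template,
            rhythm=RhythmScript(base_frequency=0.55),
            noise_sd=0.0,
            seed=0,
        )
        tr, _ = simulate_trace(cfg)
        beats, summary, _ = analyze_trace(tr)
        assert summary.metric("baseline") == pytest.approx(0.46, abs=0.005)
        assert summary.metric("d80") == pytest.approx(0.74, abs=0.025)

    def test_censoring_of_interrupted_repolarization(self):
        tmpl = solve_template(0.02, 0.2, 0.5)  # D90 = 0.5 s
        fs = 100.0
        t = np.arange(0, 2.0, 1 / fs)
        v = tmpl.evaluate(t - 0.5) + tmpl.evaluate(t - 0.7, v_start=tmpl.evaluate(0.2))
        v = np.where(t < 0.7, tmpl.evaluate(t - 0.5), tmpl.evaluate(t - 0.7, v_start=tmpl.evaluate(0.2)))
        m = measure_beat(Trace(values=v, frame_rate=fs), 0.51, next_activation_time=0.71)
        assert m.censored
        assert math.isnan(m.d90)

    def test_no_transient_rejected(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1e-12, 300)
        v[100:110] -= 0.5  # downward deflection only
        with pytest.raises(ValueError):
            measure_beat(Trace(values=v, frame_rate=100.0), 1.0)

    def test_duration_ordering_invariant(self, noisy_wt_trace, fd_voltage_template):
        """D30 <= D80 <= D90 on every measured synthetic beat."""
        tr, _ = noisy_wt_trace
        beats, _, _ = analyze_trace(tr)
        for seed in range(5):
            cfg = SimulationConfig(
                duration=20.0,
                waveform=fd_voltage_template,
                rhythm=RhythmScript(base_frequency=1.28, jitter_cv=0.05),
                seed=seed,
            )
            tr2, _ = simulate_trace(cfg)
            beats += analyze_trace(tr2)[0]
        assert beats
        for b in beats:
            if not b.censored:
                assert b.d30 <= b.d80 <= b.d90
                assert b.triangulation >= 0


class TestParameterRecovery:
    def test_noiseless_cohort_d80_within_one_frame(self, wt_voltage_template):
        cfg = SimulationConfig(
            duration=10.0,
            waveform=wt_voltage_template,
            rhythm=RhythmScript(base_frequency=0.67, jitter_cv=0.03),
            noise_sd=0.0,
        )
        errs = []
        from cardiomap.synth import CohortGroup, generate_cohort

        for rec in generate_cohort([CohortGroup.replicate("g", 50, cfg)], seed=3):
            _, summary, _ = analyze_trace(rec.trace)
            errs.append(summary.metric("d80") - wt_voltage_template.duration(0.8))
        assert abs(np.mean(errs)) <= 0.010

    def test_snr20_cohort_group_mean_errors(self, wt_voltage_template):
        """Group-mean |error| <= 5% for D80, baseline, amplitude and
        frequency at SNR 20."""
        from cardiomap.synth import CohortGroup, generate_cohort

        cfg = SimulationConfig(
            duration=10.0,
            waveform=wt_voltage_template,
            rhythm=RhythmScript(base_frequency=0.67, jitter_cv=0.03),
        )
        d80s, bases, amps, freqs = [], [], [], []
        for rec in generate_cohort([CohortGroup.replicate("g", 50, cfg)], seed=4):
            _, s, _ = analyze_trace(rec.trace)
            d80s.append(s.metric("d80"))
            bases.append(s.metric("baseline"))
            amps.append(s.metric("amplitude"))
            freqs.append(s.frequency)
        t = wt_voltage_template
        assert abs(np.mean(d80s) - t.duration(0.8)) <= 0.05 * t.duration(0.8)
        assert abs(np.mean(bases) - t.baseline) <= 0.05 * t.amplitude
        assert abs(np.mean(amps) - t.amplitude) <= 0.05 * t.amplitude
        assert abs(np.mean(freqs) - 0.67) <= 0.05 * 0.67


class TestFridericia:
    def test_identity_at_rr_one(self):
        assert fridericia_correct(0.2, 1.0) == pytest.approx(0.2)

    def test_exact_cube_root_case(self):
        # 0.512^(1/3) = 0.8 exactly
        assert fridericia_correct(0.2, 0.512) == pytest.approx(0.25, abs=1e-12)

    def test_at_fd_rate(self):
        # RR from the FD group frequency, direct evaluation
        assert fridericia_correct(0.14, 1 / 1.28) == pytest.approx(0.1520, abs=5e-5)

    def test_rejects_nonpositive_rr(self):
        with pytest.raises(ValueError):
            fridericia_correct(0.2, 0.0)

    @given(d80=st.floats(0.01, 1.0), rr=st.floats(0.1, 5.0), c=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity_property(self, d80, rr, c):
        assert fridericia_correct(c * d80, rr) == pytest.approx(
            c * fridericia_correct(d80, rr), rel=1e-12
        )


class TestFrequency:
    def test_regular_beats(self):
        est = spontaneous_frequency(np.arange(10.0), window=10.0)
        assert est.hz == pytest.approx(1.0)
        assert not est.quiescent

    def test_single_beat_quiescent(self):
        est = spontaneous_frequency(np.array([12.0]), window=30.0)
        assert est.hz == 0.0
        assert est.quiescent

    def test_monte_carlo_against_rhythm_truth(self):
        """Mean estimate over 200 Gamma-jittered 1.28 Hz scripts, 30 s,
        within 3% of the scripted rate (beat times straight from the
        generator, no detection in the loop)."""
        rng = np.random.default_rng(8)
        script = RhythmScript(base_frequency=1.28, jitter_cv=0.05)
        ests = []
        for _ in range(200):
            beats = script.draw_beat_times(30.0, rng)
            ests.append(spontaneous_frequency(beats, 30.0).hz)
        assert np.mean(ests) == pytest.approx(1.28, rel=0.03)


class TestIsoResponse:
    def _summary(self, rid, freq, d80=0.2):
        from cardiomap.transients import SyncytiumSummary

        return SyncytiumSummary(
            recording_id=rid, modality="calcium", n_beats=10, frequency=freq,
            quiescent=False, analysis_window=10.0, means={"d80": d80},
        )

    def test_frequency_doubling(self):
        r = iso_response(self._summary("a", 0.5), self._summary("a", 1.0), "frequency")
        assert r == pytest.approx(2.0)

    def test_identity(self):
        s = self._summary("a", 0.8)
        for metric in ("frequency", "d80"):
            assert iso_response(s, s, metric) == pytest.approx(1.0)

    def test_group_mean_of_ratios(self):
        pre = [self._summary(f"r{i}", 1.0) for i in range(3)]
        post = [self._summary(f"r{i}", f) for i, f in enumerate((3.0, 4.0, 5.0))]
        ratios = [iso_response(p, q, "frequency") for p, q in zip(pre, post)]
        assert np.mean(ratios) == pytest.approx(4.0)

    def test_zero_pre_value_excluded(self):
        with pytest.raises(ValueError):
            iso_response(self._summary("a", 0.0), self._summary("a", 1.0), "frequency")

    def test_mismatched_recordings_rejected(self):
        with pytest.raises(ValueError):
            iso_response(self._summary("a", 1.0), self._summary("b", 1.0), "frequency")
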