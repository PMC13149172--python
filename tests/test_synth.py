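import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from cardiomap.synth import (
    CohortGroup,
    PropagationModel,
    RhythmScript,
    SimulationConfig,
    WaveformTemplate,
    generate_cohort,
    simulate_recording,
    simulate_trace,
    solve_template,
)


class TestSolveTemplate:
    def test_against_numeric_root_find(self):
        """Closed-form (tau_r, p) must reproduce both target durations.

        Oracle: solve D_x = t_up + tau_r * x**(1/p) for the 0.3-crossing
        numerically given the returned tau_r, and compare durations.
        """
        t = solve_template(0.02, 0.08, 0.15)
        assert t.p == pytest.approx(1.421, abs=1e-3)
        assert t.tau_r == pytest.approx(0.140, abs=1e-3)
        for x, d in [(0.3, 0.08), (0.9, 0.15)]:
            # numeric inversion of the duration equation
            tau = brentq(lambda s: (s / t.tau_r) ** t.p - x, 1e-9, t.tau_r)
            assert 0.02 + tau == pytest.approx(d, abs=1e-9)
            assert t.duration(x) == pytest.approx(d, abs=1e-9)

    def test_linear_repolarization_identity(self):
        big_t = 0.5
        t = solve_template(0.0, 0.3 * big_t, 0.9 * big_t)
        assert t.p == pytest.approx(1.0)
        assert t.tau_r == pytest.approx(big_t)

    def test_rejects_unordered_durations(self):
        with pytest.raises(ValueError):
            solve_template(0.02, 0.15, 0.08)
        with pytest.raises(ValueError):
            solve_template(0.02, 0.1, 0.1)

    @given(
        t_up=st.floats(0.0, 0.1),
        d_a=st.floats(0.05, 0.5),
        spread=st.floats(0.01, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_duration_roundtrip_property(self, t_up, d_a, spread):
        d_a = d_a + t_up + 0.01
        t = solve_template(t_up, d_a, d_a + spread)
        assert t.duration(0.3) == pytest.approx(d_a, rel=1e-9)
        assert t.duration(0.9) == pytest.approx(d_a + spread, rel=1e-9)
        # monotone recovery: durations increase with the fraction
        assert t.duration(0.3) < t.duration(0.8) < t.duration(0.9)


class TestTemplateShape:
    def test_dense_sampling_recovers_durations(self, fd_calcium_template):
        """Measuring D_x on a >=1 kHz noiseless template matches the
        closed form to <0.1 ms."""
        for tmpl in (
            solve_template(0.02, 0.08, 0.15),
            fd_calcium_template,
        ):
            fs = 10_000.0
            tau = np.arange(0, tmpl.total_duration + 0.1, 1 / fs)
            vals = tmpl.evaluate(tau)
            peak = tmpl.baseline + tmpl.amplitude
            for x in (0.3, 0.8, 0.9):
                level = peak - x * tmpl.amplitude
                below = np.flatnonzero(vals <= level)
                below = below[tau[below] >= tmpl.t_up]
                k = below[0]
                # linear interpolation of the crossing between samples
                frac = (vals[k - 1] - level) / (vals[k - 1] - vals[k])
                measured = tau[k - 1] + frac / fs
                assert measured == pytest.approx(tmpl.duration(x), abs=1e-4)

    def test_baseline_before_and_after(self):
        t = WaveformTemplate(t_up=0.02, tau_r=0.2, p=1.5, amplitude=2.0, baseline=0.4)
        assert t.evaluate(-0.01) == pytest.approx(0.4)
        assert t.evaluate(t.total_duration + 0.01) == pytest.approx(0.4)
        assert t.evaluate(t.t_up) == pytest.approx(2.4)


class TestRhythmScript:
    def test_regular_intervals(self):
        rng = np.random.default_rng(0)
        beats = RhythmScript(base_frequency=0.67).draw_beat_times(30.0, rng)
        np.testing.assert_allclose(np.diff(beats), 1 / 0.67)

    def test_quiescent_episode_removes_beats(self):
        rng = np.random.default_rng(0)
        script = RhythmScript(base_frequency=1.0, quiescent_episodes=((5.0, 6.0),))
        beats = script.draw_beat_times(20.0, rng)
        assert not np.any((beats >= 5.0) & (beats < 11.0))

    def test_tachy_segment_overrides_rate(self):
        rng = np.random.default_rng(0)
        script = RhythmScript(base_frequency=0.5, tachy_segments=((10.0, 5.0, 4.0),))
        beats = script.draw_beat_times(20.0, rng)
        in_seg = np.diff(beats[(beats > 10.2) & (beats < 15.0)])
        assert np.allclose(in_seg, 0.25)

    def test_beat_times_strictly_increasing(self):
        rng = np.random.default_rng(5)
        script = RhythmScript(base_frequency=1.3, jitter_cv=0.5)
        beats = script.draw_beat_times(60.0, rng)
        assert np.all(np.diff(beats) > 0)


class TestSimulateRecording:
    def test_kinematic_planar_delays(self, wt_voltage_template):
        cfg = SimulationConfig(
            shape=(4, 32),
            pixel_pitch=0.01,
            duration=10.0,
            waveform=wt_voltage_template,
            rhythm=RhythmScript(base_frequency=1.0),
            propagation=PropagationModel(pattern="planar", speed=10.0),
            noise_sd=0.0,
        )
        movie, truth = simulate_recording(cfg)
        assert len(truth.beats) == 9  # beats at 1, 2, ... 9 s
        # column at distance d cm activates d/v later: compare column
        # onsets via first-crossing of half amplitude after beat 1
        t = movie.times
        bt = truth.beats["time"].iloc[0]
        half = wt_voltage_template.baseline + 0.5 * wt_voltage_template.amplitude
        onsets = []
        for c in (0, 16, 31):
            trace = movie.frames[:, 2, c]
            k = np.flatnonzero((t >= bt - 0.05) & (trace > half))[0]
            onsets.append(t[k])
        assert onsets[1] - onsets[0] == pytest.approx(0.16 / 10.0, abs=0.011)
        assert onsets[2] - onsets[0] == pytest.approx(0.31 / 10.0, abs=0.011)

    def test_seed_determinism(self, wt_voltage_template):
        cfg = SimulationConfig(
            shape=(8, 8),
            duration=5.0,
            waveform=wt_voltage_template,
            rhythm=RhythmScript(base_frequency=1.0, jitter_cv=0.1),
            seed=99,
        )
        m1, t1 = simulate_recording(cfg)
        m2, t2 = simulate_recording(cfg)
        np.testing.assert_array_equal(m1.frames, m2.frames)
        assert t1.beats.equals(t2.beats)

    def test_unphysical_rate_rejected(self, wt_voltage_template):
        cfg = SimulationConfig(
            duration=5.0,
            waveform=WaveformTemplate(t_up=0.3, tau_r=0.2, p=1.0),
            rhythm=RhythmScript(base_frequency=4.0),
        )
        with pytest.raises(ValueError, match="unphysical"):
            simulate_recording(cfg)

    def test_truncation_has_no_jumps(self, fd_voltage_template):
        """A beat interrupting repolarization starts from the
        instantaneous value: no sample-to-sample jump exceeds the
        amplitude."""
        cfg = SimulationConfig(
            duration=10.0,
            waveform=solve_template(0.05, 0.4, 0.9),
            rhythm=RhythmScript(base_frequency=2.5),
            noise_sd=0.0,
        )
        tr, truth = simulate_trace(cfg)
        assert truth.beats["censored"].any()
        assert np.max(np.abs(np.diff(tr.values))) < cfg.waveform.amplitude

    def test_bleaching_is_monoexponential(self, wt_voltage_template):
        from dataclasses import replace

        cfg = SimulationConfig(
            duration=10.0,
            waveform=replace(wt_voltage_template, baseline=1.0),
            rhythm=RhythmScript(base_frequency=0.0),
            noise_sd=0.0,
            bleach_rate=0.02,
        )
        tr, _ = simulate_trace(cfg)
        expected = 1.0 * np.exp(-0.02 * tr.times)
        np.testing.assert_allclose(tr.values, expected, rtol=1e-12)

    def test_snr20_default_noise(self, wt_voltage_template):
        cfg = SimulationConfig(duration=5.0, waveform=wt_voltage_template,
                               rhythm=RhythmScript(base_frequency=0.0), seed=3)
        tr, _ = simulate_trace(cfg)
        assert np.std(tr.values) == pytest.approx(wt_voltage_template.amplitude / 20, rel=0.1)


class TestPropagationModel:
    def test_planar_linear_activation_times(self):
        pm = PropagationModel(pattern="planar", speed=10.0)
        d = pm.delay_map(8, 32, 0.01)
        # slope along propagation axis = 1/v per cm
        slope = (d[0, -1] - d[0, 0]) / (31 * 0.01)
        assert slope == pytest.approx(1 / 10.0, rel=1e-12)
        assert np.allclose(d, d[0:1, :])  # rows identical

    def test_target_radial(self):
        pm = PropagationModel(pattern="target", speed=5.0, origin=(8, 8))
        d = pm.delay_map(17, 17, 0.02)
        assert d[8, 8] == pytest.approx(0.0)
        assert d[8, 13] == pytest.approx(5 * 0.02 / 5.0)

    def test_global_activation(self):
        d = PropagationModel(pattern="planar", speed=math.inf).delay_map(8, 8, 0.01)
        assert np.all(d == 0)


class TestGenerateCohort:
    def test_counts_and_labels(self, wt_voltage_template, fd_voltage_template):
        wt = SimulationConfig(duration=5.0, waveform=wt_voltage_template,
                              rhythm=RhythmScript(base_frequency=0.67))
        fd = SimulationConfig(duration=5.0, waveform=fd_voltage_template,
                              rhythm=RhythmScript(base_frequency=1.28))
        recs = generate_cohort(
            [CohortGroup.replicate("WT", 3, wt), CohortGroup.replicate("FD", 3, fd)], seed=1
        )
        assert len(recs) == 6
        assert [r.group for r in recs] == ["WT"] * 3 + ["FD"] * 3
        assert all(r.truth.labels["base_frequency"] == 0.67 for r in recs[:3])
        # no scripted arrhythmic features anywhere
        assert all(not r.truth.labels["scripted_tachy"] for r in recs)
        assert all(r.truth.labels["scripted_ead_count"] == 0 for r in recs)

    def test_same_seed_identical_cohort(self, wt_voltage_template):
        cfg = SimulationConfig(duration=5.0, waveform=wt_voltage_template,
                               rhythm=RhythmScript(base_frequency=1.0, jitter_cv=0.2))
        g = [CohortGroup.replicate("g", 4, cfg)]
        recs1 = generate_cohort(g, seed=11)
        recs2 = generate_cohort(g, seed=11)
        for a, b in zip(recs1, recs2):
            np.testing.assert_array_equal(a.movie.frames, b.movie.frames)

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort([], seed=0)
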