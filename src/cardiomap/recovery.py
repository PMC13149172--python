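"""Parameter-recovery cohorts at the published group means.

The study's raw recordings are not deposited, so the pipeline is
validated by closure: the generator is configured with the published
group-level values (conduction velocities, spontaneous rates, action
potential and calcium transient durations, baselines, incidence
counts), synthetic cohorts are rendered at realistic noise (peak SNR
about 20), and the full analysis chain must recover the configured
values.  Each ``recover_*`` function returns ``(estimate, n)`` where
``n`` is the number of recordings used.

Published group means used as generator settings (voltage, Fluovolt-like):
WT conduction velocity 14 cm/s, FD 8.5 cm/s; WT spontaneous rate
0.67 Hz (n=36), FD 1.28 Hz (n=26); WT Fridericia-corrected APD80
0.17 s with APD triangulation 0.05 s; FD corrected APD80 0.14 s with
triangulation 0.10 s.  Calcium (Calbryte-like), pre-isoproterenol:
WT rate 0.55 Hz, CaTD80 0.74 s, triangulation 0.43 s, baseline
0.46 a.u., amplitude 0.15 a.u.; FD rate 0.07 Hz, CaTD80 1.08 s,
triangulation 1.172 s, baseline 0.09 a.u., amplitude 1.05 a.u.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .mapping import beat_window, compute_activation_map, estimate_cv
from .rhythm import RhythmThresholds, classify_rhythm
from .synth import (
    CohortGroup,
    PropagationModel,
    RhythmScript,
    SimulationConfig,
    WaveformTemplate,
    generate_cohort,
)
from .transients import analyze_trace

__all__ = [
    "WT_CV_CM_S",
    "FD_CV_CM_S",
    "WT_FREQUENCY_HZ",
    "FD_FREQUENCY_HZ",
    "WT_APD80_CORRECTED_S",
    "FD_APD80_CORRECTED_S",
    "WT_APD_TRI_S",
    "FD_APD_TRI_S",
    "FD_CATD80_S",
    "FD_CATD_TRI_S",
    "WT_CA_BASELINE_AU",
    "solve_template_d80_tri",
    "wt_voltage_template",
    "fd_voltage_template",
    "wt_calcium_template",
    "fd_calcium_template",
    "recover_cv",
    "recover_frequency",
    "recover_apd80_corrected",
    "recover_apd_triangulation",
    "recover_catd80",
    "recover_ca_baseline",
    "arrhythmic_count_scripted",
    "arrhythmic_count_normal",
    "tachy_count_mixed",
    "run_full_recovery",
]

# ---- generator settings: the published group means ----
WT_CV_CM_S = 14.0
FD_CV_CM_S = 8.5
WT_FREQUENCY_HZ = 0.67
FD_FREQUENCY_HZ = 1.28
WT_APD80_CORRECTED_S = 0.17
FD_APD80_CORRECTED_S = 0.14
WT_APD_TRI_S = 0.05
FD_APD_TRI_S = 0.10
WT_CATD80_S = 0.74
WT_CATD_TRI_S = 0.43
WT_CA_BASELINE_AU = 0.46
WT_CA_AMPLITUDE_AU = 0.15
WT_CA_FREQUENCY_HZ = 0.55
FD_CATD80_S = 1.08
FD_CATD_TRI_S = 1.172
FD_CA_BASELINE_AU = 0.09
FD_CA_AMPLITUDE_AU = 1.05
FD_CA_FREQUENCY_HZ = 0.07

_V_T_UP = 0.02  # voltage upstroke, s
_CA_T_UP = 0.10  # calcium rise, s


def solve_template_d80_tri(
    t_up: float,
    d80: float,
    tri: float,
    amplitude: float = 1.0,
    baseline: float = 0.0,
) -> WaveformTemplate:
    """Template with prescribed D80 and triangulation (D90 - D30).

    D80 fixes ``tau_r * 0.8**u`` (u = 1/p) and the triangulation fixes
    ``tau_r * (0.9**u - 0.3**u)``; their ratio is monotone in u, so u is
    found by bracketing root-finding and tau_r follows in closed form.
    """
    if tri <= 0 or not t_up < d80:
        raise ValueError("need tri > 0 and d80 > t_up")
    ratio = tri / (d80 - t_up)

    def f(u: float) -> float:
        return (0.9**u - 0.3**u) / 0.8**u - ratio

    u = brentq(f, 1e-3, 20.0)
    tau_r = (d80 - t_up) / 0.8**u
    return WaveformTemplate(
        t_up=t_up, tau_r=tau_r, p=1.0 / u, amplitude=amplitude, baseline=baseline
    )


def _uncorrected_d80(corrected: float, frequency_hz: float) -> float:
    """Invert the Fridericia correction at a regular rate."""
    rr = 1.0 / frequency_hz
    return corrected * rr ** (1.0 / 3.0)


def wt_voltage_template() -> WaveformTemplate:
    d80 = _uncorrected_d80(WT_APD80_CORRECTED_S, WT_FREQUENCY_HZ)
    return solve_template_d80_tri(_V_T_UP, d80, WT_APD_TRI_S)


def fd_voltage_template() -> WaveformTemplate:
    d80 = _uncorrected_d80(FD_APD80_CORRECTED_S, FD_FREQUENCY_HZ)
    return solve_template_d80_tri(_V_T_UP, d80, FD_APD_TRI_S)


def wt_calcium_template() -> WaveformTemplate:
    return solve_template_d80_tri(
        _CA_T_UP, WT_CATD80_S, WT_CATD_TRI_S,
        amplitude=WT_CA_AMPLITUDE_AU, baseline=WT_CA_BASELINE_AU,
    )


def fd_calcium_template() -> WaveformTemplate:
    return solve_template_d80_tri(
        _CA_T_UP, FD_CATD80_S, FD_CATD_TRI_S,
        amplitude=FD_CA_AMPLITUDE_AU, baseline=FD_CA_BASELINE_AU,
    )


def _trace_cohort(config: SimulationConfig, n: int, seed: int):
    return generate_cohort([CohortGroup.replicate("g", n, config)], seed=seed)


def recover_cv(
    speed_cm_s: float, seed: int, n: int = 10, noiseless: bool = False
) -> tuple[float, int]:
    """Cohort mean of per-recording median conduction velocity.

    Each recording: 64 x 64 pixels at 0.01 cm/pixel, 100 fps, 10 s,
    planar wave at ``speed_cm_s``, regular WT-rate rhythm.
    """
    cfg = SimulationConfig(
        shape=(64, 64),
        pixel_pitch=0.01,
        frame_rate=100.0,
        duration=10.0,
        modality="voltage",
        waveform=wt_voltage_template(),
        rhythm=RhythmScript(base_frequency=WT_FREQUENCY_HZ, jitter_cv=0.0),
        propagation=PropagationModel(pattern="planar", speed=speed_cm_s),
        noise_sd=0.0 if noiseless else None,
    )
    medians = []
    for rec in _trace_cohort(cfg, n, seed):
        trace_beats, _, _ = analyze_trace(rec.trace)
        times = np.array([b.activation_time for b in trace_beats])
        bi = 1 if times.size >= 3 else 0
        amap = compute_activation_map(
            rec.movie, beat_window(times, bi, rec.movie.duration), beat_index=bi
        )
        medians.append(estimate_cv(amap).median_cv)
    return float(np.mean(medians)), n


def recover_frequency(seed: int, n: int = 26) -> tuple[float, int]:
    """Mean spontaneous rate over 30-s voltage traces at the FD rate."""
    cfg = SimulationConfig(
        duration=30.0,
        waveform=fd_voltage_template(),
        rhythm=RhythmScript(base_frequency=FD_FREQUENCY_HZ, jitter_cv=0.05),
    )
    freqs = []
    for rec in _trace_cohort(cfg, n, seed):
        _, summary, _ = analyze_trace(rec.trace)
        freqs.append(summary.frequency)
    return float(np.mean(freqs)), n


def recover_apd80_corrected(seed: int, n: int = 20) -> tuple[float, int]:
    """Cohort mean Fridericia-corrected APD80 at the WT rate."""
    cfg = SimulationConfig(
        duration=10.0,
        waveform=wt_voltage_template(),
        rhythm=RhythmScript(base_frequency=WT_FREQUENCY_HZ, jitter_cv=0.03),
    )
    vals = []
    for rec in _trace_cohort(cfg, n, seed):
        _, summary, _ = analyze_trace(rec.trace)
        vals.append(summary.d80_fridericia)
    return float(np.nanmean(vals)), n


def recover_apd_triangulation(seed: int, n: int = 20) -> tuple[float, int]:
    """Cohort mean APD triangulation for the FD-configured template."""
    cfg = SimulationConfig(
        duration=10.0,
        waveform=fd_voltage_template(),
        rhythm=RhythmScript(base_frequency=FD_FREQUENCY_HZ, jitter_cv=0.03),
    )
    vals = []
    for rec in _trace_cohort(cfg, n, seed):
        _, summary, _ = analyze_trace(rec.trace)
        vals.append(summary.metric("triangulation"))
    return float(np.nanmean(vals)), n


def recover_catd80(seed: int, n: int = 8) -> tuple[float, int]:
    """Cohort mean CaTD80 at the FD pre-isoproterenol configuration."""
    cfg = SimulationConfig(
        duration=30.0,
        modality="calcium",
        waveform=fd_calcium_template(),
        rhythm=RhythmScript(base_frequency=FD_CA_FREQUENCY_HZ, jitter_cv=0.05),
    )
    vals = []
    for rec in _trace_cohort(cfg, n, seed):
        _, summary, _ = analyze_trace(rec.trace)
        vals.append(summary.metric("d80"))
    return float(np.nanmean(vals)), n


def recover_ca_baseline(seed: int, n: int = 8) -> tuple[float, int]:
    """Cohort mean diastolic baseline at the WT pre-iso configuration."""
    cfg = SimulationConfig(
        duration=30.0,
        modality="calcium",
        waveform=wt_calcium_template(),
        rhythm=RhythmScript(base_frequency=WT_CA_FREQUENCY_HZ, jitter_cv=0.05),
    )
    vals = []
    for rec in _trace_cohort(cfg, n, seed):
        _, summary, _ = analyze_trace(rec.trace)
        vals.append(summary.metric("baseline"))
    return float(np.nanmean(vals)), n


# ---- scripted arrhythmia cohorts ----


def _classify_cohort(recordings, thresholds: RhythmThresholds | None = None):
    assessments = []
    for rec in recordings:
        beats, _, pp = analyze_trace(rec.trace)
        times = np.array([b.activation_time for b in beats])
        assessments.append(
            classify_rhythm(
                times, beats, window=rec.trace.duration,
                thresholds=thresholds or RhythmThresholds(), trace=pp,
            )
        )
    return assessments


def _ead_template() -> WaveformTemplate:
    # a long, strongly triangulated beat: EADs arise on prolonged,
    # slowly repolarizing action potentials, and the shallow late limb
    # also keeps the scripted bump's prominence close to its nominal
    # height
    return solve_template_d80_tri(_V_T_UP, 0.40, 0.50)


def arrhythmic_cohort_configs() -> list[SimulationConfig]:
    """16 recordings, 30 s each, one scripted arrhythmic feature apiece.

    Every feature parameter exceeds its default classifier threshold by
    at least 2x: sustained 4 Hz rate (cut 2 Hz), 12-s silent gap (cut
    5 s), inter-beat CV 0.5 (cut 0.2), EAD bumps of 0.25 relative
    height (cut 0.10).
    """
    base = dict(duration=30.0, modality="voltage")
    tachy = SimulationConfig(
        waveform=fd_voltage_template(),
        rhythm=RhythmScript(base_frequency=4.0, jitter_cv=0.02),
        **base,
    )
    quiet = SimulationConfig(
        waveform=wt_voltage_template(),
        rhythm=RhythmScript(
            base_frequency=0.5, jitter_cv=0.05, quiescent_episodes=((10.0, 12.0),)
        ),
        **base,
    )
    irregular = SimulationConfig(
        waveform=wt_voltage_template(),
        rhythm=RhythmScript(base_frequency=0.67, jitter_cv=0.5),
        **base,
    )
    ead = SimulationConfig(
        waveform=_ead_template(),
        rhythm=RhythmScript(
            base_frequency=0.4,
            jitter_cv=0.03,
            ead_beats=tuple((i, 0.25, 0.6) for i in range(1, 10)),
        ),
        **base,
    )
    return [tachy] * 4 + [quiet] * 4 + [irregular] * 4 + [ead] * 4


def arrhythmic_count_scripted(seed: int) -> tuple[int, int]:
    """Arrhythmic recordings among 16 scripted-arrhythmia syncytia."""
    recs = generate_cohort(
        [CohortGroup(name="FD", configs=arrhythmic_cohort_configs())], seed=seed
    )
    assessments = _classify_cohort(recs)
    return sum(a.arrhythmic for a in assessments), len(recs)


def arrhythmic_count_normal(seed: int, n: int = 36) -> tuple[int, int]:
    """Arrhythmic recordings among clean regular-rhythm syncytia at the WT rate."""
    cfg = SimulationConfig(
        duration=10.0,
        waveform=wt_voltage_template(),
        rhythm=RhythmScript(base_frequency=WT_FREQUENCY_HZ, jitter_cv=0.03),
    )
    recs = _trace_cohort(cfg, n, seed)
    assessments = _classify_cohort(recs)
    return sum(a.arrhythmic for a in assessments), n


def tachy_count_mixed(seed: int, n_tachy: int = 12, n_normal: int = 28) -> tuple[int, int]:
    """Tachyarrhythmia labels in a mixed cohort (scripted 4 Hz vs 0.6 Hz)."""
    tachy_cfg = SimulationConfig(
        duration=30.0,
        waveform=fd_voltage_template(),
        rhythm=RhythmScript(base_frequency=4.0, jitter_cv=0.02),
    )
    normal_cfg = SimulationConfig(
        duration=30.0,
        waveform=wt_voltage_template(),
        rhythm=RhythmScript(base_frequency=0.6, jitter_cv=0.03),
    )
    recs = generate_cohort(
        [
            CohortGroup.replicate("tachy", n_tachy, tachy_cfg),
            CohortGroup.replicate("normal", n_normal, normal_cfg),
        ],
        seed=seed,
    )
    assessments = _classify_cohort(recs)
    return (
        sum("tachyarrhythmia" in a.labels for a in assessments),
        n_tachy + n_normal,
    )


def run_full_recovery(seed: int) -> dict[str, dict]:
    """Run every recovery cohort; returns ``{name: {"value": v, "n": n}}``.

    Sub-seeds are spawned deterministically from the master seed, one
    per cohort, so cohorts are independent but the whole run is
    reproducible.
    """
    subs = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(10)
    ]
    results: dict[str, dict] = {}

    cv_wt, n = recover_cv(WT_CV_CM_S, seed=subs[0])
    results["t1"] = {"value": cv_wt, "n": n}
    cv_fd, n = recover_cv(FD_CV_CM_S, seed=subs[1])
    results["t2"] = {"value": cv_fd, "n": n}
    freq, n = recover_frequency(seed=subs[2])
    results["t3"] = {"value": freq, "n": n}
    apd, n = recover_apd80_corrected(seed=subs[3])
    results["t4"] = {"value": apd, "n": n}
    tri, n = recover_apd_triangulation(seed=subs[4])
    results["t5"] = {"value": tri, "n": n}
    catd, n = recover_catd80(seed=subs[5])
    results["t6"] = {"value": catd, "n": n}
    base, n = recover_ca_baseline(seed=subs[6])
    results["t7"] = {"value": base, "n": n}
    count, n = arrhythmic_count_scripted(seed=subs[7])
    results["t8"] = {"value": count, "n": n}
    count, n = arrhythmic_count_normal(seed=subs[8])
    results["t9"] = {"value": count, "n": n}
    count, n = tachy_count_mixed(seed=subs[9])
    results["t10"] = {"value": count, "n": n}
    return results
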