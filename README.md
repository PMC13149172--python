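# cardiomap

Optical-mapping electrophysiology analysis for cardiomyocyte syncytia.

Monolayers of stem-cell-derived ventricular cardiomyocytes loaded with a
voltage-sensitive (Fluovolt-like) or calcium-sensitive (Calbryte-like)
dye are imaged as time-lapse fluorescence movies; each functional
syncytium beats spontaneously and propagates activation as a unit.
`cardiomap` turns such movies (or pre-extracted ROI traces) into the
quantities disease-modeling studies report, and compares them across
experimental groups:

- **Transient metrics** — per-beat diastolic baseline F_d, amplitude
  ΔF, maximum upstroke slope, durations to 30/80/90% recovery
  (APD₃₀/₈₀/₉₀ for voltage, CaTD₃₀/₈₀/₉₀ for calcium), triangulation
  (APD_tri = APD₉₀ − APD₃₀), spontaneous activation frequency, and the
  Fridericia rate correction APD₈₀ᶜ = APD₈₀ / RR^(1/3).
- **Conduction velocity** — per-pixel activation times (sub-frame
  derivative timing) and local plane fits of the activation surface:
  local speed = 1/‖∇t‖, summarized as the median over the field.
- **Rhythm classification** — rule-based labels {tachyarrhythmia,
  bradyarrhythmia, quiescence, irregular, EAD}, with the numeric
  evidence for each rule recorded in the assessment.
- **Cohort statistics** — Kolmogorov–Smirnov (Lilliefors) normality and
  F-test variance screening, then ANOVA + Tukey or Kruskal–Wallis +
  Mann–Whitney with Bonferroni adjustment; chi-square for arrhythmia
  incidence; mean ± SEM summaries.
- **Synthetic syncytia** — a kinematic generator (closed-form waveform
  template × rhythm script × propagation model + noise + bleaching)
  with *exact* ground truth, so every stage of the pipeline is
  verifiable by parameter recovery.

The waveform template is flat at baseline F₀, rises to F₀ + A over the
upstroke time t_up, and repolarizes as
F(τ) = F₀ + A·(1 − (τ/τ_r)^p), giving the closed form
D_x = t_up + τ_r·x^(1/p) for the duration to x-fraction recovery —
invertible, so templates can be specified directly by target APD/CaTD
values.

## Worked example

```python
from cardiomap.synth import RhythmScript, SimulationConfig, simulate_trace
from cardiomap.recovery import wt_voltage_template
from cardiomap.transients import analyze_trace

cfg = SimulationConfig(
    duration=10.0,
    waveform=wt_voltage_template(),          # corrected APD80 = 0.17 s
    rhythm=RhythmScript(base_frequency=0.67, jitter_cv=0.03),
    seed=7,                                  # peak SNR ~ 20 by default
)
trace, truth = simulate_trace(cfg)
beats, summary, _ = analyze_trace(trace, recording_id="demo")
print(f"{summary.frequency:.3f} Hz, APD80 {summary.metric('d80')*1e3:.1f} ms, "
      f"corrected {summary.d80_fridericia*1e3:.1f} ms")
```

Output:

```
0.673 Hz, APD80 192.8 ms, corrected 168.4 ms
```

The detected rate matches the scripted 0.67 Hz; the raw APD₈₀ lands on
the template's 194 ms to within 1.5 ms, and dividing each beat by the
cube root of its ~1.49-s preceding interval recovers the configured
corrected value of 0.17 s to 1%.  `examples/` contains one short script per capability
(simulation & measurement, conduction velocity, rhythm classification,
group statistics, paired pre/post stimulation ratios), and the
`cardiomap` CLI wraps the same functions as
`simulate` / `analyze` / `compare` / `reproduce` subcommands for batch
use.

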