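"""Kinematic generator of ground-truth-labeled synthetic optical-mapping data.

Real optical-mapping movies of spontaneously beating cardiomyocyte
syncytia are emulated by a purely kinematic construction: a closed-form
per-beat waveform template, a rhythm script that draws activation times,
and a propagation model that assigns each pixel an activation delay.
Because every quantity (durations, conduction speed, baseline, amplitude,
beat times) is specified rather than emergent, the generator's ground
truth is exact and the whole analysis chain can be validated by parameter
recovery.  This is deliberate: a reaction–diffusion model would make
"true APD" itself an estimate.

The waveform template is flat at baseline ``F0``, rises to ``F0 + A``
over the upstroke time ``t_up`` (half-cosine ramp), then repolarizes as

    F(tau) = F0 + A * (1 - (tau / tau_r)**p),   tau in [0, tau_r],

clamped at ``F0`` afterwards.  The duration to x-fraction recovery
(measured from activation onset) has the closed form

    D_x = t_up + tau_r * x**(1/p),

which :func:`solve_template` inverts so that a template can be specified
directly by two target durations (e.g. D30 and D90, or D80 and D90).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FluorescenceMovie, Trace, extract_trace

__all__ = [
    "WaveformTemplate",
    "RhythmScript",
    "PropagationModel",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedRecording",
    "CohortGroup",
    "solve_template",
    "simulate_recording",
    "simulate_trace",
    "generate_cohort",
]


@dataclass(frozen=True)
class WaveformTemplate:
    """Closed-form single-beat fluorescence waveform.

    Attributes
    ----------
    t_up : float
        Upstroke duration in seconds (>= 0).
    tau_r : float
        Repolarization span in seconds (> 0).
    p : float
        Shape exponent (> 0); p=1 gives linear repolarization, p>1 a
        plateau followed by faster late recovery (low triangulation),
        p<1 a fast early drop with a long tail.
    amplitude : float
        Peak minus baseline, a.u.
    baseline : float
        Diastolic fluorescence level, a.u.
    """

    t_up: float
    tau_r: float
    p: float
    amplitude: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.t_up < 0:
            raise ValueError("t_up must be >= 0")
        if self.tau_r <= 0:
            raise ValueError("tau_r must be > 0")
        if self.p <= 0:
            raise ValueError("shape exponent p must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    @property
    def total_duration(self) -> float:
        return self.t_up + self.tau_r

    def duration(self, x: float) -> float:
        """Time from activation onset to x-fraction recovery, D_x."""
        if not 0 < x <= 1:
            raise ValueError("recovery fraction must be in (0, 1]")
        return self.t_up + self.tau_r * x ** (1.0 / self.p)

    def durations(self, fractions: Sequence[float] = (0.3, 0.8, 0.9)) -> dict[float, float]:
        return {x: self.duration(x) for x in fractions}

    def evaluate(self, tau, v_start: float | None = None) -> np.ndarray:
        """Template value at time ``tau`` after activation onset.

        ``v_start`` is the fluorescence level the upstroke departs from
        (defaults to baseline); a beat that interrupts an unfinished
        repolarization starts from the instantaneous value so the
        composite trace has no discontinuities.
        """
        tau = np.asarray(tau, dtype=np.float64)
        scalar = tau.ndim == 0
        tau = np.atleast_1d(tau)
        v0 = self.baseline if v_start is None else float(v_start)
        peak = self.baseline + self.amplitude
        out = np.full(tau.shape, self.baseline, dtype=np.float64)
        out[tau < 0] = v0
        if self.t_up > 0:
            rise = (tau >= 0) & (tau < self.t_up)
            out[rise] = v0 + (peak - v0) * 0.5 * (1.0 - np.cos(np.pi * tau[rise] / self.t_up))
        dec = (tau >= self.t_up) & (tau < self.total_duration)
        s = (tau[dec] - self.t_up) / self.tau_r
        out[dec] = self.baseline + self.amplitude * (1.0 - s**self.p)
        return out[0] if scalar else out

    @property
    def max_upstroke_slope(self) -> float:
        """Peak dF/dt of the half-cosine upstroke, a.u./s."""
        if self.t_up == 0:
            return math.inf
        return self.amplitude * math.pi / (2.0 * self.t_up)


def solve_template(
    t_up: float,
    d_a: float,
    d_b: float,
    a: float = 0.3,
    b: float = 0.9,
    amplitude: float = 1.0,
    baseline: float = 0.0,
) -> WaveformTemplate:
    """Build a template whose D_a and D_b durations match two targets.

    Inverts ``D_x = t_up + tau_r * x**(1/p)`` at recovery fractions
    ``a < b``:

        p     = ln(a/b) / ln((D_a - t_up) / (D_b - t_up))
        tau_r = (D_b - t_up) / b**(1/p)
    """
    if not 0 < a < b <= 1:
        raise ValueError("recovery fractions must satisfy 0 < a < b <= 1")
    if not t_up < d_a < d_b:
        raise ValueError(
            f"durations must satisfy t_up < D_a < D_b (got t_up={t_up}, D_a={d_a}, D_b={d_b})"
        )
    p = math.log(a / b) / math.log((d_a - t_up) / (d_b - t_up))
    tau_r = (d_b - t_up) / b ** (1.0 / p)
    return WaveformTemplate(t_up=t_up, tau_r=tau_r, p=p, amplitude=amplitude, baseline=baseline)


@dataclass(frozen=True)
class RhythmScript:
    """Script of spontaneous activations for one recording.

    Inter-beat intervals are Gamma-distributed with mean ``1/f`` and
    coefficient of variation ``jitter_cv`` (degenerate/deterministic at
    cv=0).  ``tachy_segments`` locally override the base rate,
    ``quiescent_episodes`` silence scripted windows, and ``ead_beats``
    attach a secondary depolarizing deflection to individual beats.
    """

    base_frequency: float  # Hz
    jitter_cv: float = 0.0
    quiescent_episodes: tuple[tuple[float, float], ...] = ()  # (start_s, duration_s)
    ead_beats: tuple[tuple[int, float, float], ...] = ()  # (beat_idx, rel_height, phase)
    tachy_segments: tuple[tuple[float, float, float], ...] = ()  # (start_s, dur_s, freq_Hz)

    def __post_init__(self) -> None:
        if self.base_frequency < 0:
            raise ValueError("base_frequency must be >= 0")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be >= 0")
        for _, delta, phase in self.ead_beats:
            if not 0 < delta < 1:
                raise ValueError("EAD relative height must be in (0, 1)")
            if not 0.3 <= phase <= 0.9:
                raise ValueError("EAD phase must lie in the 30-90% recovery span")

    def local_frequency(self, t: float) -> float:
        for start, dur, freq in self.tachy_segments:
            if start <= t < start + dur:
                return freq
        return self.base_frequency

    def draw_beat_times(self, duration: float, rng: np.random.Generator) -> np.ndarray:
        """Draw strictly increasing beat times within [0, duration)."""
        times: list[float] = []
        t = 0.0
        while True:
            f = self.local_frequency(t)
            if f <= 0:
                upcoming = [s for s, d, fr in self.tachy_segments if s > t and fr > 0]
                if not upcoming:
                    break
                t = min(upcoming)
                continue
            mean_iv = 1.0 / f
            if self.jitter_cv == 0:
                iv = mean_iv
            else:
                shape = 1.0 / self.jitter_cv**2
                iv = rng.gamma(shape, mean_iv / shape)
            t += iv
            if t >= duration:
                break
            times.append(t)
        beats = np.array(times, dtype=np.float64)
        if self.quiescent_episodes:
            keep = np.ones(beats.size, dtype=bool)
            for start, dur in self.quiescent_episodes:
                keep &= ~((beats >= start) & (beats < start + dur))
            beats = beats[keep]
        return beats


@dataclass(frozen=True)
class PropagationModel:
    """Activation-delay field of one propagated wavefront.

    ``planar`` sweeps the field along ``angle_deg`` at ``speed`` cm/s;
    ``target`` expands radially from ``origin`` (defaults to the field
    center); ``rotating`` is an Archimedean-spiral activation-time field
    with one turn per ``angular_period`` seconds — enough structure to
    exercise conduction-velocity heterogeneity without modeling re-entry.
    ``speed=inf`` activates every pixel simultaneously (the degenerate
    "global activation" case the mapper must flag).
    """

    pattern: str = "planar"  # planar | target | rotating
    speed: float = 10.0  # cm/s
    origin: tuple[int, int] | None = None  # (row, col), pixels
    angle_deg: float = 0.0  # planar propagation direction
    angular_period: float = 1.0  # s per turn, rotating only

    def __post_init__(self) -> None:
        if self.pattern not in ("planar", "target", "rotating"):
            raise ValueError(f"unknown propagation pattern {self.pattern!r}")
        if self.pattern in ("planar", "target") and not self.speed > 0:
            raise ValueError("propagation speed must be > 0")

    def delay_map(self, h: int, w: int, pixel_pitch: float) -> np.ndarray:
        """H x W map of activation delays (s), minimum shifted to zero."""
        rows, cols = np.mgrid[0:h, 0:w]
        y = rows * pixel_pitch
        x = cols * pixel_pitch
        if not math.isfinite(self.speed):
            return np.zeros((h, w))
        r0, c0 = self.origin if self.origin is not None else (h // 2, w // 2)
        y0, x0 = r0 * pixel_pitch, c0 * pixel_pitch
        if self.pattern == "planar":
            ang = math.radians(self.angle_deg)
            proj = x * math.cos(ang) + y * math.sin(ang)
            delay = (proj - proj.min()) / self.speed
        elif self.pattern == "target":
            delay = np.hypot(x - x0, y - y0) / self.speed
        else:  # rotating spiral
            theta = np.mod(np.arctan2(y - y0, x - x0), 2 * np.pi)
            delay = theta / (2 * np.pi) * self.angular_period + np.hypot(x - x0, y - y0) / self.speed
        return delay - delay.min()


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic recording.

    ``noise_sd=None`` selects the default noise level, amplitude/20
    (peak SNR of about 20, a plausible level for a high-NA sCMOS
    acquisition; the study's recordings carry no published SNR figure,
    so this is a knob, not a claim).  ``bleach_rate`` is the fractional
    monoexponential intensity loss per second.  The seed fully
    determines the output.
    """

    shape: tuple[int, int] = (1, 1)  # (H, W) pixels
    pixel_pitch: float = 0.01  # cm/pixel
    frame_rate: float = 100.0  # fps
    duration: float = 10.0  # s
    modality: str = "voltage"
    waveform: WaveformTemplate = field(
        default_factory=lambda: WaveformTemplate(t_up=0.02, tau_r=0.2, p=1.5)
    )
    rhythm: RhythmScript = field(default_factory=lambda: RhythmScript(base_frequency=1.0))
    propagation: PropagationModel = field(default_factory=PropagationModel)
    noise_sd: float | None = None  # a.u.; None -> amplitude / 20
    bleach_rate: float = 0.0  # fraction of signal lost per s
    seed: int = 0
    recording_id: str = ""

    @property
    def resolved_noise_sd(self) -> float:
        if self.noise_sd is None:
            return self.waveform.amplitude / 20.0
        return self.noise_sd

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 1 or w < 1:
            raise ValueError("grid must be at least 1x1")
        if self.frame_rate <= 0 or self.pixel_pitch <= 0 or self.duration <= 0:
            raise ValueError("frame_rate, pixel_pitch and duration must be > 0")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")


@dataclass
class GroundTruth:
    """Exact per-beat truth for one simulated recording.

    ``beats`` has one row per beat: ``beat_index``, ``time`` (wavefront
    origin time), ``trace_time`` (origin time plus the ROI-mean
    propagation delay, i.e. where a global-trace detector should fire),
    true ``d30``/``d80``/``d90``, ``baseline``, ``amplitude``,
    ``ead`` flag, and ``censored`` (next beat arrives before 90%
    recovery).  ``labels`` records the scripted rhythm features;
    ``cv`` is the scripted conduction speed (NaN for rotating/global).
    """

    beats: pd.DataFrame
    labels: dict
    cv: float
    frequency: float
    recording_id: str = ""


@dataclass
class SimulatedRecording:
    group: str
    recording_id: str
    movie: FluorescenceMovie
    truth: GroundTruth

    @property
    def trace(self) -> Trace:
        return extract_trace(self.movie, "global")


_EAD_SIGMA_S = 0.03  # Gaussian half-width of injected EAD bumps (s)


def simulate_recording(config: SimulationConfig) -> tuple[FluorescenceMovie, GroundTruth]:
    """Render one synthetic recording and its exact ground truth.

    Per pixel, the trace is the scripted waveform replayed at
    ``beat time + propagation delay``; a beat arriving before the
    previous repolarization has finished truncates it and starts its
    upstroke from the instantaneous value.  EAD bumps are additive
    Gaussian deflections on the repolarization limb.  Multiplicative
    monoexponential bleaching and additive white noise are applied last.
    """
    h, w = config.shape
    tmpl = config.waveform
    rng = np.random.default_rng(config.seed)
    beats = config.rhythm.draw_beat_times(config.duration, rng)

    if beats.size >= 2:
        min_iv = float(np.min(np.diff(beats)))
        if min_iv <= tmpl.t_up:
            raise ValueError(
                f"unphysical rhythm: inter-beat interval {min_iv:.4f}s is shorter "
                f"than the upstroke duration {tmpl.t_up:.4f}s"
            )

    n_frames = int(round(config.duration * config.frame_rate))
    t_grid = np.arange(n_frames) / config.frame_rate
    delays = config.propagation.delay_map(h, w, config.pixel_pitch)
    movie = np.full((n_frames, h, w), tmpl.baseline, dtype=np.float64)

    # Start-value chain: intervals are pixel-independent (delays cancel),
    # so the truncation state is shared by all pixels.
    v_starts = np.empty(beats.size)
    v = tmpl.baseline
    for i, bt in enumerate(beats):
        v_starts[i] = v
        if i + 1 < beats.size:
            v = float(tmpl.evaluate(beats[i + 1] - bt, v_start=v))

    ead_map = {idx: (delta, phase) for idx, delta, phase in config.rhythm.ead_beats}
    d_max = float(delays.max())
    fps = config.frame_rate

    for i, bt in enumerate(beats):
        t_next = beats[i + 1] if i + 1 < beats.size else math.inf
        window = min(t_next - bt, tmpl.total_duration + 6 * _EAD_SIGMA_S)
        k0 = max(0, int(math.floor(bt * fps)))
        k1 = min(n_frames, int(math.ceil((bt + window + d_max) * fps)) + 1)
        if k0 >= k1:
            continue
        tau = t_grid[k0:k1, None, None] - bt - delays[None, :, :]
        active = (tau >= 0) & (tau < (t_next - bt))
        vals = tmpl.evaluate(tau, v_start=v_starts[i])
        if i in ead_map:
            delta, phase = ead_map[i]
            tau_c = tmpl.t_up + tmpl.tau_r * phase ** (1.0 / tmpl.p)
            vals = vals + delta * tmpl.amplitude * np.exp(
                -0.5 * ((tau - tau_c) / _EAD_SIGMA_S) ** 2
            )
        block = movie[k0:k1]
        block[active] = vals[active]

    if config.bleach_rate > 0:
        movie *= np.exp(-config.bleach_rate * t_grid)[:, None, None]
    noise_sd = config.resolved_noise_sd
    if noise_sd > 0:
        movie += rng.normal(0.0, noise_sd, size=movie.shape)

    fluo = FluorescenceMovie(
        frames=movie,
        frame_rate=config.frame_rate,
        pixel_pitch=config.pixel_pitch,
        modality=config.modality,
        recording_id=config.recording_id or f"sim-{config.seed}",
    )

    intervals = np.diff(beats) if beats.size >= 2 else np.array([])
    next_iv = np.append(intervals, math.inf) if beats.size else np.array([])
    d30, d80, d90 = (tmpl.duration(x) for x in (0.3, 0.8, 0.9))
    remaining = np.minimum(next_iv, config.duration - beats) if beats.size else next_iv
    truth_beats = pd.DataFrame(
        {
            "beat_index": np.arange(beats.size, dtype=int),
            "time": beats,
            "trace_time": beats + float(delays.mean()),
            "d30": d30,
            "d80": d80,
            "d90": d90,
            "baseline": tmpl.baseline,
            "amplitude": tmpl.amplitude,
            "ead": [i in ead_map for i in range(beats.size)],
            "censored": remaining < d90 if beats.size else [],
        }
    )
    labels = {
        "base_frequency": config.rhythm.base_frequency,
        "jitter_cv": config.rhythm.jitter_cv,
        "scripted_tachy": len(config.rhythm.tachy_segments) > 0,
        "scripted_quiescence": len(config.rhythm.quiescent_episodes) > 0,
        "scripted_ead_count": len(config.rhythm.ead_beats),
        "pattern": config.propagation.pattern,
    }
    cv_true = (
        config.propagation.speed
        if config.propagation.pattern in ("planar", "target") and math.isfinite(config.propagation.speed)
        else math.nan
    )
    freq_true = (
        (beats.size - 1) / (beats[-1] - beats[0]) if beats.size >= 2 else 0.0
    )
    truth = GroundTruth(
        beats=truth_beats,
        labels=labels,
        cv=cv_true,
        frequency=freq_true,
        recording_id=fluo.recording_id,
    )
    return fluo, truth


def simulate_trace(config: SimulationConfig) -> tuple[Trace, GroundTruth]:
    """Single-trace shortcut: render on a 1x1 grid and extract the pixel."""
    cfg = replace(config, shape=(1, 1))
    movie, truth = simulate_recording(cfg)
    return extract_trace(movie, "global"), truth


@dataclass
class CohortGroup:
    """One experimental group of a synthetic cohort (one config per recording)."""

    name: str
    configs: list[SimulationConfig]

    @classmethod
    def replicate(cls, name: str, n: int, config: SimulationConfig) -> "CohortGroup":
        if n < 1:
            raise ValueError("group must contain at least one recording")
        return cls(name=name, configs=[config] * n)


def generate_cohort(groups: Sequence[CohortGroup], seed: int) -> list[SimulatedRecording]:
    """Simulate every recording of a multi-group cohort.

    Per-recording seeds are spawned from the master seed via
    ``numpy.random.SeedSequence``, so the cohort is reproducible as a
    whole while recordings stay statistically independent.
    """
    groups = list(groups)
    if not groups or any(len(g.configs) == 0 for g in groups):
        raise ValueError("cohort spec must contain at least one recording per group")
    total = sum(len(g.configs) for g in groups)
    children = np.random.SeedSequence(seed).spawn(total)
    out: list[SimulatedRecording] = []
    k = 0
    for group in groups:
        for j, cfg in enumerate(group.configs):
            rec_seed = int(children[k].generate_state(1)[0] % (2**31))
            rec_id = f"{group.name}-{j:03d}"
            cfg_j = replace(cfg, seed=rec_seed, recording_id=rec_id)
            movie, truth = simulate_recording(cfg_j)
            out.append(SimulatedRecording(group=group.name, recording_id=rec_id, movie=movie, truth=truth))
            k += 1
    return out
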