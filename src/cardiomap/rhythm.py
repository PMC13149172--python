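"""Rule-based per-recording rhythm classification.

A recording receives a subset of the labels {normal, tachyarrhythmia,
bradyarrhythmia, quiescence, irregular, EAD}; "normal" is assigned iff
no abnormal rule fires, and a recording is *arrhythmic* iff its label
set differs from {normal}.  All numeric thresholds are configurable and
recorded in the assessment; the defaults separate normal spontaneous
rates (~0.5-1.5 Hz in hiPSC-CM syncytia) from the scripted phenotypes
by a comfortable margin.  When a reference (control) cohort frequency
is supplied, the tachycardia cut becomes a multiple of it — "abnormal
increase relative to control" semantics — instead of the absolute
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import Trace
from .transients import BeatMetrics, spontaneous_frequency

__all__ = [
    "RhythmThresholds",
    "RhythmAssessment",
    "EadEvent",
    "classify_rhythm",
    "detect_ead",
]

ALL_LABELS = ("normal", "tachyarrhythmia", "bradyarrhythmia", "quiescence", "irregular", "EAD")


@dataclass(frozen=True)
class RhythmThresholds:
    """Numeric criteria for the rhythm rules.

    ``f_hi``/``f_lo`` bound the normal frequency band (Hz); a gap longer
    than ``max(gap_abs_s, gap_rel * median IBI)`` flags quiescence; an
    inter-beat-interval coefficient of variation above ``ibi_cv_max``
    (with at least ``min_beats_irregular`` beats) flags irregularity;
    ``ead_delta`` is the minimum re-elevation, as a fraction of the beat
    amplitude, that counts as an early afterdepolarization.  If
    ``reference_frequency`` is set, the tachycardia cut is
    ``reference_multiple`` times it.
    """

    f_hi: float = 2.0  # Hz
    f_lo: float = 0.2  # Hz
    gap_abs_s: float = 5.0
    gap_rel: float = 3.0
    ibi_cv_max: float = 0.20
    min_beats_irregular: int = 5
    ead_delta: float = 0.10
    reference_frequency: float | None = None
    reference_multiple: float = 2.5

    @property
    def effective_f_hi(self) -> float:
        if self.reference_frequency is not None:
            return self.reference_multiple * self.reference_frequency
        return self.f_hi


@dataclass
class EadEvent:
    """One secondary depolarizing re-elevation during repolarization."""

    beat_index: int
    time: float  # s, at the local maximum of the re-elevation
    height: float  # a.u., local-min-to-local-max rise
    rel_height: float  # height / beat amplitude


@dataclass
class RhythmAssessment:
    """Label set plus the numeric evidence behind each rule."""

    labels: tuple[str, ...]
    arrhythmic: bool
    evidence: dict = field(default_factory=dict)
    thresholds: RhythmThresholds = field(default_factory=RhythmThresholds)

    def __post_init__(self) -> None:
        if "normal" in self.labels and len(self.labels) > 1:
            raise ValueError("'normal' is exclusive of all other labels")
        if self.arrhythmic != (set(self.labels) != {"normal"}):
            raise ValueError("arrhythmic flag inconsistent with label set")


def detect_ead(
    trace: Trace,
    beats: list[BeatMetrics],
    delta: float = 0.10,
    guard_s: float = 0.03,
) -> list[EadEvent]:
    """Find early afterdepolarizations on the repolarization limbs.

    An EAD is a secondary depolarizing re-elevation of at least
    ``delta`` times the beat amplitude, occurring after the signal has
    recovered past 30% but before 90% recovery completes, and not
    attributable to the next detected beat (a guard band of ``guard_s``
    before the next activation onset is excluded).

    The repolarization segment is smoothed, fitted with a robustly
    reweighted quadratic (the monotone decay), and the bump height is
    read from the fit residual — a drawdown statistic on the raw limb
    would subtract the concurrent decay from the bump and fire on shot
    noise.  Events must clear both the relative threshold and a noise
    floor of four robust residual SDs.
    """
    from scipy.signal import savgol_filter

    fs = trace.frame_rate
    win = max(5, int(round(0.07 * fs)) | 1)
    v = savgol_filter(trace.values, win, 2) if trace.values.size > win else trace.values
    events: list[EadEvent] = []
    for bi, b in enumerate(beats):
        if not math.isfinite(b.d30):
            continue
        t_start = b.onset_time + b.d30
        if math.isfinite(b.d90):
            t_end = b.onset_time + b.d90
        else:
            # censored: search to the next beat / end of trace
            t_end = trace.duration
        if bi + 1 < len(beats):
            t_end = min(t_end, beats[bi + 1].onset_time - guard_s)
        i0 = int(math.ceil(t_start * fs))
        i1 = min(int(math.floor(t_end * fs)), v.size - 1)
        if i1 - i0 < 5:
            continue
        seg = v[i0 : i1 + 1]
        tt = np.arange(seg.size, dtype=float)
        # robust quadratic fit of the decay: two reweighting passes
        # downweight the bump so it survives in the residual
        w = np.ones_like(seg)
        for _ in range(3):
            coef = np.polyfit(tt, seg, 2, w=w)
            resid = seg - np.polyval(coef, tt)
            scale = 1.4826 * float(np.median(np.abs(resid))) + 1e-12
            w = 1.0 / (1.0 + (resid / (2.5 * scale)) ** 2)
        j = int(np.argmax(resid))
        height = float(resid[j])
        floor = 4.0 * scale
        if 0 < j < seg.size - 1 and height >= max(delta * b.amplitude, floor):
            events.append(
                EadEvent(
                    beat_index=bi,
                    time=(i0 + j) / fs,
                    height=height,
                    rel_height=height / b.amplitude,
                )
            )
    return events


def classify_rhythm(
    activation_times: np.ndarray,
    beats: list[BeatMetrics] | None = None,
    window: float = 10.0,
    thresholds: RhythmThresholds | None = None,
    trace: Trace | None = None,
) -> RhythmAssessment:
    """Assign rhythm labels to one recording.

    Rules (each independent; any firing rule removes "normal"):

    * tachyarrhythmia — frequency above the tachycardia cut;
    * bradyarrhythmia — frequency positive but below ``f_lo``;
    * quiescence — no/one beat, or any inter-beat gap exceeding
      ``max(gap_abs_s, gap_rel * median IBI)`` (also measured from the
      recording edges to the first/last beat);
    * irregular — IBI coefficient of variation above ``ibi_cv_max``
      with at least ``min_beats_irregular`` beats;
    * EAD — any event found by :func:`detect_ead` (requires ``trace``
      and ``beats``).

    The label set is deterministic given the inputs and thresholds.
    """
    if window <= 0:
        raise ValueError("analysis window must be positive")
    thr = thresholds or RhythmThresholds()
    times = np.asarray(activation_times, dtype=float)
    freq = spontaneous_frequency(times, window)

    labels: set[str] = set()
    f_hi = thr.effective_f_hi
    evidence: dict = {"frequency": freq.hz, "n_beats": freq.n_beats, "f_hi": f_hi}

    if freq.hz > f_hi:
        labels.add("tachyarrhythmia")
    if 0 < freq.hz < thr.f_lo:
        labels.add("bradyarrhythmia")

    if times.size <= 1:
        labels.add("quiescence")
        evidence["longest_gap"] = window
    else:
        ibi = np.diff(times)
        gaps = np.concatenate([[times[0]], ibi, [window - times[-1]]])
        longest = float(gaps.max())
        gap_cut = max(thr.gap_abs_s, thr.gap_rel * float(np.median(ibi)))
        evidence["longest_gap"] = longest
        evidence["gap_cut"] = gap_cut
        if longest > gap_cut:
            labels.add("quiescence")
        if times.size >= thr.min_beats_irregular:
            cv = float(ibi.std(ddof=1) / ibi.mean()) if ibi.mean() > 0 else math.inf
            evidence["ibi_cv"] = cv
            if cv > thr.ibi_cv_max:
                labels.add("irregular")

    if trace is not None and beats:
        events = detect_ead(trace, beats, delta=thr.ead_delta)
        evidence["ead_count"] = len(events)
        if events:
            labels.add("EAD")

    if not labels:
        labels = {"normal"}
    ordered = tuple(l for l in ALL_LABELS if l in labels)
    return RhythmAssessment(
        labels=ordered,
        arrhythmic=set(ordered) != {"normal"},
        evidence=evidence,
        thresholds=thr,
    )
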