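"""Beat detection and per-beat quantification of optical transients.

Per beat, the analysis measures the diastolic baseline, transient
amplitude, upstroke slope, and the durations to 30/80/90% recovery
(APD30/80/90 for voltage, CaTD30/80/90 for calcium), plus the
triangulation D90 - D30.  Recovery fractions are measured from each
beat's own baseline toward its own peak — "x% return to baseline"
semantics per beat, robust to photobleaching — with linear interpolation
between frames for sub-frame crossings.  Beats whose repolarization is
interrupted by the next activation (or by the end of the recording) are
flagged censored at the unreached fractions and excluded from duration
means, but still count toward the spontaneous frequency.

Rate correction uses the Fridericia formula, D80 / RR^(1/3), applied
per beat with the preceding inter-beat interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy.ndimage import percentile_filter

from .io import Trace

__all__ = [
    "BeatMetrics",
    "SyncytiumSummary",
    "FrequencyEstimate",
    "preprocess_trace",
    "detect_beats",
    "measure_beat",
    "measure_all_beats",
    "fridericia_correct",
    "spontaneous_frequency",
    "iso_response",
    "analyze_trace",
]

# Detection defaults: derivative threshold as a fraction of the recording's
# maximum smoothed derivative, and a refractory window for merging.
DEFAULT_DERIV_THRESHOLD = 0.20
DEFAULT_REFRACTORY_S = 0.10
DEFAULT_SMOOTH_WINDOW_S = 0.05
DEFAULT_BASELINE_WINDOW_S = 0.05
# Fraction of the per-beat peak derivative at which the activation onset
# (foot of the upstroke) is placed.
ONSET_DERIV_FRACTION = 0.10


@dataclass
class BeatMetrics:
    """Measurements of a single action potential or calcium transient."""

    activation_time: float  # s, time of maximum upstroke derivative
    onset_time: float  # s, foot of the upstroke (derivative-threshold onset)
    baseline: float  # a.u., diastolic level before the upstroke
    amplitude: float  # a.u., peak - baseline
    upstroke_slope: float  # a.u./s, max dF/dt on the rising limb
    upstroke_slope_norm: float  # 1/s, upstroke_slope / amplitude
    d30: float = math.nan  # s from onset to 30% recovery
    d80: float = math.nan
    d90: float = math.nan
    rr_prev: float = math.nan  # s, interval from previous activation
    censored: bool = False  # repolarization interrupted before 90% recovery

    @property
    def triangulation(self) -> float:
        return self.d90 - self.d30

    def as_dict(self) -> dict:
        d = {
            "activation_time": self.activation_time,
            "onset_time": self.onset_time,
            "baseline": self.baseline,
            "amplitude": self.amplitude,
            "upstroke_slope": self.upstroke_slope,
            "upstroke_slope_norm": self.upstroke_slope_norm,
            "d30": self.d30,
            "d80": self.d80,
            "d90": self.d90,
            "triangulation": self.triangulation,
            "rr_prev": self.rr_prev,
            "censored": self.censored,
        }
        return d


@dataclass
class FrequencyEstimate:
    hz: float
    n_beats: int
    quiescent: bool


@dataclass
class SyncytiumSummary:
    """Per-recording aggregate: the row of the cohort table.

    Means and SEMs are over non-censored beats (durations) or all
    measured beats (baseline, amplitude, upstroke); SEM is NaN for
    n < 2.  ``d80_fridericia`` is the mean of per-beat rate-corrected
    D80 values (beats without a preceding interval are excluded).
    """

    recording_id: str
    modality: str
    n_beats: int
    frequency: float  # Hz
    quiescent: bool
    analysis_window: float  # s
    means: dict = field(default_factory=dict)
    sems: dict = field(default_factory=dict)
    d80_fridericia: float = math.nan
    rhythm_labels: tuple[str, ...] = ()

    def metric(self, name: str) -> float:
        if name == "frequency":
            return self.frequency
        if name == "d80_fridericia":
            return self.d80_fridericia
        return self.means.get(name, math.nan)


def _odd_window(window_s: float, frame_rate: float, minimum: int = 3) -> int:
    n = max(minimum, int(round(window_s * frame_rate)))
    return n + 1 if n % 2 == 0 else n


def preprocess_trace(
    trace: Trace,
    smooth_window_s: float | None = DEFAULT_SMOOTH_WINDOW_S,
    detrend: bool = False,
    detrend_window_s: float = 5.0,
) -> Trace:
    """Savitzky–Golay smoothing and optional slow-drift removal.

    Detrending subtracts a rolling 10th-percentile baseline (window
    ``detrend_window_s``) and re-adds its mean, so slow photobleaching
    drift is flattened while the absolute a.u. level — which carries the
    diastolic-calcium signal — is preserved.  With smoothing off and
    detrend off the trace is returned unchanged.
    """
    values = trace.values
    if detrend:
        n = max(3, int(round(detrend_window_s * trace.frame_rate)))
        floor = percentile_filter(values, percentile=10, size=n, mode="nearest")
        # the filter flattens near the boundaries (no centered window
        # there); extend the adjacent trend linearly into the edges
        half = n // 2
        if half > 2 and values.size > 3 * half:
            idx = np.arange(values.size, dtype=float)
            for edge, fit in (
                (slice(0, half), slice(half, 2 * half)),
                (slice(values.size - half, None), slice(values.size - 2 * half, values.size - half)),
            ):
                coef = np.polyfit(idx[fit], floor[fit], 1)
                floor[edge] = np.polyval(coef, idx[edge])
        values = values - floor + floor.mean()
    if smooth_window_s is not None and smooth_window_s > 0:
        win = _odd_window(smooth_window_s, trace.frame_rate, minimum=5)
        if win >= values.size:
            raise ValueError(
                f"smoothing window ({win} samples) longer than trace ({values.size})"
            )
        values = savgol_filter(values, window_length=win, polyorder=3)
    return trace.copy_with(values)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample offset of a discrete peak by parabolic interpolation."""
    if i <= 0 or i >= y.size - 1:
        return 0.0
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    off = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(off, -0.5, 0.5))


def detect_beats(
    trace: Trace,
    deriv_threshold: float = DEFAULT_DERIV_THRESHOLD,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    deriv_smooth_s: float = 0.11,
) -> np.ndarray:
    """Detect activation times from suprathreshold upstroke derivatives.

    The first derivative is computed with a Savitzky–Golay derivative
    filter (window ``deriv_smooth_s``; detection needs a heavier
    smoother than measurement because shot noise differentiates badly)
    and thresholded at ``deriv_threshold`` times its recording-wide
    maximum; each suprathreshold excursion yields one activation at the
    time of its derivative peak, refined to sub-frame precision by
    parabolic interpolation.  Events closer than the refractory window
    are merged, keeping the larger-derivative event.  An empty array is
    a valid result (quiescent trace).
    """
    fs = trace.frame_rate
    win = _odd_window(deriv_smooth_s, fs, minimum=5)
    if win >= trace.values.size:
        win = trace.values.size - 1 if trace.values.size % 2 == 0 else trace.values.size - 2
        win = max(win, 3)
    v = trace.values
    # Quiescence guard: a trace with no transients has a peak-to-peak
    # range comparable to its high-frequency noise floor (estimated
    # robustly from first differences, which a beat barely affects).
    sigma_hf = 1.4826 * float(np.median(np.abs(np.diff(v)))) / math.sqrt(2.0)
    v_range = float(np.ptp(savgol_filter(v, 5, 2))) if v.size > 7 else float(np.ptp(v))
    if v_range < 8.0 * sigma_hf:
        return np.array([])
    d = savgol_filter(v, win, polyorder=2, deriv=1, delta=1.0 / fs)
    d_max = d.max()
    if d_max <= 0:
        return np.array([])
    thresh = deriv_threshold * d_max
    # the SG edge polynomials can spike; ignore the half-window margins
    edge = win // 2
    d = d.copy()
    d[:edge] = 0.0
    d[d.size - edge :] = 0.0
    idx = np.flatnonzero(d > thresh)
    if idx.size == 0:
        return np.array([])
    breaks = np.flatnonzero(np.diff(idx) > 1)
    segments = np.split(idx, breaks + 1)
    cand: list[tuple[float, float]] = []  # (time, deriv_peak)
    for seg in segments:
        i_pk = seg[np.argmax(d[seg])]
        off = _parabolic_refine(d, i_pk)
        cand.append(((i_pk + off) / fs, d[i_pk]))
    # merge within refractory window, keep larger derivative
    merged: list[tuple[float, float]] = []
    for t, amp in cand:
        if merged and t - merged[-1][0] < refractory_s:
            if amp > merged[-1][1]:
                merged[-1] = (t, amp)
        else:
            merged.append((t, amp))
    return np.array([t for t, _ in merged])


def measure_beat(
    trace: Trace,
    activation_time: float,
    next_activation_time: float | None = None,
    fractions: Sequence[float] = (0.3, 0.8, 0.9),
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> BeatMetrics:
    """Quantify one beat of a preprocessed trace.

    The activation onset is placed at the foot of the upstroke (last
    point before the derivative peak where the derivative falls below
    10% of that beat's peak derivative); the baseline is the median of
    the window ending at the onset; recovery crossings are found after
    the peak with linear interpolation and measured from the onset.
    Raises ``ValueError`` when no discernible transient is present
    (amplitude <= 0).
    """
    v = trace.values
    fs = trace.frame_rate
    n = v.size
    # derivative on a heavier smoother than the values: it only localizes
    # the upstroke and the baseline-window end, so smear is harmless
    win = _odd_window(0.11, fs, minimum=5)
    if win < n:
        d = savgol_filter(v, win, polyorder=2, deriv=1, delta=1.0 / fs)
    else:
        d = np.gradient(v) * fs

    i_end = n if next_activation_time is None else min(n, int(next_activation_time * fs))
    i_act = int(round(activation_time * fs))
    i_act = min(max(i_act, 0), n - 1)

    # derivative peak of this upstroke (detection already placed us near it)
    lo = max(0, i_act - 3)
    hi = min(n, i_act + 4)
    i_dpk = lo + int(np.argmax(d[lo:hi]))
    d_pk = d[i_dpk]
    if d_pk <= 0:
        raise ValueError("no rising limb at the requested activation time")

    # rough onset by derivative-threshold walk-back: defines where the
    # pre-upstroke baseline window ends (deliberately on the early side)
    onset_thresh = ONSET_DERIV_FRACTION * d_pk
    j = i_dpk
    max_back = int(0.5 * fs)
    while j > 0 and d[j - 1] > onset_thresh and (i_dpk - j) < max_back:
        j -= 1
    i_rough = j

    # diastolic baseline: median of the window ending at the rough onset
    nb = max(1, int(round(baseline_window_s * fs)))
    b_lo = max(0, i_rough - nb + 1)
    baseline = float(np.median(v[b_lo : i_rough + 1]))

    # peak sample between activation and the next activation; located on
    # a lightly smoothed copy so an isolated noise spike cannot win
    if n > 7:
        v_loc = savgol_filter(v, 5, polyorder=2)
    else:
        v_loc = v
    i_pk = i_dpk + int(np.argmax(v_loc[i_dpk:i_end])) if i_end > i_dpk else i_dpk
    peak_sample = float(v[i_pk])
    amp_rough = peak_sample - baseline
    if amp_rough <= 0:
        raise ValueError("no discernible transient: peak does not exceed baseline")

    # Upstroke line: through the interpolated 25% and 75% rise crossings.
    # Its intersection with the baseline is the activation onset (foot);
    # fitting the steep limb makes the foot stable under noise, unlike a
    # walked-back derivative threshold which drifts with smoothing.
    lev25 = baseline + 0.25 * amp_rough
    lev75 = baseline + 0.75 * amp_rough
    t25 = t75 = math.nan
    k = i_pk - 1
    search_lo = max(0, i_rough - 2)
    while k >= search_lo:
        if math.isnan(t75) and v[k] <= lev75 < v[k + 1]:
            t75 = (k + (lev75 - v[k]) / (v[k + 1] - v[k])) / fs
        if not math.isnan(t75) and v[k] <= lev25 < v[k + 1]:
            t25 = (k + (lev25 - v[k]) / (v[k + 1] - v[k])) / fs
            break
        k -= 1
    if math.isfinite(t25) and math.isfinite(t75) and t75 > t25:
        rise_slope = 0.5 * amp_rough / (t75 - t25)
        onset_time = t25 - 0.25 * amp_rough / rise_slope
    else:
        # truncated upstroke (previous beat ended above the 25% level):
        # fall back to the derivative-threshold onset
        rise_slope = float(d_pk)
        onset_time = i_rough / fs
        t25 = onset_time

    # Refined peak value.  A noisy sample maximum is biased upward
    # (order statistic), so the default estimate is a quadratic fit over
    # the peak sample and the early falling limb, evaluated at the peak
    # sample.  Sharp (cusp-like) peaks are instead *under*-sampled: when
    # the early decay is steep, the upstroke line and a line through the
    # first falling samples are intersected ("triangle" reconstruction),
    # clamped to at most one frame's worth of decay above the sample max.
    peak_val = peak_sample
    j_hi = min(i_pk + 5, i_end)
    if j_hi - i_pk >= 3:
        tt = (np.arange(i_pk, j_hi) - i_pk) / fs
        coef = np.polyfit(tt, v[i_pk:j_hi], 2)
        peak_val = float(coef[2])  # fitted value at the peak sample
    drop3 = peak_sample - v[min(i_pk + 3, i_end - 1)]
    noise_sd = 1.4826 * float(np.median(np.abs(v[b_lo : i_rough + 1] - baseline))) if i_rough > b_lo else 0.0
    cusp = drop3 > max(0.10 * amp_rough, 4.0 * noise_sd)
    j0, j1 = i_pk + 1, min(i_pk + 4, i_end)
    if cusp and j1 - j0 >= 2 and math.isfinite(t75):
        tt = np.arange(j0, j1) / fs
        b_dec, a_dec = np.polyfit(tt, v[j0:j1], 1)
        if b_dec < rise_slope:
            # rise line: y = lev25 + rise_slope * (t - t25)
            t_star = (a_dec - lev25 + rise_slope * t25) / (rise_slope - b_dec)
            v_star = lev25 + rise_slope * (t_star - t25)
            cap = peak_sample + min(0.5 * amp_rough, abs(b_dec) / fs)
            if t25 < t_star <= j0 / fs and v_star > peak_val:
                peak_val = float(min(v_star, cap))
    peak_val = max(peak_val, baseline + 0.5 * amp_rough)  # sanity floor
    amplitude = peak_val - baseline

    up_slice = d[i_rough : i_pk + 1]
    upstroke_slope = float(up_slice.max()) if up_slice.size else float(d_pk)

    fractions = sorted(fractions)
    durations: dict[float, float] = {}
    censored = False
    guard = 3  # samples that must confirm a crossing (noise-dip rejection)
    k = i_pk
    for x in fractions:
        level = peak_val - x * amplitude
        t_cross = math.nan
        while k + 1 < i_end:
            if v[k] <= level and k == i_pk:
                # reconstructed peak already below this level at the peak
                # sample: the crossing happened within the peak frame
                t_cross = k / fs
                break
            if v[k + 1] <= level < v[k]:
                confirm = v[k + 1 : min(k + 1 + guard, i_end)]
                if confirm.size == guard and float(np.median(confirm)) > level:
                    k += 1
                    continue  # transient noise dip, not a real crossing
                if v[k] == v[k + 1]:
                    t_cross = (k + 1) / fs
                else:
                    frac = (v[k] - level) / (v[k] - v[k + 1])
                    t_cross = (k + frac) / fs
                break
            k += 1
        if math.isnan(t_cross):
            censored = True
            break
        # Symmetric refinement: a first-passage crossing is biased early
        # under noise, so re-estimate it by a local linear regression
        # around the current estimate, with a window scaled to the
        # elapsed decay (slow transients get wide, noise-averaging
        # windows).  Iterated to a fixed point because the initial
        # first-passage guess can sit well before the true crossing.
        # A near-vertical fall (most of the amplitude within one frame)
        # is sharper than any fitted line, so the interpolated crossing
        # is kept as-is.
        if k + 1 < n and v[k] - v[k + 1] >= 0.25 * amplitude:
            if durations:
                t_cross = max(t_cross, max(durations.values()) + onset_time)
            durations[x] = t_cross - onset_time
            continue
        t_est = t_cross
        for _ in range(3):
            k_c = int(t_est * fs)
            w = max(2, int(round(0.15 * (t_est - i_pk / fs) * fs)))
            idx_r = np.arange(max(i_pk + 1, k_c - w), min(i_end, k_c + w + 1))
            # truncate the window where the signal reaches the diastolic
            # floor: the flat tail would drag the fitted slope to zero.
            # The cut is in time (first smoothed floor crossing), not a
            # pointwise value mask, which would selectively discard
            # noise-low samples and bias the fit upward.
            below = np.flatnonzero(v_loc[idx_r] < baseline + 0.04 * amplitude)
            if below.size:
                idx_r = idx_r[: below[0]]
            if idx_r.size < 4:
                break
            b_fit, a_fit = np.polyfit(idx_r / fs, v[idx_r], 1)
            span_s = (idx_r.max() - idx_r.min()) / fs
            # the line must genuinely descend across the window, else the
            # crossing extrapolation is numerically meaningless
            if b_fit * span_s > -0.02 * amplitude:
                break
            t_new = (level - a_fit) / b_fit
            t_new = min(max(t_new, i_pk / fs), (i_end - 1) / fs)
            if abs(t_new - t_est) < 0.5 / fs:
                t_est = t_new
                break
            t_est = t_new
        t_cross = t_est
        if durations:
            t_cross = max(t_cross, max(durations.values()) + onset_time)
        durations[x] = t_cross - onset_time

    metrics = BeatMetrics(
        activation_time=activation_time,
        onset_time=onset_time,
        baseline=baseline,
        amplitude=amplitude,
        upstroke_slope=upstroke_slope,
        upstroke_slope_norm=upstroke_slope / amplitude,
        d30=durations.get(0.3, math.nan),
        d80=durations.get(0.8, math.nan),
        d90=durations.get(0.9, math.nan),
        censored=censored,
    )
    return metrics


def measure_all_beats(
    trace: Trace,
    activation_times: np.ndarray,
    **kwargs,
) -> list[BeatMetrics]:
    """Measure every detected beat; beats with no transient are dropped."""
    out: list[BeatMetrics] = []
    times = np.asarray(activation_times, dtype=float)
    for i, t in enumerate(times):
        t_next = times[i + 1] if i + 1 < times.size else None
        try:
            m = measure_beat(trace, t, t_next, **kwargs)
        except ValueError:
            continue
        if i > 0:
            m.rr_prev = t - times[i - 1]
        out.append(m)
    return out


def fridericia_correct(d80: float, rr_prev: float) -> float:
    """Rate-corrected duration: D80 / RR^(1/3).

    Identity at RR = 1 s; homogeneous of degree 1 in D80.  Applied per
    beat with the preceding inter-beat interval, then averaged per
    recording.
    """
    if not rr_prev > 0:
        raise ValueError("RR interval must be positive")
    return d80 / rr_prev ** (1.0 / 3.0)


def spontaneous_frequency(activation_times: np.ndarray, window: float) -> FrequencyEstimate:
    """Spontaneous activation frequency over an analysis window.

    For >= 2 beats the estimator is (N-1) / (t_N - t_1); recordings
    with <= 1 beat report 0 Hz and are flagged quiescent.
    """
    if window <= 0:
        raise ValueError("analysis window must be positive")
    times = np.asarray(activation_times, dtype=float)
    if times.size < 2:
        return FrequencyEstimate(hz=0.0, n_beats=int(times.size), quiescent=True)
    span = times[-1] - times[0]
    return FrequencyEstimate(hz=(times.size - 1) / span, n_beats=int(times.size), quiescent=False)


def iso_response(
    pre: SyncytiumSummary, post: SyncytiumSummary, metric: str
) -> float:
    """Post/pre ratio of one metric for a single syncytium.

    Responses to beta-adrenergic stimulation are expressed per syncytium
    (the group statistic is the mean of per-syncytium ratios, never the
    ratio of group means).  Raises ``ValueError`` when the pre value is
    zero or the summaries belong to different recordings/modalities.
    """
    if pre.recording_id != post.recording_id:
        raise ValueError("pre/post summaries are from different recordings")
    if pre.modality != post.modality:
        raise ValueError("pre/post summaries are from different modalities")
    pre_val = pre.metric(metric)
    post_val = post.metric(metric)
    if pre_val == 0 or math.isnan(pre_val):
        raise ValueError(f"pre-treatment {metric} is zero/undefined; ratio excluded")
    return post_val / pre_val


_MEAN_FIELDS = (
    "baseline",
    "amplitude",
    "upstroke_slope",
    "upstroke_slope_norm",
    "d30",
    "d80",
    "d90",
    "triangulation",
)


def summarize_beats(
    beats: list[BeatMetrics],
    activation_times: np.ndarray,
    window: float,
    recording_id: str,
    modality: str,
) -> SyncytiumSummary:
    """Aggregate per-beat metrics into a per-recording summary row."""
    freq = spontaneous_frequency(activation_times, window)
    means: dict[str, float] = {}
    sems: dict[str, float] = {}
    for name in _MEAN_FIELDS:
        if name in ("d30", "d80", "d90", "triangulation"):
            vals = np.array(
                [getattr(b, name) if name != "triangulation" else b.triangulation
                 for b in beats if not b.censored],
                dtype=float,
            )
            vals = vals[np.isfinite(vals)]
        else:
            vals = np.array([getattr(b, name) for b in beats], dtype=float)
        if vals.size:
            means[name] = float(vals.mean())
            sems[name] = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size >= 2 else math.nan
        else:
            means[name] = math.nan
            sems[name] = math.nan
    corrected = np.array(
        [
            fridericia_correct(b.d80, b.rr_prev)
            for b in beats
            if not b.censored and math.isfinite(b.d80) and b.rr_prev > 0
        ],
        dtype=float,
    )
    return SyncytiumSummary(
        recording_id=recording_id,
        modality=modality,
        n_beats=freq.n_beats,
        frequency=freq.hz,
        quiescent=freq.quiescent,
        analysis_window=window,
        means=means,
        sems=sems,
        d80_fridericia=float(corrected.mean()) if corrected.size else math.nan,
    )


def analyze_trace(
    trace: Trace,
    recording_id: str = "",
    smooth_window_s: float | None = None,
    detrend: bool = False,
    deriv_threshold: float = DEFAULT_DERIV_THRESHOLD,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> tuple[list[BeatMetrics], SyncytiumSummary, Trace]:
    """Preprocess, detect and measure a whole trace.

    By default no value smoothing is applied before measurement: every
    per-beat estimator is fit-based (median baseline, quadratic peak,
    regression-refined crossings) and beat detection and EAD screening
    smooth internally, so pre-smoothing would only distort sharp peaks.
    Returns the per-beat metrics, the recording summary, and the
    (possibly preprocessed) trace.
    """
    pp = preprocess_trace(trace, smooth_window_s=smooth_window_s, detrend=detrend)
    times = detect_beats(pp, deriv_threshold=deriv_threshold, refractory_s=refractory_s)
    beats = measure_all_beats(pp, times)
    summary = summarize_beats(
        beats, times, window=trace.duration, recording_id=recording_id or trace.origin,
        modality=trace.modality,
    )
    return beats, summary, pp
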