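"""Per-pixel activation maps and conduction-velocity estimation.

For one propagated beat, each pixel's activation time is the sub-frame-
interpolated time of its maximum temporal derivative within the beat
window.  Conduction velocity is then estimated by fitting a local plane
to the activation-time surface over a sliding k x k neighborhood (the
classic local-gradient approach): the wavefront speed at a pixel is the
inverse norm of the fitted time gradient, converted to cm/s by the pixel
pitch.  The headline per-recording value is the *median* of local
speeds, which is robust to wavefront-collision outliers; the mean is
reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .io import FluorescenceMovie, extract_trace

__all__ = [
    "ActivationMap",
    "ConductionEstimate",
    "compute_activation_map",
    "estimate_cv",
    "beat_window",
    "save_activation_png",
]


@dataclass
class ActivationMap:
    """Per-pixel activation times (s) for one beat.

    ``act_time`` is NaN wherever the pixel failed quality control
    (amplitude below the floor); ``quality`` is False there.
    """

    act_time: np.ndarray  # H x W, seconds (NaN where rejected)
    quality: np.ndarray  # H x W boolean
    pixel_pitch: float  # cm / pixel
    frame_rate: float  # Hz
    beat_index: int = 0

    def __post_init__(self) -> None:
        if self.act_time.shape != self.quality.shape:
            raise ValueError("act_time and quality mask shapes differ")
        defined = np.isfinite(self.act_time)
        if np.any(self.quality & ~defined):
            raise ValueError("quality mask true on undefined activation times")


@dataclass
class ConductionEstimate:
    """Summary of local wavefront speeds for one activation map."""

    median_cv: float  # cm/s (NaN if undefined)
    mean_cv: float  # cm/s
    speed_field: np.ndarray  # H x W local speeds, NaN where not estimated
    quality_fraction: float  # fraction of pixels passing amplitude QC
    n_local: int  # number of accepted local plane fits
    global_activation: bool = False  # simultaneous activation, no finite CV


def beat_window(
    beat_times: np.ndarray, beat_index: int, duration: float
) -> tuple[float, float]:
    """Window around one beat bounded by the midpoints to its neighbors.

    Chosen so that for most pixels the window contains exactly one
    activation even with propagation delays of a sizeable fraction of
    the beat period.
    """
    beats = np.asarray(beat_times, dtype=float)
    t = beats[beat_index]
    t0 = (beats[beat_index - 1] + t) / 2 if beat_index > 0 else max(0.0, t - 0.3)
    t1 = (t + beats[beat_index + 1]) / 2 if beat_index + 1 < beats.size else min(duration, t + 0.5)
    return t0, t1


def compute_activation_map(
    movie: FluorescenceMovie,
    window: tuple[float, float],
    beat_index: int = 0,
    spatial_sigma: float = 1.0,
    temporal_sigma: float = 2.0,
    amplitude_floor: float = 0.20,
) -> ActivationMap:
    """Map per-pixel activation times within one beat window.

    Frames are spatially smoothed (Gaussian, ``spatial_sigma`` pixels)
    before per-pixel timing — activation-time fields are locally smooth,
    so this suppresses shot-like noise without biasing the local
    gradient.  Pixels whose within-window amplitude falls below
    ``amplitude_floor`` times the global-trace amplitude are masked out.
    """
    t0, t1 = window
    fs = movie.frame_rate
    k0 = max(0, int(math.floor(t0 * fs)))
    k1 = min(movie.n_frames, int(math.ceil(t1 * fs)) + 1)
    if k1 - k0 < 3:
        raise ValueError("beat window too short for activation mapping")
    sub = movie.frames[k0:k1]
    if spatial_sigma > 0 or temporal_sigma > 0:
        # Spatial smoothing suppresses shot noise without biasing the
        # local gradient (the activation field is locally planar);
        # temporal smoothing widens upstrokes that span only a frame or
        # two so their timing is not frame-quantized.  Both kernels are
        # symmetric and introduce no timing shift.
        sub = gaussian_filter(
            sub, sigma=(temporal_sigma, spatial_sigma, spatial_sigma), mode="nearest"
        )

    global_trace = extract_trace(movie, "global").values[k0:k1]
    global_amp = float(global_trace.max() - global_trace.min())
    amp = sub.max(axis=0) - sub.min(axis=0)
    quality = amp >= amplitude_floor * global_amp
    if global_amp <= 0 or not quality.any():
        raise ValueError("no detectable activation anywhere in the window")

    # Temporal upsampling (cubic spline) before derivative timing: at
    # fast conduction the activation range across a plane-fit
    # neighborhood is a fraction of a frame, and frame-quantized peak
    # times would distort the local gradients systematically.
    up = 8
    t_sub = np.arange(k0, k1) / fs
    t_fine = np.linspace(t_sub[0], t_sub[-1], (k1 - k0 - 1) * up + 1)
    deriv = CubicSpline(t_sub, sub, axis=0)(t_fine, 1)
    i_pk = np.argmax(deriv, axis=0)
    # parabolic sub-sample refinement on the fine grid
    h, w = i_pk.shape
    rows, cols = np.mgrid[0:h, 0:w]
    i_c = np.clip(i_pk, 1, deriv.shape[0] - 2)
    y0 = deriv[i_c - 1, rows, cols]
    y1 = deriv[i_c, rows, cols]
    y2 = deriv[i_c + 1, rows, cols]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        off = np.where(denom != 0, 0.5 * (y0 - y2) / denom, 0.0)
    off = np.clip(off, -0.5, 0.5)
    dt_fine = t_fine[1] - t_fine[0]
    act = t_fine[0] + (i_pk + np.where(i_pk == i_c, off, 0.0)) * dt_fine
    act = np.where(quality, act, np.nan)
    return ActivationMap(
        act_time=act,
        quality=quality,
        pixel_pitch=movie.pixel_pitch,
        frame_rate=fs,
        beat_index=beat_index,
    )


def estimate_cv(
    amap: ActivationMap,
    neighborhood: int = 5,
    min_quality_pixels: int = 100,
    r2_min: float = 0.9,
    gradient_floor_frac: float = 0.01,
) -> ConductionEstimate:
    """Local plane-fit conduction-velocity estimate.

    Over every sliding ``neighborhood x neighborhood`` window with at
    least 80% quality pixels, activation time is regressed on the pixel
    coordinates (in cm); the local speed is ``1 / ||gradient||``.
    Neighborhoods with near-zero gradient (below ``gradient_floor_frac``
    of the median gradient norm) or poor planarity (R^2 < ``r2_min``)
    are excluded.  If the whole field activates within one frame the
    estimate is flagged ``global_activation`` and no CV is reported.
    """
    act = amap.act_time
    mask = amap.quality
    h, w = act.shape
    n_quality = int(mask.sum())
    if n_quality < min_quality_pixels:
        raise ValueError(
            f"too few quality pixels for CV estimation ({n_quality} < {min_quality_pixels})"
        )
    spread = np.nanmax(act) - np.nanmin(act)
    if spread < 1.0 / amap.frame_rate:
        return ConductionEstimate(
            median_cv=math.nan,
            mean_cv=math.nan,
            speed_field=np.full((h, w), np.nan),
            quality_fraction=n_quality / act.size,
            n_local=0,
            global_activation=True,
        )

    k = neighborhood
    half = k // 2
    pitch = amap.pixel_pitch
    min_pts = int(math.ceil(0.8 * k * k))
    # local coordinates in cm, common to every window
    dy, dx = np.mgrid[-half : half + 1, -half : half + 1]
    dx_cm = (dx * pitch).ravel()
    dy_cm = (dy * pitch).ravel()

    grads = np.full((h, w), np.nan)
    r2s = np.full((h, w), np.nan)
    for r in range(half, h - half):
        for c in range(half, w - half):
            win_mask = mask[r - half : r + half + 1, c - half : c + half + 1].ravel()
            if win_mask.sum() < min_pts:
                continue
            t = act[r - half : r + half + 1, c - half : c + half + 1].ravel()[win_mask]
            X = np.column_stack(
                [np.ones(win_mask.sum()), dx_cm[win_mask], dy_cm[win_mask]]
            )
            coef, _, _, _ = np.linalg.lstsq(X, t, rcond=None)
            resid = t - X @ coef
            sst = float(np.sum((t - t.mean()) ** 2))
            sse = float(np.sum(resid**2))
            r2 = 1.0 - sse / sst if sst > 0 else 0.0
            grads[r, c] = math.hypot(coef[1], coef[2])
            r2s[r, c] = r2

    valid = np.isfinite(grads)
    if not valid.any():
        raise ValueError("no local plane fits possible")
    med_grad = float(np.nanmedian(grads[valid]))
    accept = valid & (r2s >= r2_min) & (grads > gradient_floor_frac * med_grad)
    speed_field = np.full((h, w), np.nan)
    with np.errstate(divide="ignore"):
        speed_field[accept] = 1.0 / grads[accept]
    speeds = speed_field[accept]
    if speeds.size == 0:
        return ConductionEstimate(
            median_cv=math.nan,
            mean_cv=math.nan,
            speed_field=speed_field,
            quality_fraction=n_quality / act.size,
            n_local=0,
            global_activation=False,
        )
    return ConductionEstimate(
        median_cv=float(np.median(speeds)),
        mean_cv=float(np.mean(speeds)),
        speed_field=speed_field,
        quality_fraction=n_quality / act.size,
        n_local=int(speeds.size),
        global_activation=False,
    )


def save_activation_png(amap: ActivationMap, path: str | Path) -> Path:
    """Render the activation map to a PNG (isochronal colormap)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(4, 4))
    t_ms = (amap.act_time - np.nanmin(amap.act_time)) * 1e3
    im = ax.imshow(t_ms, cmap="viridis")
    fig.colorbar(im, ax=ax, label="activation time (ms)")
    ax.set_title(f"beat {amap.beat_index}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
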