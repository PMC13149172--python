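"""Reading, writing and basic slicing of fluorescence movies and traces.

A recording is a T x H x W stack of fluorescence intensities (arbitrary
units) acquired at a known frame rate from a monolayer of known physical
extent.  Two containers are supported: HDF5 (lossless, metadata in
attributes) and multi-frame TIFF (metadata in a JSON sidecar, since TIFF
tag dialects are fragile).  Intensities are never rescaled at read time —
absolute a.u. levels such as diastolic baselines are meaningful downstream
and any normalization is an explicit, logged analysis step.

Conventions: frame index is 0-based and frame ``k`` occurs at time
``k / frame_rate`` seconds; pixels are addressed ``(row, col)``, 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
import h5py
import numpy as np
import pandas as pd
import tifffile

VALID_MODALITIES = ("voltage", "calcium")

__all__ = [
    "FluorescenceMovie",
    "Trace",
    "read_movie",
    "write_movie",
    "extract_trace",
    "read_trace_csv",
    "write_trace_csv",
]


@dataclass
class FluorescenceMovie:
    """A T x H x W fluorescence stack with acquisition metadata.

    Parameters
    ----------
    frames
        3-D float array, time first.  Stored as-is (a.u.), never normalized.
    frame_rate
        Acquisition rate in frames per second.
    pixel_pitch
        Physical size of one pixel in cm.  Not recoverable from the data,
        so it is always supplied by the caller.
    modality
        ``"voltage"`` or ``"calcium"``.
    recording_id
        Free-text identifier carried into every derived artifact.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch: float
    modality: str = "voltage"
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"expected a 3-D T x H x W stack, got {self.frames.ndim}-D "
                "(a 2-D array is a single image, not a movie stack)"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("not a movie stack: fewer than 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("movie contains non-finite intensities")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.modality not in VALID_MODALITIES:
            raise ValueError(f"modality must be one of {VALID_MODALITIES}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Recording length in seconds (T / frame_rate)."""
        return self.frames.shape[0] / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in seconds; frame 0 is at t=0."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class Trace:
    """A single fluorescence time series (ROI mean or one pixel)."""

    values: np.ndarray
    frame_rate: float
    modality: str = "voltage"
    source: str = "roi_mean"  # "roi_mean" | "pixel"
    origin: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.frame_rate

    def copy_with(self, values: np.ndarray) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=np.float64))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: FluorescenceMovie, path: str | Path, format: str | None = None) -> Path:
    """Write a movie to HDF5 or multi-frame TIFF.

    HDF5 stores frames as float32 in dataset ``"frames"`` with the
    acquisition metadata as attributes.  TIFF stores one page per frame
    (float32) plus a JSON sidecar ``<path>.json`` with the metadata.
    Roundtrip through :func:`read_movie` is value-identical at float32.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "tiff"
    frames32 = movie.frames.astype(np.float32)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("frames", data=frames32)
            dset.attrs["frame_rate"] = movie.frame_rate
            dset.attrs["pixel_pitch"] = movie.pixel_pitch
            dset.attrs["modality"] = movie.modality
            dset.attrs["recording_id"] = movie.recording_id
    elif format == "tiff":
        tifffile.imwrite(path, frames32, photometric="minisblack")
        meta = {
            "frame_rate": movie.frame_rate,
            "pixel_pitch": movie.pixel_pitch,
            "modality": movie.modality,
            "recording_id": movie.recording_id,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unknown format {format!r} (use 'tiff' or 'hdf5')")
    return path


def read_movie(
    path: str | Path,
    format: str | None = None,
    frame_rate: float | None = None,
    pixel_pitch: float | None = None,
    modality: str | None = None,
    recording_id: str | None = None,
) -> FluorescenceMovie:
    """Read a movie stack from HDF5 or multi-frame TIFF.

    Metadata stored in the file (HDF5 attributes or TIFF JSON sidecar) is
    used unless overridden by the keyword arguments; for externally
    produced files without metadata, ``frame_rate`` and ``pixel_pitch``
    are required.  Frames are cast to floating point without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "tiff"

    meta: dict = {}
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise ValueError(f"{path}: no 'frames' dataset")
            dset = f["frames"]
            frames = np.asarray(dset[...], dtype=np.float64)
            for key in ("frame_rate", "pixel_pitch", "modality", "recording_id"):
                if key in dset.attrs:
                    v = dset.attrs[key]
                    meta[key] = v.item() if hasattr(v, "item") and not isinstance(v, str) else v
    elif format == "tiff":
        frames = np.asarray(tifffile.imread(path), dtype=np.float64)
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
    else:
        raise ValueError(f"unknown format {format!r} (use 'tiff' or 'hdf5')")

    if frames.ndim == 2:
        raise ValueError(f"{path}: not a movie stack (single 2-D image)")
    if frames.ndim != 3:
        raise ValueError(f"{path}: not a movie stack (got {frames.ndim}-D data)")

    kwargs = {
        "frame_rate": frame_rate if frame_rate is not None else meta.get("frame_rate"),
        "pixel_pitch": pixel_pitch if pixel_pitch is not None else meta.get("pixel_pitch"),
        "modality": modality if modality is not None else meta.get("modality", "voltage"),
        "recording_id": recording_id if recording_id is not None else str(meta.get("recording_id", path.stem)),
    }
    if kwargs["frame_rate"] is None or kwargs["pixel_pitch"] is None:
        raise ValueError(
            f"{path}: frame_rate and pixel_pitch not stored in file; pass them explicitly"
        )
    return FluorescenceMovie(frames=frames, **kwargs)


def _roi_mask(movie: FluorescenceMovie, roi) -> np.ndarray:
    """Resolve an ROI spec to a boolean H x W mask.

    Accepted forms: the string ``"global"`` (whole field), a boolean mask,
    a ``(r0, r1, c0, c1)`` rectangle (half-open), or an iterable of
    ``(row, col)`` pixels.
    """
    _, H, W = movie.frames.shape
    if isinstance(roi, str):
        if roi != "global":
            raise ValueError(f"unknown ROI spec {roi!r}")
        return np.ones((H, W), dtype=bool)
    roi_arr = np.asarray(roi)
    if roi_arr.dtype == bool:
        if roi_arr.shape != (H, W):
            raise ValueError("boolean ROI mask must match movie H x W")
        mask = roi_arr
    elif roi_arr.ndim == 1 and roi_arr.size == 4:
        r0, r1, c0, c1 = (int(v) for v in roi_arr)
        if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
            raise ValueError(f"rectangle ROI {roi!r} out of bounds for {H}x{W}")
        mask = np.zeros((H, W), dtype=bool)
        mask[r0:r1, c0:c1] = True
    elif roi_arr.ndim == 2 and roi_arr.shape[1] == 2:
        rows, cols = roi_arr[:, 0].astype(int), roi_arr[:, 1].astype(int)
        if rows.min() < 0 or rows.max() >= H or cols.min() < 0 or cols.max() >= W:
            raise ValueError("pixel-set ROI out of bounds")
        mask = np.zeros((H, W), dtype=bool)
        mask[rows, cols] = True
    else:
        raise ValueError(f"cannot interpret ROI spec of shape {roi_arr.shape}")
    if not mask.any():
        raise ValueError("empty ROI")
    return mask


def extract_trace(movie: FluorescenceMovie, roi="global") -> Trace:
    """Average the movie over an ROI to a single time series.

    ``values[t]`` is the mean of ``frames[t]`` over the ROI pixels, so the
    operation is linear in the movie.  A single-pixel ROI returns that
    pixel's series exactly.
    """
    mask = _roi_mask(movie, roi)
    values = movie.frames[:, mask].mean(axis=1)
    n_px = int(mask.sum())
    source = "pixel" if n_px == 1 else "roi_mean"
    if n_px == 1:
        r, c = (int(v[0]) for v in np.nonzero(mask))
        origin = f"{movie.recording_id}:px({r},{c})"
    else:
        origin = f"{movie.recording_id}:roi[{n_px}px]"
    return Trace(
        values=values,
        frame_rate=movie.frame_rate,
        modality=movie.modality,
        source=source,
        origin=origin,
    )


def write_trace_csv(trace: Trace, path: str | Path) -> Path:
    """Write a trace as a two-column CSV (time_s, value)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_trace_csv(
    path: str | Path, modality: str = "voltage", origin: str | None = None
) -> Trace:
    """Read a (time_s, value) CSV written by :func:`write_trace_csv`.

    The frame rate is inferred from the median time step; sampling must
    be uniform to within 1%.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,value")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > 0.01 * step:
        raise ValueError(f"{path}: non-uniform sampling")
    return Trace(
        values=df["value"].to_numpy(dtype=float),
        frame_rate=1.0 / step,
        modality=modality,
        source="roi_mean",
        origin=origin or path.stem,
    )
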