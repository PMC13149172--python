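"""End-to-end simulate → analyze → compare workflow.

Every run writes a manifest (inputs, parameters, seed, package version)
next to its outputs, and all tabular outputs are written with a fixed
float format so reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import FluorescenceMovie, extract_trace, read_movie, write_movie
from .mapping import beat_window, compute_activation_map, estimate_cv
from .rhythm import RhythmThresholds, classify_rhythm
from .stats import compare_groups, incidence_test
from .synth import (
    CohortGroup,
    PropagationModel,
    RhythmScript,
    SimulationConfig,
    WaveformTemplate,
    generate_cohort,
    solve_template,
)
from .transients import analyze_trace

logger = logging.getLogger("cardiomap")

__all__ = [
    "config_from_dict",
    "cohort_from_yaml",
    "run_simulate",
    "run_analyze",
    "run_compare",
]

_FLOAT_FMT = "%.9g"


def _waveform_from_dict(d: dict) -> WaveformTemplate:
    d = dict(d)
    if "tau_r" in d and "p" in d:
        return WaveformTemplate(**d)
    # duration-specified template: solve (tau_r, p) from two D_x targets
    t_up = d.pop("t_up", 0.02)
    amplitude = d.pop("amplitude", 1.0)
    baseline = d.pop("baseline", 0.0)
    frac_keys = sorted(
        (float(k[1:]) / 100.0, float(v)) for k, v in d.items() if k.startswith("d")
    )
    if len(frac_keys) != 2:
        raise ValueError(
            "waveform must give tau_r+p or exactly two duration targets (e.g. d30, d90)"
        )
    (a, d_a), (b, d_b) = frac_keys
    return solve_template(t_up, d_a, d_b, a=a, b=b, amplitude=amplitude, baseline=baseline)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (YAML/JSON-friendly).

    The ``waveform`` block accepts either ``{t_up, tau_r, p, ...}`` or a
    duration specification ``{t_up, d30: .., d90: .., ...}`` which is
    inverted with :func:`cardiomap.synth.solve_template`.
    """
    d = dict(d)
    kwargs: dict = {}
    if "shape" in d:
        kwargs["shape"] = tuple(int(v) for v in d.pop("shape"))
    if "waveform" in d:
        kwargs["waveform"] = _waveform_from_dict(d.pop("waveform"))
    if "rhythm" in d:
        r = dict(d.pop("rhythm"))
        for key in ("quiescent_episodes", "ead_beats", "tachy_segments"):
            if key in r:
                r[key] = tuple(tuple(item) for item in r[key])
        kwargs["rhythm"] = RhythmScript(**r)
    if "propagation" in d:
        p = dict(d.pop("propagation"))
        if "origin" in p and p["origin"] is not None:
            p["origin"] = tuple(int(v) for v in p["origin"])
        if p.get("speed") in ("inf", "Infinity"):
            p["speed"] = math.inf
        kwargs["propagation"] = PropagationModel(**p)
    kwargs.update(d)
    return SimulationConfig(**kwargs)


def cohort_from_yaml(path: str | Path) -> list[CohortGroup]:
    """Parse a cohort specification YAML into CohortGroups.

    Schema::

        groups:
          - name: WT
            n: 3                 # or 'configs': a list of config blocks
            config: {shape: [16, 16], rhythm: {base_frequency: 0.67}, ...}
    """
    spec = yaml.safe_load(Path(path).read_text())
    if not spec or "groups" not in spec or not spec["groups"]:
        raise ValueError("cohort spec must contain a non-empty 'groups' list")
    groups = []
    for g in spec["groups"]:
        if "configs" in g:
            configs = [config_from_dict(c) for c in g["configs"]]
            groups.append(CohortGroup(name=g["name"], configs=configs))
        else:
            cfg = config_from_dict(g.get("config", {}))
            groups.append(CohortGroup.replicate(g["name"], int(g["n"]), cfg))
    return groups


def _write_manifest(out_dir: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["cardiomap_version"] = __version__
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=1, default=str))


def run_simulate(
    groups: Sequence[CohortGroup], seed: int, out_dir: str | Path
) -> pd.DataFrame:
    """Simulate a cohort and write recordings + ground truth to disk.

    Writes one HDF5 movie per recording, ``ground_truth.csv`` (one row
    per beat across the cohort), ``labels.json`` (scripted rhythm
    features per recording), ``groups.csv`` (recording → group), and a
    manifest.  Returns the ground-truth beat table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings = generate_cohort(groups, seed=seed)
    truth_rows = []
    labels = {}
    group_rows = []
    for rec in recordings:
        write_movie(rec.movie, out_dir / f"{rec.recording_id}.h5", format="hdf5")
        beats = rec.truth.beats.copy()
        beats.insert(0, "recording_id", rec.recording_id)
        beats.insert(0, "group", rec.group)
        truth_rows.append(beats)
        labels[rec.recording_id] = {**rec.truth.labels, "true_cv": rec.truth.cv}
        group_rows.append({"recording_id": rec.recording_id, "group": rec.group})
    truth = pd.concat(truth_rows, ignore_index=True) if truth_rows else pd.DataFrame()
    truth.to_csv(out_dir / "ground_truth.csv", index=False, float_format=_FLOAT_FMT)
    (out_dir / "labels.json").write_text(json.dumps(labels, indent=1, default=str))
    pd.DataFrame(group_rows).to_csv(out_dir / "groups.csv", index=False)
    _write_manifest(
        out_dir,
        {
            "command": "simulate",
            "seed": seed,
            "groups": [{"name": g.name, "n": len(g.configs)} for g in groups],
        },
    )
    return truth


_SUMMARY_METRICS = (
    "frequency",
    "d80_fridericia",
    "d30",
    "d80",
    "d90",
    "triangulation",
    "baseline",
    "amplitude",
    "upstroke_slope",
    "upstroke_slope_norm",
)

_MIN_PIXELS_FOR_CV = 256  # below this the field is too small for plane fitting


def _analyze_one(
    movie: FluorescenceMovie,
    thresholds: RhythmThresholds,
    detrend: bool,
    with_cv: bool,
) -> tuple[dict, list, object]:
    trace = extract_trace(movie, "global")
    beats, summary, pp = analyze_trace(trace, recording_id=movie.recording_id, detrend=detrend)
    times = np.array([b.activation_time for b in beats])
    assessment = classify_rhythm(
        times, beats, window=trace.duration, thresholds=thresholds, trace=pp
    )
    row = {
        "recording_id": movie.recording_id,
        "modality": movie.modality,
        "n_beats": summary.n_beats,
        "quiescent": summary.quiescent,
        "labels": "|".join(assessment.labels),
        "arrhythmic": assessment.arrhythmic,
    }
    for m in _SUMMARY_METRICS:
        row[m] = summary.metric(m)
    row["cv_median_cm_s"] = math.nan
    h, w = movie.frames.shape[1:]
    if with_cv and h * w >= _MIN_PIXELS_FOR_CV and times.size:
        try:
            bi = 1 if times.size >= 3 else 0
            amap = compute_activation_map(
                movie, beat_window(times, bi, movie.duration), beat_index=bi
            )
            est = estimate_cv(amap, min_quality_pixels=min(100, h * w // 2))
            row["cv_median_cm_s"] = est.median_cv
        except ValueError as exc:
            logger.warning("CV estimation skipped for %s: %s", movie.recording_id, exc)
    return row, beats, assessment


def run_analyze(
    in_dir: str | Path,
    out_dir: str | Path,
    modality: str | None = None,
    pixel_pitch: float | None = None,
    frame_rate: float | None = None,
    thresholds: RhythmThresholds | None = None,
    detrend: bool = False,
    alpha: float = 0.05,
    with_cv: bool = True,
) -> pd.DataFrame:
    """Analyze every recording in a directory.

    Reads ``*.h5``/``*.hdf5``/``*.tif``/``*.tiff`` movies, runs beat
    analysis, rhythm classification and (for fields of at least 16x16
    pixels) conduction-velocity mapping; writes per-recording beat CSVs
    and assessment JSONs, a cohort ``summary.csv``, and — when a
    ``groups.csv`` is present with at least two groups — a group
    comparison report with the premise-checked statistics and the
    chi-square arrhythmia-incidence test.  Unreadable recordings are
    skipped with a logged error; if *all* recordings fail, raises.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = thresholds or RhythmThresholds()
    paths = sorted(
        p for p in in_dir.iterdir() if p.suffix.lower() in (".h5", ".hdf5", ".tif", ".tiff")
    )
    if not paths:
        raise FileNotFoundError(f"no recordings found in {in_dir}")

    rows = []
    skipped = []
    for path in paths:
        try:
            movie = read_movie(
                path, frame_rate=frame_rate, pixel_pitch=pixel_pitch, modality=modality
            )
            row, beats, assessment = _analyze_one(movie, thresholds, detrend, with_cv)
        except Exception as exc:  # noqa: BLE001 — robust batch processing
            logger.error("skipping %s: %s", path.name, exc)
            skipped.append({"file": path.name, "error": str(exc)})
            continue
        rows.append(row)
        beat_df = pd.DataFrame([b.as_dict() for b in beats])
        beat_df.to_csv(out_dir / f"beats_{row['recording_id']}.csv", index=False, float_format=_FLOAT_FMT)
        (out_dir / f"rhythm_{row['recording_id']}.json").write_text(
            json.dumps(
                {
                    "recording_id": row["recording_id"],
                    "labels": list(assessment.labels),
                    "arrhythmic": assessment.arrhythmic,
                    "evidence": assessment.evidence,
                    "thresholds": asdict(assessment.thresholds),
                },
                indent=1,
                default=str,
            )
        )
    if not rows:
        raise RuntimeError(f"all {len(paths)} recordings failed to analyze")

    summary = pd.DataFrame(rows)
    groups_csv = in_dir / "groups.csv"
    if groups_csv.exists():
        groups = pd.read_csv(groups_csv)
        summary = summary.merge(groups, on="recording_id", how="left")
    summary.to_csv(out_dir / "summary.csv", index=False, float_format=_FLOAT_FMT)

    report: dict = {"alpha": alpha, "skipped": skipped}
    if "group" in summary.columns and summary["group"].nunique() >= 2:
        comparisons = {}
        for m in _SUMMARY_METRICS:
            table = summary[["group", m]].rename(columns={m: "value"}).dropna()
            counts = table.groupby("group").size()
            if len(counts) >= 2 and (counts >= 2).all():
                try:
                    comparisons[m] = compare_groups(table, metric=m, alpha=alpha).as_dict()
                except ValueError as exc:
                    comparisons[m] = {"error": str(exc)}
        report["comparisons"] = comparisons
        inc = summary.groupby("group")["arrhythmic"].agg(["sum", "count"])
        contingency = np.array([inc["sum"].to_numpy(), (inc["count"] - inc["sum"]).to_numpy()])
        report["incidence"] = {
            "groups": list(inc.index),
            "arrhythmic": [int(v) for v in inc["sum"]],
            "n": [int(v) for v in inc["count"]],
        }
        try:
            chi2, df, p = incidence_test(contingency)
            report["incidence"].update({"chi2": chi2, "df": df, "p": p})
        except ValueError as exc:
            report["incidence"]["error"] = str(exc)
    (out_dir / "comparison_report.json").write_text(json.dumps(report, indent=1, default=str))
    _write_manifest(
        out_dir,
        {
            "command": "analyze",
            "in_dir": str(in_dir),
            "n_recordings": len(rows),
            "n_skipped": len(skipped),
            "thresholds": asdict(thresholds),
            "alpha": alpha,
        },
    )
    return summary


def run_compare(table_csv: str | Path, out_path: str | Path, alpha: float = 0.05) -> dict:
    """Group comparison on a tidy CSV (recording_id, group, metric, value)."""
    df = pd.read_csv(table_csv)
    required = {"group", "metric", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"{table_csv}: expected columns {sorted(required)}")
    report = {}
    for metric, sub in df.groupby("metric"):
        report[str(metric)] = compare_groups(sub, metric=str(metric), alpha=alpha).as_dict()
    out_path = Path(out_path)
    out_path.write_text(json.dumps(report, indent=1, default=str))
    return report
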