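"""Readers and writers for the pipeline's file formats.

GRF CSV dialect: comma-separated, UTF-8, '.' decimal, header ``time_s,force``
(the time column is optional; without it the sampling rate must be supplied).
A cohort on disk is a manifest CSV plus two GRF CSVs and one ground-truth JSON
sidecar per subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .core import SIDES, ClinicalStatus, GRFSeries, SubjectRecord

_FLOAT_FMT = "%.12g"  # 12 significant digits: round-trip safe for this data


@dataclass
class SensorGridFrameSet:
    """Raw insole pressure frames: one per-sensor grid per time sample."""

    frames: np.ndarray  # (n_frames, rows, cols)
    sampling_rate_hz: float
    side: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n, rows, cols) array")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.side not in SIDES:
            raise ValueError("side must be 'left' or 'right'")


def sum_sensors(grid: SensorGridFrameSet) -> GRFSeries:
    """Total vertical force per frame: the sum over all insole sensors."""
    nan_frames = np.where(np.isnan(grid.frames).any(axis=(1, 2)))[0]
    if nan_frames.size:
        raise ValueError(f"NaN in sensor frame {int(nan_frames[0])}")
    totals = grid.frames.sum(axis=(1, 2))
    if totals.size < 2:
        raise ValueError("need at least 2 frames")
    return GRFSeries(samples=totals, sampling_rate_hz=grid.sampling_rate_hz, side=grid.side)


def write_grf_csv(series: GRFSeries, path) -> None:
    df = pd.DataFrame({"time_s": series.times_s, "force": series.samples})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_grf_csv(
    path,
    side: str = "left",
    sampling_rate_hz: Optional[float] = None,
    units: str = "bw",
    subject_id: Optional[str] = None,
) -> GRFSeries:
    df = pd.read_csv(path)
    if "force" not in df.columns:
        raise ValueError(f"{path}: missing required column(s): force")
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(float)
        dt = np.diff(t)
        if dt.size == 0 or np.any(dt <= 0):
            raise ValueError(f"{path}: time column not strictly increasing")
        if np.max(np.abs(dt - np.median(dt))) > 0.01 * np.median(dt):
            raise ValueError(f"{path}: irregular time steps beyond 1% tolerance")
        rate = 1.0 / float(np.median(dt))
    elif sampling_rate_hz is not None:
        rate = float(sampling_rate_hz)
    else:
        raise ValueError(f"{path}: no time_s column and no sampling_rate_hz given")
    return GRFSeries(
        samples=df["force"].to_numpy(float),
        sampling_rate_hz=rate,
        side=side,
        units=units,
        subject_id=subject_id,
    )


_SUBJECT_REQUIRED = ["subject_id", "group", "age_years", "sex", "weight_kg", "height_m"]
_CLINICAL_COLS = ["updrs_iii", "mmse", "ledd_mg", "disease_duration_years", "affected_side"]


def read_subject_table(path) -> List[SubjectRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _SUBJECT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        clinical = None
        if all(c in df.columns for c in _CLINICAL_COLS) and not pd.isna(row.get("updrs_iii")):
            clinical = ClinicalStatus(
                updrs_iii=float(row["updrs_iii"]),
                mmse=float(row["mmse"]),
                ledd_mg=float(row["ledd_mg"]),
                disease_duration_years=float(row["disease_duration_years"]),
                affected_side=str(row["affected_side"]),
            )
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group_label=str(row["group"]),
                age_years=float(row["age_years"]),
                sex=str(row["sex"]),
                weight_kg=float(row["weight_kg"]),
                height_m=float(row["height_m"]),
                clinical=clinical,
            )
        )
    return records


def write_feature_table(rows: Iterable[dict], path) -> pd.DataFrame:
    df = pd.DataFrame(list(rows))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return df


def save_cohort(cohort, out_dir) -> Path:
    """Write a generated cohort: manifest CSV, per-foot GRF CSVs, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(cohort.manifest_rows()).to_csv(
        out / "manifest.csv", index=False, float_format=_FLOAT_FMT
    )
    for sid, (left, right) in cohort.series.items():
        write_grf_csv(left, out / f"{sid}_left.csv")
        write_grf_csv(right, out / f"{sid}_right.csv")
        with open(out / f"{sid}_truth.json", "w") as fh:
            json.dump(cohort.truths[sid].to_jsonable(), fh)
    return out


def load_cohort_series(cohort_dir):
    """Manifest dataframe plus per-subject (left, right) GRFSeries pairs."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    series = {}
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        series[sid] = (
            read_grf_csv(cohort_dir / f"{sid}_left.csv", side="left", subject_id=sid),
            read_grf_csv(cohort_dir / f"{sid}_right.csv", side="right", subject_id=sid),
        )
    return manifest, series
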