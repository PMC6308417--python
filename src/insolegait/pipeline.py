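"""Pipeline orchestration: simulate -> extract -> analyze -> classify.

Every stage is reproducible from (config, seed); the run manifest records the
configuration, seed and library versions alongside the outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import DATASET_IDS, build_datasets, loo_cross_validate
from .core import GRFSeries, SubjectRecord, combine_feet
from .events import detect_contacts, moving_average, remove_outlier_strides
from .io import save_cohort, write_feature_table
from .kinematics import kinematic_features
from .kinetics import kinetic_features
from .stats import compare_groups, run_table4_analyses
from .synthetic import Cohort, generate_cohort

__all__ = ["PipelineConfig", "extract_subject", "extract_cohort_features", "run_pipeline"]


@dataclass
class PipelineConfig:
    sampling_rate_hz: float = 100.0
    smoothing_window: int = 5
    contact_threshold_frac: float = 0.05
    outlier_window: int = 9
    outlier_mad_factor: float = 3.0
    relieff_k: int = 10
    phase_deviation: str = "percent"  # or "degrees"
    seed: int = 0
    n_yc: int = 16
    n_amc: int = 12
    n_pd: int = 11
    duration_s: float = 300.0
    out_dir: str = "insolegait_out"
    input_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if min(self.sampling_rate_hz, self.contact_threshold_frac,
               self.outlier_mad_factor) <= 0:
            raise ValueError("thresholds must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.phase_deviation not in ("percent", "degrees"):
            raise ValueError("phase_deviation must be 'percent' or 'degrees'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def extract_subject(
    left: GRFSeries,
    right: GRFSeries,
    distance_m: float,
    weight_kg: Optional[float] = None,
    config: Optional[PipelineConfig] = None,
) -> Tuple[Dict[str, float], Dict[str, float], Dict[str, int]]:
    """Smooth, detect events, filter outliers, extract both feature sets.

    Returns (kinematic features, kinetic features, audit counts).
    """
    cfg = config or PipelineConfig()
    sm = {
        "left": moving_average(left, cfg.smoothing_window),
        "right": moving_average(right, cfg.smoothing_window),
    }
    events = {}
    counts: Dict[str, int] = {}
    for side in ("left", "right"):
        ev = detect_contacts(sm[side], cfg.contact_threshold_frac)
        ev = remove_outlier_strides(ev, cfg.outlier_window, cfg.outlier_mad_factor)
        events[side] = ev
        counts[f"{side}_strides"] = ev.n_strides
        counts[f"{side}_removed"] = int(ev.n_strides - ev.n_valid())
    total = combine_feet(sm["left"], sm["right"])
    kin = kinematic_features(
        events["left"],
        events["right"],
        total,
        distance_m=distance_m,
        phi_convention=cfg.phase_deviation,
    )
    # kinetics segments the *raw* series: smoothing skews the M-shape peak
    # times toward the flatter side of each peak by about one sample
    kit, kit_counts = kinetic_features(left, right, events["left"], events["right"], weight_kg)
    counts.update(kit_counts)
    return kin, kit, counts


def _demographic_row(rec: SubjectRecord) -> dict:
    row = {
        "subject_id": rec.subject_id,
        "group": rec.group_label,
        "age_years": rec.age_years,
        "sex": rec.sex,
        "weight_kg": rec.weight_kg,
        "height_m": rec.height_m,
        "bmi_kg_m2": rec.bmi_kg_m2,
    }
    if rec.clinical is not None:
        row.update(
            updrs_iii=rec.clinical.updrs_iii,
            mmse=rec.clinical.mmse,
            ledd_mg=rec.clinical.ledd_mg,
            disease_duration_years=rec.clinical.disease_duration_years,
            affected_side=rec.clinical.affected_side,
        )
    return row


def extract_cohort_features(
    cohort: Cohort, config: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """One row per subject: demographics (+ clinical) + 28 + 24 features."""
    rows = []
    for rec in cohort.subjects:
        left, right = cohort.series[rec.subject_id]
        try:
            kin, kit, counts = extract_subject(
                left,
                right,
                distance_m=cohort.truths[rec.subject_id].distance_m,
                weight_kg=rec.weight_kg,
                config=config,
            )
        except ValueError as err:
            raise ValueError(f"extraction failed for subject {rec.subject_id}: {err}") from err
        row = _demographic_row(rec)
        row.update(kin)
        row.update(kit)
        row.update({f"audit_{k}": v for k, v in counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_config(config: PipelineConfig) -> Cohort:
    """Generate the synthetic cohort a config describes."""
    from dataclasses import replace as _replace

    from .synthetic import default_profiles

    profiles = {
        g: _replace(p, sampling_rate_hz=config.sampling_rate_hz,
                    duration_s=config.duration_s)
        for g, p in default_profiles().items()
    }
    return generate_cohort(
        n_yc=config.n_yc, n_amc=config.n_amc, n_pd=config.n_pd,
        profiles=profiles, seed=config.seed,
    )


def run_pipeline(config: PipelineConfig, write_cohort_csv: bool = False) -> dict:
    """End-to-end run; returns the artifact bundle and writes it to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = cohort_from_config(config)
    if write_cohort_csv:
        save_cohort(cohort, out / "cohort")

    features = extract_cohort_features(cohort, config)
    write_feature_table(features.to_dict(orient="records"), out / "features.csv")

    comparisons = pd.DataFrame([r.to_row() for r in compare_groups(
        features, parameters=[c for c in features.columns
                              if c not in ("subject_id", "group", "sex", "affected_side")
                              and not c.startswith("audit_")]
    )])
    comparisons.to_csv(out / "comparisons.csv", index=False)

    k = config.relieff_k
    n_min = features["group"].value_counts().min()
    if k > n_min - 1:
        warnings.warn(f"ReliefF k={k} too large for smallest group; truncating")
        k = int(n_min - 1)
    rankings = run_table4_analyses(features, k=k)
    pd.DataFrame(
        [row for r in rankings for row in r.to_rows()]
    ).to_csv(out / "rankings.csv", index=False)

    datasets = build_datasets(features)
    labels = features["group"].to_numpy()
    reports = {
        did: loo_cross_validate(datasets[did], labels, dataset_id=did)
        for did in DATASET_IDS
    }
    with open(out / "classification.json", "w") as fh:
        json.dump({did: r.to_jsonable() for did, r in reports.items()}, fh, indent=2)
    pd.DataFrame(
        [
            {
                "dataset": did,
                "n_predictors": datasets[did].shape[1],
                "ACC_pct": r.accuracy_pct,
                "SEN_pct": r.sensitivity_pct,
                "SPE_pct": r.specificity_pct,
            }
            for did, r in reports.items()
        ]
    ).to_csv(out / "classification_summary.csv", index=False)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "insolegait_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "cohort": cohort,
        "features": features,
        "comparisons": comparisons,
        "rankings": rankings,
        "reports": reports,
        "out_dir": out,
    }
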