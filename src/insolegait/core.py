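"""Core containers for insole gait analysis.

A recording is one foot's vertical ground-reaction force (GRF) sampled at a
fixed rate; forces are tracked either in Newtons (``"N"``) or as a fraction
of body weight (``"bw"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

LEFT = "left"
RIGHT = "right"
SIDES = (LEFT, RIGHT)

#: Standard gravity used to convert weight [kg] to body-weight force [N].
GRAVITY_M_S2 = 9.81


@dataclass
class GRFSeries:
    """One foot's vertical GRF time series at a fixed sampling rate."""

    samples: np.ndarray
    sampling_rate_hz: float
    side: str
    units: str = "bw"  # "bw" (fraction of body weight) or "N"
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.units not in ("bw", "N"):
            raise ValueError(f"units must be 'bw' or 'N', got {self.units!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray) -> "GRFSeries":
        return replace(self, samples=np.asarray(samples, dtype=float))


def combine_feet(left: GRFSeries, right: GRFSeries) -> GRFSeries:
    """Total (left + right) vertical GRF, used for cadence estimation.

    The combined signal oscillates at the *step* rate (two steps per stride),
    which is where its dominant spectral peak sits.
    """
    if left.sampling_rate_hz != right.sampling_rate_hz:
        raise ValueError("feet sampled at different rates")
    if left.units != right.units:
        raise ValueError("feet recorded in different units")
    n = min(left.n_samples, right.n_samples)
    total = left.samples[:n] + right.samples[:n]
    return GRFSeries(
        samples=total,
        sampling_rate_hz=left.sampling_rate_hz,
        side=LEFT,  # side tag meaningless for the sum; kept for container validity
        units=left.units,
        subject_id=left.subject_id,
    )


@dataclass
class ClinicalStatus:
    """Disease-related covariates (patients only)."""

    updrs_iii: float
    mmse: float
    ledd_mg: float
    disease_duration_years: float
    affected_side: str  # "left" | "right"

    def __post_init__(self) -> None:
        if self.affected_side not in SIDES:
            raise ValueError("affected_side must be 'left' or 'right'")


@dataclass
class SubjectRecord:
    """Demographic (and, for patients, clinical) description of one subject."""

    subject_id: str
    group_label: str  # YC | AMC | PD
    age_years: float
    sex: str  # "M" | "F"
    weight_kg: float
    height_m: float
    bmi_kg_m2: float = field(default=float("nan"))
    clinical: Optional[ClinicalStatus] = None

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.height_m <= 0:
            raise ValueError("weight and height must be positive")
        expected_bmi = self.weight_kg / self.height_m**2
        if np.isnan(self.bmi_kg_m2):
            self.bmi_kg_m2 = expected_bmi
        elif abs(self.bmi_kg_m2 - expected_bmi) > 0.1:
            raise ValueError("bmi inconsistent with weight/height")
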