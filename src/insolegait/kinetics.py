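"""Kinetic gait parameters from body-weight-normalized stance cycles.

Each valid stride's stance phase is cropped from the GRF series, normalized
by body weight, resampled to a 101-point 0-100% stance grid, and reduced to
the M-shape landmarks: heel-peak, mid-stance and toe-off forces (HPF, MSF,
TOF, fractions of body weight) and their times (HPT, MST, TOT, % of stance).
Per-cycle values come first; subject-level means and CVs second, because the
reported variability measures are CVs of per-cycle quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .core import GRAVITY_M_S2, GRFSeries
from .events import GaitEvents

__all__ = [
    "StanceCycle",
    "MShape",
    "KINETIC_COLUMNS",
    "segment_and_normalize",
    "extract_m_shape",
    "average_cycle",
    "assemble_kinetics",
    "kinetic_features",
]

STANCE_GRID = 101  # 0..100% of stance, 1% steps

#: The 24 kinetic parameters, in reporting order.
KINETIC_COLUMNS = [
    "R HPF [%BW]",
    "L HPF [%BW]",
    "R MSF [%BW]",
    "L MSF [%BW]",
    "R TOF [%BW]",
    "L TOF [%BW]",
    "R HPF CV",
    "L HPF CV",
    "R MSF CV",
    "L MSF CV",
    "R TOF CV",
    "L TOF CV",
    "R HPT [% stance]",
    "L HPT [% stance]",
    "R MST [% stance]",
    "L MST [% stance]",
    "R TOT [% stance]",
    "L TOT [% stance]",
    "R HPT CV",
    "L HPT CV",
    "R MST CV",
    "L MST CV",
    "R TOT CV",
    "L TOT CV",
]


@dataclass
class StanceCycle:
    """One stance phase resampled to the 101-point grid, in body weights."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (STANCE_GRID,):
            raise ValueError(f"stance cycle must have {STANCE_GRID} points")
        if np.any(self.values < 0):
            raise ValueError("stance cycle values must be >= 0")


@dataclass
class MShape:
    """Per-cycle M-shape landmark forces (BW) and times (% stance)."""

    hpf: float
    msf: float
    tof: float
    hpt: float
    mst: float
    tot: float

    def as_tuple(self) -> Tuple[float, ...]:
        return (self.hpf, self.msf, self.tof, self.hpt, self.mst, self.tot)


def segment_and_normalize(
    series: GRFSeries,
    events: GaitEvents,
    weight_kg: Optional[float] = None,
) -> Tuple[List[StanceCycle], int]:
    """Crop each valid stride's stance, normalize by body weight, resample.

    Newton-valued input requires ``weight_kg`` (divides by weight x g);
    body-weight-fraction input passes through.  Returns the cycles and the
    count of cycles skipped as too short.
    """
    if series.units == "N":
        if weight_kg is None or weight_kg <= 0:
            raise ValueError("weight_kg required to normalize Newton-valued series")
        scale = 1.0 / (weight_kg * GRAVITY_M_S2)
    else:
        scale = 1.0
    fs_hz = series.sampling_rate_hz
    cycles: List[StanceCycle] = []
    skipped = 0
    grid = np.linspace(0.0, 1.0, STANCE_GRID)
    for i in range(events.n_strides):
        if not events.valid[i]:
            continue
        i0 = int(round(events.foot_strike_s[i] * fs_hz))
        i1 = int(round(events.toe_off_s[i] * fs_hz))
        seg = series.samples[max(i0, 0) : min(i1 + 1, series.n_samples)]
        if seg.size < 5:
            skipped += 1
            continue
        resampled = np.interp(grid, np.linspace(0.0, 1.0, seg.size), seg * scale)
        cycles.append(StanceCycle(values=np.maximum(resampled, 0.0)))
    if not cycles:
        warnings.warn("no usable stance cycles")
    return cycles, skipped


def extract_m_shape(cycle: StanceCycle, min_prominence: float = 0.05) -> Optional[MShape]:
    """M-shape landmarks of one stance cycle, or None if no M-shape exists.

    HPF is the first prominent local maximum in (0, 50]% of stance, TOF the
    last in [50, 100)%, MSF the minimum between them; times are the landmark
    positions in % of stance.  Cycles without two distinct prominent maxima
    (flat, monotone or single-bump) are unusable.
    """
    y = cycle.values
    peaks, _ = find_peaks(y, prominence=min_prominence)
    early = peaks[(peaks > 0) & (peaks <= 50)]
    late = peaks[(peaks >= 50) & (peaks < 100)]
    if early.size == 0 or late.size == 0:
        return None
    i_hp = int(early[0])
    i_to = int(late[-1])
    if i_to <= i_hp:
        return None
    between = y[i_hp : i_to + 1]
    i_ms = i_hp + int(np.argmin(between))
    if i_ms in (i_hp, i_to):
        return None
    msf = float(y[i_ms])
    if not (msf < y[i_hp] and msf < y[i_to]):
        return None
    return MShape(
        hpf=float(y[i_hp]),
        msf=msf,
        tof=float(y[i_to]),
        hpt=float(i_hp),
        mst=float(i_ms),
        tot=float(i_to),
    )


def average_cycle(cycles: Sequence[StanceCycle]) -> StanceCycle:
    """Pointwise mean over the 101-point stance grid."""
    if len(cycles) == 0:
        raise ValueError("cannot average zero cycles")
    return StanceCycle(values=np.mean([c.values for c in cycles], axis=0))


_QUANTITIES = ("HPF", "MSF", "TOF")
_TIMES = ("HPT", "MST", "TOT")


def assemble_kinetics(
    shapes_left: Sequence[MShape], shapes_right: Sequence[MShape]
) -> Dict[str, float]:
    """The 24-parameter kinetic feature set from per-cycle M-shapes."""
    per_side = {"L": shapes_left, "R": shapes_right}
    for side, shapes in per_side.items():
        if len(shapes) < 2:
            raise ValueError(f"fewer than 2 usable cycles on side {side}")
    cols: Dict[str, np.ndarray] = {}
    for side, shapes in per_side.items():
        arr = np.array([s.as_tuple() for s in shapes])  # (n, 6)
        for j, q in enumerate(_QUANTITIES + _TIMES):
            cols[f"{side} {q}"] = arr[:, j]

    from .kinematics import coefficient_of_variation

    out: Dict[str, float] = {}
    for q in _QUANTITIES:
        for side in ("R", "L"):
            out[f"{side} {q} [%BW]"] = float(np.mean(cols[f"{side} {q}"]))
    for q in _QUANTITIES:
        for side in ("R", "L"):
            out[f"{side} {q} CV"] = coefficient_of_variation(cols[f"{side} {q}"])
    for q in _TIMES:
        for side in ("R", "L"):
            out[f"{side} {q} [% stance]"] = float(np.mean(cols[f"{side} {q}"]))
    for q in _TIMES:
        for side in ("R", "L"):
            out[f"{side} {q} CV"] = coefficient_of_variation(cols[f"{side} {q}"])
    assert list(out.keys()) == KINETIC_COLUMNS
    return out


def kinetic_features(
    left_series: GRFSeries,
    right_series: GRFSeries,
    left_events: GaitEvents,
    right_events: GaitEvents,
    weight_kg: Optional[float] = None,
) -> Tuple[Dict[str, float], Dict[str, int]]:
    """Convenience wrapper: series + events -> 24 kinetic features + audit counts."""
    shapes: Dict[str, List[MShape]] = {}
    counts: Dict[str, int] = {}
    for key, series, events in (
        ("left", left_series, left_events),
        ("right", right_series, right_events),
    ):
        cycles, skipped = segment_and_normalize(series, events, weight_kg)
        ms = [m for m in (extract_m_shape(c) for c in cycles) if m is not None]
        shapes[key] = ms
        counts[f"{key}_cycles"] = len(cycles)
        counts[f"{key}_skipped_short"] = skipped
        counts[f"{key}_unusable"] = len(cycles) - len(ms)
    return assemble_kinetics(shapes["left"], shapes["right"]), counts
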