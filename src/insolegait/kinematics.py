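"""Kinematic gait parameters from per-foot gait events.

Covers stride/stance/swing intervals and their stride-to-stride variability,
double support time, the bilateral phase series φ and the phase coordination
index (PCI), periodogram cadence, spatial estimates, and assembly of the
28-parameter kinematic feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.signal import periodogram

from .core import GRFSeries
from .events import GaitEvents

__all__ = [
    "StrideIntervals",
    "PhaseSeries",
    "PhaseStats",
    "KINEMATIC_COLUMNS",
    "stride_intervals",
    "coefficient_of_variation",
    "gait_asymmetry",
    "phase_series",
    "phase_stats",
    "cadence",
    "spatial_estimates",
    "assemble_kinematics",
    "kinematic_features",
]

#: The 28 kinematic parameters, in reporting order.
KINEMATIC_COLUMNS = [
    "Nr steps",
    "Distance [m]",
    "Step length [m]",
    "Speed [m/s]",
    "Cadence [strides/s]",
    "R stride time [s]",
    "L stride time [s]",
    "R stance time [s]",
    "L stance time [s]",
    "R swing time [s]",
    "L swing time [s]",
    "R stride time CV",
    "L stride time CV",
    "R stance time CV",
    "L stance time CV",
    "R swing time CV",
    "L swing time CV",
    "R PST [%]",
    "L PST [%]",
    "R PSWT [%]",
    "L PSWT [%]",
    "DST [s]",
    "DST CV",
    "phi [deg]",
    "phi CV",
    "phi deviation",
    "GA",
    "PCI",
]


@dataclass
class StrideIntervals:
    """Per-valid-stride durations for both feet plus per-stride DST."""

    stride_s: Dict[str, np.ndarray]
    stance_s: Dict[str, np.ndarray]
    swing_s: Dict[str, np.ndarray]
    dst_s: np.ndarray


@dataclass
class PhaseSeries:
    """Bilateral phase φ_i per reference-leg stride, in degrees."""

    phases_deg: np.ndarray
    reference_side: str
    t_long: np.ndarray  # reference foot-strike opening each used stride
    t_short: np.ndarray  # contralateral strike inside it
    n_skipped: int = 0


@dataclass
class PhaseStats:
    phi_mean_deg: float
    phi_cv: float
    phi_deviation: float  # percent of 180 by default; see `convention`
    pci: float
    phi_deviation_deg: float
    convention: str = "percent"


def coefficient_of_variation(values) -> float:
    """CV = 100 x sample standard deviation / mean (percent)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = float(np.mean(v))
    if abs(m) < 1e-12:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / m


def gait_asymmetry(mean_swing_a_s: float, mean_swing_b_s: float) -> float:
    """GA = 100 x |ln(short swing / long swing)|; 0 for symmetric gait."""
    if mean_swing_a_s <= 0 or mean_swing_b_s <= 0:
        raise ValueError("swing times must be positive")
    return 100.0 * abs(float(np.log(mean_swing_a_s / mean_swing_b_s)))


def _valid_contacts(events: GaitEvents) -> list:
    """(fs, to) pairs belonging to valid strides."""
    return [
        (events.foot_strike_s[i], events.toe_off_s[i])
        for i in range(events.n_strides)
        if events.valid[i]
    ]


def stride_intervals(left: GaitEvents, right: GaitEvents) -> StrideIntervals:
    """Stride/stance/swing durations per valid stride, plus per-stride DST.

    DST for (left) stride i is the total bilateral-contact time inside
    [fs_i, fs_i+1): the loading-response and pre-swing double-support
    intervals.  Only strides fully covered by valid contralateral contacts
    contribute a DST value.
    """
    out_stride, out_stance, out_swing = {}, {}, {}
    for ev in (left, right):
        mask = ev.valid
        if int(np.sum(mask)) < 2:
            raise ValueError(f"fewer than 2 valid strides on {ev.side} side")
        out_stride[ev.side] = ev.stride_times()[mask]
        out_stance[ev.side] = ev.stance_times()[mask]
        out_swing[ev.side] = ev.swing_times()[mask]

    # all detected contralateral contact pairs: a contact is trustworthy even
    # when the stride it opens was flagged (the flagged *left* stride already
    # excludes the distorted region from DST)
    right_contacts = list(zip(right.foot_strike_s, right.toe_off_s))
    dst = []
    for i in range(left.n_strides):
        if not left.valid[i]:
            continue
        w0, w1 = left.foot_strike_s[i], left.foot_strike_s[i + 1]
        inside = [c for c in right_contacts if w0 < c[0] < w1]
        if len(inside) != 1:
            continue  # bilateral coverage broken (e.g. next to a removed turn)
        # bilateral contact within the stride = overlap of the left contact
        # interval [fs_i, to_i] with the right contact intervals: the
        # loading-response and pre-swing double-support pieces
        la, lb = left.foot_strike_s[i], left.toe_off_s[i]
        pieces = []
        for a, b in right_contacts:
            lo, hi = max(a, la), min(b, lb)
            if hi > lo:
                pieces.append(hi - lo)
        if len(pieces) != 2:
            continue  # a double-support piece is missing or spurious
        dst.append(sum(pieces))
    dst = np.asarray(dst)
    if dst.size == 0:
        raise ValueError("no overlapping valid strides across feet")
    return StrideIntervals(stride_s=out_stride, stance_s=out_stance, swing_s=out_swing, dst_s=dst)


def phase_series(left: GaitEvents, right: GaitEvents) -> PhaseSeries:
    """φ_i = 360 x (t_Si - t_Li) / (t_L(i+1) - t_Li) per reference stride.

    The reference ("long") leg is the one with the higher mean swing time
    over valid strides; ties break to the left leg with a warning.  Reference
    strides containing anything other than exactly one interior contralateral
    strike are skipped and counted.
    """
    mean_swing = {
        ev.side: float(np.mean(ev.swing_times()[ev.valid])) for ev in (left, right)
    }
    if mean_swing["left"] == mean_swing["right"]:
        warnings.warn("mean swing times tie; using left leg as phase reference")
        ref, other = left, right
    elif mean_swing["left"] > mean_swing["right"]:
        ref, other = left, right
    else:
        ref, other = right, left

    other_fs = other.foot_strike_s[:-1][other.valid] if other.n_strides else np.array([])
    phases, t_long, t_short = [], [], []
    skipped = 0
    for i in range(ref.n_strides):
        if not ref.valid[i]:
            continue
        t0, t1 = ref.foot_strike_s[i], ref.foot_strike_s[i + 1]
        inside = other_fs[(other_fs > t0) & (other_fs < t1)]
        if inside.size != 1:
            skipped += 1
            continue
        phi = 360.0 * (inside[0] - t0) / (t1 - t0)
        phases.append(phi)
        t_long.append(t0)
        t_short.append(inside[0])
    return PhaseSeries(
        phases_deg=np.asarray(phases),
        reference_side=ref.side,
        t_long=np.asarray(t_long),
        t_short=np.asarray(t_short),
        n_skipped=skipped,
    )


def phase_stats(phases: PhaseSeries, convention: str = "percent") -> PhaseStats:
    """Mean φ, φ CV, φ deviation and PCI = φ CV + φ deviation.

    φ deviation is the mean absolute departure of φ from 180 deg, normalized
    to percent of 180 by default (so PCI sums two percentages); the raw-degree
    value is always reported alongside.
    """
    phi = phases.phases_deg
    if phi.size < 2:
        raise ValueError("need at least 2 phase values")
    mean = float(np.mean(phi))
    cv = coefficient_of_variation(phi)
    dev_deg = float(np.mean(np.abs(phi - 180.0)))
    dev_pct = 100.0 * dev_deg / 180.0
    if convention == "percent":
        dev = dev_pct
    elif convention == "degrees":
        dev = dev_deg
    else:
        raise ValueError("convention must be 'percent' or 'degrees'")
    return PhaseStats(
        phi_mean_deg=mean,
        phi_cv=cv,
        phi_deviation=dev,
        pci=cv + dev,
        phi_deviation_deg=dev_deg,
        convention=convention,
    )


def cadence(total_grf: GRFSeries, f_lo: float = 0.5, f_hi: float = 4.0) -> float:
    """Dominant periodogram frequency of the combined GRF in [f_lo, f_hi] Hz.

    The left+right sum oscillates at the step rate, i.e. twice per stride.
    """
    if total_grf.duration_s < 30.0:
        raise ValueError("cadence needs at least 30 s of signal")
    x = total_grf.samples - float(np.mean(total_grf.samples))
    if np.allclose(x, 0.0):
        raise ValueError("cadence undefined for a constant series")
    f, pxx = periodogram(x, fs=total_grf.sampling_rate_hz)
    band = (f >= f_lo) & (f <= f_hi)
    if not np.any(pxx[band] > 0):
        raise ValueError("no spectral power in the cadence band")
    return float(f[band][np.argmax(pxx[band])])


def spatial_estimates(
    n_steps: float, duration_s: float, distance_m: float
) -> Tuple[float, float]:
    """(speed, step length): displacement over duration and over step count."""
    if n_steps <= 0 or duration_s <= 0 or distance_m <= 0:
        raise ValueError("n_steps, duration_s and distance_m must be positive")
    return distance_m / duration_s, distance_m / n_steps


def assemble_kinematics(
    intervals: StrideIntervals,
    phase: PhaseStats,
    cadence_hz: float,
    speed_m_s: float,
    step_length_m: float,
    n_steps: int,
    distance_m: float,
) -> Dict[str, float]:
    """The 28-parameter kinematic feature set, in reporting order."""
    for name, value in (
        ("intervals", intervals),
        ("phase", phase),
        ("cadence", cadence_hz),
        ("speed", speed_m_s),
        ("step length", step_length_m),
        ("n_steps", n_steps),
        ("distance", distance_m),
    ):
        if value is None:
            raise ValueError(f"missing kinematic component: {name}")

    def per_leg(d: Dict[str, np.ndarray], side: str) -> np.ndarray:
        return d["right" if side == "R" else "left"]

    out: Dict[str, float] = {
        "Nr steps": float(n_steps),
        "Distance [m]": float(distance_m),
        "Step length [m]": float(step_length_m),
        "Speed [m/s]": float(speed_m_s),
        "Cadence [strides/s]": float(cadence_hz),
    }
    quantities = {
        "stride time": intervals.stride_s,
        "stance time": intervals.stance_s,
        "swing time": intervals.swing_s,
    }
    for name, values in quantities.items():
        for side in ("R", "L"):
            out[f"{side} {name} [s]"] = float(np.mean(per_leg(values, side)))
    for name, values in quantities.items():
        for side in ("R", "L"):
            out[f"{side} {name} CV"] = coefficient_of_variation(per_leg(values, side))
    for name, values in (("PST", intervals.stance_s), ("PSWT", intervals.swing_s)):
        for side in ("R", "L"):
            out[f"{side} {name} [%]"] = float(
                np.mean(100.0 * per_leg(values, side) / per_leg(intervals.stride_s, side))
            )
    out["DST [s]"] = float(np.mean(intervals.dst_s))
    out["DST CV"] = coefficient_of_variation(intervals.dst_s)
    out["phi [deg]"] = phase.phi_mean_deg
    out["phi CV"] = phase.phi_cv
    out["phi deviation"] = phase.phi_deviation
    out["GA"] = gait_asymmetry(
        float(np.mean(intervals.swing_s["left"])), float(np.mean(intervals.swing_s["right"]))
    )
    out["PCI"] = phase.pci
    assert list(out.keys()) == KINEMATIC_COLUMNS
    return out


def kinematic_features(
    left_events: GaitEvents,
    right_events: GaitEvents,
    total_grf: GRFSeries,
    distance_m: float,
    duration_s: Optional[float] = None,
    phi_convention: str = "percent",
) -> Dict[str, float]:
    """Convenience wrapper: events + combined GRF + manifest distance -> 28 features.

    Also emits the auxiliary raw-degree phase deviation under
    ``"phi deviation [deg]"`` (not part of the 28-parameter set).
    """
    intervals = stride_intervals(left_events, right_events)
    ps = phase_stats(phase_series(left_events, right_events), convention=phi_convention)
    cad = cadence(total_grf)
    dur = duration_s if duration_s is not None else total_grf.duration_s
    # every detected foot-strike is a step over the measured distance; the
    # validity flags only exclude strides from the timing statistics
    n_steps = left_events.n_pairs + right_events.n_pairs
    speed, step_len = spatial_estimates(n_steps, dur, distance_m)
    feats = assemble_kinematics(intervals, ps, cad, speed, step_len, n_steps, distance_m)
    feats["phi deviation [deg]"] = ps.phi_deviation_deg
    return feats
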