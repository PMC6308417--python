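"""Synthetic two-insole GRF cohort generator.

Emulates 5-minute free-walking recordings at 100 Hz for three groups (young
controls YC, age-matched controls AMC, Parkinson's disease PD): per-leg
stride/swing timing with stride-to-stride variability, bilateral phase noise,
double-support variability, M-shaped stance force profiles, additive sensor
noise, and inflated "turn" strides at walkway ends.  Every generated quantity
is recorded as ground truth so downstream extraction can be tested against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import LEFT, RIGHT, ClinicalStatus, GRFSeries, SubjectRecord

__all__ = [
    "GaitProfile",
    "StrideSchedule",
    "GroundTruth",
    "Cohort",
    "default_profiles",
    "noise_free",
    "generate_stride_schedule",
    "synth_stance_curve",
    "generate_subject",
    "generate_cohort",
]


@dataclass
class GaitProfile:
    """Generative gait parameters for one group.

    Timing means/sds are per leg as ``(left, right)``.  The two legs share a
    common cycle, so the realized stride time of both legs follows the mean of
    the two stride entries; per-leg swing means are honored exactly and are
    what create gait asymmetry.  ``phase_offset_deg`` / ``phase_sd_deg``
    control where contralateral foot-strikes fall inside the reference stride
    (180 deg = perfect alternation); phase noise is applied to foot-strike
    placement only, so phase and double-support variability are independently
    controllable.  Toe-offs are anchored to the contralateral foot-strike plus
    a double-support interval jittered by ``double_support_sd_s`` (plus any
    per-leg ``swing_time_sd_s``), so double-support variability is a direct
    dial; swing-time variability largely emerges from stride-time noise.
    """

    group_label: str = "YC"
    stride_time_mean_s: Tuple[float, float] = (1.12, 1.13)
    stride_time_sd_s: Tuple[float, float] = (0.027, 0.027)
    swing_time_mean_s: Tuple[float, float] = (0.380, 0.3834)
    swing_time_sd_s: Tuple[float, float] = (0.0, 0.0)
    double_support_sd_s: float = 0.011
    phase_offset_deg: float = 180.0
    phase_sd_deg: float = 2.8
    phase_offset_subject_sd_deg: float = 1.0  # between-subject spread of mean phase
    swing_asym_subject_sd: float = 0.004  # between-subject per-leg swing-ratio jitter
    landmark_fractions: Tuple[float, float, float] = (0.26, 0.46, 0.74)
    peak_magnitudes_bw: Tuple[float, float, float] = (0.95, 0.63, 1.10)
    peak_sd_frac: float = 0.05
    landmark_sd: float = 0.010
    noise_sd_bw: float = 0.01
    sampling_rate_hz: float = 100.0
    duration_s: float = 300.0
    walkway_length_m: float = 25.0
    step_length_m: float = 0.71
    turn_every_n_strides: int = 18  # 0 disables turns

    def validate(self) -> None:
        for leg in (0, 1):
            if self.swing_time_mean_s[leg] >= self.stride_time_mean_s[leg]:
                raise ValueError("infeasible profile: swing >= stride")
            if self.stride_time_sd_s[leg] < 0 or self.swing_time_sd_s[leg] < 0:
                raise ValueError("timing sds must be >= 0")
        f1, f2, f3 = self.landmark_fractions
        if not (0.0 < f1 < f2 < f3 < 1.0):
            raise ValueError("landmark fractions must be strictly increasing in (0, 1)")
        p1, v, p2 = self.peak_magnitudes_bw
        if not (v < p1 and v < p2):
            raise ValueError("mid-stance magnitude must be below both peaks")
        if min(p1, v, p2) <= 0:
            raise ValueError("peak magnitudes must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.noise_sd_bw < 0 or self.double_support_sd_s < 0 or self.phase_sd_deg < 0:
            raise ValueError("noise sds must be >= 0")
        # nominal double-support intervals must both be positive
        if min(self.nominal_double_support_s) <= 0:
            raise ValueError("infeasible profile: double support would be negative")

    @property
    def cycle_time_s(self) -> float:
        return float(np.mean(self.stride_time_mean_s))

    @property
    def nominal_step_time_s(self) -> float:
        return self.phase_offset_deg / 360.0 * self.cycle_time_s

    @property
    def nominal_double_support_s(self) -> Tuple[float, float]:
        """(loading-response, pre-swing) bilateral intervals of a left stride.

        The first ends with the right toe-off just after a left strike
        (``step - right swing``), the second runs from the right strike to the
        left toe-off (``left stance - step``).
        """
        step = self.nominal_step_time_s
        cycle = self.cycle_time_s
        ds1 = step - self.swing_time_mean_s[1]
        ds2 = (cycle - self.swing_time_mean_s[0]) - step
        return ds1, ds2


def default_profiles() -> Dict[str, GaitProfile]:
    """Group profiles centered on the study-condition medians.

    Timing, variability, phase and M-shape values follow the reported group
    medians: similar stride/stance/swing times everywhere, but the PD profile
    carries doubled double-support variability, larger swing asymmetry and
    wider phase noise — the bilateral-coordination signature the analysis is
    meant to recover.
    """
    yc = GaitProfile(
        group_label="YC",
        stride_time_mean_s=(1.12, 1.13),
        stride_time_sd_s=(0.027, 0.027),
        swing_time_mean_s=(0.380, 0.3834),  # GA ~ 0.9
        swing_time_sd_s=(0.0, 0.0),
        double_support_sd_s=0.011,
        phase_offset_deg=180.1,
        phase_sd_deg=2.8,
        phase_offset_subject_sd_deg=1.0,
        swing_asym_subject_sd=0.004,
        peak_magnitudes_bw=(0.95, 0.63, 1.10),
        step_length_m=0.71,
    )
    amc = GaitProfile(
        group_label="AMC",
        stride_time_mean_s=(1.13, 1.14),
        stride_time_sd_s=(0.026, 0.026),
        swing_time_mean_s=(0.376, 0.3843),  # GA ~ 2.2
        swing_time_sd_s=(0.0, 0.0),
        double_support_sd_s=0.014,
        phase_offset_deg=181.3,
        phase_sd_deg=3.0,
        phase_offset_subject_sd_deg=1.5,
        swing_asym_subject_sd=0.0055,
        peak_magnitudes_bw=(0.97, 0.60, 1.07),
        step_length_m=0.73,
    )
    pd_ = GaitProfile(
        group_label="PD",
        stride_time_mean_s=(1.10, 1.10),
        stride_time_sd_s=(0.025, 0.025),
        swing_time_mean_s=(0.366, 0.3764),  # GA ~ 2.8
        swing_time_sd_s=(0.0, 0.0),
        double_support_sd_s=0.021,  # ~2x controls -> raised DST CV
        phase_offset_deg=181.5,
        phase_sd_deg=4.2,
        phase_offset_subject_sd_deg=3.5,
        swing_asym_subject_sd=0.008,
        peak_magnitudes_bw=(0.93, 0.60, 1.01),
        step_length_m=0.70,
    )
    return {"YC": yc, "AMC": amc, "PD": pd_}


def noise_free(profile: Optional[GaitProfile] = None, **overrides) -> GaitProfile:
    """Copy of ``profile`` with every stochastic term zeroed and turns off."""
    base = profile if profile is not None else default_profiles()["YC"]
    kwargs = dict(
        stride_time_sd_s=(0.0, 0.0),
        swing_time_sd_s=(0.0, 0.0),
        double_support_sd_s=0.0,
        phase_sd_deg=0.0,
        peak_sd_frac=0.0,
        landmark_sd=0.0,
        noise_sd_bw=0.0,
        turn_every_n_strides=0,
    )
    kwargs.update(overrides)
    return replace(base, **kwargs)


@dataclass
class StrideSchedule:
    """Per-leg contact event schedule (seconds, continuous time)."""

    left_fs: np.ndarray  # n+1 foot-strikes
    left_to: np.ndarray  # n toe-offs
    right_fs: np.ndarray  # n+1 foot-strikes
    right_to: np.ndarray  # n toe-offs
    phase_deg: np.ndarray  # realized phase per stride
    turn_stride_idx: np.ndarray  # stride indices inflated as turns

    @property
    def n_strides(self) -> int:
        return int(self.left_to.size)


@dataclass
class GroundTruth:
    """Everything the generator knows about one subject's recording."""

    schedule: StrideSchedule
    stride_s: Dict[str, np.ndarray]
    stance_s: Dict[str, np.ndarray]
    swing_s: Dict[str, np.ndarray]
    dst_s: np.ndarray  # per left stride, both bilateral-contact intervals
    landmark_fractions: Dict[str, np.ndarray]  # (n, 3) per leg, per cycle
    peak_magnitudes_bw: Dict[str, np.ndarray]  # (n, 3) per leg, per cycle
    turn_stride_idx: np.ndarray
    n_steps: int
    distance_m: float

    def to_jsonable(self) -> dict:
        sch = self.schedule
        return {
            "left_fs": sch.left_fs.tolist(),
            "left_to": sch.left_to.tolist(),
            "right_fs": sch.right_fs.tolist(),
            "right_to": sch.right_to.tolist(),
            "phase_deg": sch.phase_deg.tolist(),
            "turn_stride_idx": self.turn_stride_idx.tolist(),
            "dst_s": self.dst_s.tolist(),
            "n_steps": self.n_steps,
            "distance_m": self.distance_m,
        }


def generate_stride_schedule(profile: GaitProfile, seed=0) -> StrideSchedule:
    """Draw a per-leg foot-strike / toe-off schedule from a gait profile.

    The left leg carries the base cycle: its foot-strikes accumulate stride
    draws.  Right foot-strikes are placed inside each left stride at the drawn
    phase; each toe-off follows the contralateral foot-strike by a jittered
    double-support interval.  A zero-variance profile yields exactly the
    nominal durations.
    """
    profile.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fs_hz = profile.sampling_rate_hz
    cycle = profile.cycle_time_s
    pad = 1.0  # quiet lead-in/out so stance curves never touch the buffer edge
    n = max(2, int(np.floor((profile.duration_s - 2 * pad) / cycle)))

    stride_sd = float(np.mean(profile.stride_time_sd_s))
    stride = rng.normal(cycle, stride_sd, size=n) if stride_sd > 0 else np.full(n, cycle)

    turn_idx = np.array([], dtype=int)
    if profile.turn_every_n_strides > 0:
        turn_idx = np.arange(profile.turn_every_n_strides - 1, n, profile.turn_every_n_strides)
        stride[turn_idx] *= rng.uniform(1.5, 2.5, size=turn_idx.size)

    max_swing = max(profile.swing_time_mean_s)
    stride = np.maximum(stride, max_swing + 5.0 / fs_hz)

    left_fs = pad + np.concatenate(([0.0], np.cumsum(stride)))

    phase = (
        rng.normal(profile.phase_offset_deg, profile.phase_sd_deg, size=n)
        if profile.phase_sd_deg > 0
        else np.full(n, profile.phase_offset_deg)
    )
    phase = np.clip(phase, 20.0, 340.0)
    right_fs_inner = left_fs[:-1] + phase / 360.0 * (left_fs[1:] - left_fs[:-1])
    # closing right strike keeps the last right stride well-defined
    right_fs = np.concatenate((right_fs_inner, [right_fs_inner[-1] + stride[-1]]))

    # toe-offs anchor to the *contralateral* strike plus a double-support
    # interval (load transfer), so double-support variability is controlled
    # directly by double_support_sd_s rather than inherited from stride noise
    ds1_nom, ds2_nom = profile.nominal_double_support_s

    def _jitter(leg: int) -> np.ndarray:
        sd = float(np.hypot(profile.double_support_sd_s, profile.swing_time_sd_s[leg]))
        return rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)

    left_to = right_fs_inner + ds2_nom + _jitter(0)
    left_to = np.clip(left_to, left_fs[:-1] + 5.0 / fs_hz, left_fs[1:] - 2.0 / fs_hz)
    right_to = left_fs[1:] + ds1_nom + _jitter(1)
    right_to = np.clip(right_to, right_fs[:-1] + 5.0 / fs_hz, right_fs[1:] - 2.0 / fs_hz)

    # truncate anything that spills past the recording window
    keep = right_fs[1:] <= profile.duration_s - 0.5
    m = int(np.sum(keep))
    if m < 2:
        raise ValueError("duration too short for two strides")
    return StrideSchedule(
        left_fs=left_fs[: m + 1],
        left_to=left_to[:m],
        right_fs=right_fs[: m + 1],
        right_to=right_to[:m],
        phase_deg=phase[:m],
        turn_stride_idx=turn_idx[turn_idx < m],
    )


def synth_stance_curve(
    stance_duration_s: float,
    landmarks: Sequence[float],
    peaks: Sequence[float],
    sampling_rate_hz: float,
) -> np.ndarray:
    """Sampled M-shaped stance force profile.

    Piecewise half-cosine interpolant through (0,0), (f1,p1), (f2,v), (f3,p2),
    (1,0): each segment is strictly monotone with zero slope at the knots, so
    the curve has exactly two local maxima (heel peak, toe-off peak) and one
    interior minimum (mid-stance valley) at the requested stance fractions,
    with the requested magnitudes.
    """
    f1, f2, f3 = landmarks
    p1, v, p2 = peaks
    if not (0.0 < f1 < f2 < f3 < 1.0):
        raise ValueError("landmark fractions must be strictly increasing in (0, 1)")
    if not (0 < v < min(p1, p2)):
        raise ValueError("mid-stance magnitude must be below both peaks")
    n = int(round(stance_duration_s * sampling_rate_hz))
    return _stance_curve_n(n, (f1, f2, f3), (p1, v, p2))


def _stance_curve_n(n: int, landmarks, peaks) -> np.ndarray:
    """M-shaped stance profile on exactly ``n`` samples (0 .. n-1)."""
    f1, f2, f3 = landmarks
    p1, v, p2 = peaks
    if n < 5:
        raise ValueError("stance shorter than 5 samples")
    u = np.arange(n) / (n - 1)

    def half_cos(x, a, b):
        """Monotone blend a -> b with zero slope at both ends, x in [0, 1]."""
        return a + (b - a) * (1.0 - np.cos(np.pi * x)) / 2.0

    y = np.empty(n)
    seg = u <= f1
    y[seg] = half_cos(u[seg] / f1, 0.0, p1)
    seg = (u > f1) & (u <= f2)
    y[seg] = half_cos((u[seg] - f1) / (f2 - f1), p1, v)
    seg = (u > f2) & (u <= f3)
    y[seg] = half_cos((u[seg] - f2) / (f3 - f2), v, p2)
    seg = u > f3
    y[seg] = half_cos((u[seg] - f3) / (1.0 - f3), p2, 0.0)
    return y


def _jitter_mshape(
    profile: GaitProfile, rng: np.random.Generator, n: int, force_scale: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cycle landmark fractions and peak magnitudes with physiological jitter."""
    lm = np.tile(np.asarray(profile.landmark_fractions, dtype=float), (n, 1))
    pk = np.tile(np.asarray(profile.peak_magnitudes_bw, dtype=float), (n, 1))
    if profile.landmark_sd > 0:
        lm += rng.normal(0.0, profile.landmark_sd, size=lm.shape)
        lm[:, 0] = np.clip(lm[:, 0], 0.10, 0.40)
        lm[:, 1] = np.clip(lm[:, 1], lm[:, 0] + 0.04, 0.60)
        lm[:, 2] = np.clip(lm[:, 2], lm[:, 1] + 0.04, 0.92)
    if profile.peak_sd_frac > 0:
        pk *= rng.normal(1.0, profile.peak_sd_frac, size=pk.shape)
        pk = np.maximum(pk, 0.05)
    pk *= force_scale[:, None]
    # keep the valley strictly below both peaks
    pk[:, 1] = np.minimum(pk[:, 1], 0.9 * np.minimum(pk[:, 0], pk[:, 2]))
    return lm, pk


def _render_leg(
    buffer: np.ndarray,
    fs_times: np.ndarray,
    to_times: np.ndarray,
    lm: np.ndarray,
    pk: np.ndarray,
    fs_hz: float,
) -> None:
    n_samp = buffer.size
    for i in range(to_times.size):
        # snap contact endpoints to the sample grid before rendering, so the
        # rendered span is consistent with what sample-resolution detection
        # can recover (the schedule stays the continuous-time ground truth)
        i0 = int(round(fs_times[i] * fs_hz))
        i1 = int(round(to_times[i] * fs_hz))
        curve = _stance_curve_n(i1 - i0 + 1, lm[i], pk[i])
        if i0 < 0 or i0 >= n_samp:
            continue
        i1c = min(i0 + curve.size, n_samp)
        buffer[i0:i1c] += curve[: i1c - i0]


def _true_dst(schedule: StrideSchedule) -> np.ndarray:
    """Bilateral-contact time within each left stride, from the schedule."""
    intervals = _contact_intersections(
        list(zip(schedule.left_fs[:-1], schedule.left_to)),
        list(zip(schedule.right_fs[:-1], schedule.right_to)),
    )
    out = np.zeros(schedule.n_strides)
    for i in range(schedule.n_strides):
        w0, w1 = schedule.left_fs[i], schedule.left_fs[i + 1]
        for a, b in intervals:
            out[i] += max(0.0, min(b, w1) - max(a, w0))
    return out


def _contact_intersections(left_pairs, right_pairs) -> List[Tuple[float, float]]:
    out = []
    for a0, a1 in left_pairs:
        for b0, b1 in right_pairs:
            lo, hi = max(a0, b0), min(a1, b1)
            if hi > lo:
                out.append((lo, hi))
    return out


def generate_subject(
    profile: GaitProfile, seed=0, subject_id: str = "S000"
) -> Tuple[GRFSeries, GRFSeries, GroundTruth]:
    """One subject's left/right GRF series plus full ground truth."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    schedule = generate_stride_schedule(profile, rng)
    fs_hz = profile.sampling_rate_hz
    n_samp = int(round(profile.duration_s * fs_hz))
    n = schedule.n_strides

    force_scale = np.ones(n)
    force_scale[schedule.turn_stride_idx] = 0.8

    truth_lm: Dict[str, np.ndarray] = {}
    truth_pk: Dict[str, np.ndarray] = {}
    series = {}
    for side, fs_t, to_t in (
        (LEFT, schedule.left_fs, schedule.left_to),
        (RIGHT, schedule.right_fs, schedule.right_to),
    ):
        lm, pk = _jitter_mshape(profile, rng, n, force_scale)
        buf = np.zeros(n_samp)
        _render_leg(buf, fs_t[:-1], to_t, lm, pk, fs_hz)
        if profile.noise_sd_bw > 0:
            buf += rng.normal(0.0, profile.noise_sd_bw, size=n_samp)
        series[side] = GRFSeries(
            samples=buf, sampling_rate_hz=fs_hz, side=side, units="bw", subject_id=subject_id
        )
        truth_lm[side] = lm
        truth_pk[side] = pk

    n_steps = int(schedule.left_fs.size + schedule.right_fs.size)
    truth = GroundTruth(
        schedule=schedule,
        stride_s={
            LEFT: np.diff(schedule.left_fs),
            RIGHT: np.diff(schedule.right_fs),
        },
        stance_s={
            LEFT: schedule.left_to - schedule.left_fs[:-1],
            RIGHT: schedule.right_to - schedule.right_fs[:-1],
        },
        swing_s={
            LEFT: schedule.left_fs[1:] - schedule.left_to,
            RIGHT: schedule.right_fs[1:] - schedule.right_to,
        },
        dst_s=_true_dst(schedule),
        landmark_fractions=truth_lm,
        peak_magnitudes_bw=truth_pk,
        turn_stride_idx=schedule.turn_stride_idx,
        n_steps=n_steps,
        distance_m=n_steps * profile.step_length_m,
    )
    return series[LEFT], series[RIGHT], truth


# ---------------------------------------------------------------------------
# Cohort assembly

# Demographic sampling centers (median, sd) per group; sex as P(female).
_DEMOGRAPHICS = {
    "YC": {"age": (29.5, 3.63), "weight": (68.0, 9.28), "height": (1.68, 0.08), "p_f": 7 / 16},
    "AMC": {"age": (56.5, 12.4), "weight": (70.0, 11.03), "height": (1.70, 0.07), "p_f": 4 / 12},
    "PD": {"age": (57.0, 7.84), "weight": (81.0, 12.92), "height": (1.75, 0.09), "p_f": 1 / 11},
}

# Clinical covariate centers for PD (median, sd).
_CLINICAL = {"updrs": (15.0, 4.28), "mmse": (29.0, 1.63), "ledd": (400.0, 327.0), "dur": (4.0, 1.8)}


@dataclass
class Cohort:
    subjects: List[SubjectRecord]
    series: Dict[str, Tuple[GRFSeries, GRFSeries]]  # subject_id -> (left, right)
    truths: Dict[str, GroundTruth]
    profiles: Dict[str, GaitProfile]
    seed: int = 0

    def manifest_rows(self) -> List[dict]:
        rows = []
        for s in self.subjects:
            t = self.truths[s.subject_id]
            row = {
                "subject_id": s.subject_id,
                "group": s.group_label,
                "age_years": s.age_years,
                "sex": s.sex,
                "weight_kg": s.weight_kg,
                "height_m": s.height_m,
                "bmi_kg_m2": s.bmi_kg_m2,
                "distance_m": t.distance_m,
                "duration_s": self.series[s.subject_id][0].duration_s,
                "sampling_rate_hz": self.series[s.subject_id][0].sampling_rate_hz,
            }
            if s.clinical is not None:
                row.update(
                    updrs_iii=s.clinical.updrs_iii,
                    mmse=s.clinical.mmse,
                    ledd_mg=s.clinical.ledd_mg,
                    disease_duration_years=s.clinical.disease_duration_years,
                    affected_side=s.clinical.affected_side,
                )
            rows.append(row)
        return rows


def _truncated_normal(rng, mean, sd, low, high=np.inf):
    for _ in range(100):
        x = rng.normal(mean, sd)
        if low < x < (high if high is not None else np.inf):
            return x
    return float(np.clip(mean, low + 1e-9, high))


def _subject_profile(
    base: GaitProfile, rng: np.random.Generator, disease_duration: Optional[float]
) -> GaitProfile:
    """Between-subject variation around the group profile.

    Multiplicative jitters sized from the between-subject spread of the
    reported group tables.  For patients, double-support variability scales
    with disease duration so that clinical status genuinely predicts
    double-support-time variability.
    """
    tempo = rng.normal(1.0, 0.04)
    swing_common = rng.normal(1.0, 0.03)
    asym = rng.normal(1.0, base.swing_asym_subject_sd, size=2)  # per-leg asymmetry
    ds_scale = float(rng.lognormal(0.0, 0.25))
    if disease_duration is not None:
        ds_scale *= max(0.3, 1.0 + 0.12 * (disease_duration - _CLINICAL["dur"][0]))
    return replace(
        base,
        stride_time_mean_s=tuple(np.array(base.stride_time_mean_s) * tempo),
        swing_time_mean_s=tuple(
            np.array(base.swing_time_mean_s) * tempo * swing_common * asym
        ),
        double_support_sd_s=base.double_support_sd_s * ds_scale,
        phase_offset_deg=base.phase_offset_deg
        + rng.normal(0.0, base.phase_offset_subject_sd_deg),
        phase_sd_deg=base.phase_sd_deg * float(rng.lognormal(0.0, 0.2)),
        peak_magnitudes_bw=tuple(
            np.maximum(np.array(base.peak_magnitudes_bw) * rng.normal(1.0, 0.06, size=3), 0.1)
        ),
        step_length_m=max(0.3, rng.normal(base.step_length_m, 0.05)),
    )


def generate_cohort(
    n_yc: int = 16,
    n_amc: int = 12,
    n_pd: int = 11,
    profiles: Optional[Dict[str, GaitProfile]] = None,
    seed: int = 0,
    subject_variation: bool = True,
) -> Cohort:
    """Synthetic study cohort: subjects, two GRF series each, ground truth.

    ``subject_variation`` adds between-subject spread around each group
    profile (see ``_subject_profile``); disable it to give every subject in a
    group the exact group profile (e.g. for zero-variance oracle checks).
    """
    counts = {"YC": n_yc, "AMC": n_amc, "PD": n_pd}
    if any(v < 0 for v in counts.values()) or all(v == 0 for v in counts.values()):
        raise ValueError("group sizes must be >= 0 with at least one non-empty group")
    profiles = dict(default_profiles() if profiles is None else profiles)
    rng = np.random.default_rng(seed)

    subjects: List[SubjectRecord] = []
    series: Dict[str, Tuple[GRFSeries, GRFSeries]] = {}
    truths: Dict[str, GroundTruth] = {}
    idx = 0
    for group in ("YC", "AMC", "PD"):
        demo = _DEMOGRAPHICS[group]
        for _ in range(counts[group]):
            sid = f"S{idx:03d}"
            idx += 1
            clinical = None
            duration_y = None
            if group == "PD":
                duration_y = _truncated_normal(rng, *_CLINICAL["dur"], 0.5)
                clinical = ClinicalStatus(
                    updrs_iii=round(_truncated_normal(rng, *_CLINICAL["updrs"], 1.0)),
                    mmse=min(30.0, round(_truncated_normal(rng, *_CLINICAL["mmse"], 10.0))),
                    ledd_mg=_truncated_normal(rng, *_CLINICAL["ledd"], 50.0),
                    disease_duration_years=duration_y,
                    affected_side=LEFT if rng.random() < 4 / 11 else RIGHT,
                )
            weight = _truncated_normal(rng, *demo["weight"], 35.0)
            height = _truncated_normal(rng, *demo["height"], 1.2)
            rec = SubjectRecord(
                subject_id=sid,
                group_label=group,
                age_years=_truncated_normal(rng, *demo["age"], 18.0),
                sex="F" if rng.random() < demo["p_f"] else "M",
                weight_kg=weight,
                height_m=height,
                clinical=clinical,
            )
            if subject_variation:
                prof = _subject_profile(profiles[group], rng, duration_y)
            else:
                prof = profiles[group]
            left, right, truth = generate_subject(prof, rng, subject_id=sid)
            subjects.append(rec)
            series[sid] = (left, right)
            truths[sid] = truth
    if counts["PD"] == 0 and any(s.clinical is not None for s in subjects):
        warnings.warn("clinical fields present without a PD group")
    return Cohort(subjects=subjects, series=series, truths=truths, profiles=profiles, seed=seed)


def sensor_grid_from_series(series: GRFSeries, shape: Tuple[int, int] = (3, 3), seed: int = 0):
    """Coarse per-sensor pressure frames whose sum reproduces ``series``.

    Only exists so the grid-summing reader can be exercised; it spreads each
    total-force sample over a small grid with a random but fixed spatial
    weighting (a stand-in for a real pressure map, not a model of one).
    """
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(shape[0] * shape[1])).reshape(shape)
    frames = series.samples[:, None, None] * w[None, :, :]
    from .io import SensorGridFrameSet

    return SensorGridFrameSet(
        frames=frames, sampling_rate_hz=series.sampling_rate_hz, side=series.side
    )
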