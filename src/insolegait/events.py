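"""Gait event detection from one foot's vertical GRF.

The pipeline is: moving-average smoothing, threshold-based contact detection
with local-minimum refinement of foot-strike/toe-off, and running-median
outlier flagging of stride durations (turn strides at walkway ends and the
stride immediately following each).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import median_filter

from .core import GRFSeries

__all__ = ["GaitEvents", "moving_average", "detect_contacts", "remove_outlier_strides"]


@dataclass
class GaitEvents:
    """Ordered foot-strike / toe-off pairs for one foot.

    Contact pair i is ``(foot_strike_s[i], toe_off_s[i])``.  Stride i is the
    interval between foot-strikes i and i+1, so there is one fewer stride than
    contact pairs; ``valid[i]`` and ``reasons[i]`` refer to stride i.
    """

    side: str
    foot_strike_s: np.ndarray
    toe_off_s: np.ndarray
    sampling_rate_hz: float
    valid: Optional[np.ndarray] = None
    reasons: List[Optional[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.foot_strike_s = np.asarray(self.foot_strike_s, dtype=float)
        self.toe_off_s = np.asarray(self.toe_off_s, dtype=float)
        if self.foot_strike_s.shape != self.toe_off_s.shape:
            raise ValueError("foot_strike_s and toe_off_s must have equal length")
        if np.any(self.toe_off_s <= self.foot_strike_s):
            raise ValueError("each toe-off must follow its foot-strike")
        if self.n_pairs > 1:
            if np.any(np.diff(self.foot_strike_s) <= 0):
                raise ValueError("foot-strikes must be strictly increasing")
            if np.any(self.foot_strike_s[1:] <= self.toe_off_s[:-1]):
                raise ValueError("contact pairs must alternate with swing")
        if self.valid is None:
            self.valid = np.ones(self.n_strides, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.size != self.n_strides:
                raise ValueError("valid must have one flag per stride")
        if not self.reasons:
            self.reasons = [None] * self.n_strides

    @property
    def n_pairs(self) -> int:
        return int(self.foot_strike_s.size)

    @property
    def n_strides(self) -> int:
        return max(0, self.n_pairs - 1)

    def stride_times(self) -> np.ndarray:
        return np.diff(self.foot_strike_s)

    def stance_times(self) -> np.ndarray:
        """Stance of stride i: foot-strike i to toe-off i."""
        return self.toe_off_s[:-1] - self.foot_strike_s[:-1]

    def swing_times(self) -> np.ndarray:
        """Swing of stride i: toe-off i to foot-strike i+1."""
        return self.foot_strike_s[1:] - self.toe_off_s[:-1]

    def n_valid(self) -> int:
        return int(np.sum(self.valid))

    def to_rows(self) -> List[dict]:
        return [
            {
                "side": self.side,
                "stride_index": i,
                "foot_strike_s": float(self.foot_strike_s[i]),
                "toe_off_s": float(self.toe_off_s[i]),
                "valid": bool(self.valid[i]) if i < self.n_strides else None,
                "reason": self.reasons[i] if i < self.n_strides else None,
            }
            for i in range(self.n_pairs)
        ]


def moving_average(series: GRFSeries, window: int = 5) -> GRFSeries:
    """Centered moving average; edges average over the available samples."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 1 or window > series.n_samples:
        raise ValueError("window must be in [1, len(series)]")
    kernel = np.ones(window)
    num = np.convolve(series.samples, kernel, mode="same")
    den = np.convolve(np.ones(series.n_samples), kernel, mode="same")
    return series.with_samples(num / den)


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Inclusive (start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = np.where(d == 1)[0] + 1
    stops = np.where(d == -1)[0]
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        stops = np.concatenate((stops, [mask.size - 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def _refine(x: np.ndarray, est: int, radius: int, threshold: float, kind: str) -> int:
    """Refine a threshold crossing to the contact onset/offset sample.

    Two estimators are combined.  (1) Ratio walk: the force onset is locally
    quadratic in time, so on the loading edge the ratio of consecutive
    (smoothed) samples is scale-free — about 0.36 one sample inside the
    contact but 0.2 just outside it; walking outward from the crossing while
    the next sample stays above ``max(0.3 x, 0.1 threshold)`` stops at the
    contact sample itself, independent of stance duration and peak amplitude.
    (2) Flat-minimum candidates: window samples within 0.25 x threshold of the
    window minimum, i.e. the near-zero plateau (a plain argmin is ill-posed
    there: the unloaded baseline is flat, identically zero without noise).
    The walk result is kept when it lands on the plateau; otherwise — single
    noisy samples can stop the walk early on the loaded edge — the latest
    (foot-strike) or earliest (toe-off) plateau sample is used instead.
    """
    lo = max(0, est - radius)
    hi = min(x.size - 1, est + radius)
    floor = 0.1 * threshold
    j = est
    if kind == "fs":
        while j - 1 >= lo and x[j - 1] >= max(0.3 * x[j], floor):
            j -= 1
    else:
        while j + 1 <= hi and x[j + 1] >= max(0.3 * x[j], floor):
            j += 1
    w = x[lo : hi + 1]
    cand = lo + np.where(w <= w.min() + 0.25 * threshold)[0]
    if j in cand:
        return j
    return int(cand[-1] if kind == "fs" else cand[0])


def detect_contacts(
    series: GRFSeries,
    contact_threshold_frac: float = 0.05,
    min_contact_s: float = 0.2,
    min_swing_s: float = 0.1,
    refine_radius: int = 3,
) -> GaitEvents:
    """Foot-strike/toe-off detection on a smoothed GRF series.

    The contact threshold is ``contact_threshold_frac`` times the median
    supra-zero peak force.  Foot-strike is the last sub-threshold sample
    before each supra-threshold run and toe-off the first one after it, each
    refined to the neighbouring local minimum (see ``_refine``).  Runs shorter
    than ``min_contact_s`` are treated as noise; sub-threshold dips shorter
    than ``min_swing_s`` are bridged.
    """
    x = series.samples
    fs_hz = series.sampling_rate_hz
    peak = float(np.max(x)) if x.size else 0.0
    if peak <= 0:
        return GaitEvents(series.side, np.array([]), np.array([]), fs_hz)

    rough = _runs(x > contact_threshold_frac * peak)
    run_peaks = [float(np.max(x[a : b + 1])) for a, b in rough]
    threshold = contact_threshold_frac * float(np.median(run_peaks))

    mask = x > threshold
    if float(np.mean(mask)) > 0.9:
        raise ValueError("no swing phase detected: force never drops below threshold")
    # bridge short sub-threshold dips (noise inside stance)
    max_gap = int(round(min_swing_s * fs_hz))
    for a, b in _runs(~mask):
        if a > 0 and b < mask.size - 1 and (b - a + 1) < max_gap:
            mask[a : b + 1] = True
    runs = [(a, b) for a, b in _runs(mask) if (b - a + 1) >= int(round(min_contact_s * fs_hz))]
    # drop contacts clipped by the recording window
    runs = [(a, b) for a, b in runs if a > 0 and b < mask.size - 1]

    if not runs:
        return GaitEvents(series.side, np.array([]), np.array([]), fs_hz)

    fs_idx, to_idx = [], []
    for a, b in runs:
        i_fs = _refine(x, a - 1, refine_radius, threshold, "fs")
        i_to = _refine(x, b + 1, refine_radius, threshold, "to")
        if i_to <= i_fs:
            continue
        if fs_idx and i_fs <= to_idx[-1]:  # refinement collided with previous contact
            continue
        fs_idx.append(i_fs)
        to_idx.append(i_to)

    if len(fs_idx) < 2:
        raise ValueError("fewer than 2 strides detected")
    return GaitEvents(
        side=series.side,
        foot_strike_s=np.array(fs_idx) / fs_hz,
        toe_off_s=np.array(to_idx) / fs_hz,
        sampling_rate_hz=fs_hz,
    )


def remove_outlier_strides(
    events: GaitEvents, window: int = 9, mad_factor: float = 3.0
) -> GaitEvents:
    """Flag turn strides: running-median filter on stride durations.

    Stride durations are compared to a centered running median over
    ``window`` strides; strides deviating by more than ``mad_factor`` times
    the MAD of those deviations are invalidated, along with the stride
    immediately following each (the recovery step after a turn).  Nothing is
    deleted — flags are set and reasons recorded.  Deterministic and
    idempotent: the statistics are always computed over all strides.
    """
    d = events.stride_times()
    if d.size < window:
        warnings.warn("fewer strides than filter window; outlier filtering skipped")
        return events
    # 'mirror' edge handling: 'nearest' would pad with the edge value itself,
    # letting an outlier in the first/last stride hide inside its own window
    runmed = median_filter(d, size=window, mode="mirror")
    dev = np.abs(d - runmed)
    # sigma-consistent scaled MAD (x1.4826), the conventional "k MADs" rule:
    # mad_factor is then in sd units, keeping the false-flag rate of ordinary
    # stride-to-stride variability negligible; floored at half a sample
    scale = max(1.4826 * float(np.median(dev)), 0.5 / events.sampling_rate_hz)
    outlier = dev > mad_factor * scale

    valid = events.valid.copy()
    reasons = list(events.reasons)
    for i in np.where(outlier)[0]:
        valid[i] = False
        if reasons[i] is None:
            reasons[i] = "outlier stride duration"
        j = i + 1
        if j < valid.size and not outlier[j]:
            valid[j] = False
            if reasons[j] is None:
                reasons[j] = "follows outlier stride"
    return GaitEvents(
        side=events.side,
        foot_strike_s=events.foot_strike_s,
        toe_off_s=events.toe_off_s,
        sampling_rate_hz=events.sampling_rate_hz,
        valid=valid,
        reasons=reasons,
    )
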