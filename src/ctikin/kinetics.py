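"""Per-point and per-segment CTI motion analysis.

Definitions
-----------
trajectory differential
    Position change of one contour point between consecutive frames,
    ``delta_n = pos(t_n) - pos(t_{n-1})``; a track of F frames yields
    F - 1 differentials whose sum telescopes to final - initial position.
instantaneous velocity
    Differential divided by the frame interval, mm/s.
displacement
    Net displacement is final - initial position.  Because the cine is
    cyclic (the wall returns to its start), net displacement is close to
    zero and uninformative; segmental summaries therefore use the
    maximum displacement relative to the first frame,
    ``max_n |coord(t_n) - coord(t_1)|`` per axis and for the 2-D norm.
    The first frame is the one anchor every cine defines.
segments
    The CTI is divided into five contiguous segments of near-equal point
    count, segment 1 at the Eustachian-valve/IVC end and segment 5 at
    the TV hinge end.  When the point count is not divisible by five the
    larger runs are placed TV-side, where motion is largest and finer
    sampling is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .io import ContourCine

#: dt fallback: one cardiac cycle at the cohort's mean heart rate
#: (68 bpm) divided by the frame count.
DEFAULT_HEART_RATE_BPM = 68.0


def default_frame_interval(n_frames: int, heart_rate_bpm: float = DEFAULT_HEART_RATE_BPM) -> float:
    return 60.0 / heart_rate_bpm / n_frames


def trajectory_differentials(track: np.ndarray) -> np.ndarray:
    """Frame-to-frame position deltas of one point track, shape (F-1, 2)."""
    t = np.asarray(track, dtype=float).reshape(-1, 2)
    if len(t) < 2:
        raise DegenerateInputError("trajectory_differentials: need >= 2 frames")
    return np.diff(t, axis=0)


def instantaneous_velocity(track: np.ndarray, dt: float) -> np.ndarray:
    """Trajectory differentials divided by the frame interval, mm/s."""
    if dt <= 0:
        raise DegenerateInputError("instantaneous_velocity: dt must be > 0")
    return trajectory_differentials(track) / dt


@dataclass
class PointDisplacement:
    net: np.ndarray          # final - initial, shape (2,)
    max_ap: float            # max_n |x(t_n) - x(t_1)|
    max_cc: float            # max_n |y(t_n) - y(t_1)|
    max_euclid: float        # max_n ||pos(t_n) - pos(t_1)||


def point_displacement(track: np.ndarray) -> PointDisplacement:
    t = np.asarray(track, dtype=float).reshape(-1, 2)
    if len(t) < 2:
        raise DegenerateInputError("point_displacement: need >= 2 frames")
    dev = t - t[0]
    return PointDisplacement(
        net=t[-1] - t[0],
        max_ap=float(np.abs(dev[:, 0]).max()),
        max_cc=float(np.abs(dev[:, 1]).max()),
        max_euclid=float(np.linalg.norm(dev, axis=1).max()),
    )


def segment_partition(cine: ContourCine, n_segments: int = 5) -> list[np.ndarray]:
    """Contiguous partition of the CTI point indices into segments.

    Returns absolute point-index arrays, segment 1 first (EV/IVC end).
    With remainder ``r``, the ``r`` largest runs sit nearest the TV.
    """
    idx = cine.cti_point_indices
    return partition_indices(idx, n_segments)


def partition_indices(indices: np.ndarray, n_segments: int = 5) -> list[np.ndarray]:
    indices = np.asarray(indices)
    n = len(indices)
    if n < n_segments:
        raise DegenerateInputError(
            f"segment_partition: {n} CTI points cannot form {n_segments} segments"
        )
    base, rem = divmod(n, n_segments)
    sizes = [base] * (n_segments - rem) + [base + 1] * rem
    out, pos = [], 0
    for s in sizes:
        out.append(indices[pos : pos + s])
        pos += s
    return out


@dataclass
class SegmentSummary:
    segment: int                     # 1 (EV/IVC end) .. 5 (TV end)
    point_indices: np.ndarray
    mean_max_disp_ap_mm: float
    mean_max_disp_cc_mm: float
    mean_max_disp_euclid_mm: float
    mean_net_disp_mm: float          # mean over points of ||net||


@dataclass
class SegmentKinetics:
    """Segmental displacement summaries plus raw per-point kinetics."""

    patient_id: str
    dt: float
    segments: list[SegmentSummary]
    cti_point_indices: np.ndarray
    differentials: np.ndarray        # (P_cti, F-1, 2) mm
    velocities: np.ndarray           # (P_cti, F-1, 2) mm/s

    def segment_of_point(self, abs_index: int) -> int:
        for seg in self.segments:
            if abs_index in seg.point_indices:
                return seg.segment
        raise KeyError(abs_index)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": self.patient_id,
                "segment": s.segment,
                "n_points": len(s.point_indices),
                "mean_max_disp_ap_mm": s.mean_max_disp_ap_mm,
                "mean_max_disp_cc_mm": s.mean_max_disp_cc_mm,
                "mean_max_disp_euclid_mm": s.mean_max_disp_euclid_mm,
                "mean_net_disp_mm": s.mean_net_disp_mm,
            }
            for s in self.segments
        ]
        return pd.DataFrame(rows)


def segment_kinetics(
    cine: ContourCine,
    dt: float | None = None,
    n_segments: int = 5,
) -> SegmentKinetics:
    """Per-segment motion summary of one cine.

    ``dt`` falls back to the cine's own frame interval, then to one
    cycle at 68 bpm divided by the frame count.
    """
    if dt is None:
        dt = cine.frame_interval or default_frame_interval(cine.n_frames)
    if dt <= 0:
        raise DegenerateInputError("segment_kinetics: dt must be > 0")
    cti = cine.cti_frames()                      # (F, P_cti, 2)
    dev = cti - cti[0]                           # relative to frame 1
    max_ap = np.abs(dev[:, :, 0]).max(axis=0)    # (P_cti,)
    max_cc = np.abs(dev[:, :, 1]).max(axis=0)
    max_eu = np.linalg.norm(dev, axis=2).max(axis=0)
    net = np.linalg.norm(cti[-1] - cti[0], axis=1)

    diffs = np.diff(cti, axis=0)                 # (F-1, P_cti, 2)
    diffs = np.moveaxis(diffs, 0, 1)             # (P_cti, F-1, 2)

    parts = segment_partition(cine, n_segments)
    start = cine.cti_index_range[0]
    summaries = []
    for k, seg_idx in enumerate(parts, start=1):
        loc = seg_idx - start                    # local positions in CTI arrays
        summaries.append(
            SegmentSummary(
                segment=k,
                point_indices=seg_idx,
                mean_max_disp_ap_mm=float(max_ap[loc].mean()),
                mean_max_disp_cc_mm=float(max_cc[loc].mean()),
                mean_max_disp_euclid_mm=float(max_eu[loc].mean()),
                mean_net_disp_mm=float(net[loc].mean()),
            )
        )
    return SegmentKinetics(
        patient_id=cine.patient_id,
        dt=float(dt),
        segments=summaries,
        cti_point_indices=cine.cti_point_indices,
        differentials=diffs,
        velocities=diffs / dt,
    )


def kinetics_table(kinetics: Sequence[SegmentKinetics]) -> pd.DataFrame:
    """Long-format per-segment summary over a cohort."""
    return pd.concat([k.summary_frame() for k in kinetics], ignore_index=True)


def kinetics_wide_table(kinetics: Sequence[SegmentKinetics]) -> pd.DataFrame:
    """One row per patient with seg{k}_{ap,cc,euclid} columns, patient-indexed."""
    rows = {}
    for k in kinetics:
        row = {}
        for s in k.segments:
            row[f"seg{s.segment}_max_ap_mm"] = s.mean_max_disp_ap_mm
            row[f"seg{s.segment}_max_cc_mm"] = s.mean_max_disp_cc_mm
            row[f"seg{s.segment}_max_euclid_mm"] = s.mean_max_disp_euclid_mm
        rows[k.patient_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "patient_id"
    return out


# ---------------------------------------------------------------------
# motion-pattern classification
# ---------------------------------------------------------------------

@dataclass
class MotionThresholds:
    """Cut-offs for the four motion phenotypes.

    Amplitude cut-offs default to cohort quartiles (see
    :func:`cohort_motion_thresholds`); the axis-dominance ratios default
    to 2:1 either way.
    """

    t_low_mm: float
    t_high_mm: float
    r_lo: float = 0.5
    r_hi: float = 2.0


@dataclass
class MotionPattern:
    label: str                      # hyperkinetic | hypokinetic | ap_dominant | cc_dominant
    amplitude_mm: float             # mean over segments of mean max Euclidean displacement
    ap_cc_ratio: float


def classify_motion_pattern(
    sk: SegmentKinetics, thresholds: MotionThresholds
) -> MotionPattern:
    """Assign one of four wall-motion phenotypes to a patient.

    Hypokinetic below ``t_low_mm``, hyperkinetic above ``t_high_mm``;
    otherwise the prevailing axis decides, with anterior-posterior the
    default when neither axis dominates (AP motion dominates the cohort).
    """
    amp = float(np.mean([s.mean_max_disp_euclid_mm for s in sk.segments]))
    ap = float(np.mean([s.mean_max_disp_ap_mm for s in sk.segments]))
    cc = float(np.mean([s.mean_max_disp_cc_mm for s in sk.segments]))
    ratio = ap / cc if cc > 0 else np.inf
    if amp < thresholds.t_low_mm:
        label = "hypokinetic"
    elif amp > thresholds.t_high_mm:
        label = "hyperkinetic"
    elif ratio < thresholds.r_lo:
        label = "cc_dominant"
    else:
        label = "ap_dominant"
    return MotionPattern(label=label, amplitude_mm=amp, ap_cc_ratio=ratio)


def cohort_motion_thresholds(
    kinetics: Sequence[SegmentKinetics],
    q_low: float = 0.25,
    q_high: float = 0.75,
) -> MotionThresholds:
    """Amplitude cut-offs at cohort quantiles (defaults: quartiles)."""
    amps = [
        np.mean([s.mean_max_disp_euclid_mm for s in k.segments]) for k in kinetics
    ]
    return MotionThresholds(
        t_low_mm=float(np.quantile(amps, q_low)),
        t_high_mm=float(np.quantile(amps, q_high)),
    )
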