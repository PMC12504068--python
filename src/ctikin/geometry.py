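"""CTI geometric measurements.

The cavotricuspid isthmus is measured per frame as an ordered 2-D
polyline.  Four scalar descriptors summarise a cine:

* curvilinear length — cumulated Euclidean distance between consecutive
  CTI points (the primary length used throughout the kinetic analysis);
* linear length — Euclidean distance between the two CTI endpoints
  (IVC side and TV hinge side), reported in RA diastole;
* pouch depth — maximum perpendicular distance of interior CTI points
  from the straight endpoint-to-endpoint line, reported in RA diastole;
* normalized elongation (NE) — (diastolic - systolic curvilinear
  length) / systolic curvilinear length, a dimensionless strain-like
  compliance measure.

RA systole and diastole are identified per patient as the frames of
minimal and maximal CTI curvilinear length (ties resolved to the
earliest frame).  That criterion is a declared convention: it is the
one choice that makes the elongation and NE definitions self-consistent
without access to ECG gating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .io import ContourCine


def curvilinear_length(points: np.ndarray) -> float:
    """Cumulated distance between consecutive points; 0 for a single point."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        pts = pts.reshape(-1, 2)
    if len(pts) == 0:
        raise DegenerateInputError("curvilinear_length: empty point sequence")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def linear_length(points: np.ndarray) -> float:
    """Euclidean distance between the first and last point of the CTI."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise DegenerateInputError("linear_length: need at least 2 points")
    return float(np.linalg.norm(pts[-1] - pts[0]))


def pouch_depth(points: np.ndarray) -> float:
    """Maximum perpendicular distance of interior points from the endpoint line.

    The line is the infinite line through the first and last CTI point
    (the same line that defines the linear length).  Coincident endpoints
    leave the line undefined.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise DegenerateInputError("pouch_depth: need at least 3 points")
    a, b = pts[0], pts[-1]
    chord = b - a
    norm = np.linalg.norm(chord)
    if norm == 0.0:
        raise DegenerateInputError("pouch_depth: coincident endpoints")
    rel = pts[1:-1] - a
    cross = rel[:, 0] * chord[1] - rel[:, 1] * chord[0]
    return float(np.abs(cross).max() / norm)


def select_phase_frames(cine: ContourCine) -> tuple[int, int]:
    """(systole_frame, diastole_frame) from CTI curvilinear length extremes.

    Systole is the frame of minimal CTI length (maximal atrial
    contraction), diastole the frame of maximal length; ties go to the
    earliest frame index.
    """
    cti = cine.cti_frames()
    lengths = np.linalg.norm(np.diff(cti, axis=1), axis=2).sum(axis=1)
    return int(np.argmin(lengths)), int(np.argmax(lengths))


@dataclass
class CTIGeometry:
    """Per-patient geometric summary of one contour cine."""

    patient_id: str
    systole_frame: int
    diastole_frame: int
    curvilinear_systolic_mm: float
    curvilinear_diastolic_mm: float
    linear_diastolic_mm: float
    pouch_depth_mm: float
    elongation_mm: float
    ne: float
    phase_criterion: str = "cti-curvilinear-length-extremes"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_geometry(cine: ContourCine) -> CTIGeometry:
    """All geometric descriptors of one cine.

    Pouch depth and linear length are measured on the diastolic frame.
    A zero systolic curvilinear length leaves NE undefined and raises
    :class:`DegenerateInputError`.
    """
    sys_f, dia_f = select_phase_frames(cine)
    cti = cine.cti_frames()
    l_sys = curvilinear_length(cti[sys_f])
    l_dia = curvilinear_length(cti[dia_f])
    if l_sys <= 0.0:
        raise DegenerateInputError(
            f"patient {cine.patient_id!r}: systolic curvilinear length is 0, "
            "NE undefined"
        )
    elong = l_dia - l_sys
    return CTIGeometry(
        patient_id=cine.patient_id,
        systole_frame=sys_f,
        diastole_frame=dia_f,
        curvilinear_systolic_mm=l_sys,
        curvilinear_diastolic_mm=l_dia,
        linear_diastolic_mm=linear_length(cti[dia_f]),
        pouch_depth_mm=pouch_depth(cti[dia_f]),
        elongation_mm=elong,
        ne=elong / l_sys,
    )


def geometry_table(cines: Sequence[ContourCine]) -> pd.DataFrame:
    """Geometry of a collection of cines as a patient-indexed DataFrame."""
    rows = [compute_geometry(c).as_dict() for c in cines]
    return pd.DataFrame(rows).set_index("patient_id")


def summarize_geometry(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean/SD and median/IQR of each geometric field, 1 decimal."""
    cols = [
        "curvilinear_systolic_mm",
        "curvilinear_diastolic_mm",
        "linear_diastolic_mm",
        "pouch_depth_mm",
        "elongation_mm",
        "ne",
    ]
    out = pd.DataFrame(
        {
            "mean": table[cols].mean(),
            "sd": table[cols].std(ddof=1),
            "median": table[cols].median(),
            "iqr": table[cols].quantile(0.75) - table[cols].quantile(0.25),
        }
    )
    return out.round(1)


@dataclass
class MedianSplitResult:
    field: str
    threshold: float
    low: pd.DataFrame        # rows with value < threshold
    high: pd.DataFrame       # rows with value >= threshold
    ne_low_mean: float
    ne_low_sd: float
    ne_high_mean: float
    ne_high_sd: float
    excluded: tuple[str, ...]


def median_split(
    cohort: pd.DataFrame,
    field: str,
    threshold: float | str = "median",
    exclude: Sequence[str] = (),
) -> MedianSplitResult:
    """Split the cohort at a threshold on ``field`` and summarise NE per group.

    ``threshold="median"`` uses the cohort median (midpoint of the two
    central order statistics for even n).  The split rule is strict:
    ``value < threshold`` goes low, ``value >= threshold`` goes high.
    Patients on the ``exclude`` list (e.g. a flagged NE outlier) are
    removed before the median is computed and appear in neither group.
    """
    if field not in cohort.columns:
        raise KeyError(f"median_split: no column {field!r}")
    data = cohort.drop(index=[p for p in exclude if p in cohort.index])
    if data.empty:
        raise DegenerateInputError("median_split: empty cohort")
    if threshold == "median":
        thr = float(data[field].median())
    else:
        thr = float(threshold)
    low = data[data[field] < thr]
    high = data[data[field] >= thr]

    def _stats(df: pd.DataFrame) -> tuple[float, float]:
        if "ne" not in df.columns or df.empty:
            return float("nan"), float("nan")
        return float(df["ne"].mean()), float(df["ne"].std(ddof=1))

    lo_m, lo_s = _stats(low)
    hi_m, hi_s = _stats(high)
    return MedianSplitResult(
        field=field,
        threshold=thr,
        low=low,
        high=high,
        ne_low_mean=lo_m,
        ne_low_sd=lo_s,
        ne_high_mean=hi_m,
        ne_high_sd=hi_s,
        excluded=tuple(exclude),
    )
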