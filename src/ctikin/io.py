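"""Contour-cine and clinical-covariate data model and CSV round trip.

A contour cine is one patient's right-atrial (RA) wall contour followed
over one cardiac cycle: ``F`` frames (default 25), each an ordered set of
``P`` labelled 2-D points in millimetres (default 49: one critical point
near the inferior vena cava plus 24 points on each side, hence odd ``P``).
The x axis is anterior(+)/posterior(-), the y axis cranial(+)/caudal(-).

Only a contiguous index range of those points constitutes the
cavotricuspid isthmus (CTI); which indices these are is explicit
per-patient metadata, by default the span from the IVC midpoint index
``(P - 1) // 2`` to the tricuspid-valve end of the contour.

Files are long-format UTF-8 CSV with '.' decimals:

* contours:  ``patient_id,frame,point_index,x_mm,y_mm``
* clinical:  ``patient_id,ec_within_12h,smoker,dyslipidaemia,bmi,
  nyha_class,age,procedural_time_min,ablation_duration_min``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ClinicalValidationError,
    ContourValidationError,
    MalformedInputError,
)

CONTOUR_COLUMNS = ["patient_id", "frame", "point_index", "x_mm", "y_mm"]
CLINICAL_COLUMNS = [
    "patient_id",
    "ec_within_12h",
    "smoker",
    "dyslipidaemia",
    "bmi",
    "nyha_class",
    "age",
    "procedural_time_min",
    "ablation_duration_min",
]

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}

#: Minimum CTI points for a cine to be measurable at all (a length needs
#: two points).  Segment-level analyses impose their own, stricter
#: requirement at partition time.
MIN_CTI_POINTS = 2


def default_cti_range(n_points: int) -> tuple[int, int]:
    """Default CTI span: IVC midpoint index to the TV-side contour end.

    Half-open ``(start, stop)`` over point indices.  The midpoint
    convention follows the contouring layout of one critical point near
    the IVC with an equal number of points on each side.
    """
    return ((n_points - 1) // 2, n_points)


@dataclass
class ContourCine:
    """One patient's RA contour cine.

    Parameters
    ----------
    patient_id
        Cohort-unique identifier.
    frames
        Array of shape ``(F, P, 2)`` in mm; ``frames[n, i]`` is point
        ``i`` at cine frame ``n``.  Frames are in temporal order, points
        in contour order.
    cti_index_range
        Half-open ``(start, stop)`` identifying the CTI sub-contour,
        ordered from the Eustachian-valve/IVC end to the TV hinge end.
    frame_interval
        Seconds between consecutive frames.  Optional; velocity
        computations fall back to an explicit ``dt``.
    """

    patient_id: str
    frames: np.ndarray
    cti_index_range: tuple[int, int] | None = None
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.cti_index_range is None:
            self.cti_index_range = default_cti_range(self.frames.shape[1])
        else:
            self.cti_index_range = (
                int(self.cti_index_range[0]),
                int(self.cti_index_range[1]),
            )
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        f = self.frames
        if f.ndim != 3 or f.shape[2] != 2:
            raise ContourValidationError(
                f"patient {self.patient_id!r}: frames must have shape "
                f"(F, P, 2), got {f.shape}"
            )
        if f.shape[0] < 2:
            raise ContourValidationError(
                f"patient {self.patient_id!r}: need at least 2 frames, "
                f"got {f.shape[0]}"
            )
        if f.shape[1] % 2 == 0:
            raise ContourValidationError(
                f"patient {self.patient_id!r}: point count must be odd "
                f"(critical IVC point plus equal flanks), got {f.shape[1]}"
            )
        if not np.isfinite(f).all():
            raise ContourValidationError(
                f"patient {self.patient_id!r}: non-finite coordinates"
            )
        start, stop = self.cti_index_range
        if not (0 <= start < stop <= f.shape[1]):
            raise ContourValidationError(
                f"patient {self.patient_id!r}: cti_index_range "
                f"({start}, {stop}) outside [0, {f.shape[1]})"
            )
        if stop - start < MIN_CTI_POINTS:
            raise ContourValidationError(
                f"patient {self.patient_id!r}: CTI needs at least "
                f"{MIN_CTI_POINTS} points, got {stop - start}"
            )
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ContourValidationError(
                f"patient {self.patient_id!r}: frame_interval must be > 0"
            )

    # -- convenience ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_points(self) -> int:
        return self.frames.shape[1]

    @property
    def cti_point_indices(self) -> np.ndarray:
        start, stop = self.cti_index_range
        return np.arange(start, stop)

    def cti_frames(self) -> np.ndarray:
        """CTI sub-contour over time, shape ``(F, P_cti, 2)``."""
        start, stop = self.cti_index_range
        return self.frames[:, start:stop, :]


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates used by the cohort analyses."""

    patient_id: str
    ec_within_12h: bool   # electrical cardioversion <= 12 h before ablation
    smoker: bool
    dyslipidaemia: bool
    bmi: float            # kg/m^2
    nyha_class: int       # 1..4
    age: float            # years
    procedural_time_min: float
    ablation_duration_min: float

    def __post_init__(self) -> None:
        if self.bmi <= 0:
            raise ClinicalValidationError(
                f"patient {self.patient_id!r}: bmi must be > 0, got {self.bmi}"
            )
        if self.nyha_class not in (1, 2, 3, 4):
            raise ClinicalValidationError(
                f"patient {self.patient_id!r}: nyha_class must be in 1..4, "
                f"got {self.nyha_class}"
            )
        for name in ("procedural_time_min", "ablation_duration_min"):
            if getattr(self, name) < 0:
                raise ClinicalValidationError(
                    f"patient {self.patient_id!r}: {name} must be >= 0"
                )


def parse_bool(token: object, *, context: str = "") -> bool:
    s = str(token).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise MalformedInputError(
        f"unknown boolean token {token!r}" + (f" ({context})" if context else "")
    )


# ---------------------------------------------------------------------
# contour CSV
# ---------------------------------------------------------------------

def read_contour_table(
    path: str | Path,
    expected_points: int | None = None,
    expected_frames: int | None = None,
    cti_index_range: tuple[int, int] | None = None,
    frame_interval: float | None = None,
) -> list[ContourCine]:
    """Read a long-format contour CSV into one :class:`ContourCine` per patient.

    Frames are sorted by frame index and points by point index.  Every
    patient must have a complete ``frames x points`` grid; a missing or
    duplicated ``(frame, point_index)`` cell raises
    :class:`MalformedInputError` naming the patient and cell, a
    non-numeric coordinate raises the same, and a point/frame count that
    disagrees with ``expected_points`` / ``expected_frames`` raises
    :class:`ContourValidationError`.
    """
    path = Path(path)
    # round_trip parsing keeps write->read bit-exact on coordinates
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")

    for col in ("frame", "point_index", "x_mm", "y_mm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[coerced.isna() & df[col].notna()]
        if len(bad):
            row = bad.iloc[0]
            raise MalformedInputError(
                f"{path}: non-numeric {col}={row[col]!r} for patient "
                f"{row['patient_id']!r}"
            )
        if coerced.isna().any():
            row = df.loc[coerced.isna()].iloc[0]
            raise MalformedInputError(
                f"{path}: empty {col} cell for patient {row['patient_id']!r}"
            )
        df[col] = coerced

    cines = []
    for pid, sub in df.groupby("patient_id", sort=True):
        dup = sub.duplicated(subset=["frame", "point_index"])
        if dup.any():
            row = sub.loc[dup].iloc[0]
            raise MalformedInputError(
                f"{path}: duplicate cell patient {pid!r} frame "
                f"{int(row['frame'])} point {int(row['point_index'])}"
            )
        frames_idx = np.sort(sub["frame"].unique()).astype(int)
        points_idx = np.sort(sub["point_index"].unique()).astype(int)
        if len(sub) != len(frames_idx) * len(points_idx):
            # locate one offending cell for the message
            have = set(zip(sub["frame"].astype(int), sub["point_index"].astype(int)))
            for fr in frames_idx:
                for pt in points_idx:
                    if (fr, pt) not in have:
                        raise MalformedInputError(
                            f"{path}: patient {pid!r} frame {fr} lacks "
                            f"point_index {pt}"
                        )
            raise MalformedInputError(f"{path}: patient {pid!r} has a ragged grid")
        if expected_frames is not None and len(frames_idx) != expected_frames:
            raise ContourValidationError(
                f"{path}: patient {pid!r} has {len(frames_idx)} frames, "
                f"expected {expected_frames}"
            )
        if expected_points is not None and len(points_idx) != expected_points:
            raise ContourValidationError(
                f"{path}: patient {pid!r} has {len(points_idx)} points, "
                f"expected {expected_points}"
            )
        wide = sub.sort_values(["frame", "point_index"])
        arr = wide[["x_mm", "y_mm"]].to_numpy(dtype=float).reshape(
            len(frames_idx), len(points_idx), 2
        )
        cines.append(
            ContourCine(
                patient_id=str(pid),
                frames=arr,
                cti_index_range=cti_index_range,
                frame_interval=frame_interval,
            )
        )
    return cines


def write_contour_table(cines: Iterable[ContourCine], path: str | Path) -> None:
    """Write cines as long-format CSV at full decimal precision.

    ``repr``-level float formatting is used so that a read/write round
    trip reproduces coordinates bit-exactly.
    """
    path = Path(path)
    chunks = []
    for cine in cines:
        F, P, _ = cine.frames.shape
        frame_col = np.repeat(np.arange(F), P)
        point_col = np.tile(np.arange(P), F)
        chunks.append(
            pd.DataFrame(
                {
                    "patient_id": cine.patient_id,
                    "frame": frame_col,
                    "point_index": point_col,
                    "x_mm": cine.frames[:, :, 0].ravel(),
                    "y_mm": cine.frames[:, :, 1].ravel(),
                }
            )
        )
    if chunks:
        out = pd.concat(chunks, ignore_index=True)
    else:
        out = pd.DataFrame(columns=CONTOUR_COLUMNS)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------
# clinical CSV
# ---------------------------------------------------------------------

def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical covariate CSV into typed records.

    Boolean columns accept ``{0, 1, true, false, yes, no}``
    case-insensitively.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        try:
            rec = ClinicalRecord(
                patient_id=pid,
                ec_within_12h=parse_bool(row["ec_within_12h"], context=pid),
                smoker=parse_bool(row["smoker"], context=pid),
                dyslipidaemia=parse_bool(row["dyslipidaemia"], context=pid),
                bmi=float(row["bmi"]),
                nyha_class=int(row["nyha_class"]),
                age=float(row["age"]),
                procedural_time_min=float(row["procedural_time_min"]),
                ablation_duration_min=float(row["ablation_duration_min"]),
            )
        except (TypeError, ValueError) as exc:
            raise MalformedInputError(
                f"{path}: patient {pid!r}: {exc}"
            ) from exc
        records.append(rec)
    return records


def write_clinical_table(
    records: Iterable[ClinicalRecord], path: str | Path
) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "ec_within_12h": int(r.ec_within_12h),
            "smoker": int(r.smoker),
            "dyslipidaemia": int(r.dyslipidaemia),
            "bmi": r.bmi,
            "nyha_class": r.nyha_class,
            "age": r.age,
            "procedural_time_min": r.procedural_time_min,
            "ablation_duration_min": r.ablation_duration_min,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by patient_id."""
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("patient_id")
    return df


def build_cohort(
    clinical: pd.DataFrame | Sequence[ClinicalRecord],
    *tables: pd.DataFrame,
) -> pd.DataFrame:
    """Join clinical covariates with per-patient metric tables.

    Every table must be indexed by ``patient_id``.  The join is inner;
    patients lacking either a cine-derived table row or a clinical record
    are dropped with a warning, which keeps the one-row-per-patient,
    both-sources-present invariant.
    """
    if not isinstance(clinical, pd.DataFrame):
        clinical = clinical_frame(clinical)
    out = clinical
    for tab in tables:
        before = set(out.index)
        out = out.join(tab, how="inner")
        dropped = before - set(out.index)
        if dropped:
            warnings.warn(
                f"build_cohort: dropping patients without complete data: "
                f"{sorted(dropped)}",
                stacklevel=2,
            )
    if out.index.has_duplicates:
        raise MalformedInputError("cohort table has duplicate patient ids")
    return out
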