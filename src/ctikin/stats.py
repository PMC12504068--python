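"""Cohort statistics: Spearman, point-biserial, two-sample KS.

Thin, validated wrappers around ``scipy.stats`` with a uniform result
type, plus the cardioversion comparison that pools per-point kinetic
quantities by EC status.

Conventions
-----------
* Spearman rho uses average ranks for ties and the t approximation with
  n - 2 degrees of freedom for the p-value.
* The point-biserial coefficient is numerically identical to the
  Pearson correlation between the 0/1 group indicator and the values.
* The KS test uses the asymptotic two-sided p-value (its size at the
  cohort scales involved here sits near, slightly under, the nominal
  level).
* Ordinal covariates are binarized before the point-biserial test:
  NYHA at class >= 2, BMI at >= 30 kg/m^2 (obesity), both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError
from .io import ClinicalRecord, clinical_frame
from .kinetics import SegmentKinetics

NYHA_BINARIZE_AT = 2      # class >= 2 codes 1
BMI_BINARIZE_AT = 30.0    # kg/m^2, obesity cut


@dataclass
class StatResult:
    statistic: float
    p_value: float
    n: int
    method: str
    n0: int | None = None
    n1: int | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation between two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("spearman: x and y must be equal-length 1-D")
    if len(x) < 3:
        raise DegenerateInputError("spearman: need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("spearman: constant input, rho undefined")
    rho, p = sps.spearmanr(x, y)
    return StatResult(float(rho), float(p), len(x), "spearman")


def point_biserial(group: Sequence[bool], values: Sequence[float]) -> StatResult:
    """Correlation between a dichotomous grouping and a continuous variable.

    ``r_pb = (M1 - M0) / s_n * sqrt(n1 * n0 / n^2)`` with the population
    standard deviation ``s_n``; identical to Pearson correlation with
    0/1 coding of the group.
    """
    g = np.asarray(group).astype(bool)
    v = np.asarray(values, dtype=float)
    if g.shape != v.shape or g.ndim != 1:
        raise DegenerateInputError("point_biserial: shapes must match, 1-D")
    n1, n0 = int(g.sum()), int((~g).sum())
    if n0 == 0 or n1 == 0:
        raise DegenerateInputError("point_biserial: one group is empty")
    if n0 + n1 < 3:
        raise DegenerateInputError("point_biserial: need n >= 3")
    if np.ptp(v) == 0:
        raise DegenerateInputError("point_biserial: zero variance in values")
    r, p = sps.pointbiserialr(g.astype(int), v)
    return StatResult(float(r), float(p), n0 + n1, "point-biserial", n0=n0, n1=n1)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided two-sample Kolmogorov-Smirnov test, asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateInputError("ks_two_sample: empty sample")
    res = sps.ks_2samp(a, b, method="asymp")
    return StatResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), len(a) + len(b),
        "ks-2samp-asymp", n0=len(a), n1=len(b),
    )


def binarize_nyha(nyha: Sequence[int], cut: int = NYHA_BINARIZE_AT) -> np.ndarray:
    return np.asarray(nyha) >= cut


def binarize_bmi(bmi: Sequence[float], cut: float = BMI_BINARIZE_AT) -> np.ndarray:
    return np.asarray(bmi, dtype=float) >= cut


def compare_ec_distributions(
    kinetics: Mapping[str, SegmentKinetics] | Sequence[SegmentKinetics],
    clinical: pd.DataFrame | Sequence[ClinicalRecord],
    pooling: str = "point",
) -> pd.DataFrame:
    """KS comparison of kinetic distributions between EC and non-EC patients.

    Four quantities are compared: trajectory differentials and
    instantaneous velocities, each on the anterior-posterior (x) and
    caudo-cranial (y) axis.

    ``pooling="point"`` pools raw point x transition values per group —
    the comparison of raw distributions; note that points within a
    patient are not independent, so the pooled p-values are calibrated
    only under an exchangeable-patients null.  ``pooling="patient"``
    first reduces each patient to per-patient means of |value|.
    """
    if not isinstance(clinical, pd.DataFrame):
        clinical = clinical_frame(clinical)
    if not isinstance(kinetics, Mapping):
        kinetics = {k.patient_id: k for k in kinetics}
    ec_ids = set(clinical.index[clinical["ec_within_12h"].astype(bool)])
    non_ids = set(clinical.index) - ec_ids
    groups: dict[bool, dict[str, list[np.ndarray]]] = {
        True: {q: [] for q in ("dx", "dy", "vx", "vy")},
        False: {q: [] for q in ("dx", "dy", "vx", "vy")},
    }
    for pid, sk in kinetics.items():
        if pid in ec_ids:
            is_ec = True
        elif pid in non_ids:
            is_ec = False
        else:
            continue
        src = {
            "dx": sk.differentials[:, :, 0],
            "dy": sk.differentials[:, :, 1],
            "vx": sk.velocities[:, :, 0],
            "vy": sk.velocities[:, :, 1],
        }
        for q, arr in src.items():
            if pooling == "point":
                groups[is_ec][q].append(arr.ravel())
            elif pooling == "patient":
                groups[is_ec][q].append(np.array([np.abs(arr).mean()]))
            else:
                raise ValueError(f"unknown pooling {pooling!r}")
    if not groups[True]["dx"] or not groups[False]["dx"]:
        raise DegenerateInputError(
            "compare_ec_distributions: need patients in both EC groups"
        )
    rows = []
    for q in ("dx", "dy", "vx", "vy"):
        ec_vals = np.concatenate(groups[True][q])
        non_vals = np.concatenate(groups[False][q])
        res = ks_two_sample(ec_vals, non_vals)
        rows.append(
            {
                "quantity": q,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_ec": res.n0,
                "n_non_ec": res.n1,
                "method": res.method,
                "pooling": pooling,
            }
        )
    return pd.DataFrame(rows)
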