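"""Supervised models: EC classification and CTI length regression.

Two models are provided:

* an L2-regularized logistic regression predicting whether a patient was
  electrically cardioverted within 12 h, from the vector of trajectory
  differentials of the points of one CTI segment (one observation per
  patient x segment by default; observations of one patient stay on the
  same side of the train/test split to avoid within-patient leakage);
* a Lasso regression predicting the curvilinear systolic or diastolic
  CTI length from the complementary curvilinear length, pouch depth,
  linear length and (optionally) the clinical flags EC / smoker /
  dyslipidaemia, with the penalty weight chosen by 10-fold
  cross-validation on mean squared error.

The Lasso objective is ``(1/(2n)) * sum (y_i - yhat_i)^2 +
alpha * sum |beta_j|`` on standardized (zero-mean, unit-variance)
features; coefficients are reported on both the standardized and the
raw-feature scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV, LinearRegression, LogisticRegression
from sklearn.metrics import confusion_matrix, mean_absolute_error, r2_score
from sklearn.model_selection import GroupShuffleSplit, KFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import DegenerateInputError
from .kinetics import SegmentKinetics

LENGTH_TARGETS = {
    "systolic": "curvilinear_systolic_mm",
    "diastolic": "curvilinear_diastolic_mm",
}
GEOMETRY_FEATURES = {
    # target -> complementary curvilinear length feature
    "systolic": "curvilinear_diastolic_mm",
    "diastolic": "curvilinear_systolic_mm",
}
SHARED_GEOMETRY = ["pouch_depth_mm", "linear_diastolic_mm"]
CLINICAL_FEATURES = ["ec_within_12h", "smoker", "dyslipidaemia"]


# ---------------------------------------------------------------------
# EC classification from trajectory differentials
# ---------------------------------------------------------------------

def build_ec_design(
    kinetics: Mapping[str, SegmentKinetics] | Sequence[SegmentKinetics],
    ec_by_patient: Mapping[str, bool],
    axis: str = "x",
    pad: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Design matrix for EC classification.

    One observation per (patient, CTI segment): the concatenated
    trajectory-differential sequences of the segment's points on the
    chosen axis (``axis="plane"`` uses per-transition Euclidean norms,
    hence non-negative features).  Labels are the patient's EC flag.

    Feature length is points-per-segment x (F - 1); segments of unequal
    point count make the design ragged, which raises unless ``pad=True``
    (zero-padding at the TV-side end, documented behaviour).
    """
    if axis not in ("x", "y", "plane"):
        raise ValueError(f"axis must be x, y or plane, got {axis!r}")
    if not isinstance(kinetics, Mapping):
        kinetics = {k.patient_id: k for k in kinetics}
    feats: list[np.ndarray] = []
    labels: list[bool] = []
    obs: list[tuple[str, int]] = []
    for pid, sk in kinetics.items():
        if pid not in ec_by_patient:
            continue
        start = sk.cti_point_indices[0]
        for seg in sk.segments:
            loc = seg.point_indices - start
            d = sk.differentials[loc]            # (n_pts, F-1, 2)
            if axis == "x":
                vec = d[:, :, 0].ravel()
            elif axis == "y":
                vec = d[:, :, 1].ravel()
            else:
                vec = np.linalg.norm(d, axis=2).ravel()
            feats.append(vec)
            labels.append(bool(ec_by_patient[pid]))
            obs.append((pid, seg.segment))
    if not feats:
        raise DegenerateInputError("build_ec_design: no observations")
    lengths = {len(v) for v in feats}
    if len(lengths) > 1:
        if not pad:
            raise DegenerateInputError(
                f"build_ec_design: ragged feature lengths {sorted(lengths)}; "
                "pass pad=True to zero-pad"
            )
        m = max(lengths)
        feats = [np.pad(v, (0, m - len(v))) for v in feats]
    X = np.vstack(feats)
    y = np.asarray(labels, dtype=int)
    return X, y, obs


@dataclass
class ECClassifierFit:
    axis: str
    accuracy: float
    confusion: tuple[int, int, int, int]   # (TN, FP, FN, TP) on the test set
    coefficients: np.ndarray
    intercept: float
    observation_unit: str
    n_train: int
    n_test: int

    def as_dict(self) -> dict:
        return {
            "axis": self.axis,
            "accuracy": self.accuracy,
            "confusion": {
                k: v
                for k, v in zip(("tn", "fp", "fn", "tp"), self.confusion)
            },
            "observation_unit": self.observation_unit,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def fit_ec_classifier(
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence[str] | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
    C: float = 0.01,
    axis: str = "x",
) -> ECClassifierFit:
    """Train/test an L2 logistic regression for EC status.

    ``groups`` (typically the patient id of each observation) keeps all
    observations of one patient on one side of the split.  Accuracy and
    the (TN, FP, FN, TP) confusion matrix are reported on the held-out
    set.  Deterministic given seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if groups is not None:
        splitter = GroupShuffleSplit(
            n_splits=1, train_size=train_fraction, random_state=seed
        )
        train_idx, test_idx = next(splitter.split(X, y, groups=np.asarray(groups)))
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(y))
        cut = int(round(train_fraction * len(y)))
        train_idx, test_idx = perm[:cut], perm[cut:]
    if len(np.unique(y[train_idx])) < 2:
        raise DegenerateInputError(
            "fit_ec_classifier: single-class training data"
        )
    model = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=C, max_iter=5000),  # ridge-penalized (default l2)
    )
    model.fit(X[train_idx], y[train_idx])
    pred = model.predict(X[test_idx])
    cm = confusion_matrix(y[test_idx], pred, labels=[0, 1])
    tn, fp, fn, tp = int(cm[0, 0]), int(cm[0, 1]), int(cm[1, 0]), int(cm[1, 1])
    acc = (tn + tp) / max(len(test_idx), 1)
    clf = model.named_steps["logisticregression"]
    return ECClassifierFit(
        axis=axis,
        accuracy=float(acc),
        confusion=(tn, fp, fn, tp),
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        observation_unit="patient-segment" if groups is not None else "observation",
        n_train=len(train_idx),
        n_test=len(test_idx),
    )


# ---------------------------------------------------------------------
# Lasso length prediction
# ---------------------------------------------------------------------

@dataclass
class LassoFit:
    target: str
    features: list[str]
    alpha: float
    coefficients_std: np.ndarray     # standardized-feature scale
    coefficients_raw: np.ndarray     # raw-feature scale
    intercept_raw: float
    cv_folds: int
    mae_mm: float                    # cross-validated held-out MAE
    r2: float                        # cross-validated held-out R^2
    n: int
    include_clinical: bool

    def as_dict(self) -> dict:
        return {
            "target": self.target,
            "alpha": self.alpha,
            "cv_folds": self.cv_folds,
            "mae_mm": self.mae_mm,
            "r2": self.r2,
            "n": self.n,
            "include_clinical": self.include_clinical,
            "coefficients_std": dict(zip(self.features, map(float, self.coefficients_std))),
            "coefficients_raw": dict(zip(self.features, map(float, self.coefficients_raw))),
            "intercept_raw": self.intercept_raw,
        }


def lasso_feature_names(target: str, include_clinical: bool = True) -> list[str]:
    if target not in LENGTH_TARGETS:
        raise ValueError(f"target must be systolic or diastolic, got {target!r}")
    names = [GEOMETRY_FEATURES[target], *SHARED_GEOMETRY]
    if include_clinical:
        names += CLINICAL_FEATURES
    return names


def fit_lasso_length(
    cohort: pd.DataFrame,
    target: str,
    alpha: float | str = "cv",
    folds: int = 10,
    seed: int = 0,
    include_clinical: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> LassoFit:
    """Lasso prediction of curvilinear CTI length.

    ``alpha="cv"`` selects the penalty minimizing mean squared
    cross-validation error over ``folds`` shuffled folds (fixed seed);
    a numeric alpha is used as-is, with ``alpha=0`` solved as ordinary
    least squares.  MAE and R^2 are computed on cross-validated held-out
    predictions with the same folds.
    """
    names = lasso_feature_names(target, include_clinical)
    ycol = LENGTH_TARGETS[target]
    cols = [*names, ycol]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"fit_lasso_length: cohort lacks columns {missing}")
    data = cohort[cols].dropna()
    n = len(data)
    if n < folds:
        raise DegenerateInputError(f"fit_lasso_length: n={n} < folds={folds}")
    X = data[names].astype(float).to_numpy()
    y = data[ycol].astype(float).to_numpy()
    if np.ptp(y) == 0:
        raise DegenerateInputError("fit_lasso_length: constant target")

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)

    if alpha == "cv":
        search = LassoCV(cv=cv, random_state=seed, tol=tol, max_iter=max_iter)
        search.fit(Xs, y)
        alpha_val = float(search.alpha_)
    else:
        alpha_val = float(alpha)
    if alpha_val < 0:
        raise ValueError("alpha must be >= 0")

    if alpha_val == 0.0:
        model = LinearRegression()
    else:
        model = Lasso(alpha=alpha_val, tol=tol, max_iter=max_iter)
    model.fit(Xs, y)
    pred = cross_val_predict(model, Xs, y, cv=cv)
    coef_std = np.asarray(model.coef_, dtype=float)
    coef_raw = coef_std / scaler.scale_
    intercept_raw = float(model.intercept_ - np.sum(coef_raw * scaler.mean_))
    return LassoFit(
        target=target,
        features=names,
        alpha=alpha_val,
        coefficients_std=coef_std,
        coefficients_raw=coef_raw,
        intercept_raw=intercept_raw,
        cv_folds=folds,
        mae_mm=float(mean_absolute_error(y, pred)),
        r2=float(r2_score(y, pred)),
        n=n,
        include_clinical=include_clinical,
    )


def lasso_kkt_residual(
    X: np.ndarray, y: np.ndarray, coef: np.ndarray, intercept: float, alpha: float
) -> float:
    """Maximum violation of the Lasso stationarity conditions.

    For the objective ``(1/(2n))||y - Xb - b0||^2 + alpha ||b||_1`` the
    smooth-part gradient ``g = -(1/n) X^T r`` must satisfy
    ``|g_j| <= alpha`` on zero coefficients and ``g_j = -alpha *
    sign(b_j)`` on active ones.  Returns the largest violation (0 for an
    exact solution); used by verification tests.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    r = y - X @ coef - intercept
    g = -X.T @ r / len(y)
    viol = 0.0
    for j, b in enumerate(coef):
        if b == 0.0:
            viol = max(viol, abs(g[j]) - alpha)
        else:
            viol = max(viol, abs(g[j] + alpha * np.sign(b)))
    viol = max(viol, abs(r.mean()))   # intercept stationarity
    return float(viol)


def ablation_report(fit_with: LassoFit, fit_without: LassoFit) -> dict:
    """Effect of the clinical features on prediction quality.

    Deltas are ``with-clinical minus without-clinical``; a negative
    ``delta_mae_mm`` and a positive ``delta_r2`` mean the clinical flags
    improved the prediction.
    """
    if fit_with.target != fit_without.target:
        raise ValueError("ablation_report: fits target different lengths")
    return {
        "target": fit_with.target,
        "mae_with_mm": fit_with.mae_mm,
        "mae_without_mm": fit_without.mae_mm,
        "delta_mae_mm": fit_with.mae_mm - fit_without.mae_mm,
        "r2_with": fit_with.r2,
        "r2_without": fit_without.r2,
        "delta_r2": fit_with.r2 - fit_without.r2,
    }
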