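"""K-means phenotype clustering of patients on normalized elongation.

Patients are clustered on the scalar NE value; the number of clusters is
chosen by an elbow criterion on the within-cluster sum of squares
(WCSS) curve, singleton clusters are flagged as outliers and removed,
and the surviving clusters are named low / intermediate / high NE by
ascending centroid.

Elbow criterion
---------------
The knee of a WCSS scree plot is where the *relative* gain of adding a
cluster collapses, so the curvature is measured on the log scale: the
selected k maximises ``log w(k-1) - 2 log w(k) + log w(k+1)`` over
``2 <= k <= k_max - 1``.  A linear-scale second difference is dominated
by the first large drop of the curve and systematically under-counts
well-separated groups in the presence of an extreme outlier; the
log-scale form recovers the group count in that regime.  A manual
override is available for visual selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DegenerateInputError

GROUP_NAMES_3 = ("low", "intermediate", "high")


def kmeans_1d(
    values: Sequence[float],
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd k-means on scalar values; best of ``n_restarts`` by WCSS.

    Returns ``(labels, centroids, wcss)`` with
    ``wcss = sum_i (x_i - c_{label_i})^2``.  Deterministic given seed.
    """
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(v) == 0:
        raise DegenerateInputError("kmeans_1d: empty input")
    n_distinct = len(np.unique(v))
    if k > n_distinct:
        raise DegenerateInputError(
            f"kmeans_1d: k={k} exceeds {n_distinct} distinct values"
        )
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        random_state=seed,
        max_iter=300,
        algorithm="lloyd",
    ).fit(v)
    return km.labels_.copy(), km.cluster_centers_.ravel().copy(), float(km.inertia_)


def elbow_select(
    values: Sequence[float],
    k_max: int = 8,
    seed: int = 0,
    n_restarts: int = 10,
    k_override: int | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose k from the WCSS curve for k = 1..k_max.

    Returns ``(k_selected, wcss_curve)``.  A flat/degenerate curve (all
    points identical up to k_max clusters resolving to zero WCSS
    immediately) selects 1 with a warning.  ``k_override`` bypasses the
    criterion but still reports the curve.
    """
    v = np.asarray(values, dtype=float)
    if k_max < 3:
        raise DegenerateInputError("elbow_select: k_max must be >= 3")
    n_distinct = len(np.unique(v))
    curve: dict[int, float] = {}
    top = min(k_max, n_distinct)
    for k in range(1, top + 1):
        _, _, w = kmeans_1d(v, k, n_restarts=n_restarts, seed=seed)
        curve[k] = w
    if k_override is not None:
        return int(k_override), curve
    if top < 3 or curve[1] <= 1e-12:
        warnings.warn(
            "elbow_select: degenerate WCSS curve, returning k=1", stacklevel=2
        )
        return 1, curve

    eps = 1e-12
    best_k, best_d2 = 1, -math.inf
    for k in range(2, top):
        d2 = (
            math.log(curve[k - 1] + eps)
            - 2.0 * math.log(curve[k] + eps)
            + math.log(curve[k + 1] + eps)
        )
        if d2 > best_d2:
            best_k, best_d2 = k, d2
    if best_d2 <= 0.0:
        warnings.warn(
            "elbow_select: no convex knee in the WCSS curve, returning k=1",
            stacklevel=2,
        )
        return 1, curve
    return best_k, curve


@dataclass
class ClusterResult:
    k_selected: int
    assignments: "pd.Series"            # patient_id -> cluster label (retained only)
    centroids: np.ndarray               # all k centroids, original labels
    wcss_curve: dict[int, float]
    removed_outliers: tuple[str, ...]
    final_group_labels: dict[int, str]  # retained cluster -> group name
    group_centroids: dict[str, float]   # group name -> centroid NE

    @property
    def group_of_patient(self) -> pd.Series:
        return self.assignments.map(self.final_group_labels)


def cluster_ne(
    ne: pd.Series | Mapping[str, float],
    k_max: int = 8,
    seed: int = 0,
    n_restarts: int = 10,
    outlier_max_size: int = 1,
    k_override: int | None = None,
) -> ClusterResult:
    """Cluster patients on NE, drop singleton-outlier clusters, name groups.

    Clusters whose cardinality is <= ``outlier_max_size`` are flagged as
    outliers and their members removed; the remaining clusters are
    relabeled by ascending centroid (low / intermediate / high for three
    groups, ``group_1..n`` otherwise).  Clustering is *not* re-run after
    removal, matching a remove-then-analyse workflow.
    """
    if not isinstance(ne, pd.Series):
        ne = pd.Series(dict(ne))
    ne = ne.astype(float)
    if ne.isna().any():
        raise DegenerateInputError("cluster_ne: NaN NE values")
    if len(ne) < 4:
        raise DegenerateInputError("cluster_ne: need at least 4 patients")
    if len(np.unique(ne.to_numpy())) < 2:
        raise DegenerateInputError("cluster_ne: all NE values identical")

    k_sel, curve = elbow_select(
        ne.to_numpy(), k_max=k_max, seed=seed, n_restarts=n_restarts,
        k_override=k_override,
    )
    labels, centroids, _ = kmeans_1d(
        ne.to_numpy(), max(k_sel, 1), n_restarts=n_restarts, seed=seed
    )
    assign = pd.Series(labels, index=ne.index, name="cluster")

    sizes = assign.value_counts()
    outlier_clusters = set(sizes.index[sizes <= outlier_max_size])
    removed = tuple(sorted(assign.index[assign.isin(outlier_clusters)]))
    retained = assign[~assign.isin(outlier_clusters)]
    kept_clusters = sorted(retained.unique(), key=lambda c: centroids[c])
    if len(kept_clusters) < 2:
        raise DegenerateInputError(
            "cluster_ne: fewer than 2 clusters remain after outlier removal"
        )
    if len(kept_clusters) == 3:
        names = GROUP_NAMES_3
    else:
        names = tuple(f"group_{i + 1}" for i in range(len(kept_clusters)))
    final = {int(c): names[i] for i, c in enumerate(kept_clusters)}
    group_centroids = {names[i]: float(centroids[c]) for i, c in enumerate(kept_clusters)}
    return ClusterResult(
        k_selected=int(k_sel),
        assignments=retained,
        centroids=centroids,
        wcss_curve=curve,
        removed_outliers=removed,
        final_group_labels=final,
        group_centroids=group_centroids,
    )
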