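"""Redundancy reduction: distance-correlation clustering of the selected
features on concatenated training data, then one representative per
cluster.

Distance correlation (dCor) is Székely's dependence measure: 0 only for
independent variables (in population), 1 for a perfect linear relation.
Features are clustered agglomeratively with dissimilarity 1 - dCor and
complete linkage, cutting the tree so that every within-cluster pair has
dCor strictly above the threshold (default 0.7) — complete linkage is the
only standard linkage that guarantees this pairwise property.  Singleton
"clusters" are carried forward as independent features; each real cluster
contributes the member with the highest concatenated-night AUC (ties
broken by name).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

DCOR_THRESHOLD = 0.7


def _center(d: np.ndarray) -> np.ndarray:
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample (V-statistic) distance correlation of two 1-d samples.

    Double-centres the Euclidean distance matrices; dCov^2 is the mean of
    their elementwise product and dCor = dCov / sqrt(dVar_x * dVar_y),
    defined as 0 when either dVar vanishes (constant input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("distance_correlation needs two equal-length 1-d arrays")
    if x.size < 4:
        raise ValueError("distance_correlation needs n >= 4")
    a = _center(np.abs(x[:, None] - x[None, :]))
    b = _center(np.abs(y[:, None] - y[None, :]))
    dcov2 = (a * b).mean()
    dvarx = (a * a).mean()
    dvary = (b * b).mean()
    if dvarx <= 0.0 or dvary <= 0.0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))


def dcor_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Pairwise dCor between columns of ``data`` (rows = observations)."""
    cols = list(data.columns)
    n = len(cols)
    mat = np.eye(n)
    arrays = [data[c].to_numpy(dtype=float) for c in cols]
    # pre-centre each feature's distance matrix once
    centred = [_center(np.abs(a[:, None] - a[None, :])) for a in arrays]
    dvars = np.array([(c * c).mean() for c in centred])
    for i in range(n):
        for j in range(i + 1, n):
            if dvars[i] <= 0 or dvars[j] <= 0:
                mat[i, j] = mat[j, i] = 0.0
                continue
            dcov2 = (centred[i] * centred[j]).mean()
            mat[i, j] = mat[j, i] = np.sqrt(max(dcov2, 0.0) / np.sqrt(dvars[i] * dvars[j]))
    for i in range(n):
        mat[i, i] = 1.0 if dvars[i] > 0 else 0.0
    return pd.DataFrame(mat, index=cols, columns=cols)


@dataclass
class ClusterResult:
    dcor: pd.DataFrame
    clusters: list[list[str]]  # size >= 2 each
    independents: list[str]
    representatives: list[str] = field(default_factory=list)

    @property
    def reduced_set(self) -> list[str]:
        return list(self.representatives) + list(self.independents)


def cluster_features(dcor: pd.DataFrame, threshold: float = DCOR_THRESHOLD) -> ClusterResult:
    """Complete-linkage clustering of features at dissimilarity 1 - dCor,
    cut so every within-cluster pair has dCor > threshold (strict)."""
    if dcor.shape[0] != dcor.shape[1]:
        raise ValueError("dcor matrix must be square")
    names = list(dcor.index)
    if len(names) == 1:
        return ClusterResult(dcor=dcor, clusters=[], independents=names)
    d = 1.0 - dcor.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    link = hierarchy.linkage(condensed, method="complete")
    # strict cut: pairs at exactly the threshold must not merge
    cut = (1.0 - threshold) - 1e-12
    labels = hierarchy.fcluster(link, t=cut, criterion="distance")
    groups: dict[int, list[str]] = {}
    for name, lab in zip(names, labels):
        groups.setdefault(int(lab), []).append(name)
    clusters = [sorted(g) for g in groups.values() if len(g) >= 2]
    clusters.sort(key=lambda g: g[0])
    independents = sorted(g[0] for g in groups.values() if len(g) == 1)
    # complete-linkage guarantee, asserted post hoc
    for grp in clusters:
        sub = dcor.loc[grp, grp].to_numpy()
        off = sub[~np.eye(len(grp), dtype=bool)]
        if not (off > threshold).all():
            raise AssertionError("within-cluster pair at or below the dCor threshold")
    return ClusterResult(dcor=dcor, clusters=clusters, independents=independents)


def pick_representatives(result: ClusterResult, records: pd.DataFrame) -> ClusterResult:
    """Per cluster, keep the feature with the highest concatenated-night
    AUC (``auc_concat`` column of the selection records); ties broken by
    lexicographic feature name.  Returns the result with representatives
    filled in; ``reduced_set`` is representatives + independents."""
    reps = []
    for grp in result.clusters:
        missing = [f for f in grp if f not in records.index or pd.isna(records.loc[f, "auc_concat"])]
        if missing:
            raise ValueError(f"no concatenated AUC for clustered features {missing}")
        best = sorted(grp, key=lambda f: (-records.loc[f, "auc_concat"], f))[0]
        reps.append(best)
    return ClusterResult(
        dcor=result.dcor,
        clusters=result.clusters,
        independents=result.independents,
        representatives=reps,
    )
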