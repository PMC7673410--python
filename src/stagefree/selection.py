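"""Univariate screening: per-night AUC with DeLong 95% CI on the training
set; a feature survives only if the CI lower bound exceeds 0.5 on *each*
night.  Surviving features get a concatenated-night vector (each training
subject contributes both nights with the same label) for the clustering
and classifier stages.

AUC here is the Mann-Whitney statistic, ties counted half.  AUC is
direction-sensitive, so each feature is given a fixed orientation — the
sign that makes its training night-1 AUC >= 0.5 — which is then reused on
night 2, on the concatenated vector and in the classifier, to avoid the
selection bias of flipping per night.

The CI is the asymptotic DeLong variance interval (deterministic); a
seeded bootstrap is available as an alternative.  Concatenated-night CIs
are not used for selection: doubling observations per subject makes them
anticonservative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .features import feature_columns

CI_LEVEL = 0.95


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC needs both classes present")
    return labels


def auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(positive > negative) + 0.5*P(tie).

    ``labels`` True marks the positive (PTSD) class.
    """
    values = np.asarray(values, dtype=float)
    labels = _check_labels(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(values)  # midranks handle ties at 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_variance(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong AUC point estimate and asymptotic variance via midranks."""
    values = np.asarray(values, dtype=float)
    labels = _check_labels(labels)
    pos = values[labels]
    neg = values[~labels]
    m, n = pos.size, neg.size
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    # structural components (Sun & Xu midrank formulation)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    a = float(v10.mean())
    if m > 1 and n > 1:
        var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    else:
        var = 0.0
    return a, float(var)


def auc_ci(
    values: np.ndarray,
    labels: np.ndarray,
    level: float = CI_LEVEL,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the AUC, clipped to [0, 1].

    ``method='delong'`` (default) uses the asymptotic DeLong variance;
    ``method='bootstrap'`` uses a seeded stratified percentile bootstrap.
    A degenerate variance (e.g. perfect separation) collapses the DeLong
    interval to the point estimate, with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = _check_labels(labels)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("auc_ci needs at least two observations per class")
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = values[labels]
        neg = values[~labels]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            pb = rng.choice(pos, size=pos.size, replace=True)
            nb = rng.choice(neg, size=neg.size, replace=True)
            v = np.concatenate([pb, nb])
            lab = np.zeros(v.size, dtype=bool)
            lab[: pos.size] = True
            aucs[b] = auc(v, lab)
        alpha = 1.0 - level
        lb, ub = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
        return float(lb), float(ub)
    if method != "delong":
        raise ValueError(f"unknown CI method {method!r}")
    a, var = delong_variance(values, labels)
    if var <= 0.0:
        warnings.warn("degenerate AUC variance; CI collapsed to point estimate")
        return a, a
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(np.clip(a - half, 0.0, 1.0)), float(np.clip(a + half, 0.0, 1.0))


def orientation(values: np.ndarray, labels: np.ndarray) -> int:
    """+1 if the raw direction gives AUC >= 0.5, else -1 (flip)."""
    return 1 if auc(values, labels) >= 0.5 else -1


def concatenate_nights(train: pd.DataFrame, feature: str) -> tuple[np.ndarray, np.ndarray]:
    """Stack night-1 and night-2 observations of a feature (train rows),
    each subject contributing two rows with the same label."""
    sub = train.sort_values(["night", "subject_id"])
    return sub[feature].to_numpy(dtype=float), (sub["group"] == "PTSD").to_numpy()


def select_features(
    table: pd.DataFrame,
    features: list[str] | None = None,
    level: float = CI_LEVEL,
    ci_method: str = "delong",
) -> pd.DataFrame:
    """Per-feature, per-night AUC + CI on the training split; the selected
    flag requires the CI lower bound to exceed 0.5 on both nights.

    Returns a SelectionRecord frame indexed by feature with columns
    orientation, auc_night1/2, ci_lb/ub per night, auc_concat, selected.
    Only training rows are used; deleting test rows changes nothing.
    """
    train = table[table["split"] == "train"]
    features = features if features is not None else feature_columns(table)
    records = []
    for feat in features:
        n1 = train[train["night"] == 1]
        n2 = train[train["night"] == 2]
        v1 = n1[feat].to_numpy(dtype=float)
        l1 = (n1["group"] == "PTSD").to_numpy()
        v2 = n2[feat].to_numpy(dtype=float)
        l2 = (n2["group"] == "PTSD").to_numpy()
        sign = orientation(v1, l1)
        a1 = auc(sign * v1, l1)
        lb1, ub1 = auc_ci(sign * v1, l1, level, method=ci_method)
        a2 = auc(sign * v2, l2)
        lb2, ub2 = auc_ci(sign * v2, l2, level, method=ci_method)
        vc, lc = concatenate_nights(train, feat)
        ac = auc(sign * vc, lc)
        records.append(
            {
                "feature": feat,
                "orientation": sign,
                "auc_night1": a1,
                "ci_lb_night1": lb1,
                "ci_ub_night1": ub1,
                "auc_night2": a2,
                "ci_lb_night2": lb2,
                "ci_ub_night2": ub2,
                "auc_concat": ac,
                "selected": bool(lb1 > 0.5 and lb2 > 0.5),
            }
        )
    return pd.DataFrame(records).set_index("feature")
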