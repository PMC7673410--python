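"""Multivariate model: recursive feature elimination (RFE) with six-fold
cross-validated logistic regression, final fit on the combined two-night
training data, ROC threshold selection at target training sensitivities,
and per-night test evaluation with prevalence-adjusted PPV.

Key choices:

* Logistic regression is fitted on training-standardized features with a
  weak L2 ridge (penalty strength 1/(100·n)), which keeps the fit
  deterministic and convergent even under perfect separation.
* RFE drops, at each step, the feature with the smallest standardized
  coefficient magnitude, and keeps the smallest feature set whose mean
  cross-validated AUC is within one standard error of the best — with a
  ridge, coefficients are never exactly zero, so "smallest set with
  non-zero coefficients" needs this operational surrogate.
* CV folds are stratified by group and keep both nights of a subject in
  the same fold, preventing within-subject leakage.
* PPV is reported "adjusted": re-expressed as an explicit function of
  sensitivity, specificity, and an assumed population prevalence
  (default 0.15 for combat-exposed Veteran men), rather than of the
  enriched study-sample prevalence:

      PPV = sens·π / (sens·π + (1 − spec)·(1 − π))
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .selection import auc, auc_ci

DEFAULT_FOLDS = 6
DEFAULT_PREVALENCE = 0.15
RIDGE_SCALE = 100.0  # penalty strength 1 / (RIDGE_SCALE * n)
TARGET_SENSITIVITIES = (0.80, 0.90)


def adjusted_ppv(sens: float, spec: float, prevalence: float = DEFAULT_PREVALENCE) -> float:
    """Positive predictive value as an explicit function of prevalence.

    Returns NaN when the denominator vanishes (sens = 0 and spec = 1:
    the model never calls anyone positive).
    """
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    denom = sens * prevalence + (1.0 - spec) * (1.0 - prevalence)
    if denom == 0.0:
        return float("nan")
    return sens * prevalence / denom


@dataclass
class FittedClassifier:
    """Logistic model over a fixed feature set, with training-derived
    standardization and sensitivity-targeted decision thresholds."""

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    means: np.ndarray
    sds: np.ndarray
    thresholds: dict[float, float] = field(default_factory=dict)
    achieved_sens: dict[float, float] = field(default_factory=dict)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.feature_names].to_numpy(dtype=float)
        z = (x - self.means) / self.sds
        logit = z @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "coefficients": list(self.coefficients),
                "intercept": self.intercept,
                "means": list(self.means),
                "sds": list(self.sds),
                "thresholds": {str(k): v for k, v in self.thresholds.items()},
                "achieved_sens": {str(k): v for k, v in self.achieved_sens.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedClassifier":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            thresholds={float(k): v for k, v in d["thresholds"].items()},
            achieved_sens={float(k): v for k, v in d.get("achieved_sens", {}).items()},
        )


@dataclass
class EvalMetrics:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    adjusted_ppv: float
    prevalence: float
    threshold: float
    night: int | None = None
    split: str | None = None


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    if (sds == 0).any():
        raise ValueError("degenerate (constant) feature; cannot standardize")
    return (x - means) / sds, means, sds


def _fit_ridge_logistic(
    z: np.ndarray, y: np.ndarray, C: float | None = None
) -> tuple[np.ndarray, float]:
    """Logistic fit with L2 ridge.  The default C = RIDGE_SCALE * n gives a
    near-unpenalized fit (penalty 1/(RIDGE_SCALE*n) on the summed
    log-likelihood scale); pass an explicit C for a stronger ridge."""
    if C is None:
        C = RIDGE_SCALE * z.shape[0]
    model = LogisticRegression(
        penalty="l2", C=C, solver="lbfgs", max_iter=10000, tol=1e-10
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(z, y)
    return model.coef_[0].copy(), float(model.intercept_[0])


def fit_logistic(table: pd.DataFrame, features: list[str]) -> FittedClassifier:
    """Maximum-likelihood logistic fit (weak ridge) on training-standardized
    features.  Deterministic given the data; converges under perfect
    separation thanks to the ridge."""
    x = table[features].to_numpy(dtype=float)
    y = (table["group"] == "PTSD").to_numpy()
    z, means, sds = _standardize(x)
    coef, intercept = _fit_ridge_logistic(z, y.astype(int))
    return FittedClassifier(
        feature_names=list(features),
        coefficients=coef,
        intercept=intercept,
        means=means,
        sds=sds,
    )


def grouped_stratified_folds(
    subjects: np.ndarray, groups: np.ndarray, n_folds: int, seed: int
) -> dict[str, int]:
    """Assign subjects to folds, stratified by class, all nights of a
    subject together.  ``subjects``/``groups`` are per-subject arrays."""
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for g in np.unique(groups):
        members = subjects[groups == g]
        if members.size < n_folds:
            raise ValueError(
                f"class {g!r} has {members.size} subjects, fewer than {n_folds} folds"
            )
        members = members[rng.permutation(members.size)]
        for i, s in enumerate(members):
            fold_of[str(s)] = i % n_folds
    return fold_of


def _cv_auc(
    table: pd.DataFrame, features: list[str], fold_of: dict[str, int], n_folds: int
) -> tuple[float, float]:
    """Mean and standard error of fold-wise validation AUC."""
    aucs = []
    fold_idx = table["subject_id"].map(fold_of).to_numpy()
    y = (table["group"] == "PTSD").to_numpy()
    x = table[features].to_numpy(dtype=float)
    for k in range(n_folds):
        val = fold_idx == k
        z_train, means, sds = _standardize(x[~val])
        coef, intercept = _fit_ridge_logistic(z_train, y[~val].astype(int))
        scores = (x[val] - means) / sds @ coef + intercept
        aucs.append(auc(scores, y[val]))
    aucs = np.asarray(aucs)
    return float(aucs.mean()), float(aucs.std(ddof=1) / math.sqrt(n_folds))


def _deviance(table: pd.DataFrame, features: list[str]) -> float:
    """In-sample deviance of the ridge-logistic fit (intercept-only model
    when ``features`` is empty)."""
    y = (table["group"] == "PTSD").to_numpy().astype(int)
    if not features:
        p = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    z, _, _ = _standardize(table[features].to_numpy(dtype=float))
    coef, intercept = _fit_ridge_logistic(z, y)
    p = np.clip(1.0 / (1.0 + np.exp(-(z @ coef + intercept))), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def rfe_cv(
    table: pd.DataFrame,
    features: list[str],
    n_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    criterion: str = "bic",
    ebic_gamma: float = 0.5,
    ranking_C: float = 1.0,
) -> list[str]:
    """Recursive feature elimination to the smallest well-performing set.

    The elimination path drops, at each size, the feature with the
    smallest |standardized coefficient| on the full training data (ties
    broken by name, later name dropped first).  The ranking fit uses a
    moderate ridge (``ranking_C``, default 1.0): a near-unpenalized fit
    with many features on few subjects sits close to separation and its
    coefficient magnitudes rank unreliably.  The returned size along the
    path is chosen by ``criterion``:

    * ``"bic"`` (default): minimize in-sample deviance, rescaled to the
      subject level (concatenated nights double-count highly correlated
      observations), plus ``log(n_subjects)`` per coefficient.  The
      six-fold CV AUC is still computed along the path for diagnostics.
    * ``"ebic"``: BIC plus the extended term ``2*gamma*log(p)`` per
      coefficient, for stricter control when many candidates enter.
    * ``"cv_1se"``: smallest set whose mean six-fold CV AUC is within one
      standard error of the best along the path.  Small-cohort CV AUC is
      noisy, which makes this rule unstable for support recovery (see the
      methods documentation); it is kept as an option.

    Folds are stratified by group and keep both nights of a subject in
    the same fold; ``table`` must be the concatenated two-night training
    data.
    """
    train = table[table["split"] == "train"]
    subj = train.drop_duplicates("subject_id")
    fold_of = grouped_stratified_folds(
        subj["subject_id"].to_numpy(), subj["group"].to_numpy(), n_folds, seed
    )
    n_subjects = int(subj.shape[0])
    n_rows = int(train.shape[0])
    p_total = max(len(features), 2)
    current = list(features)
    history: list[dict] = []
    while current:
        mean_auc, se = _cv_auc(train, current, fold_of, n_folds)
        dev = _deviance(train, current) * (n_subjects / n_rows)
        penalty = len(current) * math.log(n_subjects)
        if criterion == "ebic":
            penalty += len(current) * 2.0 * ebic_gamma * math.log(p_total)
        history.append(
            {"features": list(current), "cv_auc": mean_auc, "cv_se": se, "ic": dev + penalty}
        )
        if len(current) == 1:
            break
        z, _, _ = _standardize(train[current].to_numpy(dtype=float))
        coef, _ = _fit_ridge_logistic(
            z, (train["group"] == "PTSD").to_numpy().astype(int), C=ranking_C
        )
        order = sorted(zip(np.abs(coef), current), key=lambda t: (t[0], tuple(-ord(c) for c in t[1])))
        weakest = order[0][1]
        current.remove(weakest)
    if criterion in ("bic", "ebic"):
        best = min(history, key=lambda h: (h["ic"], len(h["features"])))
        return best["features"]
    if criterion != "cv_1se":
        raise ValueError(f"unknown RFE criterion {criterion!r}")
    best_mean, best_se = max(((h["cv_auc"], h["cv_se"]) for h in history), key=lambda t: t[0])
    cutoff = best_mean - best_se
    eligible = [h["features"] for h in history if h["cv_auc"] >= cutoff]
    return min(eligible, key=len)


def threshold_for_sensitivity(
    model: FittedClassifier, table: pd.DataFrame, target_sens: float
) -> tuple[float, float]:
    """Largest probability cutoff whose training sensitivity (predict
    positive when p >= cutoff) meets or exceeds the target.

    Returns (cutoff, achieved sensitivity).  target 0 yields cutoff 1.0
    (all-negative predictions allowed, barring probabilities of exactly 1).
    """
    if not 0.0 <= target_sens <= 1.0:
        raise ValueError("target sensitivity must be in [0, 1]")
    p = model.predict_proba(table)
    y = (table["group"] == "PTSD").to_numpy()
    pos = np.sort(p[y])[::-1]
    if pos.size == 0:
        raise ValueError("no positive-class rows to set a sensitivity target")
    k = math.ceil(target_sens * pos.size)
    if k == 0:
        return 1.0, float((p[y] >= 1.0).mean())
    cutoff = float(pos[k - 1])
    achieved = float((p[y] >= cutoff).mean())
    return cutoff, achieved


def attach_thresholds(
    model: FittedClassifier,
    train_table: pd.DataFrame,
    targets: tuple[float, ...] = TARGET_SENSITIVITIES,
) -> FittedClassifier:
    for t in targets:
        cutoff, achieved = threshold_for_sensitivity(model, train_table, t)
        model.thresholds[t] = cutoff
        model.achieved_sens[t] = achieved
    return model


def evaluate(
    model: FittedClassifier,
    table: pd.DataFrame,
    cutoff: float,
    prevalence: float = DEFAULT_PREVALENCE,
) -> EvalMetrics:
    """Confusion-matrix rates at a cutoff plus AUC and adjusted PPV on one
    slice (typically one night of one split).  A single-class slice gets
    NaN AUC but rates are still reported where defined."""
    p = model.predict_proba(table)
    y = (table["group"] == "PTSD").to_numpy()
    pred = p >= cutoff
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    if y.any() and not y.all():
        a = auc(p, y)
        ci = auc_ci(p, y)
    else:
        a, ci = float("nan"), (float("nan"), float("nan"))
    ppv = (
        adjusted_ppv(sens, spec, prevalence)
        if np.isfinite(sens) and np.isfinite(spec)
        else float("nan")
    )
    night = int(table["night"].iloc[0]) if table["night"].nunique() == 1 else None
    split = table["split"].iloc[0] if table["split"].nunique() == 1 else None
    return EvalMetrics(
        auc=a,
        auc_ci=ci,
        sensitivity=sens,
        specificity=spec,
        adjusted_ppv=ppv,
        prevalence=prevalence,
        threshold=cutoff,
        night=night,
        split=split,
    )
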