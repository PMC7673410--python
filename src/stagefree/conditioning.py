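"""Feature conditioning: synchrony log-transform, night-concordance filter,
and regression-based age correction.

All statistics here are estimated on the *training* split only and then
applied to every row (train and test, both nights) — the conditioning is
train-derived, all-applied, so deleting test rows cannot change the
retained feature set or the fitted age slopes.

* Synchrony features W in [0, 1] are replaced by ln(max(W, 1e-6)); the
  floor keeps a hard zero finite without affecting attainable WPLI values.
* Night consistency is measured with Lin's concordance correlation
  coefficient (CCC) between the night-1 and night-2 vectors across
  training subjects; features with CCC > 0.7 (strict) are retained.
* Age effects are screened with Pearson's r between feature and age on
  control (non-PTSD) training observations, both nights pooled.  Features
  with p < 0.05 are corrected for everyone by subtracting
  b*(age - mean control-train age), where b is the slope of the
  feature-on-age regression fitted on those same control observations.
  Centring at the control-train mean age preserves the feature scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import feature_columns, synchrony_columns

LOG_FLOOR = 1e-6
CCC_THRESHOLD = 0.7
AGE_ALPHA = 0.05


def log_transform_synchrony(table: pd.DataFrame) -> pd.DataFrame:
    """Replace every W feature by ln(max(W, 1e-6)); LP/LCV untouched."""
    table = table.copy()
    cols = synchrony_columns(table)
    vals = table[cols].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if ((vals[finite] < 0) | (vals[finite] > 1)).any():
        raise ValueError("synchrony features must lie in [0, 1] before log transform")
    table[cols] = np.log(np.maximum(vals, LOG_FLOOR))
    return table


def ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2*s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2), with variances and
    covariance using denominator n.  Equals 1 iff y = x elementwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ccc needs two equal-length 1-d arrays")
    if x.size < 3:
        raise ValueError("ccc needs n >= 3 pairs")
    vx = x.var()
    vy = y.var()
    dmean = x.mean() - y.mean()
    denom = vx + vy + dmean**2
    if denom == 0.0:
        # both constant with equal means: identical vectors are perfectly
        # concordant, anything else is undefined
        return 1.0 if np.array_equal(x, y) else float("nan")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * sxy / denom)


@dataclass
class ConditioningReport:
    """Per-feature record of the concordance filter and age correction."""

    table: pd.DataFrame  # index: feature; columns: concordance_ccc,
    # retained_concordance, age_r, age_p, age_slope, age_corrected

    @property
    def retained(self) -> list[str]:
        t = self.table
        return list(t.index[t["retained_concordance"]])

    @property
    def age_corrected(self) -> list[str]:
        t = self.table
        return list(t.index[t["age_corrected"].astype("boolean").fillna(False).astype(bool)])


def _night_pair(table: pd.DataFrame, feature: str) -> tuple[np.ndarray, np.ndarray]:
    """Night-1 and night-2 feature vectors paired by subject (train rows).

    Subjects missing either night are excluded pairwise.
    """
    wide = table.pivot_table(index="subject_id", columns="night", values=feature)
    wide = wide.dropna()
    if wide.shape[1] != 2:
        raise ValueError("need two nights per training subject")
    return wide[1].to_numpy(), wide[2].to_numpy()


def concordance_filter(
    table: pd.DataFrame, threshold: float = CCC_THRESHOLD
) -> tuple[list[str], pd.Series]:
    """Features whose CCC across training subjects' two nights exceeds the
    threshold (strict).  Returns (retained names, per-feature CCC)."""
    train = table[table["split"] == "train"]
    cccs = {}
    for feat in feature_columns(table):
        x, y = _night_pair(train, feat)
        cccs[feat] = ccc(x, y)
    cvals = pd.Series(cccs, name="concordance_ccc")
    retained = [f for f, v in cvals.items() if np.isfinite(v) and v > threshold]
    return retained, cvals


def age_screen_and_correct(
    table: pd.DataFrame,
    features: list[str],
    alpha: float = AGE_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen features for age dependence on control training observations
    and remove fitted linear age effects from all rows.

    Returns the corrected table and a per-feature report frame with the
    Pearson r, two-sided p (exact t transform), fitted slope, and whether
    the correction was applied.
    """
    ctrl = table[(table["split"] == "train") & (table["group"] == "control")]
    if ctrl["subject_id"].nunique() < 3:
        raise ValueError("need at least 3 control training subjects for age screening")
    ages = ctrl["age"].to_numpy(dtype=float)
    if np.allclose(ages, ages[0]):
        # degenerate age variance: screening impossible, pass features through
        report = pd.DataFrame(
            index=pd.Index(features, name="feature"),
            data={"age_r": np.nan, "age_p": np.nan, "age_slope": 0.0, "age_corrected": False},
        )
        return table.copy(), report

    out = table.copy()
    mean_age = ages.mean()
    all_ages = out["age"].to_numpy(dtype=float)
    records = []
    for feat in features:
        vals = ctrl[feat].to_numpy(dtype=float)
        r, p = stats.pearsonr(ages, vals)
        corrected = p < alpha
        slope = 0.0
        if corrected:
            slope = float(np.polyfit(ages, vals, 1)[0])
            out[feat] = out[feat] - slope * (all_ages - mean_age)
        records.append(
            {"feature": feat, "age_r": float(r), "age_p": float(p),
             "age_slope": slope, "age_corrected": bool(corrected)}
        )
    report = pd.DataFrame(records).set_index("feature")
    return out, report


def condition_features(
    table: pd.DataFrame,
    ccc_threshold: float = CCC_THRESHOLD,
    age_alpha: float = AGE_ALPHA,
) -> tuple[pd.DataFrame, ConditioningReport]:
    """Run the full conditioning stage.

    Log-transform synchrony, filter by night concordance on the training
    split, then age-screen and correct the retained features.  The
    returned table keeps only metadata plus retained (corrected) features.
    """
    table = log_transform_synchrony(table)
    retained, cvals = concordance_filter(table, ccc_threshold)
    corrected, age_report = age_screen_and_correct(table, retained, age_alpha)

    report = pd.DataFrame({"concordance_ccc": cvals})
    report["retained_concordance"] = report.index.isin(retained)
    report = report.join(age_report)
    report["age_corrected"] = report["age_corrected"].astype("boolean").fillna(False).astype(bool)

    from .features import METADATA_COLUMNS

    kept_table = corrected[METADATA_COLUMNS + retained].copy()
    return kept_table, ConditioningReport(report)
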