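"""Logistic model, RFE, thresholds, evaluation, adjusted PPV."""

import math

import numpy as np
import pandas as pd
import pytest

from stagefree.classifier import (
    FittedClassifier,
    adjusted_ppv,
    attach_thresholds,
    evaluate,
    fit_logistic,
    grouped_stratified_folds,
    rfe_cv,
    threshold_for_sensitivity,
)


def logistic_table(n, beta, seed=0, split="train"):
    """Synthetic logistic data with known coefficients (one night)."""
    rng = np.random.default_rng(seed)
    p_feat = len(beta)
    x = rng.standard_normal((n, p_feat))
    logit = x @ np.asarray(beta)
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    cols = {f"f{i}": x[:, i] for i in range(p_feat)}
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "night": 1,
            "group": np.where(y, "PTSD", "control"),
            "age": 35.0,
            "split": split,
            **cols,
        }
    )


def planted_table(seed, d=1.5, n_sub=100, n_null=16, frac_pos=0.4):
    """Two iid nights; first three features carry a group shift."""
    rng = np.random.default_rng(seed)
    n_pos = round(frac_pos * n_sub)
    groups = np.array(["PTSD"] * n_pos + ["control"] * (n_sub - n_pos))
    rng.shuffle(groups)
    feats = [f"P{i}" for i in range(3)] + [f"N{i}" for i in range(n_null)]
    rows = []
    for s in range(n_sub):
        eff = np.zeros(len(feats))
        eff[:3] = d * (groups[s] == "PTSD")
        for night in (1, 2):
            vals = eff + rng.standard_normal(len(feats))
            rows.append(
                {
                    "subject_id": f"S{s}", "night": night, "group": groups[s],
                    "age": 35.0, "split": "train", **dict(zip(feats, vals)),
                }
            )
    return pd.DataFrame(rows), feats


class TestAdjustedPpv:
    def test_perfect_test_gives_one(self):
        assert adjusted_ppv(1.0, 1.0, 0.15) == 1.0

    def test_useless_test_returns_prevalence(self):
        # sens = 1 - spec: positive calls carry no information
        assert adjusted_ppv(0.7, 0.3, 0.15) == pytest.approx(0.15)

    def test_zero_denominator_is_missing(self):
        assert math.isnan(adjusted_ppv(0.0, 1.0, 0.15))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjusted_ppv(1.2, 0.5, 0.15)

    def test_strictly_increasing_in_each_argument(self):
        grid = np.linspace(0.05, 0.95, 7)
        for s in grid:
            vals = [adjusted_ppv(s, sp, 0.15) for sp in grid]
            assert all(a < b for a, b in zip(vals, vals[1:]))  # in spec
            vals = [adjusted_ppv(se, s, 0.15) for se in grid]
            assert all(a < b for a, b in zip(vals, vals[1:]))  # in sens
            vals = [adjusted_ppv(0.8, s, pi) for pi in grid]
            assert all(a < b for a, b in zip(vals, vals[1:]))  # in prevalence

    def test_matches_empirical_ppv_at_matching_prevalence(self):
        """On a large sample drawn at prevalence pi, TP/(TP+FP) converges
        to the prevalence-adjusted formula."""
        rng = np.random.default_rng(0)
        n, pi = 200_000, 0.15
        y = rng.random(n) < pi
        score = rng.standard_normal(n) + 1.2 * y
        cut = 0.8
        pred = score > cut
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        empirical = (pred & y).sum() / pred.sum()
        assert adjusted_ppv(sens, spec, pi) == pytest.approx(empirical, abs=0.01)


class TestFitLogistic:
    def test_symmetric_data_small_intercept(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        table = pd.DataFrame(
            {
                "subject_id": list("abcd"), "night": 1,
                "group": ["control", "control", "PTSD", "PTSD"],
                "age": 35.0, "split": "train", "f0": x,
            }
        )
        model = fit_logistic(table, ["f0"])
        assert abs(model.intercept) < 0.15

    def test_label_flip_negates_coefficients(self):
        table = logistic_table(200, [1.0, -0.5], seed=3)
        flipped = table.copy()
        flipped["group"] = np.where(table["group"] == "PTSD", "control", "PTSD")
        m1 = fit_logistic(table, ["f0", "f1"])
        m2 = fit_logistic(flipped, ["f0", "f1"])
        assert np.allclose(m1.coefficients, -m2.coefficients, atol=1e-6)
        assert m1.intercept == pytest.approx(-m2.intercept, abs=1e-6)

    def test_known_coefficients_recovered_within_2se(self):
        beta = np.array([1.0, -0.7])
        table = logistic_table(2000, beta, seed=4)
        model = fit_logistic(table, ["f0", "f1"])
        # asymptotic SE ~ sqrt(diag inverse Fisher); 2000 samples -> ~0.06
        assert np.allclose(model.coefficients, beta, atol=0.15)

    def test_json_round_trip(self):
        table = logistic_table(100, [1.0], seed=5)
        model = attach_thresholds(fit_logistic(table, ["f0"]), table)
        again = FittedClassifier.from_json(model.to_json())
        assert again.feature_names == model.feature_names
        assert np.allclose(again.coefficients, model.coefficients)
        assert again.thresholds == model.thresholds
        assert np.allclose(again.predict_proba(table), model.predict_proba(table))


class TestThresholds:
    def _model_table(self):
        table = logistic_table(300, [2.0], seed=6)
        return fit_logistic(table, ["f0"]), table

    def test_target_zero_gives_cutoff_one(self):
        model, table = self._model_table()
        cutoff, _ = threshold_for_sensitivity(model, table, 0.0)
        assert cutoff == 1.0

    def test_achieved_sensitivity_meets_target(self):
        model, table = self._model_table()
        for target in (0.5, 0.8, 0.9, 1.0):
            cutoff, achieved = threshold_for_sensitivity(model, table, target)
            assert achieved >= target
            p = model.predict_proba(table)
            y = (table["group"] == "PTSD").to_numpy()
            assert ((p[y] >= cutoff).mean()) == pytest.approx(achieved)

    def test_cutoff_monotone_in_target(self):
        model, table = self._model_table()
        c9, _ = threshold_for_sensitivity(model, table, 0.9)
        c8, _ = threshold_for_sensitivity(model, table, 0.8)
        assert c9 <= c8

    def test_perfect_separation_target_one(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        table = pd.DataFrame(
            {
                "subject_id": list("abcd"), "night": 1,
                "group": ["control", "control", "PTSD", "PTSD"],
                "age": 35.0, "split": "train", "f0": x,
            }
        )
        model = fit_logistic(table, ["f0"])
        cutoff, achieved = threshold_for_sensitivity(model, table, 1.0)
        p = model.predict_proba(table)
        assert cutoff == pytest.approx(p[2:].min())
        assert achieved == 1.0


class TestEvaluate:
    def test_all_correct_perfect_rates(self):
        table = logistic_table(40, [5.0], seed=7)
        model = fit_logistic(table, ["f0"])
        m = evaluate(model, table, 0.5)
        if m.sensitivity == 1.0 and m.specificity == 1.0:
            assert m.adjusted_ppv == 1.0
        assert 0.9 <= m.auc <= 1.0

    def test_cutoff_zero_calls_everything_positive(self):
        table = logistic_table(60, [1.0], seed=8)
        model = fit_logistic(table, ["f0"])
        m = evaluate(model, table, 0.0)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0

    def test_metrics_internally_consistent(self):
        table = logistic_table(120, [1.0], seed=9)
        model = fit_logistic(table, ["f0"])
        m = evaluate(model, table, 0.5, prevalence=0.15)
        assert m.adjusted_ppv == pytest.approx(
            adjusted_ppv(m.sensitivity, m.specificity, 0.15), abs=1e-12
        )


class TestFolds:
    def test_nights_stay_together_and_classes_stratified(self):
        subjects = np.array([f"S{i}" for i in range(24)])
        groups = np.array(["PTSD"] * 10 + ["control"] * 14)
        fold_of = grouped_stratified_folds(subjects, groups, 6, seed=0)
        assert set(fold_of.values()) == set(range(6))
        for k in range(6):
            members = [s for s, f in fold_of.items() if f == k]
            gs = {g for s, g in zip(subjects, groups) if s in members}
            assert gs == {"PTSD", "control"}

    def test_too_few_subjects_per_class_rejected(self):
        subjects = np.array([f"S{i}" for i in range(8)])
        groups = np.array(["PTSD"] * 3 + ["control"] * 5)
        with pytest.raises(ValueError, match="fewer than"):
            grouped_stratified_folds(subjects, groups, 6, seed=0)


class TestRfe:
    def test_planted_support_recovered(self):
        hits = 0
        for seed in range(5):
            table, feats = planted_table(seed)
            final = rfe_cv(table, feats, seed=seed)
            hits += set(final) == {"P0", "P1", "P2"}
        assert hits >= 4

    def test_all_null_returns_single_weak_feature(self):
        table, feats = planted_table(11, d=0.0, n_sub=60)
        final = rfe_cv(table, feats, seed=11)
        assert len(final) == 1

    def test_single_separator_always_retained(self):
        rng = np.random.default_rng(12)
        rows = []
        for s in range(48):
            group = "PTSD" if s % 2 else "control"
            for night in (1, 2):
                rows.append(
                    {
                        "subject_id": f"S{s}", "night": night, "group": group,
                        "age": 35.0, "split": "train",
                        "sep": 10.0 * (group == "PTSD") + 0.01 * rng.standard_normal(),
                        **{f"N{i}": rng.standard_normal() for i in range(5)},
                    }
                )
        table = pd.DataFrame(rows)
        final = rfe_cv(table, ["sep"] + [f"N{i}" for i in range(5)], seed=12)
        assert "sep" in final
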