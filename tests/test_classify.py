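"""Mahalanobis rule, LOO drivers, SVM grid search, and metric identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmriskin.classify import (GroupStatsPair, SVMConfig, compute_metrics,
                               enumerate_combinations, loo_driver,
                               loo_univariate, mahalanobis_assign,
                               normalize_features, svm_loo)
from qmriskin.cohort import PARAM_COLUMNS, CohortSpec, draw_cohort


class TestMahalanobisAssign:
    def test_basic_nearest_normalized_mean(self):
        stats = GroupStatsPair(mu_control=-1, sd_control=1, mu_oi=2, sd_oi=1)
        assert mahalanobis_assign(0.0, stats) == "control"

    def test_equal_sds_reduces_to_nearest_mean(self):
        stats = GroupStatsPair(mu_control=0, sd_control=2, mu_oi=10, sd_oi=2)
        midpoint = 5.0
        for x in (-1.0, 4.9, 5.1, 12.0):
            expected = "control" if x < midpoint else "OI"
            assert mahalanobis_assign(x, stats) == expected

    def test_unequal_sds_shift_the_boundary(self):
        # x=2 is nearer the OI side of the equal-SD midpoint (2.5), but the
        # control group's larger SD makes 2 only 0.5 control-SDs away
        # versus 3 OI-SDs: hand arithmetic gives control
        stats = GroupStatsPair(mu_control=0, sd_control=4, mu_oi=5, sd_oi=1)
        assert abs(2 - 0) / 4 == 0.5 and abs(2 - 5) / 1 == 3.0
        assert mahalanobis_assign(2.0, stats) == "control"

    def test_tie_goes_to_control(self):
        stats = GroupStatsPair(mu_control=0, sd_control=1, mu_oi=2, sd_oi=1)
        assert mahalanobis_assign(1.0, stats) == "control"

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            GroupStatsPair(mu_control=0, sd_control=0, mu_oi=1, sd_oi=1)


class TestComputeMetrics:
    def test_perfect_classification(self):
        y = ["OI"] * 9 + ["control"] * 9
        m = compute_metrics(y, y)
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) == (1, 1, 1)

    def test_six_of_nine_each(self):
        y_true = ["OI"] * 9 + ["control"] * 9
        y_pred = (["OI"] * 6 + ["control"] * 3
                  + ["control"] * 6 + ["OI"] * 3)
        m = compute_metrics(y_true, y_pred)
        assert m["sensitivity"] == pytest.approx(6 / 9)
        assert m["specificity"] == pytest.approx(6 / 9)
        assert m["accuracy"] == pytest.approx(12 / 18)
        from qmriskin.io import round_half_up
        assert round_half_up(m["accuracy"]) == 0.67

    def test_balanced_identity(self):
        rng = np.random.default_rng(1)
        y_true = ["OI"] * 9 + ["control"] * 9
        y_pred = list(rng.choice(["OI", "control"], size=18))
        m = compute_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(
            (m["sensitivity"] + m["specificity"]) / 2)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(["OI"], ["sick"])


class TestEnumerateCombinations:
    def test_five_parameters_give_26(self):
        combos = enumerate_combinations()
        assert len(combos) == 26
        sizes = [len(c) for c in combos]
        assert sizes.count(2) == 10 and sizes.count(3) == 10
        assert sizes.count(4) == 5 and sizes.count(5) == 1

    def test_two_parameters_give_one(self):
        assert enumerate_combinations(("a", "b")) == [("a", "b")]

    def test_contains_km_t2_once(self):
        combos = enumerate_combinations()
        assert combos.count(("km", "T2")) == 1


class TestLooUnivariate:
    def test_separated_groups_classify_perfectly(self, separated_table):
        for p in PARAM_COLUMNS:
            m = loo_univariate(separated_table, p)
            assert m.test_accuracy == 1.0
            assert len(m.folds) == 18

    def test_null_groups_near_chance_on_large_n(self, null_spec):
        spec = CohortSpec(n_per_group=(150, 150),
                          control_means=null_spec.control_means,
                          control_sds=null_spec.control_sds,
                          oi_means=null_spec.oi_means,
                          oi_sds=null_spec.oi_sds)
        table = draw_cohort(spec, seed=77)
        m = loo_univariate(table, "T2")
        assert abs(m.test_accuracy - 0.5) < 0.1

    def test_unknown_parameter_rejected(self, cohort_table):
        with pytest.raises(KeyError):
            loo_univariate(cohort_table, "T2star")

    def test_classifier_agnostic_driver_majority_rule(self, cohort_table):
        # a majority-rule classifier scores exactly the largest class share
        def build_rule(train):
            counts = train["group"].value_counts()
            label = "control" if counts.get("control", 0) >= counts.get(
                "OI", 0) else "OI"
            return lambda row: label

        m = loo_driver(cohort_table, build_rule, "majority", ())
        # 9 vs 9: removing a subject always makes its own class minority
        assert m.test_accuracy == 0.0
        # on an unbalanced table the majority class wins its share
        unbal = pd.concat([cohort_table, cohort_table[
            cohort_table.group == "control"]]).reset_index(drop=True)
        m2 = loo_driver(unbal, build_rule, "majority", ())
        frac_control = (unbal.group == "control").mean()
        assert m2.test_accuracy == pytest.approx(frac_control)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0), shift=st.floats(-50.0, 50.0))
    def test_affine_invariance(self, cohort_table, scale, shift):
        """Rescaling a parameter column rescales means and SDs alike, so
        Mahalanobis LOO assignments are unchanged."""
        base = loo_univariate(cohort_table, "T2")
        scaled = cohort_table.copy()
        scaled["T2_ms"] = scaled["T2_ms"] * scale + shift
        m = loo_univariate(scaled, "T2")
        assert [f["predicted"] for f in m.folds] == [
            f["predicted"] for f in base.folds]


class TestNormalizeFeatures:
    def test_pooled_mode_unit_sd(self, cohort_table):
        out, sds = normalize_features(cohort_table, mode="pooled")
        for col in ("T2_ms", "km_per_s"):
            assert out[col].std(ddof=1) == pytest.approx(1.0)

    def test_pooled_equals_full_table_sd_without_folds(self, cohort_table):
        _, sds = normalize_features(cohort_table, mode="pooled")
        assert sds["T2_ms"] == pytest.approx(
            cohort_table["T2_ms"].std(ddof=1))

    def test_train_fold_scaling_applied_to_held_out(self, cohort_table):
        train_idx = cohort_table.index[:-1]
        out, sds = normalize_features(cohort_table, mode="pooled",
                                      train_index=train_idx)
        sd_train = cohort_table.loc[train_idx, "T2_ms"].std(ddof=1)
        held = cohort_table.index[-1]
        assert out.loc[held, "T2_ms"] == pytest.approx(
            cohort_table.loc[held, "T2_ms"] / sd_train)

    def test_group_mean_mode(self, cohort_table):
        _, sds = normalize_features(cohort_table, mode="group_mean")
        by_group = cohort_table.groupby("group")["T2_ms"].std(ddof=1)
        assert sds["T2_ms"] == pytest.approx(by_group.mean())

    def test_zero_sd_rejected(self, cohort_table):
        t = cohort_table.copy()
        t["T2_ms"] = 5.0
        with pytest.raises(ValueError, match="zero SD|SD"):
            normalize_features(t)


class TestSvmLoo:
    def test_separable_groups_classify_perfectly(self, separated_table,
                                                 fast_svm):
        m = svm_loo(separated_table, ("km", "T2"), fast_svm)
        assert m.test_accuracy == 1.0

    def test_single_parameter_rejected(self, cohort_table, fast_svm):
        with pytest.raises(ValueError):
            svm_loo(cohort_table, ("T2",), fast_svm)

    def test_no_leakage_from_held_out_sample(self, cohort_table, fast_svm):
        """Perturbing the held-out sample must not change that fold's
        training artifacts (chosen hyperparameters, training metrics)."""
        m1 = svm_loo(cohort_table, ("km", "T2"), fast_svm)
        perturbed = cohort_table.copy()
        perturbed.loc[perturbed.index[0], "T2_ms"] *= 10.0
        perturbed.loc[perturbed.index[0], "km_per_s"] += 5.0
        m2 = svm_loo(perturbed, ("km", "T2"), fast_svm)
        f1, f2 = m1.folds[0], m2.folds[0]
        assert f1["gamma"] == f2["gamma"] and f1["C"] == f2["C"]
        assert f1["train_metrics"] == f2["train_metrics"]

    def test_deterministic(self, cohort_table, fast_svm):
        a = svm_loo(cohort_table, ("MTR", "T1"), fast_svm)
        b = svm_loo(cohort_table, ("MTR", "T1"), fast_svm)
        assert [f["predicted"] for f in a.folds] == [
            f["predicted"] for f in b.folds]

    def test_matches_public_svc_estimator(self, cohort_table, rng):
        """The low-level solver used in the grid search predicts identically
        to sklearn's public SVC for the same (C, gamma)."""
        from sklearn.svm import SVC

        from qmriskin._svm import fit_predict_rbf

        X = cohort_table[["T2_ms", "km_per_s"]].to_numpy()
        X = X / X.std(axis=0, ddof=1)
        y = (cohort_table["group"] == "OI").to_numpy().astype(int)
        Xt = X + rng.normal(0, 0.3, X.shape)
        for C in (0.4, 1.0, 16.0):
            for gamma in (2.0 ** -6, 0.5, 8.0):
                ours = fit_predict_rbf(X, y, Xt, C, gamma)
                ref = SVC(C=C, gamma=gamma).fit(X, y).predict(Xt)
                assert np.array_equal(ours, ref), (C, gamma)

    def test_balanced_identity_on_all_combinations(self, cohort_table,
                                                   fast_svm):
        for combo in enumerate_combinations()[:6]:
            m = svm_loo(cohort_table, combo, fast_svm)
            assert m.test_accuracy == pytest.approx(
                (m.test_sensitivity + m.test_specificity) / 2)
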