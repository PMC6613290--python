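"""AUC, DeLong inference, pooled metrics, grouped folds, subgroup/transfer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vrisk import (
    ClassifierConfig,
    FoldPlan,
    assign_grouped_folds,
    auc,
    delong_compare,
    delong_se_ci,
    pooled_metrics,
    run_nested_cv,
    subgroup_auc,
)
from vrisk.evaluation import delong_variance, evaluate_scores


def brute_force_auc(scores, labels):
    """Exhaustive positive-negative pair counting, ties counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def delong_fixture():
    """Fixed 40-admission instance; reference values computed independently
    with the pROC implementation of the DeLong estimator."""
    rng = np.random.default_rng(2024)
    y = np.repeat([0, 1], [25, 15])
    s1 = np.round(rng.normal(size=40) + 1.1 * y, 3)
    s2 = np.round(0.6 * s1 + rng.normal(size=40) * 0.8, 3)
    return y, s1, s2


class TestAuc:
    def test_perfect_ranking_gives_one(self):
        assert auc(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0])) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc(np.ones(10), np.repeat([0, 1], 5)) == 0.5

    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        scores = np.round(rng.normal(size=n), 1)   # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestDeLong:
    def test_perfect_separation_gives_zero_standard_error(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        se, lo, hi = delong_se_ci(scores, labels)
        assert se == 0.0
        assert lo == hi == 1.0

    def test_ci_contains_point_auc_and_is_clipped(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        a = auc(scores, labels)
        se, lo, hi = delong_se_ci(scores, labels)
        assert 0.0 <= lo <= a <= hi <= 1.0

    def test_matches_proc_reference_values(self):
        y, s1, s2 = delong_fixture()
        assert auc(s1, y) == pytest.approx(0.7973333333, abs=1e-9)
        assert delong_variance(s1, y) == pytest.approx(0.0048061799, abs=1e-9)
        assert delong_variance(s2, y) == pytest.approx(0.0052163386, abs=1e-9)
        se, lo, hi = delong_se_ci(s1, y)
        assert lo == pytest.approx(0.6614556599, abs=1e-8)
        assert hi == pytest.approx(0.9332110068, abs=1e-8)

    def test_se_close_to_bootstrap_oracle(self):
        rng = np.random.default_rng(11)
        n = 50
        labels = np.repeat([0, 1], [30, 20])
        scores = rng.normal(size=n) + 0.8 * labels
        se, _, _ = delong_se_ci(scores, labels)
        boot = np.empty(10_000)
        for b in range(10_000):
            idx = np.concatenate(
                [rng.integers(0, 30, 30), 30 + rng.integers(0, 20, 20)]
            )
            boot[b] = auc(scores[idx], labels[idx])
        assert abs(se - boot.std(ddof=1)) / boot.std(ddof=1) < 0.15


class TestDeLongCompare:
    def test_self_comparison_gives_zero_difference_and_p_one(self):
        y, s1, _ = delong_fixture()
        res = delong_compare(s1, s1, y, y, paired=True)
        assert res.auc_diff == 0.0
        assert res.p_value == 1.0

    def test_matches_proc_paired_and_unpaired_tests(self):
        y, s1, s2 = delong_fixture()
        paired = delong_compare(s1, s2, y, y, paired=True)
        assert paired.auc_diff == pytest.approx(0.0133333333, abs=1e-9)
        assert paired.p_value == pytest.approx(0.8669725693, abs=1e-8)
        unpaired = delong_compare(s1, s2, y, y, paired=False)
        # pROC refers the identical statistic to a Welch t distribution
        # instead of the normal, shifting p in the 4th decimal
        assert unpaired.p_value == pytest.approx(0.8943918702, abs=1e-3)
        z = unpaired.auc_diff / np.sqrt(0.0048061799 + 0.0052163386)
        assert z == pytest.approx(0.1331835, abs=1e-5)

    def test_paired_variance_not_larger_for_positively_correlated_scores(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            y = rng.integers(0, 2, 60)
            if y.min() == y.max():
                continue
            base = rng.normal(size=60) + y
            s1 = base + 0.3 * rng.normal(size=60)
            s2 = base + 0.3 * rng.normal(size=60)
            paired = delong_compare(s1, s2, y, y, paired=True)
            unpaired = delong_compare(s1, s2, y, y, paired=False)
            se_paired = (paired.ci_high - paired.ci_low) / 2
            se_unpaired = (unpaired.ci_high - unpaired.ci_low) / 2
            assert se_paired <= se_unpaired + 1e-12

    def test_paired_with_mismatched_labels_rejected(self):
        y, s1, s2 = delong_fixture()
        with pytest.raises(ValueError, match="identical admissions"):
            delong_compare(s1, s2, y, 1 - y, paired=True)


class TestPooledMetrics:
    def test_degenerate_perfect_prediction_reports_undefined_relative_risk(self):
        m = pooled_metrics(tn=50, fn=0, tp=50, fp=0)
        assert m.sensitivity == 1.0
        assert m.specificity == 1.0
        assert np.isnan(m.relative_risk)

    @given(st.tuples(st.integers(1, 500), st.integers(1, 500),
                     st.integers(1, 500), st.integers(1, 500)))
    def test_sensitivity_identity_holds(self, counts):
        tn, fn, tp, fp = counts
        m = pooled_metrics(tn, fn, tp, fp)
        assert m.sensitivity * (tp + fn) == pytest.approx(tp)
        assert m.specificity * (tn + fp) == pytest.approx(tn)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            pooled_metrics(-1, 0, 1, 2)


def labeled_frame(n_patients, adm_per_patient=1, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        for a in range(adm_per_patient):
            rows.append(
                {
                    "admission_id": f"p{p:03d}a{a}",
                    "patient_id": f"p{p:03d}",
                    "outcome": int(rng.random() < 0.3),
                }
            )
    return pd.DataFrame(rows)


class TestGroupedFolds:
    def test_patients_with_multiple_admissions_stay_in_one_fold(self):
        labeled = labeled_frame(30, adm_per_patient=3)
        plan = assign_grouped_folds(labeled, k=5, seed=0)
        folds = labeled.assign(fold=plan.fold_of(labeled["admission_id"]))
        assert (folds.groupby("patient_id")["fold"].nunique() == 1).all()

    def test_folds_partition_all_admissions(self):
        labeled = labeled_frame(40, adm_per_patient=2)
        plan = assign_grouped_folds(labeled, k=5, seed=1)
        folds = plan.fold_of(labeled["admission_id"])
        assert len(folds) == len(labeled)
        assert set(folds) == set(range(5))

    def test_singleton_patients_divisible_n_gives_exactly_equal_folds(self):
        labeled = labeled_frame(60, adm_per_patient=1)
        plan = assign_grouped_folds(labeled, k=5, seed=2)
        folds = plan.fold_of(labeled["admission_id"])
        assert list(np.bincount(folds)) == [12] * 5

    def test_more_folds_than_patients_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            assign_grouped_folds(labeled_frame(3), k=5, seed=0)


class TestNestedCv:
    def make_vectors(self, labeled, signal=2.0, dup_noise=None, seed=0):
        rng = np.random.default_rng(seed)
        patients = labeled["patient_id"].unique()
        base = {p: rng.normal(size=4) for p in patients}
        X = []
        for _, row in labeled.iterrows():
            v = base[row["patient_id"]] if dup_noise is not None else rng.normal(size=4)
            if dup_noise is not None:
                v = v + dup_noise * rng.normal(size=4)
            X.append(v + signal * row["outcome"])
        return np.array(X)

    def test_pooled_predictions_cover_each_admission_exactly_once(self):
        labeled = labeled_frame(50, adm_per_patient=2, seed=3)
        X = self.make_vectors(labeled, signal=1.0, seed=3)
        res = run_nested_cv(labeled, X, grid=[ClassifierConfig(cost=1.0)],
                            k_outer=4, k_inner=3, seed=3)
        preds = res.predictions
        assert len(preds) == len(labeled)
        assert preds["admission_id"].is_unique
        assert set(preds["admission_id"]) == set(labeled["admission_id"])
        assert res.tn + res.fn + res.tp + res.fp == len(labeled)

    def test_patient_grouping_prevents_identity_leakage(self):
        # same patient's admissions share (nearly) identical vectors and the
        # same patient-level outcome; ungrouped CV can exploit identity,
        # grouped CV cannot
        grouped_aucs, ungrouped_aucs = [], []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            rows = []
            for p in range(60):
                y = int(rng.random() < 0.5)
                for a in range(2):
                    rows.append({"admission_id": f"p{p}a{a}",
                                 "patient_id": f"p{p}", "outcome": y})
            labeled = pd.DataFrame(rows)
            X = self.make_vectors(labeled, signal=0.0, dup_noise=0.05, seed=seed)
            grid = [ClassifierConfig(cost=1.0)]
            grouped = run_nested_cv(labeled, X, grid=grid, k_outer=4, k_inner=3,
                                    seed=seed)
            fake = labeled.assign(patient_id=labeled["admission_id"])
            ungrouped = run_nested_cv(fake, X, grid=grid, k_outer=4, k_inner=3,
                                      seed=seed)
            grouped_aucs.append(grouped.auc_pooled)
            ungrouped_aucs.append(ungrouped.auc_pooled)
        assert np.mean(grouped_aucs) <= np.mean(ungrouped_aucs)
        assert np.mean(ungrouped_aucs) > 0.6  # the leak the grouping prevents

    def test_empty_grid_rejected(self):
        labeled = labeled_frame(20)
        with pytest.raises(ValueError, match="grid"):
            run_nested_cv(labeled, np.zeros((len(labeled), 2)), grid=[])


class TestSubgroups:
    def make_predictions(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        labeled = labeled_frame(n, seed=seed)
        labeled["length_of_stay"] = rng.lognormal(2.7, 1.0, len(labeled))
        labeled["first_incident_day"] = np.where(
            labeled["outcome"] == 1, rng.uniform(1, 28, len(labeled)), np.nan
        )
        preds = pd.DataFrame(
            {
                "admission_id": labeled["admission_id"],
                "score": rng.normal(size=len(labeled)) + labeled["outcome"],
                "outcome": labeled["outcome"],
            }
        )
        return labeled, preds

    def test_subgroups_are_disjoint_and_cover_everything(self):
        labeled, preds = self.make_predictions()
        from vrisk.evaluation import split_subgroups

        for split in ("early_late_violence", "short_long_admission"):
            mask_a, mask_b, _ = split_subgroups(labeled, split)
            assert not (mask_a & mask_b).any()
            assert (mask_a | mask_b).all()

    def test_degenerate_cutoff_skips_comparison_with_warning(self):
        labeled, preds = self.make_predictions()
        with pytest.warns(UserWarning, match="degenerate"):
            res_a, res_b, comparison = subgroup_auc(
                preds, labeled, "short_long_admission", cutoff=1e9
            )
        assert res_b is None
        assert comparison is None

    def test_both_subgroups_evaluated_on_reasonable_split(self):
        labeled, preds = self.make_predictions(n=120, seed=4)
        res_a, res_b, comparison = subgroup_auc(preds, labeled, "short_long_admission")
        assert res_a is not None and res_b is not None
        assert comparison is not None
        assert 0.0 <= comparison.p_value <= 1.0


def test_evaluate_scores_confusion_conserves_n():
    rng = np.random.default_rng(9)
    labels = rng.integers(0, 2, 200)
    labels[0], labels[1] = 0, 1
    scores = rng.normal(size=200) + labels
    res = evaluate_scores(scores, labels)
    assert res.tn + res.fn + res.tp + res.fp == 200
    assert res.auc_ci_low <= res.auc_pooled <= res.auc_ci_high
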