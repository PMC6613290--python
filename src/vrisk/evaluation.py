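"""Patient-grouped nested cross-validation, DeLong AUC inference, pooled
confusion metrics, subgroup and cross-site transfer evaluation.

Validity design: admissions used to learn a model are never used to score it
(nested cross-validation), and all admissions of one patient stay in one fold
so a patient's later admissions cannot leak into the evaluation of earlier
ones. The headline discrimination measure is the AUC averaged over the outer
folds; confidence intervals and standard errors use the DeLong
placement-value (structural components) estimator on the pooled out-of-fold
scores, and confusion-based metrics (sensitivity, specificity, relative risk)
are computed once from those pooled predictions at the FP/FN-balancing
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

from .risk_model import ClassifierConfig, RiskClassifier, confusion_at, select_threshold


# --------------------------------------------------------------------------
# fold assignment
# --------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Partition of admissions into k patient-grouped folds."""

    k: int
    assignment: dict[str, int]     # admission_id -> fold index
    seed: int

    def fold_of(self, admission_ids) -> np.ndarray:
        return np.array([self.assignment[a] for a in admission_ids])


def assign_grouped_folds(labeled: pd.DataFrame, k: int, seed: int) -> FoldPlan:
    """Assign admissions to k folds, never splitting a patient across folds.

    Patients are shuffled, ordered by admission count (largest first), and
    greedily placed in the currently smallest fold, which balances fold sizes
    as far as the grouping permits. With one admission per patient and n
    divisible by k, fold sizes are exactly n/k.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = labeled.groupby("patient_id", sort=True)["admission_id"].count()
    if k > len(counts):
        raise ValueError(f"k={k} exceeds the number of patients ({len(counts)})")
    rng = np.random.default_rng(seed)
    patients = counts.index.to_numpy()
    sizes = counts.to_numpy()
    perm = rng.permutation(len(patients))
    order = perm[np.argsort(-sizes[perm], kind="mergesort")]
    fold_sizes = np.zeros(k, dtype=int)
    patient_fold: dict[str, int] = {}
    for i in order:
        f = int(np.argmin(fold_sizes))
        patient_fold[patients[i]] = f
        fold_sizes[f] += sizes[i]
    assignment = {
        a: patient_fold[p] for a, p in zip(labeled["admission_id"], labeled["patient_id"])
    }
    return FoldPlan(k=k, assignment=assignment, seed=seed)


# --------------------------------------------------------------------------
# AUC and DeLong inference
# --------------------------------------------------------------------------

def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC requires both outcome classes to be present")
    return pos, neg


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: probability a random positive outscores a random
    negative, ties counted half."""
    pos, neg = _split_scores(scores, labels)
    m, n = len(pos), len(neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _placements(scores, labels):
    """DeLong placement values (V10 for positives, V01 for negatives)."""
    pos, neg = _split_scores(scores, labels)
    m, n = len(pos), len(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    tx = rankdata(pos)
    ty = rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    a = float((tz[:m].sum() - m * (m + 1) / 2) / (m * n))
    return a, v10, v01


def delong_variance(scores, labels) -> float:
    a, v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValueError("DeLong variance requires >= 2 members of each class")
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    return float(s10 / m + s01 / n)


def delong_se_ci(scores, labels, level: float = 0.95):
    """(se, ci_low, ci_high) for the AUC via the DeLong estimator with a
    normal-approximation interval clipped to [0, 1]."""
    a = auc(scores, labels)
    se = float(np.sqrt(max(delong_variance(scores, labels), 0.0)))
    z = norm.ppf(0.5 + level / 2.0)
    return se, float(max(a - z * se, 0.0)), float(min(a + z * se, 1.0))


@dataclass
class ComparisonResult:
    """AUC difference with DeLong-based CI and two-sided p-value."""

    auc_1: float
    auc_2: float
    auc_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    paired: bool
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def delong_compare(
    scores_1,
    scores_2,
    labels_1,
    labels_2,
    paired: bool,
    level: float = 0.95,
) -> ComparisonResult:
    """Two-sided z-test on the difference of two AUCs.

    Paired: the two score vectors are for the same admissions with identical
    labels; the DeLong covariance of the placement values accounts for the
    correlation. Unpaired: independent samples, variances add.
    """
    labels_1 = np.asarray(labels_1, dtype=int)
    labels_2 = np.asarray(labels_2, dtype=int)
    if paired:
        if len(labels_1) != len(labels_2) or not np.array_equal(labels_1, labels_2):
            raise ValueError("paired comparison requires identical admissions and labels")
        a1, v10_1, v01_1 = _placements(scores_1, labels_1)
        a2, v10_2, v01_2 = _placements(scores_2, labels_2)
        m, n = len(v10_1), len(v01_1)
        s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1)
        s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n
    else:
        a1 = auc(scores_1, labels_1)
        a2 = auc(scores_2, labels_2)
        var = delong_variance(scores_1, labels_1) + delong_variance(scores_2, labels_2)
    diff = a1 - a2
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
    else:
        p = float(2.0 * norm.sf(abs(diff) / se))
    z = norm.ppf(0.5 + level / 2.0)
    return ComparisonResult(
        auc_1=float(a1),
        auc_2=float(a2),
        auc_diff=float(diff),
        ci_low=float(diff - z * se),
        ci_high=float(diff + z * se),
        p_value=p,
        paired=paired,
    )


# --------------------------------------------------------------------------
# pooled confusion metrics
# --------------------------------------------------------------------------

@dataclass
class PooledMetrics:
    """Sensitivity, specificity and relative risk from pooled predictions.

    Relative risk is the outcome risk among predicted-high-risk admissions
    divided by the risk among predicted-low-risk admissions. Undefined
    metrics (zero denominator, zero baseline risk) are reported as NaN.
    Sensitivity/specificity CIs are Wilson intervals; the relative-risk CI is
    the Katz log-scale interval — both documented approximations.
    """

    tn: int
    fn: int
    tp: int
    fp: int
    sensitivity: float
    specificity: float
    relative_risk: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    relative_risk_ci: tuple[float, float]


def pooled_metrics(tn: int, fn: int, tp: int, fp: int, level: float = 0.95) -> PooledMetrics:
    if min(tn, fn, tp, fp) < 0:
        raise ValueError("confusion counts must be nonnegative")
    nan = float("nan")

    def _prop(x, n):
        if n == 0:
            return nan, (nan, nan)
        lo, hi = proportion_confint(x, n, alpha=1 - level, method="wilson")
        return x / n, (float(lo), float(hi))

    sens, sens_ci = _prop(tp, tp + fn)
    spec, spec_ci = _prop(tn, tn + fp)

    pred_pos, pred_neg = tp + fp, fn + tn
    if pred_pos == 0 or pred_neg == 0 or fn == 0 or tp == 0:
        rr, rr_ci = nan, (nan, nan)
    else:
        rr = (tp / pred_pos) / (fn / pred_neg)
        z = norm.ppf(0.5 + level / 2.0)
        log_se = np.sqrt(1 / tp - 1 / pred_pos + 1 / fn - 1 / pred_neg)
        rr_ci = (float(rr * np.exp(-z * log_se)), float(rr * np.exp(z * log_se)))
    return PooledMetrics(
        tn=tn, fn=fn, tp=tp, fp=fp,
        sensitivity=sens, specificity=spec, relative_risk=rr,
        sensitivity_ci=sens_ci, specificity_ci=spec_ci, relative_risk_ci=rr_ci,
    )


# --------------------------------------------------------------------------
# evaluation results
# --------------------------------------------------------------------------

@dataclass
class EvalResult:
    """AUC (fold-mean and pooled) with DeLong inference, confusion counts at
    the selected threshold, and derived metrics."""

    auc: float                       # mean of outer-fold AUCs (or pooled AUC when no folds)
    auc_pooled: float
    auc_se: float
    auc_ci_low: float
    auc_ci_high: float
    fold_aucs: list[float] = field(default_factory=list)
    tn: int = 0
    fn: int = 0
    tp: int = 0
    fp: int = 0
    threshold: float = 0.0
    metrics: PooledMetrics | None = None
    predictions: pd.DataFrame | None = None
    n: int = 0
    chosen_configs: list[ClassifierConfig] = field(default_factory=list)


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float | None = None,
    fold_aucs: list[float] | None = None,
    predictions: pd.DataFrame | None = None,
) -> EvalResult:
    """Assemble an EvalResult from a single pooled score vector."""
    a_pooled = auc(scores, labels)
    se, lo, hi = delong_se_ci(scores, labels)
    if threshold is None:
        threshold = select_threshold(scores, labels)
    tn, fn, tp, fp = confusion_at(scores, labels, threshold)
    fold_aucs = fold_aucs or []
    return EvalResult(
        auc=float(np.mean(fold_aucs)) if fold_aucs else a_pooled,
        auc_pooled=a_pooled,
        auc_se=se,
        auc_ci_low=lo,
        auc_ci_high=hi,
        fold_aucs=list(fold_aucs),
        tn=tn, fn=fn, tp=tp, fp=fp,
        threshold=float(threshold),
        metrics=pooled_metrics(tn, fn, tp, fp),
        predictions=predictions,
        n=len(labels),
    )


# --------------------------------------------------------------------------
# nested cross-validation
# --------------------------------------------------------------------------

def default_grid() -> list[ClassifierConfig]:
    """Cost x kernel-width grid for the RBF margin classifier."""
    return [
        ClassifierConfig(cost=c, kernel_width=g)
        for c in (0.1, 1.0, 10.0, 100.0)
        for g in ("scale", 0.001, 0.01, 0.1)
    ]


def _inner_select(
    train_df: pd.DataFrame,
    train_vectors: np.ndarray,
    grid: list[ClassifierConfig],
    k_inner: int,
    seed: int,
) -> ClassifierConfig:
    """Pick the grid point with best patient-grouped inner-CV mean AUC."""
    inner_plan = assign_grouped_folds(train_df, k_inner, seed)
    inner_folds = inner_plan.fold_of(train_df["admission_id"])
    y = train_df["outcome"].to_numpy()
    best_cfg, best_auc = None, -np.inf
    for cfg in grid:
        fold_aucs = []
        for f in range(k_inner):
            tr, te = inner_folds != f, inner_folds == f
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                warnings.warn(
                    f"inner fold {f} has a single outcome class; skipping", stacklevel=2
                )
                continue
            clf = RiskClassifier(cfg).fit(train_vectors[tr], y[tr])
            fold_aucs.append(auc(clf.decision_scores(train_vectors[te]), y[te]))
        if not fold_aucs:
            continue
        mean_auc = float(np.mean(fold_aucs))
        if mean_auc > best_auc:
            best_cfg, best_auc = cfg, mean_auc
    if best_cfg is None:
        raise ValueError("every inner-fold evaluation was skipped; cannot select hyperparameters")
    return best_cfg


def run_nested_cv(
    labeled: pd.DataFrame,
    vectors: np.ndarray,
    grid: list[ClassifierConfig] | None = None,
    plan: FoldPlan | None = None,
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int = 0,
) -> EvalResult:
    """Nested, patient-grouped cross-validation of the risk classifier.

    ``labeled`` rows align with ``vectors`` rows. For each outer fold the
    inner CV selects the best grid point by mean inner AUC, the classifier is
    refit on the whole outer-training set and scored on the outer-test set.
    The final AUC is the unweighted mean of the outer-fold AUCs; DeLong
    inference, the FP/FN-balancing threshold and confusion metrics come from
    the pooled out-of-fold predictions, which cover every admission exactly
    once.
    """
    if len(labeled) != len(vectors):
        raise ValueError("labeled table and vector matrix must align row-wise")
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("hyperparameter grid must be nonempty")
    if plan is None:
        plan = assign_grouped_folds(labeled, k_outer, seed)
    folds = plan.fold_of(labeled["admission_id"])
    y = labeled["outcome"].to_numpy()
    scores = np.full(len(labeled), np.nan)
    fold_aucs: list[float] = []
    chosen: list[ClassifierConfig] = []
    for f in range(plan.k):
        tr, te = folds != f, folds == f
        cfg = _inner_select(
            labeled[tr], vectors[tr], grid, k_inner, seed=seed * 1009 + f + 1
        )
        chosen.append(cfg)
        clf = RiskClassifier(cfg).fit(vectors[tr], y[tr])
        scores[te] = clf.decision_scores(vectors[te])
        if len(np.unique(y[te])) < 2:
            warnings.warn(f"outer fold {f} has a single outcome class; fold AUC skipped",
                          stacklevel=2)
            continue
        fold_aucs.append(auc(scores[te], y[te]))
    assert not np.isnan(scores).any()
    predictions = pd.DataFrame(
        {
            "admission_id": labeled["admission_id"].to_numpy(),
            "fold": folds,
            "score": scores,
            "outcome": y,
        }
    )
    result = evaluate_scores(scores, y, fold_aucs=fold_aucs, predictions=predictions)
    result.chosen_configs = chosen
    return result


# --------------------------------------------------------------------------
# subgroup analysis
# --------------------------------------------------------------------------

def split_subgroups(
    labeled: pd.DataFrame, split: str, cutoff: float | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Partition admissions into two disjoint subgroups.

    ``short_long_admission``: by length of stay <= cutoff (default: cohort
    median). ``early_late_violence``: positives split by first-incident day
    <= cutoff (default 14 d); label-negative admissions are alternated
    deterministically between the two subgroups (by admission_id order) so
    the subgroups stay disjoint and each contains its own comparison
    negatives. Returns (mask_a, mask_b, cutoff).
    """
    if split == "short_long_admission":
        if cutoff is None:
            cutoff = float(labeled["length_of_stay"].median())
        mask_a = (labeled["length_of_stay"] <= cutoff).to_numpy()
        return mask_a, ~mask_a, cutoff
    if split == "early_late_violence":
        if cutoff is None:
            cutoff = 14.0
        y = labeled["outcome"].to_numpy()
        first = labeled["first_incident_day"].to_numpy()
        mask_a = np.zeros(len(labeled), dtype=bool)
        mask_a[(y == 1) & (first <= cutoff)] = True
        neg_idx = np.flatnonzero(y == 0)
        order = np.argsort(labeled["admission_id"].to_numpy()[neg_idx], kind="mergesort")
        mask_a[neg_idx[order[::2]]] = True
        mask_b = ~mask_a
        return mask_a, mask_b, cutoff
    raise ValueError(f"unknown split {split!r}")


def subgroup_auc(
    predictions: pd.DataFrame,
    labeled: pd.DataFrame,
    split: str,
    cutoff: float | None = None,
):
    """AUC per subgroup from already-pooled predictions, plus an unpaired
    DeLong comparison. Degenerate subgroups (one class or empty) skip the
    comparison with a warning and report None for that side."""
    merged = labeled.merge(predictions[["admission_id", "score"]], on="admission_id")
    mask_a, mask_b, cutoff = split_subgroups(merged, split, cutoff)
    results = []
    for mask in (mask_a, mask_b):
        sub = merged[mask]
        if len(sub) == 0 or sub["outcome"].nunique() < 2:
            warnings.warn(f"subgroup of split {split!r} is degenerate; skipped", stacklevel=2)
            results.append(None)
            continue
        s, y = sub["score"].to_numpy(), sub["outcome"].to_numpy()
        se, lo, hi = delong_se_ci(s, y)
        results.append(
            EvalResult(
                auc=auc(s, y), auc_pooled=auc(s, y), auc_se=se,
                auc_ci_low=lo, auc_ci_high=hi, n=len(sub),
            )
        )
    comparison = None
    if results[0] is not None and results[1] is not None:
        sub_a, sub_b = merged[mask_a], merged[mask_b]
        comparison = delong_compare(
            sub_a["score"].to_numpy(), sub_b["score"].to_numpy(),
            sub_a["outcome"].to_numpy(), sub_b["outcome"].to_numpy(),
            paired=False,
        )
    return results[0], results[1], comparison


# --------------------------------------------------------------------------
# cross-site transfer
# --------------------------------------------------------------------------

def transfer_evaluate(
    embedding_model,
    classifier: RiskClassifier,
    threshold: float,
    labeled_target: pd.DataFrame,
    documents_target: list[list[str]],
    internal_predictions: pd.DataFrame | None = None,
    embed_seed: int | None = None,
):
    """Evaluate a fully frozen source-site pipeline on the target site.

    Target documents are embedded with the source site's embedding model and
    scored by its classifier; confusion counts use the source site's frozen
    threshold. If the target site's internal pooled predictions are supplied,
    a paired DeLong comparison on the identical admissions is returned.
    """
    vectors = embedding_model.embed(documents_target, seed=embed_seed)
    scores = classifier.decision_scores(vectors)
    y = labeled_target["outcome"].to_numpy()
    predictions = pd.DataFrame(
        {
            "admission_id": labeled_target["admission_id"].to_numpy(),
            "score": scores,
            "outcome": y,
        }
    )
    result = evaluate_scores(scores, y, threshold=threshold, predictions=predictions)
    comparison = None
    if internal_predictions is not None:
        merged = predictions.merge(
            internal_predictions[["admission_id", "score", "outcome"]],
            on="admission_id",
            suffixes=("_ext", "_int"),
        )
        if len(merged) != len(predictions):
            raise ValueError("internal predictions do not cover the same admissions")
        comparison = delong_compare(
            merged["score_int"].to_numpy(), merged["score_ext"].to_numpy(),
            merged["outcome_int"].to_numpy(), merged["outcome_ext"].to_numpy(),
            paired=True,
        )
    return result, comparison


def roc_coordinates(scores, labels) -> pd.DataFrame:
    """FPR/TPR coordinates over all score cut-points (for ROC plotting)."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
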