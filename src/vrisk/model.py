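"""Model/Results interface over the pipeline.

:class:`ViolenceRiskModel` holds one site's labeled admissions and predictor
documents; ``fit`` trains the unsupervised document embedding, runs
patient-grouped nested cross-validation of the RBF margin classifier, and
returns a :class:`CrossValidationResults` carrying the fold-averaged and
pooled AUCs with DeLong inference, confusion counts at the FP/FN-balancing
threshold, derived metrics with CIs, and the frozen site pipeline (embedding,
standardization, classifier, threshold) needed for cross-site transfer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import build_labeled_admissions, CohortResult
from .embedding import EmbeddingConfig, ParagraphVectors
from .risk_model import ClassifierConfig, RiskClassifier
from .evaluation import (
    ComparisonResult,
    EvalResult,
    FoldPlan,
    assign_grouped_folds,
    default_grid,
    delong_compare,
    run_nested_cv,
    subgroup_auc,
    transfer_evaluate,
)


def _fmt_ci(x, lo, hi, nd=3):
    return f"{x:.{nd}f} ({lo:.{nd}f}-{hi:.{nd}f})"


def _result_summary(title: str, res: EvalResult) -> str:
    m = res.metrics
    lines = [
        title,
        "=" * len(title),
        f"Admissions, No.                 {res.n}",
        f"AUC (95% CI) [SE]               "
        f"{_fmt_ci(res.auc, res.auc_ci_low, res.auc_ci_high)} [{res.auc_se:.3f}]",
        f"AUC, pooled over folds          {res.auc_pooled:.3f}",
    ]
    if res.fold_aucs:
        lines.append(
            "Fold AUCs                       "
            + ", ".join(f"{a:.3f}" for a in res.fold_aucs)
        )
    lines += [
        f"True negative, No.              {res.tn}",
        f"False negative, No.             {res.fn}",
        f"True positive, No.              {res.tp}",
        f"False positive, No.             {res.fp}",
        f"Specificity (95% CI)            {_fmt_ci(m.specificity, *m.specificity_ci)}",
        f"Sensitivity (95% CI)            {_fmt_ci(m.sensitivity, *m.sensitivity_ci)}",
    ]
    if np.isfinite(m.relative_risk):
        lines.append(
            f"Relative risk (95% CI)          {_fmt_ci(m.relative_risk, *m.relative_risk_ci)}"
        )
    else:
        lines.append("Relative risk (95% CI)          undefined")
    lines.append(f"Score threshold (FP~FN)         {res.threshold:.4f}")
    return "\n".join(lines)


class ViolenceRiskModel:
    """Violence risk assessment from one site's clinical-note documents.

    Parameters
    ----------
    labeled : DataFrame with admission_id, patient_id, outcome,
        length_of_stay, first_incident_day (the cohort module's output).
    documents : mapping admission_id -> predictor-window token sequence.
    embedding_config, grid, k_outer, k_inner : pipeline settings; the grid
        defaults to cost {0.1, 1, 10, 100} x kernel width {scale, 1e-3,
        1e-2, 0.1}.
    """

    def __init__(
        self,
        labeled: pd.DataFrame,
        documents: dict[str, list[str]],
        embedding_config: EmbeddingConfig | None = None,
        grid: list[ClassifierConfig] | None = None,
        k_outer: int = 5,
        k_inner: int = 5,
        site: str = "",
    ):
        missing = [a for a in labeled["admission_id"] if a not in documents]
        if missing:
            raise ValueError(f"{len(missing)} admissions lack documents (e.g. {missing[0]})")
        self.labeled = labeled.reset_index(drop=True)
        self.documents = documents
        self.embedding_config = embedding_config or EmbeddingConfig()
        self.grid = default_grid() if grid is None else grid
        self.k_outer = k_outer
        self.k_inner = k_inner
        self.site = site

    @classmethod
    def from_tables(
        cls,
        admissions: pd.DataFrame,
        notes: pd.DataFrame,
        incidents: pd.DataFrame,
        max_gap_days: int = 14,
        **kwargs,
    ) -> "ViolenceRiskModel":
        """Build from the raw admissions/notes/incidents tables by running
        the cohort pipeline (episode merging, windowing, labeling,
        documentation exclusion)."""
        cohort = build_labeled_admissions(
            admissions, notes, incidents, max_gap_days=max_gap_days
        )
        model = cls(cohort.labeled, cohort.documents, **kwargs)
        model.cohort_ = cohort
        return model

    @classmethod
    def from_corpus(cls, corpus, **kwargs) -> "ViolenceRiskModel":
        """Build from a synthetic :class:`~vrisk.synthetic.SiteCorpus`."""
        return cls.from_tables(
            corpus.admissions, corpus.notes, corpus.incidents,
            site=corpus.profile.site_id, **kwargs,
        )

    # -- estimation -----------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        training_corpus: list[list[str]] | None = None,
        plan: FoldPlan | None = None,
    ) -> "CrossValidationResults":
        """Train the embedding (optionally on a larger unsupervised corpus),
        embed all admission documents, run nested cross-validation, and
        freeze the site pipeline for transfer."""
        docs = [self.documents[a] for a in self.labeled["admission_id"]]
        corpus = training_corpus if training_corpus is not None else docs
        emb_cfg = EmbeddingConfig(**{**self.embedding_config.__dict__, "seed": seed})
        embedding = ParagraphVectors(emb_cfg).fit(corpus)
        vectors = embedding.embed(docs, seed=seed + 1)
        if plan is None:
            plan = assign_grouped_folds(self.labeled, self.k_outer, seed)
        result = run_nested_cv(
            self.labeled, vectors, grid=self.grid, plan=plan,
            k_inner=self.k_inner, seed=seed,
        )
        # freeze one site model for exchange: refit with the config most often
        # chosen by the outer folds, on all admissions, at the pooled threshold
        final_cfg = Counter(
            (c.cost, c.kernel_width) for c in result.chosen_configs
        ).most_common(1)[0][0]
        final = RiskClassifier(ClassifierConfig(*final_cfg)).fit(
            vectors, self.labeled["outcome"].to_numpy()
        )
        return CrossValidationResults(
            model=self,
            result=result,
            embedding=embedding,
            vectors=vectors,
            classifier=final,
            plan=plan,
            seed=seed,
        )


@dataclass
class CrossValidationResults:
    """Internal (in-site) nested cross-validation results plus the frozen
    site pipeline."""

    model: ViolenceRiskModel
    result: EvalResult
    embedding: ParagraphVectors
    vectors: np.ndarray
    classifier: RiskClassifier
    plan: FoldPlan
    seed: int

    @property
    def auc(self) -> float:
        return self.result.auc

    @property
    def predictions(self) -> pd.DataFrame:
        return self.result.predictions

    @property
    def threshold(self) -> float:
        return self.result.threshold

    def summary(self) -> str:
        site = self.model.site or "site"
        return _result_summary(f"Internal cross-validation — {site}", self.result)

    def subgroups(self, split: str, cutoff: float | None = None):
        """Subgroup AUCs (early/late violence or short/long admission) from
        the pooled predictions, with an unpaired DeLong comparison."""
        return subgroup_auc(self.result.predictions, self.model.labeled, split, cutoff)

    def transfer_to(
        self, target: ViolenceRiskModel, target_results: "CrossValidationResults" = None
    ) -> "TransferResults":
        """Evaluate this site's frozen pipeline on the target site's
        admissions; paired DeLong comparison against the target's internal
        pooled predictions when supplied."""
        if target is self.model:
            # assessing a site with its own model is, by definition, the
            # internal cross-validated evaluation (held-out pooled predictions)
            p = self.result.predictions
            comparison = delong_compare(
                p["score"], p["score"], p["outcome"], p["outcome"], paired=True
            )
            return TransferResults(
                source_site=self.model.site, target_site=self.model.site,
                result=self.result, comparison=comparison,
            )
        docs = [target.documents[a] for a in target.labeled["admission_id"]]
        internal = target_results.result.predictions if target_results is not None else None
        result, comparison = transfer_evaluate(
            self.embedding, self.classifier, self.threshold,
            target.labeled, docs, internal, embed_seed=self.seed + 2,
        )
        return TransferResults(
            source_site=self.model.site, target_site=target.site,
            result=result, comparison=comparison,
        )


@dataclass
class TransferResults:
    """External validation of a frozen pipeline on the other site."""

    source_site: str
    target_site: str
    result: EvalResult
    comparison: ComparisonResult | None

    @property
    def auc(self) -> float:
        return self.result.auc

    def summary(self) -> str:
        title = (
            f"External model — trained in {self.source_site or 'source'}, "
            f"evaluated in {self.target_site or 'target'}"
        )
        text = _result_summary(title, self.result)
        if self.comparison is not None:
            c = self.comparison
            text += (
                "\nInternal vs external AUC diff   "
                f"{_fmt_ci(c.auc_diff, c.ci_low, c.ci_high)}; P = {c.p_value:.3g}"
                f" ({'significant' if c.significant else 'not significant'} at 0.01)"
            )
        return text
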