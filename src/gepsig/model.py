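"""Model/Results front-end for signature discovery.

:class:`MeningiomaSignatureModel` bundles an expression matrix, a
clinical table and the discovery hyperparameters; :meth:`fit` runs the
full discovery chain (normalization, MAD and redundancy filters,
null-model deviance residuals, GA + SVR subset search, score transform,
partition cutoff, cross-validation, training evaluation) and returns a
:class:`SignatureDiscoveryResults` carrying the frozen classifier, the
per-stage reports and a ``summary()`` table.  The results object also
applies the frozen classifier to new cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as gio
from .containers import ClinicalTable, ExpressionMatrix
from .evaluation import EvaluationReport, evaluate_classification
from .preprocess import (
    FilterReport,
    batch_center,
    drop_degenerate_probes,
    hierarchical_groups,
    kmeans_redundancy_filter,
    mad_filter,
    median_scale,
)
from .signature import (
    CVReport,
    GAConfig,
    ModelScore,
    SignatureModel,
    SVRParams,
    classify,
    cross_validate,
    fit_svr,
    ga_select,
    inverse_transform_scores,
    partition_cutoff,
    standardize_response,
)
from .survstats import harrell_c, null_deviance_residuals

logger = logging.getLogger(__name__)

__all__ = [
    "MeningiomaSignatureModel",
    "SignatureDiscoveryResults",
    "derive_seed",
    "apply_frozen_preprocessing",
]


def apply_frozen_preprocessing(
    model: SignatureModel, expression: ExpressionMatrix
) -> ExpressionMatrix:
    """Frozen normalization of a new cohort for a fitted signature model.

    Median-scales the full matrix to the stored training grand median,
    then batch-centers the model probes onto the stored per-probe
    training reference locations.  Nothing is re-estimated from the new
    cohort beyond its own column medians and batch means.
    """
    meta = model.metadata
    scaled = median_scale(expression, target=meta["grand_median"])
    sub = scaled.subset_probes(model.probe_ids)
    reference = pd.Series(meta["probe_reference"]).reindex(sub.values.index)
    return batch_center(sub, reference=reference)

_STAGE_IDS = {"kmeans": 11, "ga": 23, "cv": 37}


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from the top-level seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


class MeningiomaSignatureModel:
    """Survival-supervised gene-signature discovery model.

    Parameters
    ----------
    expression : ExpressionMatrix
        Probe-by-sample log2 matrix with batch labels (training cohort).
    clinical : ClinicalTable
        Censored recurrence outcomes, sample-aligned with ``expression``.
    mad_cutoff : float
        Minimum per-probe MAD (log2 units) to enter model selection.
    radius : float
        Correlation radius of the k-means redundancy filter.
    k : int or None
        Cluster count for the redundancy filter (None: n_probes // 10).
    ga_config, svr_params
        Search and regression hyperparameters.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        clinical: ClinicalTable,
        mad_cutoff: float = 0.5,
        radius: float = 0.95,
        k: int | None = None,
        ga_config: GAConfig | None = None,
        svr_params: SVRParams | None = None,
        cv_folds: int = 50,
        cv_holdout: float = 0.10,
    ) -> None:
        missing = [s for s in expression.sample_ids if s not in clinical.data.index]
        extra = [s for s in clinical.data.index if s not in expression.sample_ids]
        if missing or extra:
            raise ValueError(
                "expression/clinical sample mismatch; "
                f"missing from clinical: {missing[:5]}, "
                f"missing from expression: {extra[:5]}"
            )
        self.expression = expression
        self.clinical = clinical.aligned_to(expression.sample_ids)
        self.mad_cutoff = mad_cutoff
        self.radius = radius
        self.k = k
        self.ga_config = ga_config or GAConfig()
        self.svr_params = svr_params or SVRParams()
        self.cv_folds = cv_folds
        self.cv_holdout = cv_holdout

    @classmethod
    def from_files(
        cls, expression_path, clinical_path, batch_path=None, **kwargs
    ) -> "MeningiomaSignatureModel":
        expr = gio.read_expression(expression_path, batch_path)
        clin = gio.read_clinical(clinical_path)
        return cls(expr, clin.aligned_to(expr.sample_ids), **kwargs)

    def fit(self, seed: int = 0) -> "SignatureDiscoveryResults":
        """Run the end-to-end discovery chain on the training cohort."""
        # 1. normalization, frozen references for prospective application
        scaled = median_scale(self.expression)
        grand_median = float(np.median(self.expression.values.to_numpy()))
        centered = batch_center(scaled)
        centered = drop_degenerate_probes(centered)
        probe_reference = centered.values.mean(axis=1)

        # 2. variability and redundancy filters
        mad_matrix, mad_report = mad_filter(centered, self.mad_cutoff)
        if mad_matrix.n_probes == 0:
            raise ValueError("no probes survive the MAD filter")
        km_seed = derive_seed(seed, "kmeans")
        pool, km_report = kmeans_redundancy_filter(
            mad_matrix, radius=self.radius, k=self.k, seed=km_seed
        )
        if pool.n_probes == 0:
            raise ValueError("no probes survive the redundancy filter")
        logger.info(
            "filter chain: %d -> %d (MAD) -> %d (redundancy)",
            centered.n_probes, mad_matrix.n_probes, pool.n_probes,
        )

        # 3. censoring-aware response
        resid = null_deviance_residuals(self.clinical.time, self.clinical.event)
        y, response_scale = standardize_response(resid.deviance)

        # 4. GA subset search (lexicographic Harrell C / AIC / BIC / RMSE)
        ga = GAConfig(**{**self.ga_config.__dict__, "seed": derive_seed(seed, "ga")})
        subset, score = ga_select(
            pool, y, self.clinical.time, self.clinical.event,
            config=ga, params=self.svr_params,
        )

        # 5. final refit on all samples; score transform and cutoff
        reg = fit_svr(pool, subset, y, self.svr_params)
        pred = reg.predict(pool)
        pred_mean = float(pred.mean())
        pred_sd = float(pred.std()) or 1.0
        raw = 1.0 / (1.0 + np.exp(-(pred - pred_mean) / pred_sd))
        transformed = inverse_transform_scores(raw)
        order = np.argsort(raw, kind="stable")
        tx, ty = raw[order], transformed[order]
        uniq = np.concatenate([[True], np.diff(tx) > 0])
        # min-leaf guard: each risk class gets >= 10% of the cohort
        min_leaf = max(5, int(round(0.10 * len(y))))
        cutoff = partition_cutoff(transformed, y, min_leaf=min_leaf)
        model = SignatureModel(
            regressor=reg,
            response_scale=response_scale,
            pred_mean=pred_mean,
            pred_sd=pred_sd,
            transform_x=tx[uniq],
            transform_y=ty[uniq],
            cutoff=cutoff,
            metadata={
                "seed": int(seed),
                "grand_median": grand_median,
                "probe_reference": {
                    p: float(probe_reference[p]) for p in subset
                },
                "mad_cutoff": self.mad_cutoff,
                "radius": self.radius,
            },
        )

        # 6. repeated-holdout CV of the selected subset
        cv = cross_validate(
            pool, subset, y,
            folds=self.cv_folds, holdout=self.cv_holdout,
            seed=derive_seed(seed, "cv"), params=self.svr_params,
        )

        # 7. training-cohort classification and evaluation
        classes = classify(model, pool)
        train_c = harrell_c(
            model.transformed_scores(pool), self.clinical.time, self.clinical.event
        )
        evaluation = evaluate_classification(classes, self.clinical)
        grouping = hierarchical_groups(pool, n_groups=2)

        return SignatureDiscoveryResults(
            model=model,
            signature_model=self,
            filter_reports=[mad_report, km_report],
            model_score=score,
            cv_report=cv,
            training_classes=classes,
            training_scores=pd.Series(
                model.transformed_scores(pool), index=pool.sample_ids, name="score"
            ),
            training_harrell_c=train_c,
            training_evaluation=evaluation,
            exploratory_grouping=grouping,
            seed=seed,
        )


@dataclass
class SignatureDiscoveryResults:
    """Fitted signature classifier plus discovery diagnostics."""

    model: SignatureModel
    signature_model: MeningiomaSignatureModel
    filter_reports: list[FilterReport]
    model_score: ModelScore
    cv_report: CVReport
    training_classes: pd.Series
    training_scores: pd.Series
    training_harrell_c: float
    training_evaluation: EvaluationReport
    exploratory_grouping: object
    seed: int = 0

    @property
    def probe_ids(self) -> list[str]:
        return self.model.probe_ids

    @property
    def cutoff(self) -> float:
        return self.model.cutoff

    def preprocess_cohort(self, expression: ExpressionMatrix) -> ExpressionMatrix:
        """Apply frozen normalization to a new cohort's matrix.

        Median-scales the full matrix to the training grand median, then
        batch-centers the model probes onto the frozen training per-probe
        reference locations.
        """
        return apply_frozen_preprocessing(self.model, expression)

    def classify(self, expression: ExpressionMatrix) -> pd.Series:
        """Frozen-model risk classes for a new cohort (no refitting)."""
        return classify(self.model, self.preprocess_cohort(expression))

    def scores(self, expression: ExpressionMatrix) -> pd.Series:
        pre = self.preprocess_cohort(expression)
        return pd.Series(
            self.model.transformed_scores(pre), index=pre.sample_ids, name="score"
        )

    def evaluate(
        self,
        expression: ExpressionMatrix,
        clinical: ClinicalTable,
        covariates: list[str] | None = None,
    ) -> EvaluationReport:
        """Classify a new cohort and evaluate against its outcomes."""
        classes = self.classify(expression)
        return evaluate_classification(classes, clinical.aligned_to(list(classes.index)), covariates)

    def plot_km(self, expression=None, clinical=None, ax=None):
        from .evaluation import plot_km

        if expression is None:
            return plot_km(self.training_classes, self.signature_model.clinical, ax=ax)
        return plot_km(self.classify(expression), clinical, ax=ax)

    def summary(self) -> str:
        n_cls = self.training_classes.value_counts().to_dict()
        lines = [
            "Signature discovery results",
            "===========================",
            f"selected probes ({len(self.probe_ids)}): "
            + ", ".join(self.probe_ids[:8])
            + (" ..." if len(self.probe_ids) > 8 else ""),
            f"training Harrell C (risk score vs outcome): {self.training_harrell_c:.4f}",
            f"model score: C={self.model_score.harrell_c:.4f}, "
            f"AIC={self.model_score.aic:.2f}, BIC={self.model_score.bic:.2f}, "
            f"RMSE={self.model_score.rmse:.4f}",
            f"cross-validation ({self.cv_report.folds}x "
            f"{int(self.cv_report.holdout * 100)}% holdout) mean RMSE: "
            f"{self.cv_report.mean_rmse:.4f}",
            f"risk cutoff (transformed score): {self.cutoff:.4f}",
            f"training classes: {n_cls}",
        ]
        for rep in self.filter_reports:
            lines.append(
                f"filter {rep.stage}: {rep.n_input} -> {rep.n_retained} "
                f"(threshold {rep.threshold})"
            )
        ev = self.training_evaluation
        if ev.logrank_p is not None:
            lines.append(
                f"training log-rank: chi2={ev.logrank_statistic:.3f}, p={ev.logrank_p:.4g}"
            )
        if ev.misclassification is not None:
            lines.append(
                f"training misclassification among events: {ev.misclassification:.4f}"
            )
        return "\n".join(lines) + "\n"
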