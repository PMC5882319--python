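"""gepsig: survival-supervised gene-expression signature discovery.

Discovers and prospectively applies a censored-survival-supervised
expression signature (Favorable / Non-favorable recurrence-risk classes)
from a probe-by-sample log2 matrix, following a deviance-residual +
genetic-algorithm + RBF support-vector-regression workflow, and ships a
matched synthetic-cohort generator for testing the whole chain.
"""

from .containers import ClinicalTable, ExpressionMatrix
from .evaluation import EvaluationReport, evaluate_classification
from .model import MeningiomaSignatureModel, SignatureDiscoveryResults
from .preprocess import (
    FilterReport,
    batch_center,
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
    ga_select,
    inverse_transform_scores,
    partition_cutoff,
    standardize_response,
)
from .simulate import SimConfig, SyntheticTruth, generate_cohort, write_fixtures
from .survstats import (
    cox_fit,
    harrell_c,
    km_estimate,
    logrank_test,
    nelson_aalen,
    null_deviance_residuals,
)

__version__ = "0.1.0"

__all__ = [
    "ClinicalTable",
    "ExpressionMatrix",
    "EvaluationReport",
    "evaluate_classification",
    "MeningiomaSignatureModel",
    "SignatureDiscoveryResults",
    "FilterReport",
    "batch_center",
    "hierarchical_groups",
    "kmeans_redundancy_filter",
    "mad_filter",
    "median_scale",
    "CVReport",
    "GAConfig",
    "ModelScore",
    "SignatureModel",
    "SVRParams",
    "classify",
    "cross_validate",
    "ga_select",
    "inverse_transform_scores",
    "partition_cutoff",
    "standardize_response",
    "SimConfig",
    "SyntheticTruth",
    "generate_cohort",
    "write_fixtures",
    "cox_fit",
    "harrell_c",
    "km_estimate",
    "logrank_test",
    "nelson_aalen",
    "null_deviance_residuals",
    "reference_signature",
]


def reference_signature():
    """The published 18-gene reference signature (symbols + cytobands).

    Metadata only: gene identities without fitted weights; discovery on
    new data does not use it.
    """
    import importlib.resources

    import pandas as pd

    with importlib.resources.files("gepsig").joinpath(
        "data/reference_signature.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
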