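"""End-to-end discovery and frozen-validation runs with file I/O.

`run_discovery` trains the signature on a training cohort and persists
every intermediate report plus the model artifact; `run_validation`
loads a frozen artifact and applies it to a validation cohort without
refitting anything.  Both write a manifest (inputs, seed, thresholds,
config hash) sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as gio
from .containers import ClinicalTable, ExpressionMatrix
from .evaluation import EvaluationReport
from .model import MeningiomaSignatureModel, SignatureDiscoveryResults
from .signature import GAConfig, SignatureModel, SVRParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_discovery", "run_validation", "load_config"]

DEFAULT_COVARIATES = ["who_grade", "mitotic_category", "simpson_grade", "sex", "location"]


@dataclass
class RunConfig:
    """File paths and hyperparameters for a pipeline run."""

    expression: str = ""
    clinical: str = ""
    batch: str | None = None
    outdir: str = "gepsig_run"
    seed: int = 0
    mad_cutoff: float = 0.5
    radius: float = 0.95
    k: int | None = None
    cv_folds: int = 50
    cv_holdout: float = 0.10
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    ga: GAConfig = field(default_factory=GAConfig)
    svr: SVRParams = field(default_factory=SVRParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    ga = GAConfig(**raw.pop("ga", {}))
    svr = SVRParams(**raw.pop("svr", {}))
    return RunConfig(ga=ga, svr=svr, **raw)


def _load_inputs(config: RunConfig) -> tuple[ExpressionMatrix, ClinicalTable]:
    expr = gio.read_expression(config.expression, config.batch)
    clin = gio.read_clinical(config.clinical)
    missing = [s for s in expr.sample_ids if s not in clin.data.index]
    if missing:
        raise ValueError(f"samples missing from clinical table: {missing[:10]}")
    return expr, clin.aligned_to(expr.sample_ids)


def _write_manifest(outdir: Path, config: RunConfig, extra: dict) -> None:
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_discovery(
    config: RunConfig,
    expression: ExpressionMatrix | None = None,
    clinical: ClinicalTable | None = None,
) -> SignatureDiscoveryResults:
    """Train the signature and persist model + reports under ``outdir``."""
    if expression is None or clinical is None:
        expression, clinical = _load_inputs(config)
    model = MeningiomaSignatureModel(
        expression,
        clinical,
        mad_cutoff=config.mad_cutoff,
        radius=config.radius,
        k=config.k,
        ga_config=config.ga,
        svr_params=config.svr,
        cv_folds=config.cv_folds,
        cv_holdout=config.cv_holdout,
    )
    results = model.fit(seed=config.seed)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.model.save(outdir / "model.json")
    for rep in results.filter_reports:
        (outdir / f"filter_{rep.stage}.txt").write_text(rep.to_text())
    (outdir / "cv_report.json").write_text(
        json.dumps(dataclasses.asdict(results.cv_report), indent=2, sort_keys=True)
    )
    results.training_classes.rename("risk_class").to_frame().to_csv(
        outdir / "training_classes.tsv", sep="\t", index_label="sample_id"
    )
    (outdir / "training_evaluation.txt").write_text(
        results.training_evaluation.to_text()
    )
    (outdir / "summary.txt").write_text(results.summary())
    _write_manifest(outdir, config, {"stage": "discovery"})
    return results


def run_validation(
    model_path,
    config: RunConfig,
    expression: ExpressionMatrix | None = None,
    clinical: ClinicalTable | None = None,
) -> EvaluationReport:
    """Apply a frozen model artifact to a validation cohort.

    No refitting of any kind: frozen normalization references, frozen
    regressor, frozen score transform and cutoff.
    """
    artifact = Path(model_path).read_text()
    model = SignatureModel.from_json(artifact)
    if expression is None or clinical is None:
        expression, clinical = _load_inputs(config)

    from .evaluation import evaluate_classification
    from .model import apply_frozen_preprocessing
    from .signature import classify as _classify

    classes = _classify(model, apply_frozen_preprocessing(model, expression))

    report = evaluate_classification(
        classes, clinical.aligned_to(list(classes.index)), config.covariates
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    classes.rename("risk_class").to_frame().to_csv(
        outdir / "validation_classes.tsv", sep="\t", index_label="sample_id"
    )
    (outdir / "validation_evaluation.txt").write_text(report.to_text())
    report.to_frame().to_csv(outdir / "validation_cox_tables.tsv", sep="\t", index=False)
    _write_manifest(outdir, config, {"stage": "validation", "model": str(model_path)})
    if Path(model_path).read_text() != artifact:
        raise RuntimeError("model artifact changed during validation run")
    return report
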