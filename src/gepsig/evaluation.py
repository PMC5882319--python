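"""Evaluation of a risk classification against censored outcomes.

Reproduces the evaluation surface of a train-then-validate signature
study: misclassification among recurrences (every recurrence is expected
in the Non-favorable class), per-class Kaplan-Meier summaries with a
log-rank comparison, and univariate/multivariate Cox tables with the
risk class and the clinical covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import COVARIATE_LEVELS, ClinicalTable
from .signature import FAVORABLE, NON_FAVORABLE
from .survstats import CoxFitResult, KMEstimate, cox_fit, km_estimate, logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "misclassification_among_events",
    "class_survival_summary",
    "cox_tables",
    "evaluate_classification",
]


@dataclass
class CoxRow:
    variable: str
    contrast: str
    hr: float
    ci_lower: float
    ci_upper: float
    p: float
    flag: str = ""  # e.g. "non-estimable", "monotone-likelihood"


@dataclass
class EvaluationReport:
    per_class_n: dict
    per_class_events: dict
    per_class_median_rfs: dict
    misclassification: float | None
    logrank_statistic: float | None
    logrank_p: float | None
    univariate: list[CoxRow] = field(default_factory=list)
    multivariate: list[CoxRow] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, table in (("univariate", self.univariate),
                            ("multivariate", self.multivariate)):
            for r in table:
                rows.append(
                    {
                        "analysis": kind,
                        "variable": r.variable,
                        "contrast": r.contrast,
                        "HR": r.hr,
                        "CI_lower": r.ci_lower,
                        "CI_upper": r.ci_upper,
                        "P": r.p,
                        "flag": r.flag,
                    }
                )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["Risk-class evaluation", "=" * 21]
        for cls in self.per_class_n:
            med = self.per_class_median_rfs[cls]
            med_s = f"{med:.2f}" if np.isfinite(med) else "not reached"
            lines.append(
                f"{cls}: n={self.per_class_n[cls]}, "
                f"events={self.per_class_events[cls]}, median RFS={med_s} y"
            )
        if self.misclassification is not None:
            lines.append(f"misclassification among events: {self.misclassification:.4f}")
        if self.logrank_p is not None:
            lines.append(
                f"log-rank chi2={self.logrank_statistic:.4f}, p={self.logrank_p:.4g}"
            )
        for flag in self.flags:
            lines.append(f"flag: {flag}")
        df = self.to_frame()
        if len(df):
            lines.append("")
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines) + "\n"


def misclassification_among_events(classes: pd.Series, clinical: ClinicalTable) -> float:
    """Fraction of event (recurrence) samples classified Favorable.

    The convention is that every recurrence belongs in the Non-favorable
    class, so an event sample labeled Favorable is a misclassification.
    """
    clin = clinical.aligned_to(list(classes.index))
    event = clin.event.astype(bool)
    if event.sum() == 0:
        raise ValueError("no events: misclassification undefined")
    fav = (classes.to_numpy() == FAVORABLE) & event
    return float(fav.sum() / event.sum())


def class_survival_summary(
    classes: pd.Series, clinical: ClinicalTable
) -> tuple[dict[str, KMEstimate], float | None, float | None, list[str]]:
    """Per-class KM estimates plus the two-class log-rank comparison.

    Returns (km per class, log-rank statistic, p, flags).  With a single
    class present the log-rank entries are None and a flag is raised.
    """
    clin = clinical.aligned_to(list(classes.index))
    km = {}
    for cls in sorted(classes.unique()):
        in_cls = classes == cls
        km[cls] = km_estimate(clin.time[in_cls.to_numpy()], clin.event[in_cls.to_numpy()])
    flags = []
    if classes.nunique() != 2:
        flags.append("log-rank omitted: need exactly 2 non-empty classes")
        return km, None, None, flags
    stat, p = logrank_test(clin.time, clin.event, classes.to_numpy())
    return km, stat, p, flags


def _expand_covariate(values: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    """Dummy-code a categorical covariate against its reference level."""
    levels = COVARIATE_LEVELS[name]
    ref = levels[0]
    cols, labels = [], []
    for lev in levels[1:]:
        if (values == lev).any():
            cols.append((values == lev).astype(float).to_numpy())
            labels.append(f"{lev} vs. {ref}")
    return (np.column_stack(cols) if cols else np.empty((len(values), 0)), labels)


def _cox_rows(fit: CoxFitResult, variable_of: list[str], contrast_of: list[str]) -> list[CoxRow]:
    rows = []
    flag = "monotone-likelihood" if fit.monotone_likelihood else (
        "" if fit.converged else "non-converged"
    )
    for i, name in enumerate(fit.names):
        rows.append(
            CoxRow(
                variable=variable_of[i],
                contrast=contrast_of[i],
                hr=float(fit.hazard_ratio[i]),
                ci_lower=float(fit.ci_lower[i]),
                ci_upper=float(fit.ci_upper[i]),
                p=float(fit.p_value[i]),
                flag=flag,
            )
        )
    return rows


def cox_tables(
    classes: pd.Series,
    clinical: ClinicalTable,
    covariates: list[str] | None = None,
) -> tuple[list[CoxRow], list[CoxRow], list[str]]:
    """Univariate Cox per variable plus one multivariate fit.

    The risk class enters as Non-favorable vs. Favorable.  Categorical
    covariates are expanded against fixed reference levels (WHO I,
    mitotic <=2, Simpson 1, F, non-skull-base).  Samples missing a
    covariate are dropped listwise for the multivariate fit (logged);
    non-estimable strata are flagged rather than aborting the report.
    """
    covariates = covariates or []
    clin = clinical.aligned_to(list(classes.index))
    flags: list[str] = []
    univariate: list[CoxRow] = []

    class_x = (classes == NON_FAVORABLE).astype(float).to_numpy()
    blocks: list[tuple[str, np.ndarray, list[str], pd.Series | None]] = [
        ("risk_class", class_x.reshape(-1, 1),
         [f"{NON_FAVORABLE} vs. {FAVORABLE}"], None)
    ]
    for cov in covariates:
        if cov not in clin.data.columns:
            flags.append(f"{cov}: not present in clinical table")
            continue
        vals = clin.covariate(cov)
        if vals.isna().all():
            univariate.append(
                CoxRow(cov, "", np.nan, np.nan, np.nan, np.nan, "all values missing")
            )
            flags.append(f"{cov}: all values missing")
            continue
        X, labels = _expand_covariate(vals, cov)
        if X.shape[1] == 0:
            univariate.append(
                CoxRow(cov, "", np.nan, np.nan, np.nan, np.nan,
                       "only reference level observed")
            )
            continue
        blocks.append((cov, X, labels, vals.isna()))

    # univariate fits: per block, complete cases for that covariate
    for var, X, labels, missing in blocks:
        keep = np.ones(len(clin.data), dtype=bool)
        if missing is not None:
            keep &= ~missing.to_numpy()
        try:
            fit = cox_fit(clin.time[keep], clin.event[keep], X[keep], names=labels)
            univariate.extend(_cox_rows(fit, [var] * len(labels), labels))
        except (ValueError, np.linalg.LinAlgError) as exc:
            for lab in labels:
                univariate.append(
                    CoxRow(var, lab, np.nan, np.nan, np.nan, np.nan,
                           f"non-estimable: {exc}")
                )

    # multivariate: listwise deletion across all requested covariates
    multivariate: list[CoxRow] = []
    keep = np.ones(len(clin.data), dtype=bool)
    for var, _, _, missing in blocks:
        if missing is not None:
            keep &= ~missing.to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        msg = f"multivariate fit: {n_drop} sample(s) dropped listwise"
        logger.info(msg)
        flags.append(msg)
    X_parts, all_labels, all_vars = [], [], []
    for var, X, labels, _ in blocks:
        X_parts.append(X[keep])
        all_labels.extend(labels)
        all_vars.extend([var] * len(labels))
    if len(blocks) > 1:
        Xm = np.column_stack(X_parts)
        try:
            fit = cox_fit(clin.time[keep], clin.event[keep], Xm, names=all_labels)
            multivariate.extend(_cox_rows(fit, all_vars, all_labels))
        except (ValueError, np.linalg.LinAlgError) as exc:
            flags.append(f"multivariate fit non-estimable: {exc}")
    return univariate, multivariate, flags


def evaluate_classification(
    classes: pd.Series,
    clinical: ClinicalTable,
    covariates: list[str] | None = None,
) -> EvaluationReport:
    """Full evaluation report for a Favorable/Non-favorable labeling."""
    clin = clinical.aligned_to(list(classes.index))
    km, stat, p, flags = class_survival_summary(classes, clin)
    per_n = {cls: est.n for cls, est in km.items()}
    per_ev = {cls: est.n_events for cls, est in km.items()}
    per_med = {cls: est.median for cls, est in km.items()}
    try:
        mis = misclassification_among_events(classes, clin)
    except ValueError:
        mis = None
        flags.append("no events: misclassification undefined")
    uni, multi = [], []
    if classes.nunique() == 2:
        uni, multi, cox_flags = cox_tables(classes, clin, covariates)
        flags.extend(cox_flags)
    else:
        flags.append("Cox tables omitted: single class present")
    return EvaluationReport(
        per_class_n=per_n,
        per_class_events=per_ev,
        per_class_median_rfs=per_med,
        misclassification=mis,
        logrank_statistic=stat,
        logrank_p=p,
        univariate=uni,
        multivariate=multi,
        flags=flags,
    )


def plot_km(classes: pd.Series, clinical: ClinicalTable, ax=None):
    """Optional Kaplan-Meier curves per risk class (matplotlib axes)."""
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    clin = clinical.aligned_to(list(classes.index))
    if ax is None:
        _, ax = plt.subplots()
    for cls in sorted(classes.unique()):
        m = (classes == cls).to_numpy()
        KaplanMeierFitter().fit(clin.time[m], clin.event[m], label=str(cls)).plot_survival_function(ax=ax)
    ax.set_xlabel("Years")
    ax.set_ylabel("Recurrence-free survival")
    return ax
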