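"""Synthetic paired training/validation cohorts with ground truth.

The generator emulates the statistical shape of a two-cohort microarray
recurrence study: a probe-by-sample log2 expression matrix with
correlated probe blocks and additive batch effects, a small set of
planted prognostic probes whose (standardized) expression drives an
exponential proportional-hazards event time, and heavy right-censoring
produced by a uniform-dropout process calibrated to a target censoring
fraction under an administrative follow-up window.

Planted probes are organized into tightly co-expressed "programs"
(default: 3 groups of 6 sharing a latent factor at correlation 0.95),
the way prognostic genes co-express in real tumors; their marginal mean
and spread match ordinary high-variability probes (the signal is
survival-linked, not mean-shifted), they pass the MAD filter, and each
program survives the correlation-radius redundancy filter as a tight
cluster of its own.  Setting ``signature_group_size = 1`` makes every
planted probe an independent prognostic axis instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io as gio
from .containers import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SyntheticTruth", "generate_cohort", "write_fixtures", "read_truth"]


@dataclass
class SimConfig:
    """Parameters of the simulated two-cohort recurrence study.

    Defaults mirror the emulated study design: 127 training and 62
    validation samples, ~2000 probes with 18 planted prognostic probes,
    censoring targets 85.83% / 80.65%, and a 25.42-year administrative
    follow-up window.
    """

    n_train: int = 127
    n_validation: int = 62
    n_probes: int = 2000
    n_signature: int = 18
    beta_magnitude: float = 0.3
    signature_group_size: int = 6
    signature_correlation: float = 0.95
    n_correlated_blocks: int = 20
    block_size: int = 30
    block_correlation_range: tuple[float, float] = (0.74, 0.87)
    n_batches_train: int = 3
    n_batches_validation: int = 1
    batch_offset_sd: float = 0.3
    baseline_hazard: float = 0.06  # events / year at eta = 0
    censoring_target_train: float = 0.8583
    censoring_target_validation: float = 0.8065
    followup_window: float = 25.42  # years
    weibull_shape: float = 1.0  # 1.0 = exponential baseline
    signature_sd_range: tuple[float, float] = (0.9, 1.3)
    block_sd_lognorm: tuple[float, float] = (0.0, 0.18)  # ln-mean, ln-sd
    noise_sd_lognorm: tuple[float, float] = (-1.1, 0.22)
    grand_mean: float = 7.0  # log2 intensity location
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_train", "n_validation", "n_probes", "n_signature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for t in (self.censoring_target_train, self.censoring_target_validation):
            if not (0 < t < 1):
                raise ValueError("censoring targets must be in (0,1)")
        for r in (self.signature_correlation, *self.block_correlation_range):
            if not (0 <= r < 1):
                raise ValueError("correlations must be in [0,1)")
        if self.n_signature > self.n_probes:
            raise ValueError("n_signature exceeds n_probes")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    planted_probe_ids: list[str]
    beta: np.ndarray  # per planted probe, on standardized expression
    eta: np.ndarray  # per-sample linear predictor
    true_event_time: np.ndarray
    censoring_time: np.ndarray
    batch: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_probe_ids": self.planted_probe_ids,
                "beta": self.beta.tolist(),
                "eta": self.eta.tolist(),
                "true_event_time": self.true_event_time.tolist(),
                "censoring_time": self.censoring_time.tolist(),
                "batch": self.batch,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        p = json.loads(text)
        return cls(
            planted_probe_ids=list(p["planted_probe_ids"]),
            beta=np.array(p["beta"], dtype=float),
            eta=np.array(p["eta"], dtype=float),
            true_event_time=np.array(p["true_event_time"], dtype=float),
            censoring_time=np.array(p["censoring_time"], dtype=float),
            batch=list(p["batch"]),
        )


def _correlated_group(rng, n_samples: int, size: int, rho: float) -> np.ndarray:
    """Rows sharing a latent factor at pairwise correlation ``rho``."""
    f = rng.standard_normal(n_samples)
    e = rng.standard_normal((size, n_samples))
    return np.sqrt(rho) * f + np.sqrt(1 - rho) * e


def _expected_event_fraction(lam: np.ndarray, tau: float, window: float) -> float:
    """Mean P(T <= min(C, W)) for T ~ Exp(lam), C ~ U(0, tau), window W."""
    m = min(tau, window)
    # integral of (1 - exp(-lam c)) dc over [0, m], then the point mass
    # of C beyond the window (if tau > window) at the window cap
    with np.errstate(over="ignore"):
        part = m - (1 - np.exp(-lam * m)) / lam
    p = (part + max(tau - window, 0.0) * (1 - np.exp(-lam * window))) / tau
    return float(np.mean(p))


def _calibrate_dropout(lam: np.ndarray, target_censoring: float, window: float) -> float:
    """Find the uniform-dropout scale tau hitting the target censoring."""
    target_event = 1.0 - target_censoring

    def f(tau):
        return _expected_event_fraction(lam, tau, window) - target_event

    lo, hi = 1e-3, 1e6
    if f(hi) < 0:
        raise ValueError(
            "infeasible censoring target: even with negligible dropout the "
            f"expected event fraction is below {target_event:.4f}; increase "
            "baseline_hazard or the follow-up window"
        )
    if f(lo) > 0:
        raise ValueError(
            "infeasible censoring target: the cohort accrues too many events "
            "even under immediate dropout; decrease baseline_hazard"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))


def generate_cohort(
    config: SimConfig, cohort: str = "train", seed: int | None = None
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Generate one cohort (``"train"`` or ``"validation"``).

    The two cohorts share the generative law (probe layout, effect
    sizes) but are drawn independently; pass the same ``config`` with
    ``cohort="validation"`` to obtain the paired validation set.  All
    draws are reproducible from ``seed`` (default: derived from
    ``config.seed`` and the cohort name).
    """
    if cohort not in {"train", "validation"}:
        raise ValueError("cohort must be 'train' or 'validation'")
    if seed is None:
        seed = config.seed
    # distinct, deterministic streams per cohort
    cohort_key = {"train": 1, "validation": 2}[cohort]
    rng = np.random.default_rng(np.random.SeedSequence([seed, cohort_key]))
    layout_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 901]))

    n = config.n_train if cohort == "train" else config.n_validation
    n_batches = config.n_batches_train if cohort == "train" else config.n_batches_validation
    cens_target = (
        config.censoring_target_train
        if cohort == "train"
        else config.censoring_target_validation
    )

    for attempt in range(10):
        out = _generate_once(config, n, n_batches, cens_target, rng, layout_rng, cohort)
        if out is not None:
            return out
        logger.warning("degenerate draw (no events) in %s cohort; redrawing", cohort)
    raise RuntimeError("could not generate a cohort with at least one event")


def _generate_once(config, n, n_batches, cens_target, rng, layout_rng, cohort):
    P = config.n_probes
    S = config.n_signature
    gsize = config.signature_group_size
    probe_ids = [f"probe_{i:05d}" for i in range(P)]
    sample_ids = [f"{cohort[0].upper()}{i:04d}" for i in range(n)]

    # --- probe layout (shared across cohorts via layout_rng) ---
    planted_idx = np.arange(S)  # deterministic layout; ids are arbitrary labels
    beta = np.empty(S)
    n_groups = int(np.ceil(S / gsize))
    for g in range(n_groups):
        sl = slice(g * gsize, min((g + 1) * gsize, S))
        sign = 1.0 if g % 2 == 0 else -1.0
        beta[sl] = sign * config.beta_magnitude
    sig_sd = layout_rng.uniform(*config.signature_sd_range, size=S)
    block_rho = layout_rng.uniform(*config.block_correlation_range,
                                   size=config.n_correlated_blocks)
    n_block_probes = config.n_correlated_blocks * config.block_size
    mu_b, sd_b = config.block_sd_lognorm
    block_sd = layout_rng.lognormal(mu_b, sd_b, size=n_block_probes)
    mu_n, sd_n = config.noise_sd_lognorm
    n_noise = P - S - n_block_probes
    if n_noise < 0:
        raise ValueError("n_probes too small for the configured block layout")
    noise_sd = layout_rng.lognormal(mu_n, sd_n, size=n_noise)

    # --- standardized expression (rows unit-variance before scaling) ---
    Z = np.empty((P, n))
    pos = 0
    for g in range(n_groups):
        size = min(gsize, S - g * gsize)
        Z[pos : pos + size] = _correlated_group(
            rng, n, size, config.signature_correlation
        )
        pos += size
    for b in range(config.n_correlated_blocks):
        Z[pos : pos + config.block_size] = _correlated_group(
            rng, n, config.block_size, block_rho[b]
        )
        pos += config.block_size
    Z[pos:] = rng.standard_normal((n_noise, n))

    sd = np.concatenate([sig_sd, block_sd, noise_sd])
    values = config.grand_mean + Z * sd[:, None]

    # --- survival from the planted linear predictor ---
    eta = beta @ Z[planted_idx]
    lam = config.baseline_hazard * np.exp(eta)
    u = rng.uniform(size=n)
    shape = config.weibull_shape
    t_event = (-np.log(u) / lam) ** (1.0 / shape)
    tau = _calibrate_dropout(lam, cens_target, config.followup_window)
    dropout = rng.uniform(0, tau, size=n)
    censor = np.minimum(dropout, config.followup_window)
    observed = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    # small positive floor; keeps times valid without clumping early
    # events into heavy ties that would attenuate proportional hazards
    observed = np.maximum(observed, 0.005)
    if event.sum() == 0:
        return None

    # --- batch structure (additive per probe x batch offsets) ---
    batch_of = np.sort(rng.integers(0, n_batches, size=n))
    batch_labels = [f"{cohort}_batch{b}" for b in batch_of]
    offsets = rng.normal(0, config.batch_offset_sd, size=(P, n_batches))
    values = values + offsets[:, batch_of]

    # --- clinical covariates, WHO grade correlated with eta ---
    eta_sd = eta.std() if eta.std() > 0 else 1.0
    latent = 0.6 * eta / eta_sd + 0.8 * rng.standard_normal(n)
    who = np.where(latent > 1.9, "III", np.where(latent > 0.9, "II", "I"))
    mit_latent = 0.5 * eta / eta_sd + 0.9 * rng.standard_normal(n)
    mitotic = np.where(mit_latent > 2.0, ">=5", np.where(mit_latent > 1.1, "3-4", "<=2"))
    simpson = rng.choice(["1", "2", "3", "4"], size=n, p=[0.35, 0.3, 0.2, 0.15])
    sex = rng.choice(["F", "M"], size=n, p=[0.7, 0.3])
    location = rng.choice(["non-skull-base", "skull-base"], size=n, p=[0.6, 0.4])

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        pd.Series(batch_labels, index=sample_ids),
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "time_years": observed,
                "event": event,
                "who_grade": who,
                "mitotic_category": mitotic,
                "simpson_grade": simpson,
                "sex": sex,
                "location": location,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SyntheticTruth(
        planted_probe_ids=[probe_ids[i] for i in planted_idx],
        beta=beta.copy(),
        eta=eta,
        true_event_time=t_event,
        censoring_time=censor,
        batch=batch_labels,
    )
    return expr, clinical, truth


def write_fixtures(
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    truth: SyntheticTruth,
    directory,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write expression/clinical/batch TSVs and the truth JSON.

    Files round-trip bit-identically through the matching readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "clinical": directory / "clinical.tsv",
        "batch": directory / "batch.tsv",
        "truth": directory / "truth.json",
    }
    if not overwrite:
        existing = [str(p) for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(f"refusing to overwrite: {existing}")
    gio.write_expression(expression, paths["expression"])
    gio.write_clinical(clinical, paths["clinical"])
    gio.write_batch(expression.batch, paths["batch"])
    paths["truth"].write_text(truth.to_json())
    return paths


def read_truth(path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())
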