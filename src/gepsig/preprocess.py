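"""Expression preprocessing: normalization, variability and redundancy
filters, and exploratory two-group hierarchical clustering.

The chain mirrors a classic microarray signature workflow: columns are
median-scaled onto a common scale, batch means are removed probe-wise,
low-variability probes are dropped by a median-absolute-deviation (MAD)
threshold, and near-redundant probes are reduced with a k-means
correlation-radius filter that keeps only probes tightly correlated with
their cluster centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "ClusterGrouping",
    "median_scale",
    "batch_center",
    "mad_filter",
    "kmeans_redundancy_filter",
    "hierarchical_groups",
]


@dataclass
class FilterReport:
    """Bookkeeping for one filtering stage."""

    stage: str
    threshold: float
    n_input: int
    n_retained: int
    n_eliminated: int
    eliminated_probe_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_retained + self.n_eliminated == self.n_input
        assert len(self.eliminated_probe_ids) == self.n_eliminated

    def to_text(self) -> str:
        lines = [
            f"stage: {self.stage}",
            f"threshold: {self.threshold}",
            f"n_input: {self.n_input}",
            f"n_retained: {self.n_retained}",
            f"n_eliminated: {self.n_eliminated}",
            "eliminated: " + ",".join(self.eliminated_probe_ids),
        ]
        return "\n".join(lines) + "\n"


@dataclass
class ClusterGrouping:
    """Per-sample group labels from unsupervised hierarchical clustering."""

    labels: pd.Series  # values in 1..G, indexed by sample id
    linkage_method: str
    distance: str

    @property
    def n_groups(self) -> int:
        return int(self.labels.nunique())


def median_scale(
    matrix: ExpressionMatrix, target: float | None = None
) -> ExpressionMatrix:
    """Shift every sample column so its median equals the grand median.

    The transformation is purely additive per column, so within-sample
    probe differences are preserved exactly.  Idempotent.  Passing a
    frozen ``target`` (e.g. a training cohort's grand median) scales the
    columns to that location instead, for prospective application.
    """
    values = matrix.values
    if values.size == 0:
        raise ValueError("cannot median-scale an empty matrix")
    grand = float(np.median(values.to_numpy())) if target is None else float(target)
    col_medians = values.median(axis=0)
    shifted = values.add(grand - col_medians, axis=1)
    return ExpressionMatrix(shifted, matrix.batch.copy())


def batch_center(
    matrix: ExpressionMatrix, reference: pd.Series | None = None
) -> ExpressionMatrix:
    """Remove additive batch effects by mean-centering each batch per probe.

    Each probe's per-batch mean is shifted to the probe's grand mean, or
    to the supplied per-probe ``reference`` locations.  Passing the
    reference vector computed on a training cohort freezes the operation
    for prospective application to a validation cohort.  Within-batch
    deviations are preserved exactly; idempotent when ``reference`` is
    None or already equal to the grand means.
    """
    values = matrix.values
    batch = matrix.batch
    if reference is None:
        target = values.mean(axis=1)
    else:
        reference = pd.Series(reference)
        if len(reference) != len(values.index):
            raise ValueError(
                f"reference length {len(reference)} != n_probes {len(values.index)}"
            )
        if not reference.index.equals(values.index):
            missing = values.index.difference(reference.index)
            if len(missing):
                raise ValueError(f"reference missing probes: {list(missing)[:5]}")
            reference = reference.reindex(values.index)
        target = reference.astype(float)
    out = values.copy()
    for b in batch.unique():
        cols = batch.index[batch == b]
        block = values[cols]
        out[cols] = block.sub(block.mean(axis=1), axis=0).add(target, axis=0)
    return ExpressionMatrix(out, batch.copy())


def probe_mad(values: pd.DataFrame) -> pd.Series:
    """Raw per-probe median absolute deviation (no consistency constant)."""
    med = values.median(axis=1)
    return values.sub(med, axis=0).abs().median(axis=1)


def mad_filter(
    matrix: ExpressionMatrix, cutoff: float = 0.5
) -> tuple[ExpressionMatrix, FilterReport]:
    """Retain probes whose MAD about the probe median is >= ``cutoff``."""
    if cutoff < 0:
        raise ValueError("MAD cutoff must be non-negative")
    if matrix.n_samples < 2:
        raise ValueError("MAD filter requires at least 2 samples")
    mad = probe_mad(matrix.values)
    keep = mad >= cutoff
    retained = matrix.values.loc[keep]
    report = FilterReport(
        stage="mad_filter",
        threshold=float(cutoff),
        n_input=matrix.n_probes,
        n_retained=int(keep.sum()),
        n_eliminated=int((~keep).sum()),
        eliminated_probe_ids=list(matrix.values.index[~keep]),
    )
    return ExpressionMatrix(retained, matrix.batch.copy()), report


def _row_standardize(values: pd.DataFrame) -> np.ndarray:
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    zero = np.nonzero(sd.ravel() == 0)[0]
    if len(zero):
        raise ValueError(
            f"zero-variance probes cannot be clustered: {list(values.index[zero])[:5]}"
        )
    return (arr - mu) / sd


def kmeans_redundancy_filter(
    matrix: ExpressionMatrix,
    radius: float = 0.95,
    k: int | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop probes that fail to cluster tightly with any k-means centroid.

    Probes (rows) are z-scored, k-means clustered with 10 restarts, and a
    probe is retained iff the Pearson correlation between its profile and
    its assigned cluster centroid is >= ``radius``.  Singleton clusters
    trivially retain their probe.  ``k`` defaults to
    ``max(2, n_probes // 10)``.
    """
    n = matrix.n_probes
    if k is None:
        k = max(2, n // 10)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds n_probes={n}")
    rows = _row_standardize(matrix.values)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(rows)
    centroids = km.cluster_centers_
    keep = np.zeros(n, dtype=bool)
    for i in range(n):
        c = centroids[assign[i]]
        c_sd = c.std()
        if c_sd == 0:
            # flat centroid: correlation undefined, treat as failing unless
            # the radius is vacuous
            r = -1.0
        else:
            r = float(np.corrcoef(rows[i], c)[0, 1])
        keep[i] = r >= radius
    retained = matrix.values.loc[keep]
    report = FilterReport(
        stage="kmeans_redundancy_filter",
        threshold=float(radius),
        n_input=n,
        n_retained=int(keep.sum()),
        n_eliminated=int((~keep).sum()),
        eliminated_probe_ids=list(matrix.values.index[~keep]),
    )
    return ExpressionMatrix(retained, matrix.batch.copy()), report


def hierarchical_groups(matrix: ExpressionMatrix, n_groups: int = 2) -> ClusterGrouping:
    """Cluster samples hierarchically and cut the tree into ``n_groups``.

    Distance is 1 - Pearson correlation between sample columns over the
    filtered probes; linkage is average (UPGMA).  Deterministic for a
    fixed input.
    """
    if n_groups > matrix.n_samples:
        raise ValueError(
            f"n_groups={n_groups} exceeds n_samples={matrix.n_samples}"
        )
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    cols = matrix.values.to_numpy(dtype=float).T  # samples as points
    if n_groups == 1:
        labels = np.ones(matrix.n_samples, dtype=int)
    else:
        dist = pdist(cols, metric="correlation")
        tree = linkage(dist, method="average")
        labels = fcluster(tree, t=n_groups, criterion="maxclust")
    return ClusterGrouping(
        labels=pd.Series(labels, index=matrix.values.columns, name="group"),
        linkage_method="average",
        distance="1 - Pearson correlation",
    )


def drop_degenerate_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop probes that are constant across samples, with a warning."""
    sd = matrix.values.std(axis=1)
    bad = sd == 0
    if bad.any():
        logger.warning(
            "dropping %d constant probe(s): %s",
            int(bad.sum()),
            list(matrix.values.index[bad])[:5],
        )
        return ExpressionMatrix(matrix.values.loc[~bad], matrix.batch.copy())
    return matrix
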