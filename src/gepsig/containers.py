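"""Core data containers shared across the pipeline.

An :class:`ExpressionMatrix` holds a probe-by-sample matrix of log2
intensities together with a per-sample batch label; a
:class:`ClinicalTable` holds the censored recurrence outcome and the
clinical covariates used in the Cox tables.  Both are thin, validated
wrappers around :class:`pandas.DataFrame` so that the rest of the code
can rely on aligned, duplicate-free identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "WHO_GRADES",
    "MITOTIC_CATEGORIES",
    "SIMPSON_GRADES",
    "SEXES",
    "LOCATIONS",
    "COVARIATE_LEVELS",
]

# Admissible covariate levels; the first entry of each list is the
# reference level used when expanding categorical covariates in Cox fits.
WHO_GRADES = ["I", "II", "III"]
MITOTIC_CATEGORIES = ["<=2", "3-4", ">=5"]
SIMPSON_GRADES = ["1", "2", "3", "4"]
SEXES = ["F", "M"]
LOCATIONS = ["non-skull-base", "skull-base"]

COVARIATE_LEVELS = {
    "who_grade": WHO_GRADES,
    "mitotic_category": MITOTIC_CATEGORIES,
    "simpson_grade": SIMPSON_GRADES,
    "sex": SEXES,
    "location": LOCATIONS,
}


@dataclass
class ExpressionMatrix:
    """Probe-by-sample log2 expression values with batch labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Probes as rows (index = probe ids), samples as columns.
    batch : pandas.Series
        Per-sample categorical batch label, indexed by sample id.
    """

    values: pd.DataFrame
    batch: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values is None or self.values.shape[1] == 0:
            raise ValueError("expression matrix has no samples")
        if self.batch is None:
            self.batch = pd.Series("batch0", index=self.values.columns)
        self.values = self.values.astype(float)
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression matrix contains non-finite values")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe ids: {dup[:5]}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        missing = self.values.columns.difference(self.batch.index)
        if len(missing):
            raise ValueError(f"samples without batch label: {list(missing)[:5]}")
        self.batch = self.batch.reindex(self.values.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(probe_ids)], self.batch.copy())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)], self.batch.loc[list(sample_ids)]
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.batch.copy())


@dataclass
class ClinicalTable:
    """Per-sample censored recurrence outcome plus optional covariates.

    The underlying frame is indexed by sample id and must contain
    ``time_years`` (float, > 0) and ``event`` (0/1).  Optional covariate
    columns (``who_grade``, ``mitotic_category``, ``simpson_grade``,
    ``sex``, ``location``) may contain missing values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        for col in ("time_years", "event"):
            if col not in df.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        times = df["time_years"].astype(float)
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("follow-up times must be finite and positive")
        events = df["event"].astype(int)
        if not set(np.unique(events)) <= {0, 1}:
            raise ValueError("event flags must be 0 or 1")
        df = df.copy()
        df["time_years"] = times
        df["event"] = events
        for col, levels in COVARIATE_LEVELS.items():
            if col in df.columns:
                bad = set(df[col].dropna()) - set(levels)
                if bad:
                    raise ValueError(f"invalid {col} levels: {sorted(bad)}")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time_years"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def aligned_to(self, sample_ids) -> "ClinicalTable":
        """Return the table restricted to and ordered by ``sample_ids``."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing[:10]}")
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def covariate(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"covariate {name!r} not present")
        return self.data[name]
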