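import numpy as np
import pandas as pd
import pytest

from gepsig.containers import ClinicalTable, ExpressionMatrix


def make_matrix(values, probe_ids=None, sample_ids=None, batch=None):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    b = pd.Series(batch, index=sample_ids) if batch is not None else None
    return ExpressionMatrix(df, b)


def make_clinical(times, events, sample_ids=None, **covariates):
    sample_ids = sample_ids or [f"s{j}" for j in range(len(times))]
    df = pd.DataFrame(
        {"time_years": times, "event": events, **covariates},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ClinicalTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_matrix(rng):
    return make_matrix(rng.normal(7, 1, size=(30, 12)),
                       batch=["a"] * 6 + ["b"] * 6)


@pytest.fixture
def survival_cohort(rng):
    """A generic censored cohort: exponential times, ~40% censoring."""
    n = 80
    t = rng.exponential(5, n)
    c = rng.exponential(8, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    if event.sum() == 0:  # pragma: no cover
        event[0] = 1
    return np.maximum(time, 0.01), event
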