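import numpy as np
import pandas as pd
import pytest

from progmet.cohort_io import ExpressionMatrix, validate_clinical


def make_clinical(times, events, **overrides):
    """Minimal valid clinical table from survival arrays."""
    n = len(times)
    base = {
        "sample_id": [f"S{i:04d}" for i in range(n)],
        "dmfs_time": np.asarray(times, dtype=float),
        "dmfs_event": np.asarray(events, dtype=int),
        "er_status": "positive",
        "ln_status": "negative",
        "tumor_size_class": "T1",
        "grade": "2",
        "age_years": 55.0,
        "treatment": "none",
        "study": "study_1",
    }
    base.update(overrides)
    return validate_clinical(pd.DataFrame(base))


def make_expr(values, probe_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    if probe_ids is None:
        probe_ids = [f"p{i}" for i in range(values.shape[0])]
    if sample_ids is None:
        sample_ids = [f"S{j:04d}" for j in range(values.shape[1])]
    return ExpressionMatrix(probe_ids, sample_ids, values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Tiny deterministic synthetic cohort shared by several suites."""
    from progmet.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_samples=120, n_genes_total=120, module_sizes=(30, 30, 30, 30),
        probe_redundancy_rate=0.0, seed=42,
    )
    return simulate_cohort(cfg)
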