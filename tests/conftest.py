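import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from morphotest.metrics import SampleSummary


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def counts_summary():
    """50 trossulus (40 T / 10 E) + 50 edulis (5 T / 45 E)."""
    return SampleSummary("s1", n_T_tros=40, n_E_tros=10, n_T_edu=5, n_E_edu=45)


def make_individuals(
    n_tros_T, n_tros_E, n_edu_T, n_edu_E, sample_id="s1", set_label="SIM"
):
    """Individual table with exact 2x2 counts (q = 0.9 / 0.1)."""
    rows = []
    for n, q, m in (
        (n_tros_T, 0.9, "T"),
        (n_tros_E, 0.9, "E"),
        (n_edu_T, 0.1, "T"),
        (n_edu_E, 0.1, "E"),
    ):
        rows.extend({"sample_id": sample_id, "set": set_label, "q": q, "morphotype": m} for _ in range(n))
    return pd.DataFrame(rows)


@pytest.fixture
def small_study():
    """Small synthetic study for smoke-level pipeline tests."""
    from morphotest.synthetic_data import SimulationConfig, generate_study

    cfg = SimulationConfig(
        prevalence_grid=tuple(np.linspace(0.0, 1.0, 8)),
        sample_size_range=(40, 60),
        seed=7,
    )
    return generate_study(cfg)
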