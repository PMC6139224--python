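import numpy as np
import pandas as pd
import pytest

from medeg import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort exercising every planted structure."""
    cfg = SimConfig(
        n_genes=300,
        n_meth_probes=800,
        n_deg=40,
        n_dmp=60,
        n_medeg_inverse=8,
        n_medeg_positive=2,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at default configuration."""
    return generate_cohort(SimConfig(seed=11))


@pytest.fixture
def two_group_metadata():
    def make(n_case, n_control, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"S{i:02d}" for i in range(n_case + n_control)]
        return pd.DataFrame(
            {
                "group": ["case"] * n_case + ["control"] * n_control,
                "age": rng.normal(43, 10, n_case + n_control).round(1),
                "sex": rng.choice(["M", "F"], n_case + n_control),
                "ild": 0,
            },
            index=pd.Index(samples, name="sample_id"),
        )

    return make
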