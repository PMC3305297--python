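import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nucleoflow as nf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> nf.GeneratorConfig:
    """A reduced cohort (two groups, ~6k events/sample) for fast tests."""
    return nf.GeneratorConfig(
        baseline_density_total=30_000.0,
        group_sizes={("FPC", "control"): 4, ("FPC", "BPD"): 4},
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> nf.CohortDataset:
    return nf.generate_cohort(small_config, seed=42)


@pytest.fixture(scope="session")
def default_sample_events():
    """One full-size sample (~20k events) from the default configuration."""
    cfg = nf.GeneratorConfig(group_sizes={("FPC", "control"): 1})
    ds = nf.generate_cohort(cfg, seed=7)
    (sample_id,) = ds.events
    return ds.specs[sample_id], ds.events[sample_id], cfg


@pytest.fixture(scope="session")
def default_sample_gating(default_sample_events):
    _, events, _ = default_sample_events
    return nf.gate_events(events, nf.GatingConfig())


def truth_classes(events) -> np.ndarray:
    """Ground-truth labels with G2/M nuclei folded into their marker class."""
    return events["truth_label"].str.replace("g2m_", "", regex=False).to_numpy()
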