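import numpy as np
import pytest

from habitatmri.simulate import SimulationConfig, generate_cohort, generate_cohort_bundle


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """10-patient desk-scale cohort with the default habitat separation."""
    return SimulationConfig(
        n_patients=10,
        shape=(32, 32, 24),
        tumor_radius_range=(5.0, 8.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """In-memory 10-patient cohort plus ground-truth habitat fractions."""
    return generate_cohort_bundle(small_config)


@pytest.fixture(scope="session")
def disk_cohort(tmp_path_factory):
    """Tiny on-disk cohort (3 patients) for I/O and CLI tests."""
    config = SimulationConfig(
        n_patients=3, shape=(24, 24, 16), tumor_radius_range=(4.0, 6.0), seed=13
    )
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(config, out)
    return out, config
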