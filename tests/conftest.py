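import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "det", derandomize=True, max_examples=60,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("det")
except ImportError:  # pragma: no cover
    pass

from introscan import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-scaffold dataset shared across read/write tests."""
    cfg = SimConfig(scaffold_lengths=[300_000, 300_000], seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_outputs(small_dataset, tmp_path_factory):
    from introscan import write_outputs

    out = tmp_path_factory.mktemp("simout")
    paths = write_outputs(small_dataset, out)
    return small_dataset, paths
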