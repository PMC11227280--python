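import numpy as np
import pytest

from selenoscan.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated organism reused across finder/CLI tests."""
    cfg = SimConfig(
        seed=101, n_contigs=8, contig_length=1600,
        plant_counts={"selD": 2, "frhA": 2, "hdrA": 2, "frhD": 2, "prxL": 2},
    )
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
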