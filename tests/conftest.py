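import numpy as np
import pandas as pd
import pytest

from ctdnamon.groom import ConsensusPileup
from ctdnamon.simcohort import SimulationConfig, simulate_error_truth, simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_patients=8,
        panel_positions=300,
        consensus_depth_target=400,
        n_donors=5,
        seed=11,
    )


@pytest.fixture
def panel(small_config, rng):
    return simulate_panel(small_config, rng)


@pytest.fixture
def error_truth(panel, small_config, rng):
    return simulate_error_truth(panel, small_config, rng)


def make_pileup(rows):
    """rows: (position, ref, allele, support, total, duplex_confirmed)"""
    return ConsensusPileup.from_frame(
        pd.DataFrame(
            rows,
            columns=["position", "ref", "allele", "support", "total", "duplex_confirmed"],
        )
    )


@pytest.fixture
def pileup_factory():
    return make_pileup
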