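import numpy as np
import pandas as pd
import pytest

from concordx.synthetic_data import SimConfig, simulate_spot_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spot_config():
    return SimConfig(
        n_probes=40,
        groups=[("DM", 3), ("MWCNT_10ug", 3)],
        planted_effects=[("probe_00007", "MWCNT_10ug", 2.0)],
        noise_sd=0.1,
        flag_rate=0.05,
        frac_undetectable=0.1,
        seed=7,
    )


@pytest.fixture
def small_arrays(small_spot_config):
    arrays, truth = simulate_spot_arrays(small_spot_config)
    return arrays, truth


def frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    try:
        pd.testing.assert_frame_equal(a, b)
        return True
    except AssertionError:
        return False
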