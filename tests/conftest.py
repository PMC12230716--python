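import numpy as np
import pytest

import cdspectra as cd


@pytest.fixture
def small_set():
    """A tiny 5-wavelength, 3-spectrum set in millidegrees."""
    wl = np.array([200.0, 210.0, 220.0, 230.0, 240.0])
    vals = np.array(
        [
            [10.0, 8.0, 2.0],
            [-5.0, -4.0, -1.0],
            [-20.0, -15.0, -3.0],
            [-12.0, -9.0, -2.0],
            [-1.0, -0.5, -0.2],
        ]
    )
    return cd.SpectraSet(wl, vals, "millidegrees", ["a", "b", "c"],
                         "temperature_C", np.array([25.0, 55.0, 85.0]))


@pytest.fixture
def sample_info():
    return cd.SampleInfo(path_length_cm=0.1, concentration_molar=2e-5,
                         molecular_weight=14300.0, n_chromophores=128)


@pytest.fixture
def thermal_noiseless():
    truth = cd.SyntheticTruth(kind="thermal-2s", noise_sd=0.0, seed=11)
    return truth, cd.gen_unfolding_dataset(truth)
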