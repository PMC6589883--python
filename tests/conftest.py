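import numpy as np
import pytest

from soilmfc import simulate


@pytest.fixture
def config():
    return simulate.SimulationConfig(seed=42)


@pytest.fixture
def noiseless_config():
    from dataclasses import replace
    cfg = simulate.SimulationConfig(seed=42)
    return replace(
        cfg,
        current_noise_mA_m2=0.0,
        polarization_noise_frac=0.0,
        concentration_noise_frac=0.0,
        qpcr=replace(cfg.qpcr, ct_noise_sd=0.0, p_multi_peak=0.0,
                     p_bad_efficiency=0.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
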