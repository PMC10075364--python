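import numpy as np
import pytest

from hippolfp import synthetic as syn
from hippolfp.behavior import BehaviorEpoch


@pytest.fixture(scope="session")
def swr_benchmark():
    """Standard detector benchmark: 100 joint events, 20 ripple-only and
    20 sharp-wave-only distractors at 5x in-band ripple SNR."""
    fs = 2500.0
    pyr, rad, truth = syn.gen_swr_benchmark(seed=1, fs=fs)
    epochs = [
        BehaviorEpoch(syn.IMMOBILITY, 0.0, len(pyr) / fs, 0, len(pyr))
    ]
    return {"pyr": pyr, "rad": rad, "truth": truth, "fs": fs,
            "epochs": epochs}


@pytest.fixture(scope="session")
def pac_sweep():
    """10-s noisy fixtures over the coupling-depth grid, fixed seed."""
    fs = 1000.0
    depths = (0.0, 0.25, 0.5, 0.75, 1.0)
    return {
        "fs": fs,
        "depths": depths,
        "signals": {
            d: syn.gen_pac_signal(
                8.0, 70.0, d, 1.0, 0.5, 10.0, fs, seed=1, noise_rms=0.2
            )
            for d in depths
        },
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
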