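import numpy as np
import pytest

from fpcgbench import synthetic as syn


@pytest.fixture(scope="session")
def fetal_60s():
    """Clean 60 s reference fetal PCG at the default parameters (seed 1)."""
    return syn.generate_fetal_pcg(duration_s=60.0, fs=1000.0, seed=1)


@pytest.fixture(scope="session")
def maternal_60s():
    return syn.generate_maternal_hs(duration_s=60.0, fs=1000.0, seed=2)


@pytest.fixture(scope="session")
def gaussian_mix_60s(fetal_60s):
    """Reference plus white noise at the low-level (-1.20 dB) scenario."""
    noise = syn.generate_gaussian_noise(duration_s=60.0, fs=1000.0, seed=101)
    mixed, scaled = syn.mix_at_snr(
        fetal_60s, [noise], syn.MixSpec(("gaussian",), -1.20),
        return_components=True)
    return fetal_60s, mixed, scaled
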