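import numpy as np
import pytest

from respyre import SynthConfig, generate


@pytest.fixture(scope="session")
def clean_record():
    """480 s clean synthetic record at 15 breaths/min, 70 bpm."""
    cfg = SynthConfig(duration_s=480.0, resp_hz=15 / 60.0, hr_bpm=70.0,
                      seed=42)
    rec, truth = generate(cfg)
    return rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
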