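import logging

import numpy as np
import pytest

from ecgmaf import SynthConfig, generate_clean_ecg
from ecgmaf.synth import make_contaminated_record

logging.disable(logging.WARNING)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_minute():
    """One minute of clean 70 bpm ECG with ground-truth annotation."""
    cfg = SynthConfig(fs=50, duration=60, heart_rate=70, artefact_fraction=0.0, seed=7)
    rec, ann = generate_clean_ecg(cfg)
    return cfg, rec, ann


@pytest.fixture
def contaminated_minute():
    """One minute of 70 bpm ECG with transient artefacts on 20% of beats."""
    cfg = SynthConfig(
        fs=50, duration=60, heart_rate=70,
        artefact_fraction=0.2, artefact_amplitude=2.0, kappa=0.0, seed=7,
    )
    return cfg, *make_contaminated_record(cfg, "walk")
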