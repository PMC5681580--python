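import logging

import numpy as np
import pytest

from borealrings import ringio, synth

logging.getLogger("borealrings").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Default synthetic cohort with pith corrections applied."""
    cfg = synth.SynthConfig(seed=11)
    climate, _ = synth.generate_climate(cfg)
    series, truth = synth.generate_cohort(cfg, climate)
    series = ringio.correct_missing_pith(series, truth.arcs)
    return cfg, climate, series, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
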