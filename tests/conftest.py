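import numpy as np
import pytest
from hypothesis import settings

import pigeontask as pt
from pigeontask import behavior_analysis as ba

settings.register_profile("repro", derandomize=True, max_examples=50)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def block2():
    return pt.get_condition(1, 2)


@pytest.fixture(scope="session")
def corr_table_snr13():
    """Bias-correction table for the SNR-1/3 conditions (default sim size)."""
    return pt.build_correction_table(0.05, 0.15, rng=np.random.default_rng(101))


@pytest.fixture(scope="session")
def analyzed_block2_cohort(block2, corr_table_snr13):
    """A 30-agent block-2 cohort run through the full estimation chain."""
    spec = pt.CohortSpec(n_participants=30, blocks=[block2], seed=102)
    trials = pt.generate_cohort(spec)
    analyzed = ba.analyze_trials(trials, corr_table_snr13, conditions={0: block2})
    return trials, analyzed
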