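import numpy as np
import pytest

from hvmap import (
    SyntheticLobeSpec,
    build_synthetic_lobe,
    synthetic_lobe_def,
)


@pytest.fixture(scope="session")
def canonical_lobe():
    """One calibrated synthetic lobe at (dE=45, δdF=0) plus its definition."""
    model, lobe = build_synthetic_lobe(SyntheticLobeSpec(45.0, 0.0))
    return model, lobe


@pytest.fixture(scope="session")
def asymmetric_lobe():
    """A lobe with a clearly non-zero δdF, for sign-sensitive checks."""
    model, lobe = build_synthetic_lobe(SyntheticLobeSpec(55.0, -20.0))
    return model, lobe


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
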