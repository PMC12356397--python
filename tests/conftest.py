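import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from srbias.observer import ObserverParams, TemplateBank


@pytest.fixture(scope="session")
def bank() -> TemplateBank:
    """Full-size template bank shared across tests (render once)."""
    return TemplateBank()


@pytest.fixture(scope="session")
def small_bank() -> TemplateBank:
    """Small field/glyph for fast simulation-heavy tests."""
    return TemplateBank(glyph_height=40, shape=(48, 48))


@pytest.fixture
def sr_params() -> ObserverParams:
    """Sub-threshold-regime observer used throughout (the package defaults)."""
    return ObserverParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
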