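import numpy as np
import pytest

from cellforge.coupling import BeatWaveforms
from cellforge.experiments.references import reference_waveforms, shipped_prepaced_state


@pytest.fixture(scope="session")
def healthy_ref() -> BeatWaveforms:
    return reference_waveforms("healthy")


@pytest.fixture(scope="session")
def untreated_fibrotic_ref() -> BeatWaveforms:
    return reference_waveforms("hf+fibrosis")


@pytest.fixture(scope="session")
def healthy_prepaced() -> np.ndarray:
    return shipped_prepaced_state("healthy")


@pytest.fixture(scope="session")
def fibrotic_prepaced() -> np.ndarray:
    return shipped_prepaced_state("hf+fibrosis")


def synthetic_waveforms(ap=None, cat=None) -> BeatWaveforms:
    """Build a 501-sample waveform pair from arbitrary callables/arrays."""
    t = np.arange(501, dtype=float)
    if ap is None:
        ap = np.full(501, -85.0)
    elif callable(ap):
        ap = ap(t)
    if cat is None:
        cat = np.full(501, 1e-4)
    elif callable(cat):
        cat = cat(t)
    return BeatWaveforms(ap=np.asarray(ap, float), cat=np.asarray(cat, float))
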