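import numpy as np
import pytest

from mbeeg.montage import standard_1020_montage
from mbeeg.synth import SynthSpec, generate_epochs


@pytest.fixture(scope="session")
def montage():
    return standard_1020_montage()


@pytest.fixture(scope="session")
def small_epochs():
    """A small preprocessed five-class epoch set (4 trials/class)."""
    spec = SynthSpec(n_trials_per_class=4, seed=1, snr=2.0)
    return generate_epochs(spec)


@pytest.fixture(scope="session")
def coupled_epochs():
    """High-SNR epochs with full C3-C4 Beta coupling and no ERD, for
    connectivity ground-truth checks."""
    spec = SynthSpec(
        n_trials_per_class=10,
        seed=2,
        snr=6.0,
        erd_channels={},
        coupling_pairs=(("C3", "C4", "Beta", 1.0),),
    )
    return generate_epochs(spec)
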