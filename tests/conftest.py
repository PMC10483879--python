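import numpy as np
import pytest

from idrfuse.simulate import DisorderCompositionSpec, simulate_proteins


@pytest.fixture(scope="session")
def mixed_records():
    """A small mixed dataset: LDR, SDR and fully ordered proteins."""
    spec = DisorderCompositionSpec(
        n_ldr=6, n_sdr=10, n_ordered=4, length_range=(50, 90), seed=11
    )
    return simulate_proteins(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
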