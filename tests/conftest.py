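import pytest
from hypothesis import settings

from circsponge import synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


SMALL_CONFIG = dict(
    seed=7,
    n_genes=60,
    n_circ=50,
    n_mirna=6,
    n_true_axes=4,
    hub_mirna_fanin=6,
    hub_mirna_fanout=8,
    frac_de=0.5,
)


@pytest.fixture(scope="session")
def small_data():
    """A small synthetic dataset shared across tests (immutable by convention)."""
    return synth.build(synth.SynthConfig(**SMALL_CONFIG))
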