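import numpy as np
import pytest

from misplice.config import PipelineConfig
from misplice.simulate import SimulationSpec, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A small but fully structured synthetic study (80 events, 4v4)."""
    spec = SimulationSpec(
        n_genes=20,
        events_per_gene=4,
        n_case=4,
        n_ctrl=4,
        depth=150.0,
        frac_missplice=0.3,
        delta_psi_effect=0.4,
        clean_background=True,
        affected_in_set_odds=4.0,
        seed=11,
    )
    return simulate_bundle(spec)


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
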