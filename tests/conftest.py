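import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kedit.simulate import SimConfig, simulate_kdna, simulate_reads

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: scaled-down study conditions for unit tests (two pan-edited cascades,
#: one minimally edited cryptogene, two gRNA-less cryptogenes)
SMALL = dict(
    pan_cascade_sizes=(4, 3),
    minimal_cascade_sizes=(1,),
    n_stochastic_cryptogenes=2,
    n_unedited_genes=2,
    n_orphan_grnas=1,
    n_double_grna_minicircles=1,
    n_minicircles=None,
    coverage=25.0,
    smallrna_reads_per_grna=12,
)


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimConfig(seed=42, **SMALL)
    truth = simulate_kdna(cfg)
    reads = simulate_reads(truth, cfg)
    return cfg, truth, reads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
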