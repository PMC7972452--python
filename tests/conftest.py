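import numpy as np
import pytest

from lineage4d.alignment import build_reference
from lineage4d.simulate import SimulationConfig, simulate_cohort, simulate_embryo


@pytest.fixture(scope="session")
def sim_config():
    cfg = SimulationConfig(seed=7)
    cfg.n_embryos = {
        "wild_type": 3,
        "control": 6,
        "equalized_alive": 7,
        "equalized_dead": 8,
        "inverted": 2,
    }
    cfg.truncation_fraction = 0.0
    return cfg


@pytest.fixture(scope="session")
def cohort(sim_config):
    embryos, meta = simulate_cohort(sim_config)
    return embryos, meta.set_index("embryo_id")


@pytest.fixture(scope="session")
def controls(cohort):
    embryos, _ = cohort
    return [e for e in embryos if e.metadata.group == "control"]


@pytest.fixture(scope="session")
def reference(controls):
    return build_reference(controls)


@pytest.fixture(scope="session")
def wild_type_embryo(sim_config):
    return simulate_embryo(sim_config, "wild_type", 11, embryo_id="wt_fixture")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
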