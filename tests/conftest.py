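import numpy as np
import pytest

from cbtc.regions import default_manifest, subjects_to_frame
from cbtc.simulate import SimulationConfig, simulate_cohort
from cbtc import fc as _fc


@pytest.fixture(scope="session")
def manifest():
    return default_manifest()


@pytest.fixture(scope="session")
def cohort64(manifest):
    """Default-scale synthetic cohort (64 patients / 64 controls, T = 200)."""
    return simulate_cohort(SimulationConfig(seed=11), manifest)


@pytest.fixture(scope="session")
def fc_loops64(cohort64, manifest):
    return _fc.extract_fc_vector(cohort64.series, manifest, "loops")


@pytest.fixture(scope="session")
def labels64(cohort64, fc_loops64):
    pheno = subjects_to_frame(cohort64.subjects).set_index("id")
    return pheno.loc[fc_loops64.index, "group"].to_numpy()
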