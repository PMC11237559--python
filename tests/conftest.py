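import numpy as np
import pytest

from soxyprof.pipeline import RunConfig, run_pipeline
from soxyprof.profiles import build_profile
from soxyprof.search import calibrate, calibrate_local
from soxyprof.signatures import DomainQuery
from soxyprof.synthetic import CYS_POSITION_1BASED, default_reference_set


@pytest.fixture(scope="session")
def refs():
    return default_reference_set()


@pytest.fixture(scope="session")
def profile(refs):
    return build_profile(refs.seed_alignment, pseudocount=1.0,
                         cys_position=CYS_POSITION_1BASED, name="SoxY")


@pytest.fixture(scope="session")
def calibration(profile):
    return calibrate(profile, [150, 200, 250, 300], n_decoys=1000, seed=7)


@pytest.fixture(scope="session")
def domain_queries(refs):
    """Calibrated SoxY/SoxZ local-search probes for fusion detection."""
    lengths = [150, 200, 250]
    qy = DomainQuery("SoxY", refs.canonical_soxy,
                     calibrate_local(refs.canonical_soxy, lengths, 1000, 11))
    qz = DomainQuery("SoxZ", refs.canonical_soxz,
                     calibrate_local(refs.canonical_soxz, lengths, 1000, 12))
    return qy, qz


@pytest.fixture(scope="session")
def run12():
    """A small end-to-end pipeline run shared by integration tests."""
    cfg = RunConfig(seed=1, n_genomes=12, bootstrap_replicates=50,
                    n_permutations=199)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def cohort50():
    """The 50-genome study-condition cohort used by the acceptance tests."""
    cfg = RunConfig(seed=1, n_genomes=50)
    return run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
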