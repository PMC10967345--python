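import numpy as np
import pytest
from hypothesis import settings

from redoxusage.simulate import SimConfig, write_fixture_bundle

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but complete synthetic bundle shared across tests."""
    cfg = SimConfig(seed=11, n_species=6, proteins_per_set=12,
                    mean_protein_length=220)
    outdir = tmp_path_factory.mktemp("bundle") / "b"
    truth = write_fixture_bundle(cfg, outdir)
    return cfg, outdir, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
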