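import pytest
from hypothesis import settings

import haplomosaic as hm
from haplomosaic.synthetic_data import generate_toy_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: small continental composition for fast end-to-end tests
SMALL_PANEL = {"AFR": 60, "AMR": 40, "ASN": 60, "EUR": 80}


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    return generate_toy_fixture(tmp_path_factory.mktemp("toy"))


@pytest.fixture(scope="session")
def toy_cohort(toy_paths):
    return hm.read_phased_vcf(toy_paths["vcf"], toy_paths["panel"])


@pytest.fixture(scope="session")
def small_synth():
    """Small noise-free synthetic cohort with one segment per scenario."""
    cfg = hm.SynthConfig(samples_per_continent=dict(SMALL_PANEL), seed=7)
    return hm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_synth():
    """Study-scale (1092-diploid) noise-free synthetic cohort."""
    return hm.generate_cohort(hm.SynthConfig(seed=11))
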