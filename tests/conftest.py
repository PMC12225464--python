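import numpy as np
import pytest
from hypothesis import settings

import patroldetect as pdt

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """Reduced-cardinality study-like config: 4 regions, 4 actors, 6 species,
    3 violation types, 7 years, 2,500 records."""
    return pdt.reference_config(
        seed=11, n_records=2500, n_regions=4, n_actors=4, n_species=6, n_violations=3
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    frame, truth = pdt.simulate_records(small_config)
    return frame, truth


@pytest.fixture(scope="session")
def small_design(small_config, small_dataset):
    frame, _ = small_dataset
    return pdt.build_design(frame, small_config.scheme)


@pytest.fixture(scope="session")
def small_fit(small_design):
    """A modest-length fit of the small synthetic dataset, shared by
    evaluation/reporting tests."""
    cfg = pdt.SamplerConfig(seed=5, n_chains=3, n_warmup=250, n_samples=500)
    return pdt.sample_posterior(small_design, cfg)
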