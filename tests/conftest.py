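import numpy as np
import pandas as pd
import pytest

import airfusion as af


@pytest.fixture
def toy_sites():
    """Six hand-written sites covering both sources and three environments."""
    return pd.DataFrame({
        "site_id": [f"s{i}" for i in range(6)],
        "easting_m": [500.0, 1500.0, 2500.0, 500.0, 1500.0, 2500.0],
        "northing_m": [500.0, 500.0, 500.0, 1500.0, 1500.0, 1500.0],
        "source": ["tube", "tube", "tube", "tube", "monitor", "monitor"],
        "environment": ["kerbside", "roadside", "urban_background",
                        "roadside", "kerbside", "urban_background"],
        "pcm_no2_ugm3": [8.0, 10.0, 6.0, 12.0, 9.0, 7.0],
        "no2_ugm3": [30.0, 28.0, 18.0, 33.0, 31.0, 20.0],
    })


@pytest.fixture(scope="session")
def small_region():
    """One m=60 synthetic dataset on a 10 km extent (tubes, monitors,
    co-located pairs), observations drawn from the generative model."""
    cfg = af.SyntheticConfig(extent_m=(0.0, 10_000.0, 0.0, 10_000.0),
                             n_tubes=52, n_monitors=8, n_colocated=4, seed=3)
    sites, grid = af.generate_dataset(cfg)
    return cfg, sites, grid


@pytest.fixture(scope="session")
def small_fit(small_region):
    """A short MCMC fit of the model-1-style spec on the small region."""
    _, sites, _ = small_region
    spec = af.CovariateSpec(include_source=True)
    return sites, af.fit_fusion_model(sites, spec, n_burn=300, n_keep=600,
                                      seed=11)
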