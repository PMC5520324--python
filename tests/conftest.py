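import numpy as np
import pandas as pd
import pytest

import painfusion as pf


@pytest.fixture(scope="session")
def cluster_params():
    return pf.load_cluster_params()


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed 6-cluster cohort with the default missing weeks, n=240+80."""
    cfg = pf.CohortConfig(n_obs=240, n_rct=80, seed=42)
    return pf.generate_cohort(cfg)


@pytest.fixture(scope="session")
def complete_cohort():
    """Fully observed observational cohort (no masking), n=300."""
    cfg = pf.CohortConfig(n_obs=300, n_rct=0, seed=7,
                          missing_weeks_obs=frozenset())
    return pf.generate_cohort(cfg)


def single_cluster_cohort(cluster, n, seed, noise_sd, n_rct=0):
    """Fully-observed cohort drawn from one latent cluster."""
    mix = tuple(1.0 if i + 1 == cluster else 0.0 for i in range(6))
    cfg = pf.CohortConfig(n_obs=n, n_rct=n_rct, seed=seed, noise_sd=noise_sd,
                          cluster_mix=mix, missing_weeks_obs=frozenset())
    return pf.generate_cohort(cfg)


@pytest.fixture(scope="session")
def cluster1_noiseless():
    return single_cluster_cohort(1, 150, seed=1, noise_sd=0.0)
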