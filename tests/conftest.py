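import warnings

import numpy as np
import pytest

from mycnimmune.simulate import (
    CohortConfig,
    MixtureConfig,
    generate_cohort,
    generate_reference_and_mixtures,
)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """300-sample, 500-gene cohort with planted signature genes."""
    cfg = CohortConfig(n_samples=300, n_genes=500, n_pos_genes=30,
                       n_neg_genes=20, seed=11)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def module_cohort():
    """Four planted co-expression factors (60/50/40/30) plus 120 noise genes."""
    cfg = CohortConfig(
        n_samples=300, n_genes=300, n_pos_genes=0, n_neg_genes=0,
        module_spec=[(60, 0.8), (50, 0.8), (40, 0.8), (30, 0.8)],
        noise_sd=0.5, seed=5,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def mixture_set():
    """5-type reference profiles and 40 simplex mixtures at 5% noise."""
    return generate_reference_and_mixtures(MixtureConfig(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
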