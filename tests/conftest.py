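import logging

import numpy as np
import pytest

from mranet import (
    PerturbationSpec,
    make_truth_network,
    simulate_cohort,
)

logging.getLogger("mranet").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_truth():
    """Three TFs x 10 targets (30% repressing) plus 20 decoy genes."""
    return make_truth_network(
        n_tf=3, targets_per_tf=10, frac_negative=0.3, n_decoys=20, seed=101
    )


@pytest.fixture(scope="session")
def reference_cohort(small_truth):
    """Unlabelled 120-sample reference cohort from the small truth network."""
    return simulate_cohort(small_truth, n_samples=120, noise_sd=0.5, seed=102)


@pytest.fixture(scope="session")
def perturbed_cohort(small_truth):
    """30 case vs 31 control cohort with TF000's regulon repressed."""
    perturb = PerturbationSpec("TF000", "repressed", 1.5)
    return simulate_cohort(
        small_truth, n_samples=61, noise_sd=0.5,
        perturbation=perturb, n_case=30, seed=103,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
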