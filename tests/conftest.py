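import numpy as np
import pytest

from dynstates.synthetic import CohortSpec, gen_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 20-subject cohort (time courses only), shared across tests."""
    spec = CohortSpec(n_group_a=9, n_group_b=11, seed=123)
    manifest = gen_cohort(spec, tmp_path_factory.mktemp("cohort"),
                          write_images=False)
    return spec, manifest


@pytest.fixture(scope="session")
def noiseless_image_cohort(tmp_path_factory):
    """A 6-subject noiseless image cohort for exact-recovery tests."""
    spec = CohortSpec(n_group_a=3, n_group_b=3, noise_sd=0.0,
                      image_noise_sd=0.0, seed=321)
    manifest = gen_cohort(spec, tmp_path_factory.mktemp("imgcohort"))
    return spec, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(0)
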