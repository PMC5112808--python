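import warnings

import numpy as np
import pytest

from flrw import PhantomSpec, denoise, generate_cohort, train_flrw_model
from flrw.texture_features import FeatureWindowSpec


def micro_phantom_spec() -> PhantomSpec:
    """Desk-scale phantom: same structure as the default, quarter area."""
    return PhantomSpec(
        shape=(64, 64),
        liver_radius=17.0,
        confuser_radius=9.0,
        liver_smooth_sigma=1.5,
    )


@pytest.fixture(scope="session")
def micro_spec() -> FeatureWindowSpec:
    """Small feature window for fast unit tests."""
    return FeatureWindowSpec(h=7, w=7, glcm_levels=8, hog_bins=6)


@pytest.fixture(scope="session")
def micro_cohort():
    """Five small phantoms: three for training, two held out."""
    return generate_cohort(5, micro_phantom_spec(), seed=11)


@pytest.fixture(scope="session")
def micro_model(micro_spec, micro_cohort):
    """A quickly trained ensemble reused across tests."""
    train = micro_cohort[:3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_flrw_model(
            [denoise(img) for img, _ in train],
            [mask for _, mask in train],
            spec=micro_spec,
            n_per_region=300,
            edge_band=2,
            T=4,
            resample_size=400,
            seed=5,
        )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
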