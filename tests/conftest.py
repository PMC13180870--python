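import pytest

from qsargan.classifier import ActivityClassifier, GbtConfig, SplitSpec, augment_training, split_real
from qsargan.gan import CganConfig, ConditionalGAN
from qsargan.synthetic import FixtureSpec, make_training_fixture


SMALL_SPEC = FixtureSpec(
    n_active=30,
    n_inactive=30,
    n_descriptors=10,
    class_shift=1.5,
    n_shifted=4,
    latent_rank=3,
    seed=7,
)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_table():
    return make_training_fixture(SMALL_SPEC)


@pytest.fixture(scope="session")
def tiny_gan(small_table):
    """A briefly trained GAN on the small fixture, for structural tests."""
    cfg = CganConfig(epochs=25, seed=3)
    model = ConditionalGAN(small_table, cfg)
    return model, model.fit()


@pytest.fixture(scope="session")
def small_bundle(small_table):
    """A quick boosted-tree bundle (30 rounds) plus its splits."""
    train, validation, test = split_real(small_table, SplitSpec(seed=5))
    combined, _ = augment_training(train, train.iloc[0:0], validation, test)
    results = ActivityClassifier(combined, validation, GbtConfig(n_estimators=30, seed=5)).fit()
    return results, train, validation, test
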