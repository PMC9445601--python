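import pytest

from foliar import (
    Leaf,
    Shoot,
    analyze_species,
    default_config,
    generate_shoots,
)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Shoots + ground truth under the standard synthetic conditions."""
    return generate_shoots(default_config())


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Standard conditions with measurement noise switched off."""
    return generate_shoots(default_config(noise_sigma_log10=0.0))


@pytest.fixture(scope="session")
def noise_free_report(noise_free_dataset):
    shoots, _ = noise_free_dataset
    return analyze_species(shoots)


@pytest.fixture
def three_leaf_shoot():
    return Shoot(
        shoot_id="sh1",
        species="demo",
        leaves=(Leaf(7, 3, 10), Leaf(9, 4, 20), Leaf(8, 5, 15)),
    )
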