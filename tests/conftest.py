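import pytest

import nescan as ns
from nescan.profiles import NesClass


@pytest.fixture(scope="session")
def bundled_profiles():
    return ns.default_profiles()


@pytest.fixture(scope="session")
def profile_1c(bundled_profiles):
    return next(p for p in bundled_profiles if p.nes_class is NesClass.CLASS_1C)


@pytest.fixture(scope="session")
def profile_map(bundled_profiles):
    return {p.nes_class: p for p in bundled_profiles}


@pytest.fixture(scope="session")
def small_proteome():
    """Seeded fixture proteome: 8 positives (one planted NES each), 6 decoys."""
    config = ns.FixtureConfig(n_proteins=8, n_decoy_proteins=6, seed=11)
    records, pos, neg = ns.generate_proteome(config)
    return config, records, pos, neg


@pytest.fixture(scope="session")
def training_proteome():
    """Smaller single-class proteome for trainer tests."""
    config = ns.FixtureConfig(
        n_proteins=4,
        n_decoy_proteins=4,
        min_length=120,
        max_length=150,
        planted_classes=(NesClass.CLASS_1C,),
        seed=2,
    )
    records, pos, neg = ns.generate_proteome(config)
    return config, records, pos, neg
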