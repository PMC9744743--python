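import pytest

import hsgraft as hg


@pytest.fixture(scope="session")
def planted_fixture():
    """A 30-residue line with a K–K pair 6.0 Å apart and one completable Ser."""
    spec = hg.FixtureSpec(
        n_residues=30,
        planted_pairs=[hg.PlantedPair("K", "K", 6.0)],
        planted_candidate=hg.PlantedCandidate("S"),
        seed=11,
    )
    model, truth = hg.generate_fixture(spec)
    return model, truth


@pytest.fixture(scope="session")
def planted_surface(planted_fixture):
    model, _ = planted_fixture
    return hg.surface_profile(model)


@pytest.fixture(scope="session")
def mimic():
    """The removal-design mimic: cluster {42,43,239} + motif {239,243,244}."""
    model, truth = hg.hs_minus_mimic()
    surface = hg.surface_profile(model)
    return model, truth, surface


@pytest.fixture(scope="session")
def mimic_pattern():
    return [hg.MotifPattern("BXXXBB", "BXXXBB", "user")]
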