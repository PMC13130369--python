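import pytest

from ampliscore import ConfusionParams, design_default_community, simulate_classification

SPECIES = [
    "Thermomonas carbonis",
    "Acidovorax temperans",
    "Zoogloea ramigera",
    "Dechloromonas agitata",
    "Nitrospira defluvii",
    "Gordonia amarae",
    "Tetrasphaera elongata",
    "Candidatus Accumulibacter phosphatis",
    "Acinetobacter johnsonii",
    "Arcobacter cryaerophilus",
    "Aeromonas media",
    "Flavobacterium columnare",
    "Hydrogenophaga palleronii",
    "Rhodoferax ferrireducens",
    "Paracoccus denitrificans",
]


@pytest.fixture
def species_names():
    return list(SPECIES)


@pytest.fixture
def truth(species_names):
    """Default three-tier 15-species community."""
    return design_default_community("west_bank", species_names)


@pytest.fixture
def noisy_profile(truth):
    """One simulated classifier output under the default confusion channel."""
    return simulate_classification(truth, 175_000, ConfusionParams(seed=42))


@pytest.fixture
def perfect_profile(truth):
    """Identity-channel output: every read mapped to its taxon of origin."""
    return simulate_classification(
        truth, 100_000, ConfusionParams(p_correct=1.0, p_unmapped=0.0, seed=7)
    )
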