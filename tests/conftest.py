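import pytest

from g4char import (
    GeneratorConfig,
    IonSpecies,
    Oligonucleotide,
    gen_ms_spectrum,
)
from g4char.synthetic_data import MUTANT_SEQUENCE, S1_SEQUENCE


@pytest.fixture
def s1():
    return Oligonucleotide(name="S1", sequence=S1_SEQUENCE)


@pytest.fixture
def mutant():
    return Oligonucleotide(name="S1-mutant", sequence=MUTANT_SEQUENCE)


@pytest.fixture
def binding_spectrum(s1):
    """Simulated berberine-binding spectrum at the 4- charge state with two
    ammoniums: free 30%, 1:1 100%, 1:2 75%."""
    species = [
        (IonSpecies(charge=4, n_ammonium=2, n_ligand=b), h)
        for b, h in [(0, 30.0), (1, 100.0), (2, 75.0)]
    ]
    spectrum, truth = gen_ms_spectrum(species, s1, cfg=GeneratorConfig(seed=7))
    return spectrum, truth
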