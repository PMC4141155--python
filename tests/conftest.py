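import pytest

from gqbind import (
    SpectrumSimConfig,
    TELOMERIC_DNA_CONSTANTS,
    builtin_molecules,
    oligo_average_mass,
    parse_oligo_notation,
)


@pytest.fixture(scope="session")
def dna_seq():
    """The 27-mer human telomeric DNA quadruplex-forming sequence."""
    return parse_oligo_notation("d[(TTAGGG)4TTA]")


@pytest.fixture(scope="session")
def rna_seq():
    """Its RNA analogue."""
    return parse_oligo_notation("r[(UUAGGG)4UUA]")


@pytest.fixture(scope="session")
def dna_mass(dna_seq):
    return oligo_average_mass(dna_seq)


@pytest.fixture(scope="session")
def rna_mass(rna_seq):
    return oligo_average_mass(rna_seq)


@pytest.fixture(scope="session")
def molecules():
    return builtin_molecules()


@pytest.fixture
def clean_sim_config():
    """Noise-free tetrachloride-mode simulation at the DNA truth constants."""
    return SpectrumSimConfig(
        truth=TELOMERIC_DNA_CONSTANTS,
        mz_jitter_sd=0.0,
        area_noise_sd=0.0,
        n_decoys=0,
        seed=0,
    )
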