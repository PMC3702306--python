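import numpy as np
import pytest

from etdloc import build_mass_table
from etdloc.data import fra2_fasta_path, fra2_mgf_path, fra2_peptide
from etdloc.io import read_fasta, read_mgf


@pytest.fixture(scope="session")
def mono():
    return build_mass_table("monoisotopic")


@pytest.fixture(scope="session")
def avg():
    return build_mass_table("average")


@pytest.fixture(scope="session")
def legend():
    return build_mass_table("paper_legend")


@pytest.fixture(scope="session")
def fra2_protein():
    return read_fasta(fra2_fasta_path())[0]


@pytest.fixture(scope="session")
def fra2_spectra():
    return read_mgf(fra2_mgf_path())


@pytest.fixture(scope="session")
def fra2_base():
    """The unmodified example 20-mer at protein coordinates 307-326."""
    return fra2_peptide()


@pytest.fixture(scope="session")
def fra2_ph14():
    """The example 20-mer phosphorylated at peptide position 14 (S320)."""
    return fra2_peptide(14)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def random_peptide(rng, min_len=5, max_len=30, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(alphabet), size=n))
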