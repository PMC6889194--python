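import pytest
from pyfaidx import Fasta

from factorsig.synthetic_data import make_signature_set, make_toy_reference, simulate_catalog


@pytest.fixture(scope="session")
def toy_reference(tmp_path_factory):
    """Random 3-chromosome reference with the list of plantable positions."""
    d = tmp_path_factory.mktemp("ref")
    fasta_text, positions = make_toy_reference(n_chroms=3, length=80, seed=11)
    path = d / "toy.fa"
    path.write_text(fasta_text)
    return Fasta(str(path)), positions


@pytest.fixture(scope="session")
def spec_fasta(tmp_path_factory):
    """The minimal 7-base single-chromosome reference used in doc examples."""
    d = tmp_path_factory.mktemp("minifa")
    path = d / "mini.fa"
    path.write_text(">chr1\nAAGCTAA\n")
    return Fasta(str(path))


@pytest.fixture(scope="session")
def separated_sigset():
    return make_signature_set(3, separation="well_separated", includes_strand=True, seed=21)


@pytest.fixture(scope="session")
def small_catalog(separated_sigset):
    catalog, truth = simulate_catalog(separated_sigset, n_samples=12, seed=22)
    return catalog, truth
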