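import numpy as np
import pytest

from memnovo.datasets import AnnotatedPeptide, PeptideDataset

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))


def make_dataset(peptides, name="test", enzyme="", role="unsplit"):
    """Dataset from bare peptide strings, spectrum ids auto-assigned."""
    records = tuple(
        AnnotatedPeptide(
            peptide=p,
            charge=2,
            source_enzyme=enzyme,
            spectrum_id=f"{name}:{i:05d}",
        )
        for i, p in enumerate(peptides)
    )
    return PeptideDataset(name, records, role)


@pytest.fixture
def rng():
    return np.random.default_rng(20230120)
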