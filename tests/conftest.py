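import numpy as np
import pytest

from palinbench.records import DNA, PROTEIN, SequenceRecord
from palinbench.synthetic import CompositionSpec, generate_random


def protein(residues: str, id: str = "p") -> SequenceRecord:
    return SequenceRecord(id, PROTEIN, residues)


def dna(residues: str, id: str = "d") -> SequenceRecord:
    return SequenceRecord(id, DNA, residues)


@pytest.fixture(scope="session")
def uniform_protein_300():
    """200 uniform-composition protein sequences, lengths 280-320."""
    spec = CompositionSpec.uniform_protein(("uniform_range", 280, 320))
    return generate_random(spec, 200, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def blosum62_scheme():
    from palinbench.matchstat import ScoringScheme

    return ScoringScheme.blosum62()
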