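import numpy as np
import pytest

from linkerrf import (
    AnnotatedCorpus,
    GeneratorConfig,
    PropertyTables,
    ProteinSequence,
    generate_corpus,
)
from linkerrf.sequence_io import STANDARD_AA


@pytest.fixture(scope="session")
def tables() -> PropertyTables:
    return PropertyTables.default()


@pytest.fixture
def toy_corpus() -> AnnotatedCorpus:
    """Two short sequences with hand-countable linker/domain compositions.

    seq a: residues PPPSS|GGGGG  -> linker P*3 S*2, domain G*5
    seq b: residues PP|GGGGGLLL  -> linker P*2, domain G*5 L*3
    Linker partition: P*5 S*2 (7 residues); domain: G*10 L*3 (13 residues).
    """
    seqs = [
        ProteinSequence("a", "PPPSSGGGGG"),
        ProteinSequence("b", "PPGGGGGLLL"),
    ]
    labels = [
        np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=np.int8),
        np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], dtype=np.int8),
    ]
    return AnnotatedCorpus(seqs, labels)


@pytest.fixture
def full_alphabet_corpus() -> AnnotatedCorpus:
    """Every standard amino acid present in both partitions."""
    aa = STANDARD_AA
    seqs = [ProteinSequence("all", aa * 4)]
    lab = np.zeros(80, dtype=np.int8)
    lab[:40] = 1  # first two alphabet repeats are "linker"
    return AnnotatedCorpus(seqs, [lab])


@pytest.fixture(scope="session")
def small_synthetic_corpus() -> AnnotatedCorpus:
    """A small, strongly divergent corpus for fast pipeline tests."""
    corpus, _ = generate_corpus(
        GeneratorConfig(n_sequences=12, divergence_multiplier=4.0, seed=7)
    )
    return corpus
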