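import numpy as np
import pytest

from salm.seqio import SequenceRecord
from salm.synth import SyntheticSpec, generate_transcriptome
from salm.synthetic_standins import five_class_precursors, standin_cdnas


@pytest.fixture(scope="session")
def standin_proteins() -> dict[str, SequenceRecord]:
    return {r.id: r for r in five_class_precursors()}


@pytest.fixture(scope="session")
def standin_cdna_records() -> dict[str, SequenceRecord]:
    return {r.id: r for r in standin_cdnas(seed=1)}


@pytest.fixture(scope="session")
def small_transcriptome():
    """One planted precursor among 50 decoys, seed 7."""
    spec = SyntheticSpec(n_precursors=1, n_decoys=50, seed=7)
    return generate_transcriptome(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
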