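import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from barcodeaudit.library_io import ReferenceLibrary, SequenceRecord
from barcodeaudit.synthetic_data import SimulationConfig, simulate_library


@pytest.fixture
def tiny_lib() -> ReferenceLibrary:
    """Two 2-record species plus a singleton, 20 bp."""
    return ReferenceLibrary(
        [
            SequenceRecord("a1", "Alpha one", "ACGTACGTACGTACGTACGT"),
            SequenceRecord("a2", "Alpha one", "ACGTACGTACGTACGTACGA"),
            SequenceRecord("b1", "Beta two", "TGCATGCATGCATGCATGCA"),
            SequenceRecord("b2", "Beta two", "TGCATGCATGCATGCATGCC"),
            SequenceRecord("c1", "Gamma three", "AAAACCCCGGGGTTTTAAAA"),
        ]
    )


@pytest.fixture
def sim_lib():
    cfg = SimulationConfig(
        n_species=5,
        specimens_per_species=4,
        seq_length=658,
        interspecific_divergence=0.08,
        intraspecific_divergence=0.005,
        seed=7,
    )
    return simulate_library(cfg)


@pytest.fixture
def small_sim_lib():
    cfg = SimulationConfig(
        n_species=4,
        specimens_per_species=3,
        seq_length=300,
        interspecific_divergence=0.08,
        intraspecific_divergence=0.005,
        seed=11,
    )
    return simulate_library(cfg)
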