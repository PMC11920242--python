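import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from styscreen import synthetic_data as sd


@pytest.fixture(scope="session")
def demo_amplicon():
    """Synthetic in-frame amplicon with L-S-Y codons at positions 512-514."""
    return sd.make_demo_amplicon(seed=0)


@pytest.fixture(scope="session")
def demo_haplotypes():
    return [
        sd.Haplotype(edits=[(13, "G")], fraction=0.3, label="Y514C"),
        sd.Haplotype(edits=[(7, "C"), (9, "C")], fraction=0.2, label="L512P/S513P"),
    ]


@pytest.fixture(scope="session")
def toy_transcripts():
    return sd.make_toy_proteome(n_genes=3, cds_len_range=(150, 300), seed=11)
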