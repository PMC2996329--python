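import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from nahrkit.catalog import Family, RepeatCatalog, RepeatElement, Strand


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def three_element_catalog():
    return RepeatCatalog(
        [
            RepeatElement("tyA", Family.TY1, "ACGTACGTAC", "chrI", 100, 110, Strand.PLUS),
            RepeatElement("tyB", Family.TY1, "ACGTACGAAC", "chrI", 300, 310, Strand.PLUS),
            RepeatElement("tyC", Family.TY2, "TTTTACGTAC", "chrII", 50, 60, Strand.MINUS),
        ]
    )


@pytest.fixture
def fasta_bed_files(tmp_path, three_element_catalog):
    from nahrkit.catalog import write_bed, write_fasta

    fasta = tmp_path / "elements.fasta"
    bed = tmp_path / "elements.bed"
    write_fasta(three_element_catalog, fasta)
    write_bed(three_element_catalog, bed)
    return fasta, bed
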