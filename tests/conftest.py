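import numpy as np
import pytest

from gravirebound.annotation import (
    Cytoband,
    Gene,
    GenomeAnnotation,
    Transcript,
)
from gravirebound.simulate import SimulationDesign, synthetic_annotation


@pytest.fixture
def tiny_ann() -> GenomeAnnotation:
    """Hand-built two-chromosome annotation.

    chr1 carries gene A (two isoforms, the second skipping the middle exon)
    and single-exon gene B; chr2 carries minus-strand gene C. Cytobands
    split chr1 at 1000.
    """
    ann = GenomeAnnotation()
    ann.transcripts = {
        "A.t1": Transcript(
            "A.t1", "A", "protein_coding", [(100, 200), (300, 400), (500, 600)]
        ),
        "A.t2": Transcript("A.t2", "A", "retained_intron", [(100, 200), (500, 600)]),
        "B.t1": Transcript("B.t1", "B", "protein_coding", [(1000, 1400)]),
        "C.t1": Transcript("C.t1", "C", "nmd", [(100, 300), (700, 900)]),
    }
    ann.genes = {
        "A": Gene("A", "chr1", "+", (100, 600), ["A.t1", "A.t2"]),
        "B": Gene("B", "chr1", "+", (1000, 1400), ["B.t1"]),
        "C": Gene("C", "chr2", "-", (100, 900), ["C.t1"]),
    }
    ann.chrom_lengths = {"chr1": 2000, "chr2": 1500}
    ann.cytobands = [
        Cytoband("chr1", "p1", 0, 1000),
        Cytoband("chr1", "q1", 1000, 2000),
        Cytoband("chr2", "p1", 0, 1500),
    ]
    ann.validate()
    return ann


@pytest.fixture(scope="session")
def sim_ann() -> GenomeAnnotation:
    return synthetic_annotation(300, seed=4)


@pytest.fixture(scope="session")
def design() -> SimulationDesign:
    return SimulationDesign()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
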