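import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from hipred.intervals import GenomeInterval, Transcript
from hipred.simulate import SimulationConfig


@pytest.fixture
def plus_transcript():
    """3-exon coding transcript on +: exons [100,130),[200,320),[400,490),
    CDS [210,320)+[400,446) = 156 bp, 5'-UTR exon 1."""
    iv = lambda s, e: GenomeInterval("chr1", s, e, "+")
    return Transcript(
        id="txp", gene_id="gp", interval=iv(100, 490),
        exons=[iv(100, 130), iv(200, 320), iv(400, 490)],
        cds=[iv(210, 320), iv(400, 446)],
    )


@pytest.fixture
def minus_transcript():
    """Mirror geometry on -: CDS 5' end at the highest coordinate."""
    iv = lambda s, e: GenomeInterval("chr1", s, e, "-")
    return Transcript(
        id="txm", gene_id="gm", interval=iv(100, 490),
        exons=[iv(100, 130), iv(200, 320), iv(400, 490)],
        cds=[iv(114, 130), iv(200, 310)],
    )


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=20260924)


def deletion(start, end, chrom="chr1"):
    return GenomeInterval(chrom, start, end, ".")
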