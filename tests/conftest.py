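import random

import pytest

from natpipe.io_formats import GenomeInterval, TranscriptRecord

BASES = "ACGT"


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(n))


def make_transcript(tid: str, seq: str, chrom: str = "chr1", strand: str = "+",
                    start: int = 0, end: int | None = None) -> TranscriptRecord:
    end = end if end is not None else start + len(seq)
    return TranscriptRecord(tid, tid, chrom, strand, start, end, seq)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)


@pytest.fixture
def interval():
    return GenomeInterval("chr1", 100, 200, "+")
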