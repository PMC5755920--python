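import numpy as np
import pytest

from methdomains.io import CpGCall, GenomeSequence, MethylationTrack


@pytest.fixture
def toy_genome() -> GenomeSequence:
    # CG dyads at 10 and 20; CCGG at 30 (MspI site)
    seq = "A" * 10 + "CG" + "T" * 8 + "CG" + "T" * 8 + "CCGG" + "A" * 6
    return GenomeSequence({"chr1": seq})


@pytest.fixture
def toy_track() -> MethylationTrack:
    return MethylationTrack(
        [
            CpGCall.from_counts("chr1", 10, 3, 1),
            CpGCall.from_counts("chr1", 20, 0, 8),
        ]
    )


def make_track(rows) -> MethylationTrack:
    """rows: iterable of (chrom, pos, n_meth, n_unmeth)."""
    return MethylationTrack(CpGCall.from_counts(*r) for r in rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
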