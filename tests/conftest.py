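import numpy as np
import pytest

from m5cpipe.model import AlignedRead
from m5cpipe.simdata import SimConfig, simulate


def make_read(
    seq,
    start=0,
    ref="TX0001",
    quals=40,
    name="r1",
    umi="ACGTACGT",
    is_reverse=False,
    mate="single",
    cigar=None,
):
    """Small constructor for hand-built reads in tests."""
    if isinstance(quals, int):
        quals = np.full(len(seq), quals, dtype=np.uint8)
    return AlignedRead(
        name=name,
        ref=ref,
        start=start,
        seq=seq,
        quals=np.asarray(quals, dtype=np.uint8),
        cigar=cigar or [("M", len(seq))],
        umi=umi,
        is_reverse=is_reverse,
        mate=mate,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest library with every error process switched on, shared by
    read-level tests (session-scoped: simulated once)."""
    cfg = SimConfig(
        n_transcripts=5,
        n_control_transcripts=2,
        length_range=(1400, 1600),
        n_true_sites=15,
        mean_coverage=50,
        seed=42,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free, fully converted, unmethylated library: every read is
    exactly the converted reference fragment."""
    cfg = SimConfig(
        n_transcripts=2,
        n_control_transcripts=2,
        length_range=(900, 1100),
        n_true_sites=0,
        mean_coverage=30,
        conversion_rate=1.0,
        resistant_read_fraction=0.0,
        resistant_transcript_fraction=0.0,
        pcr_cycles=0,
        pcr_error_rate=0.0,
        seq_error_rate=0.0,
        seed=7,
    )
    return simulate(cfg)
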