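"""Core data model shared by every pipeline stage.

Coordinates are 0-based, half-open everywhere inside the package; SAM I/O
converts to and from the 1-based inclusive convention at the boundary.

A read's *orientation* records which bisulfite conversion space it reports:
``C2T`` reads show unmethylated cytosines as thymines at reference-C
positions; ``G2A`` reads (reads aligned to the strand complementary to the
converted one) show them as G->A changes at reference-G positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

C2T = "C2T"
G2A = "G2A"

#: cigar operations that consume the query sequence
_CONSUMES_QUERY = frozenset("MIS=X")
#: cigar operations that consume the reference
_CONSUMES_REF = frozenset("MDN=X")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a SAM cigar string into [(op, length), ...]."""
    out: list[tuple[str, int]] = []
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            out.append((ch, int(n)))
            n = ""
    return out


def cigar_string(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


@dataclass
class AlignedRead:
    """One aligned bisulfite read.

    ``quals`` are Phred scores as integers (Phred+33 applies only on disk).
    ``seq`` is stored in reference-forward orientation, as in SAM; for
    reverse-strand reads the sequencer-order read is the reverse complement.
    """

    name: str
    ref: str
    start: int  # 0-based leftmost reference position
    seq: str
    quals: np.ndarray  # uint8 Phred values, len == len(seq)
    cigar: list[tuple[str, int]] = field(default_factory=list)
    umi: str = ""
    orientation: str = C2T
    mate: str = "single"  # single | read1 | read2
    is_reverse: bool = False
    mapq: int = 60
    discard_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.cigar and self.seq:
            self.cigar = [("M", len(self.seq))]
        if not isinstance(self.quals, np.ndarray):
            self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.seq) != len(self.quals):
            raise ValueError("seq and quals length mismatch")
        if self.start < 0:
            raise ValueError("negative start")
        if self.orientation not in (C2T, G2A):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        return self.start + sum(n for op, n in self.cigar if op in _CONSUMES_REF)

    @property
    def is_simple(self) -> bool:
        """True when the alignment is a single ungapped match block."""
        return len(self.cigar) == 1 and self.cigar[0][0] in "M=" and not self.discard_reason

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_offset, reference_position) for aligned bases only."""
        q = 0
        r = self.start
        for op, n in self.cigar:
            if op in "M=X":
                for k in range(n):
                    yield q + k, r + k
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op in "DN":
                r += n
            # H and P consume nothing we track

    def copy(self) -> "AlignedRead":
        return dataclasses.replace(
            self, quals=self.quals.copy(), cigar=[tuple(x) for x in self.cigar]
        )


@dataclass
class SiteCall:
    """One candidate methylation site.

    ``i`` counts unconverted candidate bases (C in C2T space), ``j`` the
    (C + T) coverage; the methylation level is exactly ``i / j``.
    """

    ref: str
    pos: int  # 0-based
    strand: str
    i: int
    j: int
    p_value: float = float("nan")
    q_value: float = float("nan")
    gene: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.i <= self.j:
            raise ValueError("require 0 <= i <= j")

    @property
    def level(self) -> float:
        return self.i / self.j if self.j else 0.0


# Column order used by every site table emitted by the package.
SITE_COLUMNS = ["ref", "pos0", "pos1", "strand", "i", "j", "level", "p_value", "q_value"]
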