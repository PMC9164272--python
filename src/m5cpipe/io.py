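"""SAM/BAM, FASTA and FASTQ input/output.

All conversion between the package's 0-based half-open coordinates and
SAM's 1-based convention happens here (pysam already exposes 0-based
coordinates, so the mapping is direct). UMIs are carried both as a
``_<UMI>`` read-name suffix (umi-tools convention) and in the ``RX`` tag.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pysam

from .model import C2T, G2A, AlignedRead, cigar_string, revcomp

_UMI_SUFFIX = re.compile(r"_([ACGTN]+)$")


def umi_from_name(name: str) -> Optional[str]:
    m = _UMI_SUFFIX.search(name)
    return m.group(1) if m else None


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered {name: sequence} dict."""
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fastq(path: str | Path, reads: Iterable[AlignedRead]) -> None:
    """Write reads in sequencer orientation (reverse reads are flipped back)."""
    with open(path, "w") as fh:
        for r in reads:
            seq, quals = r.seq, r.quals
            if r.is_reverse:
                seq = revcomp(seq)
                quals = quals[::-1]
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.name}\n{seq}\n+\n{qstr}\n")


def _sam_header(references: dict[str, int] | dict[str, str]) -> pysam.AlignmentHeader:
    sq = []
    for name, val in references.items():
        ln = val if isinstance(val, int) else len(val)
        sq.append({"SN": name, "LN": ln})
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": sq}
    )


def to_segment(read: AlignedRead, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = read.name
    seg.reference_name = read.ref
    seg.reference_start = read.start
    seg.mapping_quality = read.mapq
    seg.cigarstring = cigar_string(read.cigar)
    seg.query_sequence = read.seq
    seg.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in read.quals)
    )
    flag = 0
    if read.is_reverse:
        flag |= 0x10
    if read.mate == "read1":
        flag |= 0x1 | 0x40 | 0x2
        flag |= 0x20  # mate reverse
    elif read.mate == "read2":
        flag |= 0x1 | 0x80 | 0x2
    seg.flag = flag
    tags = [("NM", 0), ("RX", read.umi or "")]
    if read.orientation == G2A:
        tags.append(("YO", "G2A"))
    seg.set_tags([t for t in tags if t[1] != "" or t[0] == "NM"])
    return seg


def write_sam(
    path: str | Path, reads: Iterable[AlignedRead], references: dict[str, int] | dict[str, str]
) -> None:
    header = _sam_header(references)
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as fh:
        for r in reads:
            fh.write(to_segment(r, header))


def from_segment(seg: pysam.AlignedSegment, umi_source: str = "auto") -> AlignedRead:
    """Convert a mapped pysam segment; ``umi_source`` is name|tag|auto."""
    umi = ""
    if umi_source in ("auto", "tag") and seg.has_tag("RX"):
        umi = str(seg.get_tag("RX"))
    if not umi and umi_source in ("auto", "name"):
        umi = umi_from_name(seg.query_name) or ""
    orientation = C2T
    if seg.has_tag("YO"):
        orientation = str(seg.get_tag("YO"))
    mate = "single"
    if seg.is_paired:
        mate = "read1" if seg.is_read1 else "read2"
    quals = seg.query_qualities
    return AlignedRead(
        name=seg.query_name,
        ref=seg.reference_name,
        start=seg.reference_start,
        seq=seg.query_sequence.upper(),
        quals=np.asarray(quals, dtype=np.uint8)
        if quals is not None
        else np.full(len(seg.query_sequence), 30, dtype=np.uint8),
        cigar=[("MIDNSHP=XB"[op], n) for op, n in seg.cigartuples],
        umi=umi,
        orientation=orientation,
        mate=mate,
        is_reverse=seg.is_reverse,
        mapq=seg.mapping_quality,
    )


def read_sam(path: str | Path, umi_source: str = "auto") -> tuple[list[AlignedRead], dict[str, int]]:
    """Load all mapped reads from a SAM/BAM file.

    Returns the reads and the {reference: length} map from the header.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            reads.append(from_segment(seg, umi_source))
    return reads, lengths
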