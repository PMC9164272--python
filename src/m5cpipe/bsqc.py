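"""Read-level pre-processing filters and per-base quality profiling.

The filter chain mirrors the fastp-style pre-processing used for RNA BS-seq
libraries: 3' polyX trimming (run length >= 10), a 50 bp minimum length,
two quality gates (mean Phred < 25; more than 40% of bases below Q25), a
fixed 6 bp trim from both read ends to suppress m-bias from random-primer
residues, and — for paired input — discarding fragments whose mates do not
overlap on the reference. All operations are trim-only: a retained base and
its quality are never altered.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import C2T, AlignedRead, revcomp, _CONSUMES_QUERY, _CONSUMES_REF


@dataclass
class QcConfig:
    min_length_after_trim: int = 50
    polyx_min_run: int = 10
    min_mean_q: float = 25.0
    max_lowq_fraction: float = 0.40
    lowq_threshold: int = 25
    end_trim: int = 6
    require_mate_overlap: bool = True
    min_site_base_q: int = 30

    def __post_init__(self) -> None:
        for name in ("min_length_after_trim", "polyx_min_run", "end_trim"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _trim_query_bases(read: AlignedRead, n_left: int, n_right: int) -> AlignedRead:
    """Remove query bases from the reference-left/right ends of the stored
    sequence, rewriting the cigar and advancing the mapped start as needed."""
    if n_left == 0 and n_right == 0:
        return read
    if n_left + n_right >= len(read):
        out = read.copy()
        out.seq = ""
        out.quals = np.empty(0, dtype=np.uint8)
        out.cigar = []
        out.discard_reason = out.discard_reason or "length"
        return out

    ops = [list(x) for x in read.cigar]
    start = read.start

    def eat(side_ops: list[list], n: int, left: bool) -> int:
        nonlocal start
        advance = 0
        while n > 0 and side_ops:
            op, ln = side_ops[0] if left else side_ops[-1]
            if op in "HP":
                side_ops.pop(0 if left else -1)
                continue
            if op in _CONSUMES_QUERY:
                take = min(n, ln)
                n -= take
                if op in _CONSUMES_REF:
                    advance += take
                if take == ln:
                    side_ops.pop(0 if left else -1)
                else:
                    (side_ops[0] if left else side_ops[-1])[1] = ln - take
                    # a leading/trailing D or N after a partial cut stays put
            else:  # D/N flanking the cut: consumed reference, drop it
                advance += ln
                side_ops.pop(0 if left else -1)
        return advance

    start += eat(ops, n_left, left=True)
    eat(ops, n_right, left=False)
    # strip dangling non-query ops exposed at the ends
    while ops and ops[0][0] in "DN":
        start += ops[0][1]
        ops.pop(0)
    while ops and ops[-1][0] in "DN":
        ops.pop(-1)

    out = read.copy()
    out.start = start
    out.seq = read.seq[n_left : len(read) - n_right]
    out.quals = read.quals[n_left : len(read) - n_right].copy()
    out.cigar = [(op, n) for op, n in ops]
    return out


def trim_polyx(read: AlignedRead, min_run: int = 10) -> AlignedRead:
    """Trim a 3'-terminal single-nucleotide run of length >= ``min_run``.

    The 3' end of the read is the reference-right end for forward reads and
    the reference-left end for reverse-strand reads (SAM stores sequences
    reference-forward).
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    while True:
        seq = read.seq
        if not seq:
            return read
        if read.is_reverse:
            run = len(seq) - len(seq.lstrip(seq[0]))
            if run < min_run:
                return read
            read = _trim_query_bases(read, run, 0)
        else:
            run = len(seq) - len(seq.rstrip(seq[-1]))
            if run < min_run:
                return read
            read = _trim_query_bases(read, 0, run)


def trim_fixed_ends(read: AlignedRead, n5: int = 6, n3: int = 6) -> AlignedRead:
    """Trim fixed base counts from the read's 5' and 3' ends (m-bias guard)."""
    if len(read) <= n5 + n3:
        out = read.copy()
        out.discard_reason = out.discard_reason or "length"
        return out
    if read.is_reverse:
        return _trim_query_bases(read, n3, n5)
    return _trim_query_bases(read, n5, n3)


def filter_read(read: AlignedRead, cfg: QcConfig) -> tuple[bool, Optional[str]]:
    """Keep/discard decision with the first failed rule as reason code."""
    if read.discard_reason:
        return False, read.discard_reason
    if len(read) < cfg.min_length_after_trim:
        return False, "length"
    q = read.quals.astype(np.float64)
    if q.mean() < cfg.min_mean_q:
        return False, "mean_q"
    if np.count_nonzero(read.quals < cfg.lowq_threshold) / len(read) > cfg.max_lowq_fraction:
        return False, "lowq_fraction"
    return True, None


def mates_overlap(r1: AlignedRead, r2: AlignedRead) -> bool:
    """Mates overlap when they share at least one reference base."""
    return r1.ref == r2.ref and r1.start < r2.end and r2.start < r1.end


@dataclass
class QcReport:
    n_in: int = 0
    n_out: int = 0
    discard_reasons: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "discarded": dict(self.discard_reasons),
        }


def apply_qc(
    reads: Sequence[AlignedRead], cfg: Optional[QcConfig] = None, paired: Optional[bool] = None
) -> tuple[list[AlignedRead], QcReport]:
    """Run the full chain: polyX trim -> length -> quality gates -> fixed end
    trim -> length re-check -> (paired) mate-overlap requirement.

    In paired mode a fragment survives only if both mates survive and
    overlap; reads are counted per read, not per fragment.
    """
    cfg = cfg or QcConfig()
    if paired is None:
        paired = any(r.mate != "single" for r in reads)
    report = QcReport(n_in=len(reads))

    survivors: list[AlignedRead] = []
    for read in reads:
        r = trim_polyx(read, cfg.polyx_min_run)
        keep, reason = filter_read(r, cfg)
        if keep:
            r = trim_fixed_ends(r, cfg.end_trim, cfg.end_trim)
            keep, reason = filter_read(r, cfg)
        if keep:
            survivors.append(r)
        else:
            report.discard_reasons[reason] += 1

    if paired and cfg.require_mate_overlap:
        by_name: dict[str, list[AlignedRead]] = {}
        for r in survivors:
            by_name.setdefault(r.name, []).append(r)
        kept: list[AlignedRead] = []
        for name, group in by_name.items():
            if len(group) == 2 and mates_overlap(group[0], group[1]):
                kept.extend(group)
            elif len(group) == 1 and group[0].mate == "single":
                kept.append(group[0])
            else:
                report.discard_reasons["mate_overlap"] += len(group)
        # preserve input order
        keep_ids = {id(r) for r in kept}
        survivors = [r for r in survivors if id(r) in keep_ids]

    report.n_out = len(survivors)
    return survivors, report


def quality_profile(reads: Iterable[AlignedRead]) -> pd.DataFrame:
    """Mean Phred score and base count per read position per nucleotide.

    Positions are 1-based in sequencer orientation. Returns a table with
    columns mean_A..mean_T and count_A..count_T; empty input yields an
    empty table.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    max_len = 0
    for r in reads:
        seq, quals = r.seq, r.quals
        if r.is_reverse:
            seq = revcomp(seq)
            quals = quals[::-1]
        n = len(seq)
        max_len = max(max_len, n)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for base in "ACGT":
            if base not in sums:
                sums[base] = np.zeros(0)
                counts[base] = np.zeros(0, dtype=np.int64)
            if len(sums[base]) < max_len:
                sums[base] = np.pad(sums[base], (0, max_len - len(sums[base])))
                counts[base] = np.pad(counts[base], (0, max_len - len(counts[base])))
            mask = arr == ord(base)
            idx = np.nonzero(mask)[0]
            np.add.at(sums[base], idx, quals[idx].astype(np.float64))
            np.add.at(counts[base], idx, 1)
    if max_len == 0:
        return pd.DataFrame(
            columns=["position"]
            + [f"mean_{b}" for b in "ACGT"]
            + [f"count_{b}" for b in "ACGT"]
        )
    data = {"position": np.arange(1, max_len + 1)}
    for base in "ACGT":
        s = np.pad(sums[base], (0, max_len - len(sums[base])))
        c = np.pad(counts[base], (0, max_len - len(counts[base])))
        with np.errstate(invalid="ignore"):
            data[f"mean_{base}"] = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        data[f"count_{base}"] = c
    return pd.DataFrame(data)


def candidate_base_quality(reads: Iterable[AlignedRead], stage: str = "") -> dict:
    """Mean Phred of candidate bases (C in C2T space, G in G2A space) versus
    all other bases — the per-stage asymmetry seen on real BS-seq lanes."""
    cand_sum = cand_n = other_sum = other_n = 0.0
    for r in reads:
        arr = np.frombuffer(r.seq.encode(), dtype=np.uint8)
        target = ord("C") if r.orientation == C2T else ord("G")
        mask = arr == target
        q = r.quals.astype(np.float64)
        cand_sum += q[mask].sum()
        cand_n += int(mask.sum())
        other_sum += q[~mask].sum()
        other_n += int((~mask).sum())
    return {
        "stage": stage,
        "candidate_mean_q": cand_sum / cand_n if cand_n else float("nan"),
        "other_mean_q": other_sum / other_n if other_n else float("nan"),
        "n_candidate_bases": int(cand_n),
    }
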