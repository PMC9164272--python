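"""Strand-aware methylation calling and spike-in conversion-rate estimation.

At every reference cytosine (transcript strand; guanine for reads reporting
the complementary G->A conversion space) the caller counts unconverted
candidate bases ``i`` (read C) and converted bases (read T) among bases
passing the Phred gate, emits sites with (C+T) coverage ``j`` at or above
the minimum, and attaches a one-sided binomial tail probability
P(X >= i | n=j, p=error_rate), where the error rate is calibrated from
unmethylated spike-in controls (1 - conversion rate) when controls are
present.

Bases other than C/T at a candidate position (sequencing errors, SNVs) are
excluded from ``j`` and tracked separately. Overlapping mate bases are
counted once: the higher-quality base wins, ties go to read1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import C2T, G2A, AlignedRead, SITE_COLUMNS

_C = ord("C")
_T = ord("T")
_G = ord("G")
_A = ord("A")

DEFAULT_ERROR_RATE = 1.0 - 0.999  # used only when no spike-in is available

#: per-read candidate-count histogram bins, as reported for spike-in reads
CANDIDATE_BINS = ("0", "1", "2-5", "6-20", ">20")


def binomial_pvalue(i: int, j: int, error_rate: float) -> float:
    """One-sided binomial tail P(X >= i | n=j, p=error_rate)."""
    if not 0 <= i <= j:
        raise ValueError("require 0 <= i <= j")
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must lie strictly inside (0, 1)")
    if i == 0:
        return 1.0
    return float(stats.binom.sf(i - 1, j, error_rate))


class _Counts:
    """Per-reference candidate/converted/other counters on both strands."""

    def __init__(self, reference: dict[str, str]):
        self.ref_arrays = {
            name: np.frombuffer(seq.encode(), dtype=np.uint8)
            for name, seq in reference.items()
        }
        self.is_c = {n: a == _C for n, a in self.ref_arrays.items()}
        self.is_g = {n: a == _G for n, a in self.ref_arrays.items()}
        self.c = {}  # (strand, ref) -> candidate counts
        self.t = {}
        self.other = {}

    def arrays(self, strand: str, ref: str):
        key = (strand, ref)
        if key not in self.c:
            n = len(self.ref_arrays[ref])
            self.c[key] = np.zeros(n, dtype=np.int32)
            self.t[key] = np.zeros(n, dtype=np.int32)
            self.other[key] = np.zeros(n, dtype=np.int32)
        return self.c[key], self.t[key], self.other[key]


def _accumulate_read(counts: _Counts, read: AlignedRead, min_base_q: int) -> None:
    if read.ref not in counts.ref_arrays:
        raise KeyError(
            f"read {read.name!r} is aligned to contig {read.ref!r}, "
            "which is absent from the reference"
        )
    if read.orientation == C2T:
        mask, strand, cand, conv = counts.is_c[read.ref], "+", _C, _T
    else:
        mask, strand, cand, conv = counts.is_g[read.ref], "-", _G, _A
    c_arr, t_arr, o_arr = counts.arrays(strand, read.ref)
    seq = np.frombuffer(read.seq.encode(), dtype=np.uint8)
    if read.is_simple:
        s = read.start
        offs = np.nonzero(mask[s : s + len(seq)])[0]
        if not len(offs):
            return
        b = seq[offs]
        good = read.quals[offs] >= min_base_q
        pos = s + offs
        np.add.at(c_arr, pos[good & (b == cand)], 1)
        np.add.at(t_arr, pos[good & (b == conv)], 1)
        np.add.at(o_arr, pos[good & (b != cand) & (b != conv)], 1)
    else:
        for q, p in read.aligned_pairs():
            if not mask[p] or read.quals[q] < min_base_q:
                continue
            b = seq[q]
            if b == cand:
                c_arr[p] += 1
            elif b == conv:
                t_arr[p] += 1
            else:
                o_arr[p] += 1


def _fragment_base_calls(
    mates: list[AlignedRead], mask: np.ndarray, min_base_q: int
) -> Iterable[tuple[int, int]]:
    """(position, base) per candidate position of a mate pair, overlap
    resolved once: higher base quality wins, ties go to read1."""
    best: dict[int, tuple[int, int, int]] = {}  # pos -> (qual, mate_rank, base)
    for r in mates:
        rank = 1 if r.mate != "read2" else 0
        seq = np.frombuffer(r.seq.encode(), dtype=np.uint8)
        for q, p in r.aligned_pairs():
            if not mask[p] or r.quals[q] < min_base_q:
                continue
            cur = best.get(p)
            cand = (int(r.quals[q]), rank, int(seq[q]))
            if cur is None or cand[:2] > cur[:2]:
                best[p] = cand
    for p, (_q, _rank, b) in best.items():
        yield p, b


def pileup_counts(
    reads: Sequence[AlignedRead], reference: dict[str, str], min_base_q: int = 30
) -> _Counts:
    """Accumulate candidate/converted counts over all reads.

    Paired fragments are collapsed so overlapping mate bases count once.
    """
    counts = _Counts(reference)
    paired_names: dict[str, list[AlignedRead]] = {}
    for read in reads:
        if read.mate in ("read1", "read2"):
            paired_names.setdefault(read.name, []).append(read)
        else:
            _accumulate_read(counts, read, min_base_q)
    for name, mates in paired_names.items():
        for r in mates:
            if r.ref not in counts.ref_arrays:
                raise KeyError(
                    f"read {r.name!r} is aligned to contig {r.ref!r}, "
                    "which is absent from the reference"
                )
        orientation = mates[0].orientation
        if orientation == C2T:
            mask, strand, cand, conv = counts.is_c[mates[0].ref], "+", _C, _T
        else:
            mask, strand, cand, conv = counts.is_g[mates[0].ref], "-", _G, _A
        c_arr, t_arr, o_arr = counts.arrays(strand, mates[0].ref)
        for p, b in _fragment_base_calls(mates, mask, min_base_q):
            if b == cand:
                c_arr[p] += 1
            elif b == conv:
                t_arr[p] += 1
            else:
                o_arr[p] += 1
    return counts


def sites_from_counts(
    counts: _Counts,
    min_cov: int = 10,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_level: float = 0.0,
) -> pd.DataFrame:
    """Site table from accumulated counts (0- and 1-based coordinates)."""
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must lie strictly inside (0, 1)")
    frames = []
    for (strand, ref), c_arr in sorted(counts.c.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        t_arr = counts.t[(strand, ref)]
        j = c_arr + t_arr
        keep = j >= min_cov
        pos = np.nonzero(keep)[0]
        if not len(pos):
            continue
        i = c_arr[pos].astype(np.int64)
        jj = j[pos].astype(np.int64)
        level = i / jj
        if min_level > 0:
            sel = (i == 0) | (level >= min_level)
            pos, i, jj, level = pos[sel], i[sel], jj[sel], level[sel]
        p = np.ones(len(pos))
        nz = i > 0
        p[nz] = stats.binom.sf(i[nz] - 1, jj[nz], error_rate)
        frames.append(
            pd.DataFrame(
                {
                    "ref": ref,
                    "pos0": pos,
                    "pos1": pos + 1,
                    "strand": strand,
                    "i": i,
                    "j": jj,
                    "level": level,
                    "p_value": p,
                    "q_value": float("nan"),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SITE_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["ref", "strand", "pos0"]).reset_index(drop=True)


def call_sites(
    reads: Sequence[AlignedRead],
    reference: dict[str, str],
    min_base_q: int = 30,
    min_cov: int = 10,
    error_rate: Optional[float] = None,
    control_ids: Optional[Sequence[str]] = None,
    min_level: float = 0.0,
) -> pd.DataFrame:
    """Call candidate methylation sites from QC'd, deduplicated reads.

    When ``error_rate`` is not given and spike-in controls are named, it is
    calibrated as 1 minus the pooled control conversion rate.
    """
    if error_rate is None:
        error_rate = DEFAULT_ERROR_RATE
        if control_ids:
            cs = conversion_rate(reads, reference, control_ids)
            if cs is not None and cs.total_c_positions > 0:
                error_rate = max(1.0 - cs.rate, 1e-6)
    counts = pileup_counts(reads, reference, min_base_q)
    return sites_from_counts(counts, min_cov, error_rate, min_level)


def read_candidate_count(read: AlignedRead, reference: dict[str, str]) -> int:
    """Number of unconverted candidate bases carried by one read (its
    'p-m5C content'): read C at reference C in C2T space, read G at
    reference G in G2A space. No quality gate — this measures the molecule."""
    _check = reference.get(read.ref)
    if _check is None:
        raise KeyError(f"contig {read.ref!r} absent from reference")
    ref_arr = np.frombuffer(_check.encode(), dtype=np.uint8)
    target = _C if read.orientation == C2T else _G
    seq = np.frombuffer(read.seq.encode(), dtype=np.uint8)
    if read.is_simple:
        s = read.start
        span = ref_arr[s : s + len(seq)]
        return int(np.count_nonzero((span == target) & (seq == target)))
    n = 0
    for q, p in read.aligned_pairs():
        if ref_arr[p] == target and seq[q] == target:
            n += 1
    return n


@dataclass
class ConversionStats:
    """Bisulfite conversion statistics over unmethylated spike-in controls."""

    per_control: pd.DataFrame  # ref, converted, total, rate
    converted: int
    total_c_positions: int
    zero_candidate_fraction: float
    candidate_histogram: dict[str, int]
    n_reads: int

    @property
    def rate(self) -> float:
        return self.converted / self.total_c_positions if self.total_c_positions else float("nan")


def _candidate_bin(n: int) -> str:
    if n == 0:
        return "0"
    if n == 1:
        return "1"
    if n <= 5:
        return "2-5"
    if n <= 20:
        return "6-20"
    return ">20"


def conversion_rate(
    reads: Sequence[AlignedRead],
    reference: dict[str, str],
    control_ids: Sequence[str],
    min_base_q: int = 0,
) -> Optional[ConversionStats]:
    """Estimate the conversion rate from reads on unmethylated controls.

    rate = T / (C + T) over reference-C positions of control-mapped reads.
    Also reports the fraction of control reads free of candidate bases and
    the per-read candidate-count histogram. Returns None (with a warning)
    when no control reads exist.
    """
    control_set = set(control_ids)
    per: dict[str, list[int]] = {}
    hist = {b: 0 for b in CANDIDATE_BINS}
    n_reads = 0
    n_zero = 0
    for read in reads:
        if read.ref not in control_set:
            continue
        ref_seq = reference[read.ref]
        ref_arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
        target = _C if read.orientation == C2T else _G
        conv = _T if read.orientation == C2T else _A
        seq = np.frombuffer(read.seq.encode(), dtype=np.uint8)
        if read.is_simple:
            s = read.start
            span = ref_arr[s : s + len(seq)]
            sel = (span == target) & (read.quals >= min_base_q)
            n_cand = int(np.count_nonzero(sel & (seq == target)))
            n_conv = int(np.count_nonzero(sel & (seq == conv)))
        else:
            n_cand = n_conv = 0
            for q, p in read.aligned_pairs():
                if ref_arr[p] != target or read.quals[q] < min_base_q:
                    continue
                if seq[q] == target:
                    n_cand += 1
                elif seq[q] == conv:
                    n_conv += 1
        n_reads += 1
        if n_cand == 0:
            n_zero += 1
        hist[_candidate_bin(n_cand)] += 1
        acc = per.setdefault(read.ref, [0, 0])
        acc[0] += n_conv
        acc[1] += n_cand + n_conv
    if n_reads == 0:
        import warnings

        warnings.warn("no reads mapped to spike-in controls; conversion rate undefined")
        return None
    rows = [
        {"ref": ref, "converted": c, "total": t, "rate": c / t if t else float("nan")}
        for ref, (c, t) in sorted(per.items())
    ]
    per_df = pd.DataFrame(rows)
    return ConversionStats(
        per_control=per_df,
        converted=int(per_df["converted"].sum()),
        total_c_positions=int(per_df["total"].sum()),
        zero_candidate_fraction=n_zero / n_reads,
        candidate_histogram=hist,
        n_reads=n_reads,
    )
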