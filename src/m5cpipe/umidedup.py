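"""UMI grouping, most-prevalent-sequence deduplication, and discordance.

Reads mapped to the same reference coordinate on the same strand that carry
an identical UMI are treated as PCR amplicons of one template molecule.
Deduplication keeps the most prevalent member sequence of each group (PCR
copies may differ through PCR error). Discordance — member reads of a group
disagreeing at an aligned position — is the pipeline's direct readout of
PCR and sequencing error, and is reported per nucleotide class and for
candidate (p-m5C) positions specifically.

Grouping is exact-match on the UMI string: no edit-distance clustering.
Paired mates are grouped as one fragment keyed on the read1 coordinate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import C2T, AlignedRead

GroupKey = tuple[str, int, bool, str]  # (reference, start, is_reverse, UMI)


@dataclass
class UmiGroup:
    key: GroupKey
    members: list[AlignedRead] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.members)

    def consensus(self) -> AlignedRead:
        """The retained read: most prevalent sequence; ties broken by higher
        summed base quality, then lexicographically smaller sequence."""
        if self.depth == 1:
            return self.members[0]
        freq = Counter(r.seq for r in self.members)
        best_count = max(freq.values())
        tied = [s for s, c in freq.items() if c == best_count]
        if len(tied) == 1:
            winner_seq = tied[0]
        else:
            qual = {
                s: max(int(r.quals.sum()) for r in self.members if r.seq == s) for s in tied
            }
            best_q = max(qual.values())
            winner_seq = min(s for s in tied if qual[s] == best_q)
        candidates = [r for r in self.members if r.seq == winner_seq]
        return max(candidates, key=lambda r: (int(r.quals.sum()), r.name))

    def discordant_positions(self) -> list[tuple[int, Counter]]:
        """Reference positions where members report more than one base,
        compared over the aligned span shared by at least two members."""
        if self.depth < 2:
            return []
        per_pos: dict[int, Counter] = {}
        for r in self.members:
            arr = r.seq
            for q, p in r.aligned_pairs():
                per_pos.setdefault(p, Counter())[arr[q]] += 1
        out = []
        for p in sorted(per_pos):
            bases = per_pos[p]
            if sum(bases.values()) >= 2 and len(bases) > 1:
                out.append((p, bases))
        return out


@dataclass
class DiscordanceReport:
    n_groups: int
    n_discordant_groups: int
    per_nucleotide: dict[str, float]  # discordance ratio per base class
    depth_histogram: dict[int, int]
    candidate_base_frequencies: dict[str, int]  # bases seen at discordant p-m5C positions

    @property
    def discordance_ratio(self) -> float:
        return self.n_discordant_groups / self.n_groups if self.n_groups else float("nan")

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": f"ratio_{b}", "value": v} for b, v in sorted(self.per_nucleotide.items())
        ]
        rows.append({"metric": "ratio_any", "value": self.discordance_ratio})
        return pd.DataFrame(rows)


def group_by_umi(
    reads: Sequence[AlignedRead], regions: Optional[set[str]] = None
) -> tuple[list[UmiGroup], int]:
    """Partition reads into UMI groups keyed on (ref, start, strand, UMI).

    Paired mates are keyed by their fragment: the read1 coordinate defines
    the group for both mates. Reads without a UMI are rejected (counted and
    skipped). ``regions`` optionally restricts grouping to given references
    (e.g. spike-in controls only, as done for error-rate estimation).
    Returns (groups, n_rejected_missing_umi).
    """
    frag_anchor: dict[str, tuple[str, int, bool]] = {}
    for r in reads:
        if r.mate == "read1":
            frag_anchor[r.name] = (r.ref, r.start, r.is_reverse)
    groups: dict[GroupKey, UmiGroup] = {}
    missing = 0
    for r in reads:
        if regions is not None and r.ref not in regions:
            continue
        if not r.umi:
            missing += 1
            continue
        anchor = frag_anchor.get(r.name, (r.ref, r.start, r.is_reverse))
        key = (anchor[0], anchor[1], anchor[2], r.umi)
        groups.setdefault(key, UmiGroup(key)).members.append(r)
    return [groups[k] for k in sorted(groups)], missing


def dedup(groups: Iterable[UmiGroup]) -> tuple[list[AlignedRead], float]:
    """One retained read per group; duplication rate = 1 - groups/reads."""
    retained: list[AlignedRead] = []
    n_reads = 0
    for g in groups:
        n_reads += g.depth
        retained.append(g.consensus())
    rate = 1.0 - len(retained) / n_reads if n_reads else 0.0
    return retained, rate


def discordance(
    groups: Sequence[UmiGroup], candidate_orientation: str = C2T
) -> DiscordanceReport:
    """Within-group base disagreement statistics.

    The per-nucleotide ratio counts groups with at least one discordant
    position at which that base was observed, over all groups (depth-1
    groups count as concordant). For discordant positions where at least
    one member reports the candidate base (C in C2T space), the full
    nucleotide frequency vector across members is accumulated.
    """
    candidate_base = "C" if candidate_orientation == C2T else "G"
    per_nt_groups: Counter = Counter()
    cand_freq: Counter = Counter()
    depth_hist: Counter = Counter()
    n_disc = 0
    for g in groups:
        depth_hist[g.depth] += 1
        disc = g.discordant_positions()
        if not disc:
            continue
        n_disc += 1
        bases_seen: set[str] = set()
        for _pos, bases in disc:
            bases_seen.update(bases)
            if candidate_base in bases:
                cand_freq.update(bases)
        for b in bases_seen:
            per_nt_groups[b] += 1
    n_groups = len(groups)
    per_nt = {
        b: (per_nt_groups[b] / n_groups if n_groups else float("nan")) for b in "ACGT"
    }
    return DiscordanceReport(
        n_groups=n_groups,
        n_discordant_groups=n_disc,
        per_nucleotide=per_nt,
        depth_histogram=dict(sorted(depth_hist.items())),
        candidate_base_frequencies={b: cand_freq.get(b, 0) for b in "ACGT"},
    )
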