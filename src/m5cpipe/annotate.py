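"""Gene annotation of sites, metagene distribution, motif profiling,
expression (CPM) comparison and cross-library statistics.

The GTF reader understands the Ensembl attribute dialect
(``gene_id "X"; transcript_id "Y";``). When a transcript lacks explicit UTR
features they are derived as exon-minus-CDS. The metagene projection maps
every annotated mRNA onto 20 bins: 5'UTR -> bins 1-5, CDS -> bins 6-17,
3'UTR -> bins 18-20, each region scaled proportionally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AlignedRead
from .sitefilter import SITE_KEY, bh_fdr

_ATTR = re.compile(r'(\w+) "([^"]*)"')


@dataclass
class GeneModel:
    """One transcript's intervals (0-based half-open, sorted)."""

    gene_id: str
    transcript_id: str
    ref: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def _region_len(self, region: str) -> int:
        return sum(e - s for s, e in getattr(self, region))

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)


def _merge_sorted(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval set difference a \\ b, both sorted half-open."""
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
        if cur < e:
            out.append((cur, e))
    return out


def parse_gtf(path) -> list[GeneModel]:
    """Parse an Ensembl-style GTF into transcript models.

    UTRs are taken from five_prime_utr/three_prime_utr (or UTR) records when
    present, otherwise derived as exon minus CDS, split by CDS side with
    strand taken into account.
    """
    tx: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            ref, feature, start, end, strand, attrs = f[0], f[2], int(f[3]), int(f[4]), f[6], f[8]
            a = dict(_ATTR.findall(attrs))
            tid = a.get("transcript_id")
            if tid is None:
                continue
            if tid not in tx:
                tx[tid] = GeneModel(a.get("gene_id", tid), tid, ref, strand)
            m = tx[tid]
            iv = (start - 1, end)  # GTF is 1-based inclusive
            if feature == "exon":
                m.exons.append(iv)
            elif feature == "CDS":
                m.cds.append(iv)
            elif feature in ("five_prime_utr", "5UTR"):
                m.utr5.append(iv)
            elif feature in ("three_prime_utr", "3UTR"):
                m.utr3.append(iv)
    models = list(tx.values())
    if not any(m.exons for m in models):
        raise ValueError("GTF contains no exon records")
    for m in models:
        m.exons = _merge_sorted(m.exons)
        m.cds = _merge_sorted(m.cds)
        m.utr5 = _merge_sorted(m.utr5)
        m.utr3 = _merge_sorted(m.utr3)
        if m.cds and not (m.utr5 or m.utr3):
            non_cds = _subtract(m.exons, m.cds)
            cds_start, cds_end = m.cds[0][0], m.cds[-1][1]
            left = [iv for iv in non_cds if iv[1] <= cds_start]
            right = [iv for iv in non_cds if iv[0] >= cds_end]
            if m.strand == "+":
                m.utr5, m.utr3 = left, right
            else:
                m.utr5, m.utr3 = right, left
    return models


def annotate_sites(sites: pd.DataFrame, models: Sequence[GeneModel]) -> pd.DataFrame:
    """Label each site with its gene and feature class.

    Feature classes: 5UTR, CDS, 3UTR, exon_noncoding, intergenic. When a
    site overlaps several genes, the transcript with the longest CDS wins;
    every overlapping gene is recorded in ``all_genes``.
    """
    by_ref: dict[str, list[GeneModel]] = {}
    for m in models:
        by_ref.setdefault(m.ref, []).append(m)
    genes, features, all_genes = [], [], []
    for row in sites.itertuples(index=False):
        hits = [m for m in by_ref.get(row.ref, []) if m.contains(row.pos0)]
        if not hits:
            genes.append("")
            features.append("intergenic")
            all_genes.append("")
            continue
        best = max(hits, key=lambda m: (m.cds_length, m.transcript_id))
        pos = row.pos0
        if any(s <= pos < e for s, e in best.utr5):
            feat = "5UTR"
        elif any(s <= pos < e for s, e in best.cds):
            feat = "CDS"
        elif any(s <= pos < e for s, e in best.utr3):
            feat = "3UTR"
        else:
            feat = "exon_noncoding"
        genes.append(best.gene_id)
        features.append(feat)
        all_genes.append(",".join(sorted({m.gene_id for m in hits})))
    out = sites.copy()
    out["gene"] = genes
    out["feature"] = features
    out["all_genes"] = all_genes
    return out


#: metagene layout: region -> (first bin, number of bins), 1-based bins
METAGENE_LAYOUT = {"utr5": (1, 5), "cds": (6, 12), "utr3": (18, 3)}
N_METAGENE_BINS = 20


def _region_position(m: GeneModel, region: str, pos: int) -> Optional[float]:
    """Fractional position of ``pos`` within a (possibly split) region, in
    genomic-forward direction; None when the position is outside. The
    caller flips the fraction for minus-strand transcripts."""
    intervals = getattr(m, region)
    total = sum(e - s for s, e in intervals)
    if total == 0:
        return None
    offset = 0
    for s, e in intervals:
        if s <= pos < e:
            return (offset + (pos - s)) / total
        offset += e - s
    return None


def metagene(
    sites: pd.DataFrame, models: Sequence[GeneModel], n_bins: int = N_METAGENE_BINS
) -> tuple[np.ndarray, int]:
    """Binned site density along a scaled mRNA model.

    Returns (density over bins 1..n_bins normalised to sum 1, n_skipped).
    Sites on transcripts missing any of the three regions are skipped.
    Only the canonical 20-bin layout is supported.
    """
    if n_bins != N_METAGENE_BINS:
        raise ValueError("the metagene layout is defined for 20 bins")
    by_ref: dict[str, list[GeneModel]] = {}
    for m in models:
        by_ref.setdefault(m.ref, []).append(m)
    counts = np.zeros(n_bins)
    skipped = 0
    for row in sites.itertuples(index=False):
        hits = [m for m in by_ref.get(row.ref, []) if m.contains(row.pos0)]
        hits = [m for m in hits if m.utr5 and m.cds and m.utr3]
        if not hits:
            skipped += 1
            continue
        m = max(hits, key=lambda x: (x.cds_length, x.transcript_id))
        placed = False
        for region, (first, width) in METAGENE_LAYOUT.items():
            frac = _region_position(m, region, row.pos0)
            if frac is None:
                continue
            if m.strand == "-":
                frac = 1.0 - frac - 1e-12
            b = first + min(int(frac * width), width - 1)
            counts[b - 1] += 1
            placed = True
            break
        if not placed:
            skipped += 1
    total = counts.sum()
    density = counts / total if total else counts
    return density, skipped


def motif_matrix(
    sites: pd.DataFrame, reference: Mapping[str, str], flank: int = 10
) -> tuple[pd.DataFrame, float]:
    """Positional nucleotide frequencies around sites, center fixed to C.

    Returns (matrix with rows offset -flank..+flank and columns A/C/G/T,
    downstream-GGG enrichment score). The score is the mean G frequency at
    offsets +1..+3 over the mean G frequency at all other non-center
    offsets. Sites whose flank would leave the reference are skipped.
    """
    counts = np.zeros((2 * flank + 1, 4))
    base_index = {b: k for k, b in enumerate("ACGT")}
    for row in sites.itertuples(index=False):
        seq = reference[row.ref]
        p = row.pos0
        if p - flank < 0 or p + flank >= len(seq):
            continue
        window = seq[p - flank : p + flank + 1]
        for k, b in enumerate(window):
            if b in base_index:
                counts[k, base_index[b]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
    mat = pd.DataFrame(freqs, columns=list("ACGT"))
    mat.insert(0, "offset", np.arange(-flank, flank + 1))
    g = mat.set_index("offset")["G"]
    downstream = g.loc[1:3].mean()
    bg_offsets = [o for o in mat["offset"] if o != 0 and not 1 <= o <= 3]
    background = g.loc[bg_offsets].mean()
    score = float(downstream / background) if background and background > 0 else float("nan")
    return mat, score


def gene_cpm(
    reads: Sequence[AlignedRead],
    models: Sequence[GeneModel],
    ignore_strand: bool = True,
) -> pd.DataFrame:
    """Per-gene read counts and CPM (union-exon, unique-gene assignment).

    A read is assigned when its aligned span overlaps the exon union of
    exactly one gene; reads hitting zero or more than one gene are left
    unassigned. CPM normalises to assigned reads, so CPM sums to 1e6.
    """
    exon_union: dict[str, dict[str, list[tuple[int, int]]]] = {}
    strand_of: dict[str, str] = {}
    for m in models:
        g = exon_union.setdefault(m.gene_id, {})
        g.setdefault(m.ref, []).extend(m.exons)
        strand_of[m.gene_id] = m.strand
    for g in exon_union.values():
        for ref in g:
            g[ref] = _merge_sorted(g[ref])
    counts = {g: 0 for g in exon_union}
    seen_fragments: set[str] = set()
    for r in reads:
        if r.mate == "read2" and r.name in seen_fragments:
            continue
        if r.mate in ("read1", "read2"):
            seen_fragments.add(r.name)
        hit_genes = set()
        for gid, per_ref in exon_union.items():
            if not ignore_strand:
                want = "-" if r.is_reverse else "+"
                if strand_of[gid] != want:
                    continue
            for s, e in per_ref.get(r.ref, []):
                if r.start < e and r.end > s:
                    hit_genes.add(gid)
                    break
        if len(hit_genes) == 1:
            counts[hit_genes.pop()] += 1
    total = sum(counts.values())
    rows = [
        {
            "gene": g,
            "count": n,
            "cpm": n * 1e6 / total if total else float("nan"),
        }
        for g, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def cpm_with_without_dedup(
    reads_all: Sequence[AlignedRead],
    reads_dedup: Sequence[AlignedRead],
    models: Sequence[GeneModel],
) -> pd.DataFrame:
    """Paired CPM tables before/after UMI deduplication with log2 fold change."""
    a = gene_cpm(reads_all, models).rename(columns={"count": "count_all", "cpm": "cpm_all"})
    b = gene_cpm(reads_dedup, models).rename(
        columns={"count": "count_dedup", "cpm": "cpm_dedup"}
    )
    out = a.merge(b, on="gene", how="outer").fillna(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2fc"] = np.log2(out["cpm_dedup"] / out["cpm_all"])
    return out


def compare_libraries(
    sites_a: pd.DataFrame, sites_b: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Cross-library comparison over shared sites.

    Per shared site a two-sided Fisher exact test on the 2x2 table
    [[i_a, j_a - i_a], [i_b, j_b - i_b]] (BH-adjusted; differential at
    q <= alpha); Spearman correlation and a Wilcoxon rank-sum test over
    the shared methylation-level vectors.
    """
    import warnings

    shared = sites_a.merge(sites_b, on=SITE_KEY, suffixes=("_a", "_b"))
    if not len(shared):
        warnings.warn("no shared sites between the two libraries")
        return shared, {
            "n_shared": 0,
            "spearman_rho": float("nan"),
            "wilcoxon_p": float("nan"),
            "n_dms": 0,
        }
    pvals = []
    for row in shared.itertuples(index=False):
        table = [
            [int(row.i_a), int(row.j_a - row.i_a)],
            [int(row.i_b), int(row.j_b - row.i_b)],
        ]
        pvals.append(stats.fisher_exact(table, alternative="two-sided")[1])
    shared = shared.assign(fisher_p=pvals)
    q, passed = bh_fdr(np.asarray(pvals), alpha)
    shared["fisher_q"] = q
    shared["is_dms"] = passed
    la, lb = shared["level_a"].to_numpy(), shared["level_b"].to_numpy()
    if len(shared) > 1 and (np.std(la) > 0 or np.std(lb) > 0):
        rho = float(stats.spearmanr(la, lb).statistic)
    else:
        rho = float("nan")
    wil = float(stats.ranksums(la, lb).pvalue)
    summary = {
        "n_shared": int(len(shared)),
        "spearman_rho": rho,
        "wilcoxon_p": wil,
        "n_dms": int(passed.sum()),
    }
    return shared, summary
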