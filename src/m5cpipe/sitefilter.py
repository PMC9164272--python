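"""The multi-level high-confidence filter cascade.

Candidate sites called at >=10x coverage pass, in order:

1. **standard filter** — i >= 3 candidate counts, j >= 20 (C+T) coverage,
   level i/j >= 0.1 (all boundaries inclusive);
2. **C-cutoff + signal/noise** — reads carrying more than k unconverted
   candidate bases are treated as incomplete-conversion artifacts and
   removed; k is the smallest cutoff whose Gini coefficient over
   sites-per-gene drops to <= 0.15; a site is kept when its candidate count
   after the cutoff is >= 0.9 of its count before;
3. **structure regions** — sites inside externally predicted
   conversion-resistant regions are removed (half-open intervals);
4. **FDR** — Benjamini–Hochberg over the binomial p-values of surviving
   sites (recomputed from post-cutoff counts), pass at q <= 0.05;
5. **replicates** — a high-confidence site passes every filter in at least
   one replicate and shows i >= 1 with j >= 10 after the C-cutoff in at
   least one other replicate.

Each step is a pure set reduction; the attrition report tracks the
percentage of the starting set surviving each stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import AlignedRead
from .pileup import (
    DEFAULT_ERROR_RATE,
    _Counts,
    pileup_counts,
    read_candidate_count,
    sites_from_counts,
)

#: number of unconverted candidate bases carried by a read
read_c_content = read_candidate_count

SITE_KEY = ["ref", "pos0", "strand"]


@dataclass
class FilterConfig:
    min_i: int = 3
    min_j: int = 20
    min_level: float = 0.1
    gini_threshold: float = 0.15
    c_cutoff_range: tuple[int, int] = (1, 30)
    sn_min: float = 0.9
    fdr_alpha: float = 0.05
    resistant_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    replicate_min_count: int = 1
    replicate_min_cov: int = 10
    min_base_q: int = 30
    min_cov: int = 10

    def __post_init__(self) -> None:
        if self.min_i <= 0 or self.min_j <= 0 or self.min_level <= 0:
            raise ValueError("standard-filter thresholds must be positive")
        lo, hi = self.c_cutoff_range
        if lo > hi:
            raise ValueError("c_cutoff_range must be ascending and non-empty")

    @property
    def cutoffs(self) -> range:
        return range(self.c_cutoff_range[0], self.c_cutoff_range[1] + 1)


def standard_filter(sites: pd.DataFrame, cfg: Optional[FilterConfig] = None) -> pd.DataFrame:
    """Keep sites with i >= min_i, j >= min_j and level >= min_level."""
    cfg = cfg or FilterConfig()
    keep = (
        (sites["i"] >= cfg.min_i)
        & (sites["j"] >= cfg.min_j)
        & (sites["level"] >= cfg.min_level)
    )
    return sites[keep].reset_index(drop=True)


def gini(values: Sequence[float]) -> float:
    """Population Gini coefficient, G = sum_ab |x_a - x_b| / (2 n^2 mean).

    Computed via the sorted-rank identity (O(n log n)), equal to the
    pairwise double sum. Values must be positive counts.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("gini of an empty vector is undefined")
    if np.any(x <= 0):
        raise ValueError("gini requires strictly positive values")
    x = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float((2.0 * np.sum(ranks * x)) / (n * np.sum(x)) - (n + 1) / n)


@dataclass
class CutoffScan:
    """Per-cutoff Gini scan over sites-per-gene, plus the chosen cutoff."""

    table: pd.DataFrame  # cutoff, gini, n_genes, n_sites, n_reads
    chosen_k: int
    threshold: float


GeneOf = Callable[[str, int], Optional[str]]


def transcript_gene_map(reference_names: Sequence[str]) -> GeneOf:
    """Trivial mapper for transcriptome-space alignments: gene == contig."""
    names = set(reference_names)
    return lambda ref, pos: ref if ref in names else None


def select_c_cutoff(
    reads: Sequence[AlignedRead],
    reference: dict[str, str],
    gene_of: GeneOf,
    cfg: Optional[FilterConfig] = None,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> CutoffScan:
    """Scan C-cutoffs and pick the smallest whose Gini over candidate
    sites-per-gene is at or below the threshold.

    At cutoff k, reads whose unconverted-candidate content exceeds k are
    dropped and sites (i >= 1, j >= min_cov) re-called from the remainder.
    Reads are added incrementally in order of content so the whole scan is
    a single pileup pass. If no cutoff reaches the threshold, the maximum
    of the range is chosen with a warning.
    """
    cfg = cfg or FilterConfig()
    contents = np.array([read_candidate_count(r, reference) for r in reads])
    order = np.argsort(contents, kind="stable")
    counts = _Counts(reference)
    from .pileup import _accumulate_read

    rows = []
    ptr = 0
    n_reads_total = len(reads)
    for k in cfg.cutoffs:
        while ptr < n_reads_total and contents[order[ptr]] <= k:
            _accumulate_read(counts, reads[order[ptr]], cfg.min_base_q)
            ptr += 1
        per_gene: dict[str, int] = {}
        n_sites = 0
        for (strand, ref), c_arr in counts.c.items():
            j = c_arr + counts.t[(strand, ref)]
            site_pos = np.nonzero((j >= cfg.min_cov) & (c_arr >= 1))[0]
            n_sites += len(site_pos)
            for p in site_pos:
                g = gene_of(ref, int(p))
                if g is not None:
                    per_gene[g] = per_gene.get(g, 0) + 1
        g_val = gini(list(per_gene.values())) if per_gene else float("nan")
        rows.append(
            {
                "cutoff": k,
                "gini": g_val,
                "n_genes": len(per_gene),
                "n_sites": n_sites,
                "n_reads": int(ptr),
            }
        )
    table = pd.DataFrame(rows)
    if not len(table) or table["n_sites"].max() == 0:
        raise ValueError("no candidate sites on any gene at any C-cutoff")
    # The Gini coefficient falls as the cutoff tightens (artifact-bearing
    # reads concentrate candidate sites on few genes). Pick the least
    # stringent cutoff that still achieves an even site distribution, so no
    # read is discarded without cause; if even the strictest cutoff leaves
    # Gini above threshold, fall back to the strictest with a warning.
    ok = table[table["gini"] <= cfg.gini_threshold]
    if len(ok):
        chosen = int(ok["cutoff"].iloc[-1])
    else:
        chosen = int(table["cutoff"].iloc[0])
        warnings.warn(
            f"no C-cutoff reached Gini <= {cfg.gini_threshold}; falling back "
            f"to the strictest cutoff of the range ({chosen})"
        )
    return CutoffScan(table=table, chosen_k=chosen, threshold=cfg.gini_threshold)


def apply_c_cutoff(
    reads: Sequence[AlignedRead], reference: dict[str, str], k: int
) -> list[AlignedRead]:
    """Drop reads whose unconverted-candidate content exceeds k."""
    return [r for r in reads if read_candidate_count(r, reference) <= k]


def signal_noise(
    before: pd.DataFrame, after: pd.DataFrame, sn_min: float = 0.9
) -> pd.DataFrame:
    """Per-site ratio of candidate counts after/before the C-cutoff.

    Sites absent from ``after`` (or with before-count 0) get ratio 0.
    Returns ``before`` with ``sn_ratio`` and ``sn_pass`` columns appended.
    """
    merged = before.merge(
        after[SITE_KEY + ["i", "j", "level", "p_value"]].rename(
            columns={
                "i": "i_after",
                "j": "j_after",
                "level": "level_after",
                "p_value": "p_after",
            }
        ),
        on=SITE_KEY,
        how="left",
    )
    merged["i_after"] = merged["i_after"].fillna(0).astype(int)
    merged["j_after"] = merged["j_after"].fillna(0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(merged["i"] > 0, merged["i_after"] / merged["i"], 0.0)
    merged["sn_ratio"] = ratio
    merged["sn_pass"] = merged["sn_ratio"] >= sn_min
    return merged


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment.

    Returns (q_values, pass_mask) in the input order; pass at q <= alpha.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= alpha


def region_filter(
    sites: pd.DataFrame, resistant_regions: Mapping[str, Sequence[tuple[int, int]]]
) -> pd.DataFrame:
    """Remove sites inside conversion-resistant regions (half-open)."""
    for ref, intervals in resistant_regions.items():
        for s, e in intervals:
            if e <= s:
                raise ValueError(f"malformed interval [{s}, {e}) on {ref}")
    if not len(sites) or not resistant_regions:
        return sites.reset_index(drop=True)
    drop = np.zeros(len(sites), dtype=bool)
    pos = sites["pos0"].to_numpy()
    refs = sites["ref"].to_numpy()
    for ref, intervals in resistant_regions.items():
        on_ref = refs == ref
        for s, e in intervals:
            drop |= on_ref & (pos >= s) & (pos < e)
    return sites[~drop].reset_index(drop=True)


def load_bed_regions(path) -> dict[str, list[tuple[int, int]]]:
    """Parse a BED3+ file into {ref: [(start, end), ...]} (0-based half-open)."""
    regions: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            regions.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return regions


def replicate_concordance(
    passing: Mapping[str, pd.DataFrame],
    post_cutoff: Mapping[str, pd.DataFrame],
    cfg: Optional[FilterConfig] = None,
) -> pd.DataFrame:
    """High-confidence site set across biological replicates.

    ``passing`` maps replicate name -> sites surviving all single-library
    filters; ``post_cutoff`` maps replicate -> the full post-C-cutoff site
    table. A site is retained when it passes everything in one replicate
    and shows i >= replicate_min_count with j >= replicate_min_cov after
    the C-cutoff in at least one *different* replicate.
    """
    cfg = cfg or FilterConfig()
    if len(passing) < 2:
        raise ValueError("replicate concordance needs at least two replicates")
    support: dict[tuple, set[str]] = {}
    pooled: dict[tuple, list[int]] = {}
    for rep, table in post_cutoff.items():
        ok = table[
            (table["i"] >= cfg.replicate_min_count) & (table["j"] >= cfg.replicate_min_cov)
        ]
        for key in zip(ok["ref"], ok["pos0"], ok["strand"]):
            support.setdefault(key, set()).add(rep)
        for key, i, j in zip(
            zip(table["ref"], table["pos0"], table["strand"]), table["i"], table["j"]
        ):
            acc = pooled.setdefault(key, [0, 0])
            acc[0] += int(i)
            acc[1] += int(j)
    rows = []
    seen: set[tuple] = set()
    for rep, table in passing.items():
        for row in table.itertuples(index=False):
            key = (row.ref, row.pos0, row.strand)
            others = support.get(key, set()) - {rep}
            if others and key not in seen:
                seen.add(key)
                d = row._asdict()
                d["passed_in"] = rep
                d["supported_in"] = ",".join(sorted(others))
                # the reported level pools post-cutoff counts over replicates
                i_sum, j_sum = pooled.get(key, (0, 0))
                d["i_pooled"], d["j_pooled"] = i_sum, j_sum
                d["level_pooled"] = i_sum / j_sum if j_sum else float("nan")
                rows.append(d)
    if not rows:
        return pd.DataFrame(
            columns=list(next(iter(passing.values())).columns)
            + ["passed_in", "supported_in", "i_pooled", "j_pooled", "level_pooled"]
        )
    return (
        pd.DataFrame(rows).sort_values(["ref", "pos0", "strand"]).reset_index(drop=True)
    )


def attrition_report(stages: Mapping[str, int]) -> pd.DataFrame:
    """Percentage of the starting site set remaining after each stage."""
    items = list(stages.items())
    if not items:
        return pd.DataFrame(columns=["stage", "n_sites", "pct_remaining"])
    base = items[0][1]
    rows = [
        {
            "stage": name,
            "n_sites": n,
            "pct_remaining": 100.0 * n / base if base else float("nan"),
        }
        for name, n in items
    ]
    return pd.DataFrame(rows)


@dataclass
class FilterResult:
    """Everything produced by one library's pass through the cascade."""

    sites_start: pd.DataFrame
    sites_standard: pd.DataFrame
    scan: CutoffScan
    post_cutoff_sites: pd.DataFrame
    sites_sn: pd.DataFrame
    sites_region: pd.DataFrame
    sites_final: pd.DataFrame
    attrition: pd.DataFrame
    error_rate: float


def run_filter_cascade(
    reads: Sequence[AlignedRead],
    reference: dict[str, str],
    gene_of: GeneOf,
    cfg: Optional[FilterConfig] = None,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> FilterResult:
    """Single-library cascade: call -> standard -> C-cutoff/signal-noise ->
    regions -> FDR. ``reads`` must already be QC'd and deduplicated."""
    cfg = cfg or FilterConfig()
    counts = pileup_counts(reads, reference, cfg.min_base_q)
    called = sites_from_counts(counts, cfg.min_cov, error_rate)
    # the starting set: candidate (i >= 1) sites at >= min_cov coverage
    start = called[called["i"] >= 1].reset_index(drop=True)
    standard = standard_filter(start, cfg)

    scan = select_c_cutoff(reads, reference, gene_of, cfg, error_rate)
    kept_reads = apply_c_cutoff(reads, reference, scan.chosen_k)
    post = sites_from_counts(
        pileup_counts(kept_reads, reference, cfg.min_base_q), 1, error_rate
    )
    sn = signal_noise(standard, post, cfg.sn_min)
    sn_kept = sn[sn["sn_pass"]].reset_index(drop=True)

    region_kept = region_filter(sn_kept, cfg.resistant_regions)

    if len(region_kept):
        q, passed = bh_fdr(region_kept["p_after"].fillna(1.0).to_numpy(), cfg.fdr_alpha)
        region_kept = region_kept.assign(q_value=q)
        final = region_kept[passed].reset_index(drop=True)
    else:
        final = region_kept

    attr = attrition_report(
        {
            "called_10x": len(start),
            "standard_filter": len(standard),
            "c_cutoff_signal_noise": len(sn_kept),
            "structure_regions": len(region_kept),
            "fdr": len(final),
        }
    )
    return FilterResult(
        sites_start=start,
        sites_standard=standard,
        scan=scan,
        post_cutoff_sites=post,
        sites_sn=sn_kept,
        sites_region=region_kept,
        sites_final=final,
        attrition=attr,
        error_rate=error_rate,
    )
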