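"""End-to-end orchestration: simulate -> qc -> dedup -> call -> filter ->
replicate concordance -> report.

A run is described by a :class:`RunManifest`: either per-replicate SAM/BAM
paths plus a reference FASTA, or a simulator configuration from which
``n_replicates`` libraries are generated sharing one reference and one
planted truth (replicates of the same biological sample differ only in
read-level randomness). Results land in one output directory with
per-stage TSVs per replicate and a machine-readable ``summary.json``.
Given the same manifest and seed, a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io
from .bsqc import QcConfig, apply_qc, candidate_base_quality
from .model import AlignedRead
from .pileup import DEFAULT_ERROR_RATE, conversion_rate
from .sitefilter import (
    FilterConfig,
    FilterResult,
    replicate_concordance,
    run_filter_cascade,
    transcript_gene_map,
)
from .simdata import SimConfig, TruthTable, simulate_replicates
from .umidedup import dedup, discordance, group_by_umi

log = logging.getLogger("m5cpipe")


@dataclass
class ReplicateInput:
    """One replicate given as an aligned SAM/BAM file."""

    name: str
    sam: str


@dataclass
class RunManifest:
    replicates: list[ReplicateInput] = field(default_factory=list)
    sim: Optional[SimConfig] = None
    n_replicates: int = 2
    reference_fasta: Optional[str] = None
    control_prefix: str = "ERCC-"
    out_dir: str = "m5cpipe_run"
    qc: QcConfig = field(default_factory=QcConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [r.name for r in self.replicates]
        if len(set(names)) != len(names):
            raise ValueError("replicate names must be unique")
        if not self.replicates and self.sim is None:
            raise ValueError("manifest needs replicate inputs or a simulator config")


@dataclass
class ReplicateResult:
    name: str
    reads_dedup: list[AlignedRead]
    filter_result: FilterResult
    stats: dict


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def process_replicate(
    name: str,
    reads: Sequence[AlignedRead],
    reference: dict[str, str],
    manifest: RunManifest,
) -> ReplicateResult:
    """qc -> dedup -> conversion calibration -> single-library filter cascade."""
    log.info("[%s] qc: %d reads in", name, len(reads))
    kept, qc_report = apply_qc(list(reads), manifest.qc)
    log.info("[%s] qc: %d reads out (%s)", name, len(kept), dict(qc_report.discard_reasons))

    groups, n_missing_umi = group_by_umi(kept)
    deduped, dup_rate = dedup(groups)
    disc = discordance(groups)
    log.info(
        "[%s] dedup: %d groups, duplication rate %.3f, discordance %.4f",
        name,
        len(groups),
        dup_rate,
        disc.discordance_ratio,
    )

    control_ids = [r for r in reference if r.startswith(manifest.control_prefix)]
    conv = conversion_rate(deduped, reference, control_ids) if control_ids else None
    error_rate = DEFAULT_ERROR_RATE
    if conv is not None and conv.total_c_positions > 0:
        error_rate = max(1.0 - conv.rate, 1e-6)

    gene_of = transcript_gene_map(list(reference))
    result = run_filter_cascade(deduped, reference, gene_of, manifest.filters, error_rate)
    log.info(
        "[%s] filters: %d called, %d final, C-cutoff %d",
        name,
        len(result.sites_start),
        len(result.sites_final),
        result.scan.chosen_k,
    )

    stats = {
        "qc": qc_report.as_dict(),
        "n_missing_umi": n_missing_umi,
        "n_umi_groups": len(groups),
        "duplication_rate": dup_rate,
        "discordance_ratio": disc.discordance_ratio,
        "discordance_per_nt": disc.per_nucleotide,
        "conversion_rate": conv.rate if conv else None,
        "zero_candidate_fraction": conv.zero_candidate_fraction if conv else None,
        "candidate_histogram": conv.candidate_histogram if conv else None,
        "error_rate": error_rate,
        "chosen_c_cutoff": result.scan.chosen_k,
        "candidate_quality": candidate_base_quality(deduped, stage="dedup"),
        "stage_counts": dict(
            zip(result.attrition["stage"], result.attrition["n_sites"].astype(int))
        ),
    }
    return ReplicateResult(name, deduped, result, stats)


def run_pipeline(manifest: RunManifest) -> dict:
    """Execute the full pipeline and write stage outputs plus summary.json.

    With a single replicate the cross-replicate stage is skipped with an
    explicit warning and the high-confidence set is empty by definition.
    """
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs: list[tuple[str, list[AlignedRead]]] = []
    truth: Optional[TruthTable] = None
    if manifest.sim is not None:
        sim_cfg = dataclasses.replace(manifest.sim, seed=manifest.sim.seed + manifest.seed)
        sims = simulate_replicates(sim_cfg, manifest.n_replicates)
        reference = sims[0].reference.sequences
        truth = sims[0].truth
        sims[0].truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        sims[0].reference.write_fasta(out / "reference.fa")
        sims[0].reference.write_gtf(out / "annotation.gtf")
        for k, sim in enumerate(sims):
            inputs.append((f"rep{k + 1}", sim.reads))
    else:
        reference = io.load_fasta(manifest.reference_fasta)
        for rep in manifest.replicates:
            reads, _ = io.read_sam(rep.sam)
            inputs.append((rep.name, reads))

    results: list[ReplicateResult] = []
    for name, reads in inputs:
        try:
            res = process_replicate(name, reads, reference, manifest)
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise RuntimeError(f"replicate {name} failed: {exc}") from exc
        rep_dir = out / name
        rep_dir.mkdir(exist_ok=True)
        fr = res.filter_result
        fr.sites_start.to_csv(rep_dir / "sites_called.tsv", sep="\t", index=False)
        fr.sites_standard.to_csv(rep_dir / "sites_standard.tsv", sep="\t", index=False)
        fr.scan.table.to_csv(rep_dir / "c_cutoff_scan.tsv", sep="\t", index=False)
        fr.sites_final.to_csv(rep_dir / "sites_final.tsv", sep="\t", index=False)
        fr.attrition.to_csv(rep_dir / "attrition.tsv", sep="\t", index=False)
        results.append(res)

    if len(results) >= 2:
        high_conf = replicate_concordance(
            {r.name: r.filter_result.sites_final for r in results},
            {r.name: r.filter_result.post_cutoff_sites for r in results},
            manifest.filters,
        )
    else:
        warnings.warn("single replicate: high-confidence set is empty by definition")
        high_conf = pd.DataFrame()
    high_conf.to_csv(out / "high_confidence_sites.tsv", sep="\t", index=False)

    summary = {
        "seed": manifest.seed,
        "replicates": {r.name: r.stats for r in results},
        "n_high_confidence_sites": int(len(high_conf)),
        "thresholds": _jsonable(dataclasses.asdict(manifest.filters)),
        "qc_thresholds": _jsonable(dataclasses.asdict(manifest.qc)),
    }
    if truth is not None:
        summary["truth"] = evaluate_against_truth(high_conf, truth, reference)
    summary = _jsonable(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def evaluate_against_truth(
    high_conf: pd.DataFrame,
    truth: TruthTable,
    reference: dict[str, str],
    control_prefix: str = "ERCC-",
    level_tolerance: float = 0.1,
) -> dict:
    """Score a high-confidence site set against the simulator's truth.

    Reports sensitivity (planted sites recovered), counts of surviving
    sites on control transcripts and at non-planted positions, and the
    fraction of recovered sites whose estimated level is within
    ``level_tolerance`` of the planted level.
    """
    planted = {(r.ref, int(r.pos)): float(r.level) for r in truth.sites.itertuples()}
    n_true = len(planted)
    recovered = []
    n_control = 0
    n_offtarget = 0
    use_pooled = "level_pooled" in high_conf.columns
    for row in high_conf.itertuples(index=False):
        key = (row.ref, int(row.pos0))
        if key in planted:
            est = float(row.level_pooled) if use_pooled else float(row.level)
            recovered.append(abs(est - planted[key]) <= level_tolerance)
        elif row.ref.startswith(control_prefix):
            n_control += 1
        else:
            n_offtarget += 1
    sensitivity = len(recovered) / n_true if n_true else float("nan")
    level_ok = (sum(recovered) / len(recovered)) if recovered else float("nan")
    return {
        "n_planted": n_true,
        "n_recovered": len(recovered),
        "sensitivity": sensitivity,
        "n_false_on_controls": n_control,
        "n_false_off_target": n_offtarget,
        "level_within_tolerance_fraction": level_ok,
    }
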