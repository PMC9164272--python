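"""Synthetic directional RNA bisulfite-sequencing reads with known truth.

The simulator reproduces, molecule by molecule, the error processes that an
RNA BS-seq library accumulates between bisulfite treatment and base calling:

* per-cytosine conversion failure (an unmethylated C survives as C with
  probability ``1 - conversion_rate``);
* whole molecules that escape conversion entirely (secondary-structure
  protection, modelled as a binary per-molecule event);
* PCR amplification over discrete cycles, with efficiency penalised in
  proportion to a template's unconverted-cytosine fraction, so T-bearing
  (converted) templates are over-amplified;
* PCR and sequencing substitution errors;
* per-base Phred scores in which cytosine calls score a few points lower
  than other bases, as observed on real BS-seq runs;
* a random UMI per template molecule, shared by all of its PCR copies.

Every read is emitted pre-aligned (the simulator knows where each fragment
came from), so downstream stages can be tested without an external aligner.
All randomness flows through one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; a fixed seed yields byte-identical SAM/FASTQ output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import AlignedRead, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C = ord("C")
_T = ord("T")

DEFAULT_CONTROL_PREFIX = "ERCC-"


@dataclass
class SimConfig:
    """All knobs of the simulator, with defaults matching a clean directional
    library: conversion ~99.9% efficient, light PCR with amplification bias
    against unconverted templates, and Illumina-like qualities.

    Conversion resistance is concentrated, as it is in real libraries, on a
    subset of structure-prone transcripts (the analogue of the handful of
    spike-in species whose secondary structure blocks the reaction):
    ``resistant_transcript_fraction`` of all transcripts are prone, and on
    those each molecule escapes conversion entirely with probability
    ``resistant_read_fraction``. The product of the two is the library-wide
    resistant-read share (defaults: 0.2 x 0.1 = 2% of molecules).
    """

    n_transcripts: int = 10
    length_range: tuple[int, int] = (1800, 2200)
    n_control_transcripts: int = 3
    gc_content: float = 0.5
    n_true_sites: int = 30
    level_distribution: tuple[float, float] = (0.2, 1.0)
    mean_coverage: float = 100.0
    fragment_length: tuple[int, int] = (120, 180)
    read_length: int = 150
    conversion_rate: float = 0.999
    resistant_read_fraction: float = 0.1
    resistant_transcript_fraction: float = 0.2
    pcr_cycles: int = 3
    pcr_efficiency: float = 0.5
    pcr_bias_beta: float = 0.5
    pcr_error_rate: float = 1e-4
    seq_error_rate: float = 1e-3
    qual_mean_non_c: float = 38.0
    qual_c_penalty: float = 3.0
    qual_sd: float = 3.0
    umi_length: int = 8
    paired: bool = False
    control_prefix: str = DEFAULT_CONTROL_PREFIX
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "conversion_rate",
            "resistant_read_fraction",
            "resistant_transcript_fraction",
            "pcr_efficiency",
            "pcr_error_rate",
            "seq_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError(f"length_range inverted: {self.length_range}")
        lo, hi = self.fragment_length
        if lo > hi:
            raise ValueError(f"fragment_length inverted: {self.fragment_length}")
        lo, hi = self.level_distribution
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("level_distribution must be a range within [0, 1]")
        if self.n_transcripts < 1:
            raise ValueError("need at least one transcript")


@dataclass
class SimGene:
    """Annotation intervals for one simulated transcript (transcript space,
    0-based half-open): 5'UTR [0, utr5_end), CDS [utr5_end, cds_end),
    3'UTR [cds_end, length)."""

    gene_id: str
    transcript_id: str
    length: int
    utr5_end: int
    cds_end: int
    strand: str = "+"


@dataclass
class Reference:
    """Simulated reference pool: mRNA-like transcripts plus unmethylated
    spike-in control sequences (identified by an ID prefix)."""

    sequences: dict[str, str]
    control_prefix: str = DEFAULT_CONTROL_PREFIX
    genes: list[SimGene] = field(default_factory=list)
    resistant_ids: frozenset[str] = frozenset()

    def is_control(self, ref: str) -> bool:
        return ref.startswith(self.control_prefix)

    @property
    def control_ids(self) -> list[str]:
        return [r for r in self.sequences if self.is_control(r)]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k : k + 70] + "\n")

    def resistant_regions(self) -> dict[str, list[tuple[int, int]]]:
        """Conversion-resistant regions (whole structure-prone transcripts),
        in the shape consumed by the region filter."""
        return {r: [(0, len(self.sequences[r]))] for r in sorted(self.resistant_ids)}

    def write_resistant_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ref, ivs in self.resistant_regions().items():
                for s, e in ivs:
                    fh.write(f"{ref}\t{s}\t{e}\tresistant\n")

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'
                rows = [("transcript", 1, g.length), ("exon", 1, g.length)]
                if g.utr5_end > 0:
                    rows.append(("five_prime_utr", 1, g.utr5_end))
                if g.cds_end > g.utr5_end:
                    rows.append(("CDS", g.utr5_end + 1, g.cds_end))
                if g.length > g.cds_end:
                    rows.append(("three_prime_utr", g.cds_end + 1, g.length))
                for feature, s, e in rows:
                    fh.write(
                        f"{g.transcript_id.rsplit('.', 1)[0]}\tsim\t{feature}\t{s}\t{e}"
                        f"\t.\t{g.strand}\t.\t{attrs}\n"
                    )


@dataclass
class TruthTable:
    """Ground truth: planted sites and, after simulation, per-read provenance."""

    sites: pd.DataFrame  # columns: ref, pos, level
    reads: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["read_id", "template_id", "is_pcr_duplicate", "is_resistant"]
        )
    )

    def site_level(self, ref: str, pos: int) -> Optional[float]:
        hit = self.sites[(self.sites["ref"] == ref) & (self.sites["pos"] == pos)]
        return None if hit.empty else float(hit["level"].iloc[0])

    def write_tsv(self, sites_path: str | Path, reads_path: str | Path | None = None) -> None:
        self.sites.to_csv(sites_path, sep="\t", index=False)
        if reads_path is not None:
            self.reads.to_csv(reads_path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def generate_reference(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Reference:
    """Random transcript pool: ``n_transcripts`` mRNA-like sequences plus
    ``n_control_transcripts`` spike-in controls, with a one-transcript-per-gene
    annotation carrying 5'UTR/CDS/3'UTR sub-features (15% / 60% / 25% split)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    genes: list[SimGene] = []
    lo, hi = config.length_range
    for k in range(config.n_transcripts):
        name = f"TX{k + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        sequences[name] = _random_seq(rng, length, config.gc_content)
        u5 = max(1, int(round(0.15 * length)))
        cds = max(u5 + 1, int(round(0.75 * length)))
        genes.append(SimGene(name, f"{name}.1", length, u5, min(cds, length - 1)))
    for k in range(config.n_control_transcripts):
        name = f"{config.control_prefix}{k + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        sequences[name] = _random_seq(rng, length, config.gc_content)
        genes.append(SimGene(name, f"{name}.1", length, 0, length))
    names = list(sequences)
    n_prone = int(round(config.resistant_transcript_fraction * len(names)))
    if config.resistant_transcript_fraction > 0 and config.resistant_read_fraction > 0:
        n_prone = max(n_prone, 1)
    prone = frozenset(
        names[int(k)] for k in rng.choice(len(names), size=n_prone, replace=False)
    )
    return Reference(sequences, config.control_prefix, genes, prone)


def plant_methylation(
    reference: Reference, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> TruthTable:
    """Choose ``n_true_sites`` distinct reference-C positions on non-control
    transcripts and assign each a true methylation level drawn uniformly from
    ``level_distribution``. Control transcripts never carry planted sites,
    and neither do structure-prone transcripts: a molecule whose secondary
    structure blocks bisulfite chemistry is not assayable, so planting truth
    there would build in unrecoverable sites."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    candidates: list[tuple[str, int]] = []
    for name, seq in reference.sequences.items():
        if reference.is_control(name) or name in reference.resistant_ids:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for pos in np.nonzero(arr == _C)[0]:
            candidates.append((name, int(pos)))
    if config.n_true_sites > len(candidates):
        raise ValueError(
            f"cannot plant {config.n_true_sites} sites: only {len(candidates)} "
            "cytosine positions available on non-control transcripts"
        )
    if config.n_true_sites == 0:
        return TruthTable(pd.DataFrame(columns=["ref", "pos", "level"]))
    idx = rng.choice(len(candidates), size=config.n_true_sites, replace=False)
    lo, hi = config.level_distribution
    levels = rng.uniform(lo, hi, size=config.n_true_sites)
    rows = [
        {"ref": candidates[int(k)][0], "pos": candidates[int(k)][1], "level": float(lv)}
        for k, lv in zip(idx, levels)
    ]
    sites = pd.DataFrame(rows).sort_values(["ref", "pos"]).reset_index(drop=True)
    return TruthTable(sites)


@dataclass
class _Molecule:
    ref: str
    start: int
    seq: np.ndarray  # converted fragment, uint8
    umi: str
    template_id: int
    is_duplicate: bool
    is_resistant: bool
    n_ref_c: int

    @property
    def unconverted_fraction(self) -> float:
        if self.n_ref_c == 0:
            return 0.0
        return float(np.count_nonzero(self.seq == _C)) / self.n_ref_c


@dataclass
class SimResult:
    reads: list[AlignedRead]
    truth: TruthTable
    reference: Reference
    config: SimConfig

    def write_sam(self, path: str | Path) -> None:
        from . import io

        io.write_sam(path, self.reads, self.reference.sequences)

    def write_fastq(self, path: str | Path) -> None:
        from . import io

        io.write_fastq(path, self.reads)


def _inject_errors(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases at the given per-base rate (always to a different base)."""
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    seq = seq.copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    shift = rng.integers(1, 4, size=n_err)
    idx = np.searchsorted(_BASES, seq[pos])
    idx = np.clip(idx, 0, 3)  # N treated as A for substitution purposes
    seq[pos] = _BASES[(idx + shift) % 4]
    return seq


def simulate_reads(
    reference: Reference, truth: TruthTable, config: SimConfig
) -> SimResult:
    """Run the full molecule-level simulation and emit aligned reads.

    Per template molecule: a fragment is drawn, methylation states are
    realised per planted site (Bernoulli at the true level), bisulfite
    conversion is applied (skipped for resistant molecules), a UMI is
    attached, PCR cycles duplicate templates with biased efficiency and
    substitution errors, and finally sequencing errors and Phred scores are
    applied to every molecule that is read out.
    """
    rng = np.random.default_rng(config.seed + 2)
    site_map: dict[str, dict[int, float]] = {}
    for row in truth.sites.itertuples():
        site_map.setdefault(row.ref, {})[int(row.pos)] = float(row.level)

    flo, fhi = config.fragment_length
    molecules: list[_Molecule] = []
    template_id = 0
    for ref_name, ref_seq in reference.sequences.items():
        arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
        L = len(arr)
        mean_frag = (flo + fhi) / 2
        n_frags = max(1, int(round(config.mean_coverage * L / mean_frag)))
        planted = site_map.get(ref_name, {})
        planted_pos = np.array(sorted(planted), dtype=np.int64)
        prone = ref_name in reference.resistant_ids
        for _ in range(n_frags):
            fl = int(rng.integers(flo, fhi + 1))
            fl = min(fl, L)
            start = int(rng.integers(0, L - fl + 1))
            frag = arr[start : start + fl].copy()
            c_off = np.nonzero(frag == _C)[0]
            resistant = prone and bool(rng.random() < config.resistant_read_fraction)
            if len(planted_pos):
                inside = planted_pos[(planted_pos >= start) & (planted_pos < start + fl)]
                methylated = {
                    int(p) for p in inside if rng.random() < planted[int(p)]
                }
            else:
                methylated = set()
            if not resistant and len(c_off):
                convert = rng.random(len(c_off)) < config.conversion_rate
                for k, off in enumerate(c_off):
                    if int(off) + start in methylated:
                        convert[k] = False  # methylated C is protected
                frag[c_off[convert]] = _T
            umi = rng.choice(_BASES, size=config.umi_length).tobytes().decode()
            molecules.append(
                _Molecule(ref_name, start, frag, umi, template_id, False, resistant, len(c_off))
            )
            template_id += 1

    # PCR: discrete cycles; every molecule present at the start of a cycle may
    # duplicate, with efficiency shrunk by its unconverted-C fraction.
    for _ in range(config.pcr_cycles):
        n_now = len(molecules)
        for m in molecules[:n_now]:
            p_amp = config.pcr_efficiency * max(
                0.0, 1.0 - config.pcr_bias_beta * m.unconverted_fraction
            )
            if rng.random() < p_amp:
                seq = _inject_errors(rng, m.seq, config.pcr_error_rate)
                molecules.append(
                    _Molecule(
                        m.ref, m.start, seq, m.umi, m.template_id, True, m.is_resistant, m.n_ref_c
                    )
                )

    ref_order = {name: k for k, name in enumerate(reference.sequences)}
    molecules.sort(key=lambda m: (ref_order[m.ref], m.start, m.template_id))

    reads: list[AlignedRead] = []
    read_rows: list[dict] = []
    for k, m in enumerate(molecules):
        name = f"read{k:07d}_{m.umi}"
        for seg in _sequence_molecule(rng, m, name, config):
            reads.append(seg)
        read_rows.append(
            {
                "read_id": name,
                "template_id": m.template_id,
                "is_pcr_duplicate": m.is_duplicate,
                "is_resistant": m.is_resistant,
            }
        )

    reads.sort(key=lambda r: (ref_order[r.ref], r.start, r.name, r.mate))
    truth = TruthTable(truth.sites.copy(), pd.DataFrame(read_rows))
    return SimResult(reads, truth, reference, config)


def _phred(rng: np.random.Generator, seq: np.ndarray, config: SimConfig) -> np.ndarray:
    mean = np.full(len(seq), config.qual_mean_non_c)
    mean[seq == _C] -= config.qual_c_penalty
    q = rng.normal(mean, config.qual_sd)
    return np.clip(np.rint(q), 2, 41).astype(np.uint8)


def _sequence_molecule(
    rng: np.random.Generator, m: _Molecule, name: str, config: SimConfig
) -> list[AlignedRead]:
    rl = config.read_length
    if not config.paired:
        seq = _inject_errors(rng, m.seq[:rl], config.seq_error_rate)
        return [
            AlignedRead(
                name=name,
                ref=m.ref,
                start=m.start,
                seq=seq.tobytes().decode(),
                quals=_phred(rng, seq, config),
                umi=m.umi,
                mate="single",
            )
        ]
    # Directional paired-end: read1 covers the fragment 5' end in C2T space;
    # read2 is sequenced from the 3' end but stored reference-forward.
    s1 = _inject_errors(rng, m.seq[:rl], config.seq_error_rate)
    s2 = _inject_errors(rng, m.seq[-rl:] if len(m.seq) > rl else m.seq, config.seq_error_rate)
    r1 = AlignedRead(
        name=name,
        ref=m.ref,
        start=m.start,
        seq=s1.tobytes().decode(),
        quals=_phred(rng, s1, config),
        umi=m.umi,
        mate="read1",
    )
    r2_start = m.start + max(0, len(m.seq) - rl)
    r2 = AlignedRead(
        name=name,
        ref=m.ref,
        start=r2_start,
        seq=s2.tobytes().decode(),
        quals=_phred(rng, s2, config),
        umi=m.umi,
        mate="read2",
        is_reverse=True,
    )
    return [r1, r2]


def simulate(config: SimConfig) -> SimResult:
    """Convenience wrapper: reference -> truth -> reads from one config."""
    reference = generate_reference(config)
    truth = plant_methylation(reference, config)
    return simulate_reads(reference, truth, config)


def simulate_replicates(config: SimConfig, n_replicates: int = 2) -> list[SimResult]:
    """Independent library replicates of one biological sample: all share the
    reference and the planted truth; only read generation differs by seed."""
    reference = generate_reference(config)
    truth = plant_methylation(reference, config)
    out = []
    for k in range(n_replicates):
        cfg_k = dataclasses.replace(config, seed=config.seed + 101 * (k + 1))
        out.append(simulate_reads(reference, truth, cfg_k))
    return out
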