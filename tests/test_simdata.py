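"""Simulator behaviour: determinism, truth bookkeeping, error processes."""

import numpy as np
import pytest

from m5cpipe.pileup import read_candidate_count
from m5cpipe.simdata import (
    SimConfig,
    generate_reference,
    plant_methylation,
    simulate,
    simulate_reads,
    simulate_replicates,
)


def test_reference_determinism_and_lengths(tmp_path):
    cfg = SimConfig(n_transcripts=1, n_control_transcripts=0, length_range=(300, 300), seed=7)
    ref_a = generate_reference(cfg)
    ref_b = generate_reference(cfg)
    assert ref_a.sequences == ref_b.sequences
    (seq,) = ref_a.sequences.values()
    assert len(seq) == 300


def test_control_transcript_count():
    cfg = SimConfig(n_transcripts=4, n_control_transcripts=2, length_range=(500, 600))
    ref = generate_reference(cfg)
    assert len(ref.control_ids) == 2
    assert all(r.startswith(cfg.control_prefix) for r in ref.control_ids)


def test_inverted_length_range_rejected():
    with pytest.raises(ValueError, match="inverted"):
        SimConfig(length_range=(500, 400))


def test_gc_content_matches_config():
    # >= 100 kb of sequence: base counting is the oracle
    cfg = SimConfig(
        n_transcripts=50, n_control_transcripts=0, length_range=(2000, 2000),
        gc_content=0.4, seed=3,
    )
    ref = generate_reference(cfg)
    pool = "".join(ref.sequences.values())
    assert len(pool) >= 100_000
    gc = (pool.count("G") + pool.count("C")) / len(pool)
    assert abs(gc - 0.4) < 0.02


def test_plant_zero_sites_empty_table():
    cfg = SimConfig(n_true_sites=0)
    truth = plant_methylation(generate_reference(cfg), cfg)
    assert len(truth.sites) == 0


def test_planted_sites_distinct_on_reference_c():
    cfg = SimConfig(n_true_sites=10, seed=11)
    ref = generate_reference(cfg)
    truth = plant_methylation(ref, cfg)
    assert len(truth.sites) == 10
    keys = set(zip(truth.sites["ref"], truth.sites["pos"]))
    assert len(keys) == 10
    for name, pos in keys:
        assert ref.sequences[name][pos] == "C"
        assert not ref.is_control(name)


def test_plant_rejects_when_no_cytosines():
    cfg = SimConfig(gc_content=0.0, n_true_sites=5, length_range=(500, 500))
    ref = generate_reference(cfg)
    with pytest.raises(ValueError, match="cytosine"):
        plant_methylation(ref, cfg)


def test_fully_methylated_site_never_converts():
    cfg = SimConfig(
        n_transcripts=2, n_control_transcripts=0, length_range=(800, 900),
        n_true_sites=3, level_distribution=(1.0, 1.0), mean_coverage=30,
        resistant_read_fraction=0.0, resistant_transcript_fraction=0.0,
        pcr_error_rate=0.0, seq_error_rate=0.0, seed=5,
    )
    sim = simulate(cfg)
    planted = {(r.ref, int(r.pos)) for r in sim.truth.sites.itertuples()}
    for read in sim.reads:
        for ref, pos in planted:
            if read.ref == ref and read.start <= pos < read.end:
                assert read.seq[pos - read.start] == "C"


def test_full_conversion_leaves_controls_c_free(clean_sim):
    ref = clean_sim.reference
    for read in clean_sim.reads:
        if not ref.is_control(read.ref):
            continue
        assert read_candidate_count(read, ref.sequences) == 0


def test_no_pcr_means_no_duplicates():
    cfg = SimConfig(
        n_transcripts=2, n_control_transcripts=0, length_range=(800, 900),
        mean_coverage=20, pcr_cycles=0, seed=9,
    )
    sim = simulate(cfg)
    assert not sim.truth.reads["is_pcr_duplicate"].any()
    assert len(sim.reads) == len(sim.truth.reads)


def test_template_count_matches_truth(small_sim):
    n_templates = int((~small_sim.truth.reads["is_pcr_duplicate"]).sum())
    assert n_templates == small_sim.truth.reads["template_id"].nunique()


def test_conversion_rate_recovery_within_binomial_ci():
    # clean chemistry, known conversion probability: the truth parameter is
    # the oracle, checked against a 3-sigma binomial interval
    cfg = SimConfig(
        n_transcripts=1, n_control_transcripts=2, length_range=(2000, 2000),
        n_true_sites=0, mean_coverage=60, conversion_rate=0.99,
        resistant_read_fraction=0.0, resistant_transcript_fraction=0.0,
        pcr_cycles=0, pcr_error_rate=0.0, seq_error_rate=0.0, seed=13,
    )
    sim = simulate(cfg)
    n_c = n_t = 0
    for read in sim.reads:
        if not sim.reference.is_control(read.ref):
            continue
        span = sim.reference.sequences[read.ref][read.start : read.end]
        for ref_base, base in zip(span, read.seq):
            if ref_base == "C":
                n_c += base == "C"
                n_t += base == "T"
    total = n_c + n_t
    assert total >= 50_000
    est = n_t / total
    sd = np.sqrt(0.99 * 0.01 / total)
    assert abs(est - 0.99) < 3 * sd


def test_pcr_bias_enriches_converted_duplicates():
    cfg = SimConfig(
        n_transcripts=3, n_control_transcripts=1, length_range=(1000, 1200),
        n_true_sites=10, mean_coverage=30, pcr_bias_beta=4.0, pcr_cycles=3,
        seq_error_rate=0.0, pcr_error_rate=0.0, seed=17,
    )
    sim = simulate(cfg)
    by_id = {r.name: r for r in sim.reads}
    fractions = {True: [], False: []}
    for rec in sim.truth.reads.itertuples():
        read = by_id[rec.read_id]
        span = sim.reference.sequences[read.ref][read.start : read.end]
        n_ref_c = span.count("C")
        if n_ref_c == 0:
            continue
        frac = read_candidate_count(read, sim.reference.sequences) / n_ref_c
        fractions[bool(rec.is_pcr_duplicate)].append(frac)
    assert np.mean(fractions[True]) <= np.mean(fractions[False])


def test_sam_output_byte_identical_under_seed(tmp_path):
    cfg = SimConfig(
        n_transcripts=2, n_control_transcripts=1, length_range=(600, 700),
        mean_coverage=10, seed=23,
    )
    paths = []
    for k in range(2):
        sim = simulate(cfg)
        p = tmp_path / f"run{k}.sam"
        sim.write_sam(p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_replicates_share_reference_and_truth():
    cfg = SimConfig(
        n_transcripts=2, n_control_transcripts=1, length_range=(600, 700),
        n_true_sites=4, mean_coverage=10, seed=29,
    )
    reps = simulate_replicates(cfg, 2)
    assert reps[0].reference.sequences == reps[1].reference.sequences
    assert reps[0].truth.sites.equals(reps[1].truth.sites)
    assert [r.name for r in reps[0].reads] != [r.name for r in reps[1].reads] or (
        reps[0].reads[0].seq != reps[1].reads[0].seq
    )


def test_umis_on_name_and_tag(small_sim):
    for read in small_sim.reads[:50]:
        assert read.name.endswith("_" + read.umi)
        assert len(read.umi) == small_sim.config.umi_length


def test_resistant_reads_only_on_prone_transcripts(small_sim):
    prone = small_sim.reference.resistant_ids
    assert prone  # default fractions guarantee at least one
    by_id = {r.name: r.ref for r in small_sim.reads}
    resistant_refs = {
        by_id[rec.read_id]
        for rec in small_sim.truth.reads.itertuples()
        if rec.is_resistant
    }
    assert resistant_refs <= set(prone)
    # and planted truth avoids them
    assert not (set(small_sim.truth.sites["ref"]) & set(prone))
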