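"""Generate a synthetic RNA bisulfite-seq library with known ground truth.

Builds a transcript pool with unmethylated spike-in controls, plants m5C
sites at known levels, and simulates UMI-tagged directional bisulfite
reads through conversion, PCR (with amplification bias against unconverted
templates) and sequencing.
"""

from m5cpipe.simdata import SimConfig, simulate

cfg = SimConfig(n_transcripts=4, n_control_transcripts=2, n_true_sites=10,
                length_range=(1200, 1500), mean_coverage=40, seed=7)
sim = simulate(cfg)

print(f"reference: {len(sim.reference.sequences)} transcripts "
      f"({len(sim.reference.control_ids)} spike-in controls, "
      f"{len(sim.reference.resistant_ids)} structure-prone)")
print(f"planted sites:\n{sim.truth.sites.head()}")
n_dup = int(sim.truth.reads["is_pcr_duplicate"].sum())
print(f"reads: {len(sim.reads)} total, {n_dup} PCR duplicates")
# Each planted site is a (transcript, position, true level) triple; reads
# carry that methylation signal plus every error process of a real library.
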