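"""Methylation calling and the multi-level high-confidence filter cascade.

Sites are called at reference cytosines (i = unconverted C count,
j = C+T coverage, level = i/j) with a binomial p-value calibrated on the
unmethylated spike-ins, then pass the standard filter (i>=3, j>=20,
level>=0.1), the Gini-selected C-cutoff with its signal/noise gate, and
BH-FDR at 0.05.
"""

from m5cpipe.bsqc import apply_qc
from m5cpipe.pileup import conversion_rate
from m5cpipe.simdata import SimConfig, simulate
from m5cpipe.sitefilter import run_filter_cascade, transcript_gene_map
from m5cpipe.umidedup import dedup, group_by_umi

sim = simulate(SimConfig(seed=17))
reference = sim.reference.sequences
kept, _ = apply_qc(sim.reads)
deduped, _ = dedup(group_by_umi(kept)[0])

conv = conversion_rate(deduped, reference, sim.reference.control_ids)
print(f"spike-in conversion rate: {100 * conv.rate:.2f}% "
      f"({conv.zero_candidate_fraction * 100:.1f}% of control reads carry no candidate base)")

res = run_filter_cascade(deduped, reference, transcript_gene_map(list(reference)),
                         error_rate=max(1 - conv.rate, 1e-6))
print(f"chosen C-cutoff: {res.scan.chosen_k} "
      f"(Gini at that cutoff: {res.scan.table.set_index('cutoff').loc[res.scan.chosen_k, 'gini']:.3f})")
print(res.attrition.to_string(index=False))
print(f"{len(res.sites_final)} sites survive all single-library filters "
      f"(simulator planted {len(sim.truth.sites)})")
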