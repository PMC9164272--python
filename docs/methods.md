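# Methods

This note documents the models, parameter defaults and design decisions
behind `m5cpipe`. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement model

Bisulfite treatment deaminates unmethylated cytosine to uracil; after
reverse transcription and sequencing an unmethylated C reads as T, while
m5C is protected and reads as C. At a reference cytosine the calling
model is a per-site binomial: given (C+T) coverage *j* and a per-base
false-methylation probability *p*err (the chance an unmethylated C
survives conversion and is read as C), the unconverted count *i* under
the null of no methylation is Binomial(*j*, *p*err). The reported
p-value is the one-sided tail P(X ≥ *i*), computed with
`scipy.stats.binom.sf` (the test oracle re-derives it by direct
summation). *p*err is calibrated per library as 1 − the pooled
conversion rate on unmethylated spike-in controls, where every candidate
base is by construction an artifact; without controls it defaults to
1 − 0.999. Bases other than C/T at a candidate position (sequencing
errors, SNVs) are excluded from *j* and tracked separately. Only bases
with Phred ≥ 30 enter the counts: cytosine calls score systematically
lower than other bases in BS-seq lanes, and low-quality candidate bases
are the dominant single-base error mode.

Coordinates are 0-based half-open internally; SAM I/O and the `pos1`
column convert at the boundary. Reads carry an orientation (C→T space on
the converted strand, G→A on its complement); the caller counts G/A at
reference G for G2A reads. Overlapping mate bases are counted once
(higher base quality wins; ties go to read1).

## The filter cascade

The cascade is a pure set reduction in fixed order: standard filter →
C-cutoff with signal/noise → structure regions → FDR → replicates.

* **Standard filter**: *i* ≥ 3, *j* ≥ 20, level ≥ 0.1, all boundaries
  inclusive.
* **C-cutoff**: a read's candidate content is its number of unconverted
  candidate bases (no quality gate — it measures the molecule, not the
  base calls; bases at genuinely methylated sites are deliberately
  included, since the signal/noise gate exists to rescue true sites).
  Reads with content > *k* are removed and sites re-called. *k* is
  selected by scanning the configured range and computing the Gini
  coefficient (population pairwise form, G = Σ|x_a − x_b| / 2n²x̄) of
  candidate-sites-per-gene: molecules that escaped conversion saturate
  their transcript with candidate sites, so inequality across genes is
  the signature of concentrated incomplete conversion, and Gini falls as
  the cutoff tightens. The chosen *k* is the **largest** (least
  stringent) cutoff with Gini ≤ 0.15: every removed read is lost
  coverage, so the scan stops tightening as soon as the site distribution
  is even. If no cutoff in the range reaches the threshold the strictest
  one is used, with a warning. The scan is a single incremental pileup
  pass (reads sorted by content, counts snapshotted per cutoff), so the
  retained read sets are nested in *k* by construction.
* **Signal/noise**: per site, candidate count after the cutoff divided
  by the count before; retained iff ≥ 0.9 (a site with count 0 before
  gets ratio 0). Sites supported mainly by poorly converted reads fall
  to ~0 here — this, not the standard filter, is what empties the
  spike-in controls of artifact sites.
* **Structure regions**: half-open intervals (BED input from an external
  structure predictor); a site is removed iff start ≤ pos < end on the
  same reference. The prediction itself is out of scope.
* **FDR**: Benjamini–Hochberg step-up over the binomial p-values of the
  surviving sites, recomputed from post-cutoff counts; pass at q ≤ 0.05.
  FDR is per library over sites entering the stage, matching the
  cascade position, not transcriptome-wide over all called positions.
* **Replicates**: a high-confidence site passes everything in ≥ 1
  replicate and shows *i* ≥ 1 with *j* ≥ 10 after the other replicate's
  own C-cutoff (cutoffs are per-library, never shared). The reported
  level for a high-confidence site pools post-cutoff counts across
  replicates (Σi/Σj) — the site is by definition supported in several
  libraries, and pooling roughly halves the binomial noise of the
  estimate.

Read-level QC runs before any of this, in fixed order: 3' polyX trim
(single-nucleotide runs ≥ 10 nt, repeated until no qualifying run
remains), length ≥ 50 nt, mean Phred ≥ 25, ≤ 40% of bases below Q25,
6 bp fixed trim from both ends (m-bias from random-primer residues),
length re-check, and — for paired input — a ≥ 1-base reference overlap
requirement between mates. The keep/discard decisions are idempotent and
trimming never alters a retained base or quality; the fixed end trim is
by nature a once-per-pipeline operation, so "apply the pipeline twice"
is only guaranteed stable for the decisions and the polyX trim.

UMI deduplication groups reads by exact (reference, start, strand, UMI)
key — no edit-distance clustering, so the grouping oracle is trivial —
and retains the most prevalent member sequence; ties break by higher
summed base quality, then lexicographically smaller sequence. Discordance
(members disagreeing at a shared aligned position) is reported as the
fraction of groups affected, per nucleotide class (a position's classes
are the bases observed there, so a C/T disagreement increments both) and
as the full base-frequency vector at discordant candidate positions.
Depth-1 groups count as concordant in the denominator.

## The simulator

`simdata` emulates, per molecule: fragmentation (uniform start, length
uniform in `fragment_length`), per-site methylation realised as
Bernoulli(true level), bisulfite conversion (unmethylated C → T with
probability `conversion_rate`), whole-molecule conversion escape, PCR
over discrete cycles, sequencing error, and truncated-normal Phred
scores with the cytosine mean lowered by `qual_c_penalty`. A UMI is
attached per template and inherited by PCR copies; reads are emitted
pre-aligned (SAM, coordinate-sorted, `_UMI` name suffix and RX tag),
with a truth table of planted sites and per-read provenance. One seeded
`numpy` generator drives everything; a fixed seed gives byte-identical
SAM/FASTQ.

Key modelling choices:

* **Concentrated conversion resistance.** Incomplete conversion in real
  libraries clusters on specific structured species rather than falling
  uniformly; a uniform model would spread artifact sites evenly over
  genes and leave the Gini scan with nothing to detect. A fraction
  `resistant_transcript_fraction` (default 0.2) of transcripts —
  controls included — are structure-prone; on those, each molecule
  escapes conversion entirely with probability `resistant_read_fraction`
  (default 0.1), giving a 2% library-wide resistant share by default.
  Escape is binary per molecule; per-region resistance within a molecule
  is not modelled. Planted truth avoids prone transcripts: a molecule
  whose structure blocks the chemistry is not assayable, so ground truth
  there would be unrecoverable by construction.
* **PCR**: discrete doubling rounds; every molecule present at the start
  of a cycle duplicates with probability
  `pcr_efficiency × (1 − pcr_bias_beta × unconverted-C fraction)`,
  clamped at 0, with per-base substitution errors at `pcr_error_rate`
  per cycle. This makes converted (T-bearing) templates out-amplify
  unconverted ones — the bias that UMI deduplication corrects. The
  default `pcr_bias_beta = 0.5` is a free parameter (no quantitative
  magnitude is established for real libraries); the mechanism tests use
  `beta = 4`, where the per-site level shift (~0.03) is well above
  desk-scale simulation noise, while at 0.5 the asymmetry from a single
  methylated cytosine among ~100 fragment cytosines (~1%) would drown in
  it.
* **Quality model**: truncated normal, mean 38 for non-C bases
  (contemporary Illumina-like), cytosine mean lowered by 3 points, SD 3,
  clipped to [2, 41]. With a C mean of 35, the Q30 site gate drops ~5%
  of true candidate bases versus ~0.4% of converted ones, biasing levels
  down by under 1% relative — visible but small, as intended; a lower
  global mean would turn the gate into a major level distortion.
* **Defaults as study conditions**: conversion 0.999, 2 replicates
  sharing reference and truth (replicates of one sample differ only in
  read randomness), planted levels uniform in [0.2, 1.0], 30 sites over
  10 mRNA-like transcripts of ~2 kb plus 3 spike-in controls, mean
  coverage 100×. Coverage 100 (the recovery conditions require ≥ 50) is
  a power choice made up front: the ±0.1 level-accuracy check at the
  95% site fraction needs replicate-pooled coverage ≈ 200, since at
  pooled j the binomial SD at level 0.5 is √(0.25/j) ≈ 0.035, putting
  ±0.1 at ~2.8 SD. Transcripts of ~2 kb keep the per-gene baseline site
  counts large enough that the Gini floor of a clean library sits
  clearly below the 0.15 threshold; at ~1 kb the Poisson noise of
  sites-per-gene alone pushes Gini near 0.16 and the scan cannot
  separate clean from artifact-laden libraries at this scale.
* **What is not modelled**: splicing, indels (the pipeline itself
  accepts I/D/N/S cigars from external aligners), UMI error correction,
  adapter contamination (QC assumes adapter-free input), folding-based
  per-region resistance, and real sequence composition. Passing the
  recovery tests therefore shows the pipeline's logic is correct under
  the stated error processes, not that these thresholds are optimal for
  any particular real library.

## Numerical and interface choices

* Gini uses the population pairwise form (n², not n(n−1)), computed via
  the sorted-rank identity and cross-checked against the double sum;
  input must be strictly positive counts. Genes absent from the
  annotation are excluded from the Gini vector but still flow through
  all other filters.
* `call_sites` emits *i* = 0 positions (needed for conversion
  diagnostics); the minimum-reported-level knob (`min_level`) exists but
  defaults to 0.
* Fisher tests for differential methylation are two-sided on
  [[i_a, j_a−i_a], [i_b, j_b−i_b]], BH-adjusted, differential at
  q ≤ 0.05; Wilcoxon rank-sum and Spearman run on shared-site level
  vectors.
* Metagene projection uses 20 bins — 5'UTR → 1–5, CDS → 6–17, 3'UTR →
  18–20, each region scaled proportionally (a site at region fraction f
  of a w-bin region lands in bin first + min(⌊f·w⌋, w−1)); sites on
  transcripts missing any region are skipped and counted. The GGG
  enrichment score is the mean G frequency at offsets +1..+3 over the
  mean G frequency at the remaining non-center flank offsets.
* CPM uses union-exon, unique-gene assignment (reads overlapping two
  genes are unassigned; no fractional counting); CPM sums to 10⁶ over
  assigned genes.
* GTF parsing handles the Ensembl attribute dialect; UTRs are derived as
  exon-minus-CDS (split by strand) when explicit UTR records are absent.
  Multi-gene overlaps resolve to the transcript with the longest CDS,
  with all genes recorded in an auxiliary column.

## Problem sizes

The test suite and acceptance script run the full pipeline at the
default scale (two replicates of ~58k reads each over ~26 kb of
reference) in tens of seconds per seed; recovery is checked across five
seeds, mechanism checks across three. These sizes were chosen so a
complete run stays a desk-scale operation while every stage still sees
thousands of UMI groups and candidate sites.

## Known limitations

* Exact UMI matching over-splits groups when UMIs carry sequencing
  errors; real data with long UMIs may need the clustering this package
  deliberately omits.
* The conversion-rate estimate pools all spike-in controls; if a control
  is itself structure-prone the pooled rate (and hence *p*err) absorbs
  that contamination, making the binomial test conservative rather than
  anti-conservative.
* Single-replicate runs produce an empty high-confidence set by
  definition; the per-library tables remain available for exploration.
* The C-cutoff scan assumes the gene annotation covers the references
  reads map to; with no annotated sites at any cutoff it refuses to
  choose.
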