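# Methods

This note documents the model implemented by `teasv`, the default
parameters and why they were chosen, what the simulator does and does not
emulate, and the numerical choices that make results reproducible.

## 1. Problem model

A new TE insertion is observed through single reads whose local alignment
splits at the insertion junction: a contiguous genomic block on one side, TE
sequence on the other. Three read categories carry evidence:

* **split** — genomic flank on one side of the junction plus part of the
  element;
* **full_span** — the entire element plus genomic flank on *both* sides
  (possible when reads are longer than the element);
* **full_TE** — reads entirely within the element; they prove activity of
  the family but carry no locus information and yield no call.

All coordinates are 0-based half-open in memory; BED output stays 0-based
half-open, GFF3 output is 1-based inclusive. Calls are made in
pre-insertion reference coordinates. Simulated truth records carry both the
mutated-genome position (where reads physically originate) and the
reference-space insertion point (where calls are evaluated).

## 2. Alignment

Local alignment with affine gaps (Gotoh recurrence), match +2,
mismatch −3, gap open 5, gap extend 2. Instead of E-value significance,
HSPs are reported above deterministic cutoffs: score ≥50 and ≥40 aligned
columns (≥11 for internal oracle comparisons). These cutoffs are
database-size independent, which keeps results identical whether a read is
aligned to one chromosome or many.

Two execution paths give identical semantics:

* **exact** — problems up to 2×10⁶ matrix cells are solved with the full
  dynamic-programming matrix; multiple HSPs are enumerated by iteratively
  masking the subject interval of each reported HSP. This path is provably
  optimal (the test suite compares it against an independently written
  brute-force Smith–Waterman) and covers every construct-validation
  alignment.
* **seeded** — larger problems (reads against chromosomes) use exact 11-mer
  seeds bucketed by diagonal; a bucket with ≥4 non-overlapping seeds within
  a diagonal spread of 20 triggers banded extension (band 100, widened to
  the seed spread up to 800, X-drop 100, 500 bp extension margin).
  Requiring the 4 seeds to be *non-overlapping* matters: a single chance
  15-bp exact match otherwise counts as 5 seeds on one diagonal and floods
  the extender with random noise.

Reverse-strand hits align the reverse-complemented query and report query
coordinates on the original read. Co-linear same-strand HSPs whose query
and subject gaps are each ≤50 bp (overlap tolerance 25 bp) are chained
greedily in score order into *blocks*; a block's span is the union of its
HSP query intervals. "Contiguous genomic block" below always means such a
chain, which makes the notion robust to the frequent small indel breaks
that 13% error causes.

Identity statistics are unweighted means over HSP percent identities
(weighted variant available).

## 3. Read-set QC

A read is kept when the union of its genomic HSP query intervals covers at
least 20% of its length (boundary inclusive). Summary statistics: median
length without interpolation (lower central value, deterministic across
platforms), fraction of kept reads in [500 bp, 15 kb], unweighted mean HSP
identity, and coverage estimated as aligned bases of kept reads divided by
genome length.

The ΔΔCt utility computes
`copies = calibrator_copies · 2^−((Ct_t,s − Ct_r,s) − (Ct_t,c − Ct_r,c))`
with `calibrator_copies = 2` by default, so a sample identical to the
two-copy calibrator reports exactly 2.0.

## 4. Detection

**Targeted mode.** The TE query is aligned to every read. TE coverage
≥95% of the read ⇒ *full_TE* (no locus). Otherwise the read is aligned to
the reference; blocks left and right of the TE segment that bracket one
locus (reference gap ≤200 bp) make a *full_span* candidate; a single
flanking block of ≥50 bp makes a *split* candidate, with the junction at
the block edge facing the TE segment.

**Ab initio mode.** Works from the QC-filtered reads without knowing which
element moved. The best genomic block must span ≥400 bp (`min_block_len`)
and ≤75% of the read (`max_block_frac`); the unaligned remainder must align
to some library TE over ≥200 bp (`min_te_len`). A split candidate whose TE
segment is bracketed by a second genomic block at the same locus is
reclassified *full_span*, so both modes treat such reads identically.

**Locus re-validation.** Every candidate is re-aligned to the concatenation
of the ±1 kb reference window around the breakpoint and the TE sequence.
The union of aligned read intervals must exceed 300 bp (`min_hsp_sum`) and
amount to 33–75% of the read length. Full-span reads are exempt from the
75% cap — a flank+TE+flank read legitimately aligns over ~100% of its
length to the construct — and must instead show window-side and TE-side
HSPs within 50 bp of the junction on the read (a two-sided junction). This
quantitative rule replaces manual dot-plot inspection of candidate loci.

**Clustering and evaluation.** Validated signatures on the same chromosome
and family merge by single linkage when successive breakpoints are ≤100 bp
apart (`cluster_tolerance`). Call orientation is the majority of supporting
reads ("unknown" on ties); a call is `validated` only if every supporting
signature passed validation. Calls overlapping a self-detected reference
copy of the family (≥50% of the element covered by one chain) are flagged
`is_reference_copy` and excluded from precision/recall, which match calls
to truth within 50 bp, nearest first, each truth record at most once.

### Why the fraction window matters at low coverage

Only ~1 kb of flank can ever align to the construct (the window size), so a
read with a short flank and a long TE segment aligns over >75% of its
length and is rejected; a read with a very long flank aligns over <33% and
is likewise rejected. At low coverage (≈0.8X) many junction-overlapping
reads fail this geometry, so the number of *detectable* insertions is
governed by read geometry, not by the caller. The simulator therefore
provides a truth-side predicate (`read_is_detectable`) that applies the
same deterministic geometry (minimum block, block-fraction cap, minimum TE
overlap, HSP-sum window, full-span exemption) to a read's error-free origin
interval, with a small allowance (10% + 25 bp) for error-induced alignment
endpoint noise. Low-coverage recall is evaluated against insertions that
have at least one such qualifying read; the acceptance experiment
aggregates three seeds so this set is never empty.

## 5. Simulation

* **Genome**: i.i.d. random nucleotides at 36% GC (typical for a plant
  nuclear genome). No repeats, no homopolymer structure.
* **Elements**: a synthetic 5.3-kb LTR-retrotransposon-like element —
  random internal sequence bracketed by two identical 400-bp terminal
  repeats — and a synthetic 4-kb DNA-transposon-like element. Sequences
  are generated, not taken from any real TE.
* **Planting**: at each site the element (reverse-complemented for
  antisense insertions) is inserted with the preceding `tsd` bases
  duplicated after it (5 bp for the LTR element, 3 bp for the DNA element),
  emulating target-site duplication. Copy-paste leaves donors intact;
  cut-paste excises a stated donor interval. Random sites keep ≥20 kb
  separation and ≥10 kb from chromosome ends so junctions are separable at
  read scale.
* **Reads**: uniform start positions, 50/50 strands, log-normal lengths
  with median 4.6 kb, σ = 0.6, clipped to [100 bp, 50 kb]. Errors are
  applied per base at 13% total: ½ substitutions, ¼ single-base insertions,
  ¼ deletions. Read ids encode the true error-free origin
  (`sim_<i>:<chrom>:<start>-<end>:<strand>`), enabling truth-side analyses
  without alignment.

**Choice of σ = 0.6.** The emulated regime has a read-length *median*
(4.6 kb) well above its *mean* over all reads (≈2.8 kb): the raw-read pool
is dragged down by a large sub-500-bp junk fraction, not extended by a
heavy right tail. A spread chosen to match quantile statistics alone
(σ ≈ 1.45) implies a mean near 13 kb and floods a benchmark with >25-kb
molecules that do not exist in this regime. σ = 0.6 keeps the mean near
the median (≈5.5 kb). The junk fraction itself is *not* emulated — those
reads fail the 20% genomic filter by construction and only add runtime.

**Not emulated**: homopolymer-dependent error, quality-score correlation
with error, chimeric reads, base-composition bias, structural variation
other than TE insertion/excision, and pre-existing TE copies in the random
reference (the reference-copy flag is exercised by tests that plant a donor
copy explicitly).

## 6. Numerical and reproducibility choices

* All randomness flows from `numpy.random.default_rng(seed)` (or
  `random.Random` in tests); derived seeds are small fixed offsets of the
  user seed, reduced mod 2³¹. Identical configuration ⇒ byte-identical
  genomes, reads, and reports.
* The alignment kernel uses int32 scores with packed uint8 traceback
  pointers; scores are exact integers, so oracle comparisons are equality,
  not tolerance, checks.
* Greedy score-ordered chaining and greedy nearest-first truth matching
  break ties deterministically (score, then query start, then subject
  start; read id as the final key), so outputs are stable across platforms
  and hash orders.
* `median_lower` (no interpolation) avoids float platform differences in
  reported medians.

## 7. Known limitations

* Precision/recall figures come from synthetic genomes without repeats;
  real genomes add mapping ambiguity that the random model cannot show.
* The ab initio remainder search reports one family per read (best union
  length); nested or chimeric insertions are out of scope.
* Insertion-site resolution is limited by target-site duplication and
  chance micro-homology between flank and element ends: alignment
  endpoints shift by a few bases (typically ≤10, occasionally ~20 bp),
  which is why call matching uses a 50-bp window.
* `full_TE` reads are counted but deliberately produce no calls.
* The aligner guarantees optimal scores only on the exact path; the seeded
  path is heuristic (as any seeded aligner) and may miss alignments with
  no 11-mer exact seed, which at 13% error bounds sensitivity for
  segments ≲40 bp.
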