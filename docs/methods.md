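# Methods

## The analysis model

The pipeline treats a coIP-seq experiment as two unstranded read libraries
over one bacterial chromosome: a pull-down (IP) sample from a strain
carrying an epitope-tagged RNA-binding protein, and a mock control from an
untagged strain processed identically.  Both libraries are dominated by
the same abundant cellular RNAs (tRNA, rRNA); RNAs bound by the protein
are present at a higher *proportion* of the IP library.  Enrichment is
therefore a composition statistic, which is why peaks are compared by
RPKM ratio rather than raw counts: RPKM divides out both interval length
and library depth, so a ~7-fold difference in library size cancels.

All internal coordinates are 1-based inclusive; published peak tables in
this field print lengths equal to `end − start + 1`, and BED/bedGraph are
converted at the I/O boundary.  The chromosome is treated as linear; no
origin-spanning intervals are modeled.

### Peak definition

A peak is a maximal run of positions with depth ≥ `min_depth` (default 5,
inclusive) spanning at least `min_run` positions (default 50).  Design
choices worth stating explicitly:

* sub-threshold gaps of any size split peaks — no gap merging;
* peak boundaries are exactly the threshold run, not extended outward to
  the nearest zero-coverage position;
* the caller is implemented with a difference-array/prefix-sum pass,
  O(reads + genome), and is tested for exact equivalence against a
  position-by-position scan.

### Scoring

`rpkm(C, L, N) = C·10⁹/(L·N)`.  A read counts toward a peak when it
overlaps it by ≥ 1 bp; reads (~35 nt) are short relative to peaks
(≥ 50 nt), and any-overlap counting is simple and monotone.  The ratio
denominator uses `max(count_ctrl, 1)` (configurable pseudocount): strongly
bound RNAs can be entirely absent from the mock control, and the
pseudocount keeps their ratios finite while preserving ordering.  The
enrichment cutoff (default 2) is inclusive so that the
enriched/background partition is exhaustive.  By default the union of
intervals called in either sample is quantified in both samples; a flag
restricts quantification to IP-called intervals.

### Strand inference and classification

Strand is inferred from an independently mapped TSS table because the
library itself is unstranded.  A `+` TSS in `[start − w, end]` or a `-`
TSS in `[start, end + w]` (default window `w` = 500 bp) votes for its
strand; exactly one supported strand is required, otherwise the peak is
ambiguous.  Categories are assigned by first match:

1. **trna_rrna** — any tRNA/rRNA overlap (housekeeping signal is removed
   first, mirroring how such peaks are filtered before interpretation);
2. **srna** — overlap with an annotated sRNA;
3. **leader** — the inferred strand matches a TSS whose downstream
   same-strand CDS start lies within `leader_max_length` (default 500 bp,
   consistent with leaders typically running 150–400 nt), the CDS start is
   downstream of the peak, and the peak lies within `[TSS, CDS start − 1]`;
4. **orf_full / orf_start / orf_stop / orf_internal** — against
   strand-compatible overlapping CDSs (any strand when ambiguous), with
   start/stop codons defined as the terminal three coding bases in strand
   orientation.  A peak overlapping both codons without containing the
   CDS matches no rule;
5. **unknown** — everything else.

Ambiguous-strand peaks can still receive ORF categories by positional
overlap, but never the leader category, which requires oriented TSS
evidence.

## The synthetic experiment

The generator's defaults are the study conditions used throughout the
tests; they are fixed once, not tuned per test.

* **Genome**: 200 kb, single replicon.  Features: 32 plain CDSs (150–600 bp,
  codon multiples), 10 tRNAs (76 bp), 3 rRNAs (2.9 kb), 12 sRNAs
  (100–300 bp), 8 leader-bearing CDSs; non-overlapping with ≥ 100 bp
  spacing, random strands, placed with multinomially distributed gaps.
* **TSS**: at the 5′ end of every CDS and sRNA; leader-bearing CDSs get
  theirs 200–400 bp upstream.  This yields ~50 TSS per 200 kb, close to
  the ~600-per-4.2 Mb density of real bacterial TSS catalogs, which keeps
  strand inference informative without saturating the windows.
* **Leaders**: each leader splits into a structured 5′ domain (the part a
  pull-down of an RNA chaperone actually enriches, by analogy with
  riboswitch aptamer domains) and a 50–80 bp expression platform before
  the start codon carried only at baseline mRNA level.  The structured
  domain is the recorded truth region; the platform creates the coverage
  dip that separates leader peaks from their ORFs.
* **Libraries**: 100,000 IP and 15,000 control reads — the ~7:1 asymmetry
  of real mapped libraries at 1/100 scale so the pipeline runs in
  seconds.  Read length ~ Normal(35, 5) truncated at 20 nt.
* **Expression**: relative reads/kb class weights — housekeeping 600,
  mRNA 10, sRNA 20, leader domain 25.  Housekeeping RNAs thus dominate
  both libraries (high absolute coverage, ratio ≈ 1), baseline mRNA
  coverage sits just below the peak-calling depth threshold, and enriched
  candidates are visible but minor components of the control, as in a
  real mock pull-down.
* **Enrichment**: 20 candidate regions (12 sRNAs + 8 leader domains) with
  folds cycling through {5, 20, 100}.  Per-region read counts are Poisson
  with rates proportional to mass = weight × length, normalized *within
  each sample* (the IP normalization includes the folds) so each
  library's expected total equals its configured size: sequencing depth
  is fixed by the instrument, and immunoprecipitation changes library
  composition, not yield.  A consequence worth knowing: strong enrichment
  of some regions slightly depresses the realized ratio of everything
  else (by the IP normalizer, ≈ 1.5× under the defaults), exactly as in
  real RPKM-ratio analyses.  Poisson counts carry no overdispersion
  because the emulated experiment has a single replicate per condition
  and provides no dispersion information.
* **Noise**: a uniform genome-wide floor of 1% of each library
  (truncated-normal lengths, clipped at the genome end).  This stands in
  for nonspecific background; no model of the mock control's true noise
  structure is implied.
* **Determinism**: one `numpy` Generator seeded from `seed` drives
  placement; a second, derived via `SeedSequence([seed, 1])`, drives read
  simulation.  Same seed ⇒ byte-identical outputs.

### What the simulator does not model

Base-level sequence, sequencing error, adapter contamination, paired-end
reads, replicates, overdispersion, transcription bleed-through between
adjacent genes, and enriched ORF fragments (degradation intermediates or
sRNA pairing sites).  Passing the recovery tests therefore demonstrates
that the implementation is correct under the stated generative model, not
that the thresholds are optimal for any particular real library.

## Numerical and edge-case choices

* Depth threshold and ratio cutoff are inclusive (`≥`).
* Empty read sets, empty peak lists and empty summaries are legal inputs
  and produce empty outputs, not exceptions.
* Reads with the SAM unmapped flag or mapping quality 0 are dropped; MAPQ
  0 is the conventional marker for multi-mapped reads, matching an
  analysis restricted to unambiguously mapped reads.  The
  `total_mapped` denominator is the retained-read count.
* Peak-table ratios are printed to 3 significant figures; round-trip
  equality is defined at the printed precision.
* Overlap queries use an interval tree; read counting uses sorted-array
  bisection; both are cross-checked against brute-force enumeration in
  the tests.

## Problem sizes used in the checks

The acceptance checks run at the generator's default scale: single runs
and 20-seed/50-seed ensembles of the 200 kb genome with ~115,000 reads per
replicate, which keeps the full suite under a minute on one CPU.  The
null-calibration bound (mean truth-region ratio in [0.8, 1.2], < 5% false
enrichment) and the recovery bound (≥ 90% of the 20 candidates recovered
at Jaccard ≥ 0.5 with ≥ 90% correct categories among non-ambiguous peaks)
hold with margin under these conditions; the dominant failure mode at
much smaller library sizes would be control-count noise around the
pseudocount, not the peak caller.
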