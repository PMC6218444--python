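# Methods

## Coordinate frame and scope

All analysis happens in transcript space: coordinates are 0-based
half-open on the mature transcript, 5′→3′, with an optional
UTR5/CDS/UTR3 partition.  Genome alignment and splicing are upstream
concerns; the enrichment quantification at the package's core operates
on per-gene read counts, which transcript space captures without
alignment machinery.  BAM ingestion and genome-space operations are
deliberately out of scope.

## Peak calling (a documented stand-in)

The window caller replaces an external beta-binomial HMM caller with a
transparent test.  Reads are extended 3′ to `fragment_length`
(default 200 nt, the conventional MeRIP fragment size used as a peak
caller parameter) and clipped at transcript ends; replicate coverages
are summed.  Windows of 100 nt, stepped by 50 nt, are tiled per
transcript (transcripts shorter than one window contribute a single
whole-transcript window).  Window counts `a_w` (IP) and `b_w` (input)
are the *mean* per-position coverage in the window, which is robust to
window truncation at transcript ends.  The test is a one-sided binomial
upper tail of `round(a_w)` against `n = round(a_w) + round(b_w)` at
`p0 = libIP / (libIP + libIN)`, BH-corrected across all windows of the
run.  Windows pass at q ≤ `fdr` (0.05), library-size-normalized ratio ≥
`min_fold` (2), and IP count ≥ `min_ip_count` (10), and merge when
separated by ≤ `max_merge_gap` (0) nt; peak score is the max window
ratio, peak q the min window q.

Assumptions and caveats: the binomial model treats mean coverage as a
read count and windows as independent; both are approximations.  They
are adequate here because (i) the generative model gives IP and input
of a sample identical gene-level composition under the null, and (ii)
downstream quantification re-counts raw reads inside union peaks, so
the cross-condition results are insensitive to the caller's internals.
The false-positive behaviour of the test is itself measured (null
simulation, below).

How replicates are combined was an open choice; coverage is summed
before testing (equivalent to pooling reads), which favours power over
replicate-consistency filtering.

## Union-peak enrichment quantification

Peaks from all conditions are merged into maximal disjoint union
intervals per transcript; each interval records the contributing
conditions.  A peak called in any single condition is kept — the point
of the union is that every condition is then quantified over identical
regions.

For each (union peak, condition, replicate): `a` and `b` are the raw
read intervals (no fragment extension — the quantification counts
*reads*) overlapping the peak by ≥ 1 nt in the IP and input library,
`c` and `d` are each library's median read count over 100-bp windows
stepped by 50 nt across the peak's gene.  The median uses the mean of
the two central order statistics for even window counts.  The window
step is a package choice (the background is described as "sliding"
without a step); both window and step are configurable.  Background
windows include the peak region by default — the median is robust to
the few peak windows — with an exclude-peak toggle for sensitivity
analysis.

Normalization is counts per million mRNA-mapped reads.  Ratio-of-totals
scaling would differ only by a global constant that cancels in every
fold-enrichment ratio.

**Pseudocount.** When either member of the (a, b) pair — or of the
(c, d) pair — is zero, 0.5 raw-count units are added to *both* members
of that pair before normalization.  This keeps ratios and logs finite,
leaves fully observed pairs untouched, and preserves the identity
`fe_windowed = fe_simple × (d/c)` exactly (it is asserted to 1e-12 in
the tests).

Replicate fold enrichments are combined by arithmetic mean (any
replicate count).  Cross-condition change per peak is
`log2 fe_g2 − log2 fe_g1`; peaks quantified in only one condition are
reported separately, never silently dropped.  Per-sample summaries are
the mean and median fe across peaks; no statistical test is attached to
the Δ distribution — it is reported as summaries and a histogram.

**Compositional caveat.** CPM normalization makes peak enrichments
compete for library mass: when many sites lose methylation, IP reads
redistribute to the remaining methylated peaks, nudging their fe
upward.  The *mean* summary therefore responds robustly to global
demethylation, while the *median* can sit near the breakpoint when
close to half of the peaks are affected.

## Annotation

Segment assignment is majority-overlap with ties broken CDS > UTR3 >
UTR5 (single-label assignment, as pie-chart fractions require); peaks
on noncoding transcripts form a fourth category.  The metagene profile
maps peak *midpoints* (not full intervals, and without per-transcript
coverage weighting) to a tripartite axis where 5′UTR, CDS and 3′UTR
each span one unit interval; the density integrates to 1 over [0, 3).
Motif scanning counts occurrences at every start position (overlaps
allowed) of the four canonical m6A 5-mers, or of the degenerate DRACH
class pattern, on the RNA alphabet (T mapped to U on input).

## Expression integration

Per-gene Welch (unequal-variance) two-sample t-tests on log2
intensities; a gene is called up (down) when the *linear-scale* ratio
of group means is ≥ 1.5 (≤ 1/1.5) and p < 0.05.  No multiple-testing
correction is applied by default — matching the original microarray
criteria, which use a plain per-gene threshold — with BH adjustment
available as a flag.  Overlaps with an m6A gene set are plain set
intersections per direction, reported as counts and percentages.

## Decay kinetics

Relative expression is 2^−ΔCT against a stable reference gene.
Percent remaining at time t after transcription shut-off is
100 × 2^−(ΔCT(t) − ΔCT(0)); replicate CT wells are averaged in CT space
before transformation, and the t = 0 value is exactly 100 by
construction.  The half-life is fitted by least squares on ln(percent)
vs t — a deliberate extension, since percent-remaining curves are the
primary readout — with t½ = ln 2 / |slope| and r² from the regression.
A fitted slope ≥ −10⁻³ h⁻¹ is flagged stable (infinite half-life, rate
0); nonpositive percents or fewer than 3 timepoints are rejected.

## The synthetic generator

The generator emulates the study design the analysis assumes: ~100-nt
chemical fragmentation, antibody IP, single-end 50-bp reads (the 5′ end
of each fragment), two replicates in each of three conditions
(parental, resistant, resensitized), at 5×10⁵ reads per library over
100 genes by default.

* **Transcriptome** — lengths uniform on 500–3000 nt, 10% noncoding,
  coding transcripts split ~10/60/30% into UTR5/CDS/UTR3.  Candidate
  m6A sites are planted GGACU motifs at ~1 site/kb, ≥ ~350 nt apart and
  ≥ 50 nt from transcript ends so that fragments covering a site always
  fit; chance GGACU occurrences elsewhere are mutated away so the
  planted set *is* the candidate set and the truth table is exact.
* **Methylome** — each candidate site is methylated (level 1.0) in the
  parental condition with probability `methylation_rate` (0.5); a
  `demethylation_fraction` (0.5) of methylated sites drops to level 0
  in the resistant condition.  The demethylation fraction has no
  literature-anchored value; 0.5 gives a clearly identifiable global
  shift.  The resensitized condition restores the parental methylome
  (partial restoration is a knob).
* **Libraries** — genes are drawn proportional to a log-normal
  expression profile (sd 1 log2 unit); fragment starts are uniform
  within a transcript for input, and weighted
  `1 + (ip_enrichment − 1) × level` (enrichment 8) where the fragment
  covers a methylated site for IP.  Gene-level gamma noise (NB
  overdispersion 0.05) is drawn once per (condition, replicate) and
  shared by that sample's IP and input libraries: both are aliquots of
  one fragmented mRNA pool, so their gene-level fluctuations are
  common.  This coupling is what makes the window test's null hold.
* **Expression matrix** — microarray-style log2 intensities for 4
  samples per group; 20 planted up-regulated genes (fold 2) are drawn
  preferentially from genes that lose methylation, modelling
  stabilization-driven expression gain; Gaussian noise sd 0.2 log2.
* **Decay courses** — CT rises one cycle per halving
  (CT(t) = CT(0) + t/t½) against a flat reference, measured in
  technical triplicate wells per timepoint with Gaussian CT noise.
  Triplicates are the generator's default measurement design: with
  singlet wells at 0–8 h and CT noise sd 0.1, the log-linear slope
  carries ~9% relative error and no estimator recovers t½ within 10%
  reliably; triplicate averaging brings this to ~5%.

Everything is deterministic given the seed, including the on-disk
files.  What the generator does **not** model: sequencing errors and
quality, positional/GC bias, isoform structure, partial methylation
levels between 0 and 1, antibody off-target capture, and
fragment-length variability.  Passing tests therefore demonstrate the
correctness and calibration of the computation under a clean generative
model, not robustness to every artifact of real libraries.

## Problem sizes and runtime

The default study used by the tests and the acceptance script is 100
genes × 12 libraries × 5×10⁵ reads; oracle-equivalence checks run 500
randomized instances; half-life recovery uses 500 simulated courses.
The full test suite and the acceptance script each complete in well
under a minute on a single CPU.

## Known limitations

* The caller is a pragmatic stand-in, not a reimplementation of an HMM
  peak caller; absolute peak boundaries are coarse (window-resolution,
  widened by fragment extension).
* fe values depend on peak width relative to the true enriched
  footprint; the generator's planted 8× capture ratio appears in peak
  fe as ~2–3× because called peaks are wider than the enriched region —
  the cross-condition *contrast* is the designed readout.
* The median summary statistic is unstable when ~50% of peaks change
  (see compositional caveat above).
* Differential *peak* testing between conditions is intentionally
  absent; cross-condition comparison goes through the enrichment fold
  change.
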