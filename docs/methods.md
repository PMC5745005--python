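# Methods

## Promoter discovery by chromatin–expression correlation

**Model.** The locus of interest is tiled into fixed-size bins (default
500 bp; the final partial bin is kept so bins conserve window coverage).
For each histone mark and each cell type, a bin's score is the maximum
signalValue (fold-enrichment, narrowPeak column 7) among peak calls
overlapping the bin by ≥ 1 bp under half-open interval intersection;
absence of a peak scores exactly 0. Zero therefore means "no called peak",
not "no signal": sub-threshold enrichment is deliberately not rescued,
because the upstream peak caller's threshold is part of the measurement.
Replicate experiments on the same cell type are combined by arithmetic
mean, zeros included. Coordinates are 0-based half-open throughout, the
native BED/narrowPeak convention.

Target expression is the length-scaled measure 1000·tpm/length (an
RPKM-like per-nucleotide density), summed over the target's sense-strand
exon entries and replicate-averaged the same way. Per bin, the statistic
is the Pearson correlation r between the bin's enrichment vector and the
expression vector across cell types, computed on the raw (untransformed)
values. Bins whose enrichment vector has zero variance have no defined r;
they are flagged undefined, excluded from null pools, and can never be
significant.

**Empirical null and FDR.** The null distribution of r under zero-inflated,
heavy-tailed enrichment does not follow the textbook parametric form, so
the null is estimated empirically: the identical per-bin statistic is
computed over decoy windows (±50 kb around genes chosen to have no
relationship to the target) and pooled per mark across all decoy windows
jointly. The per-mark threshold r\* is the (1−q) quantile of this pool,
q = 0.005 by default. The quantile uses linear interpolation between order
statistics at the Weibull plotting position ((n+1)p): with that estimator
the probability that a fresh null draw exceeds r\* equals q in
expectation, so the realized false-call rate on signal-free bins matches
the nominal q even for pools of a few hundred bins (the default plotting
position (n−1)p would overshoot by ~30% at q = 0.005 on a 600-bin pool).
Thresholding is one-sided — only large positive r is called, since the
hypothesis is activation; repressive marks (H3K27me3) are ingested for
description but never thresholded. Ties at r = r\* are not significant.

**Region calls.** A bin is significant for a mark iff its defined r
strictly exceeds that mark's r\*. Promoter calls are maximal runs of
index-consecutive bins significant for both H3K4me3 and H3K27ac; enhancer
calls are maximal runs significant for both H3K4me1 and H3K27ac excluding
bins already inside promoter calls. A single bin is a valid region. As a
model check, decoy-gene expression is correlated against the target
(Pearson r with the two-sided t-approximation p-value); any decoy with
p < 0.05 raises a warning because a target-coupled decoy would distort the
null.

**Open choices made here.** Decoy windows and the target window are each
tiled from their own start (bin phase is not synchronized — nothing in the
statistic depends on phase alignment). Every bin passing r\* is reported
rather than a fixed top-N with unspecified tie handling. Zero-variance
decoy bins are excluded from pools and counted in the log.

## Split-read junction discovery

**Algorithm.** Each transcriptome-unaligned read is cut into two k-mers:
mate 1 = read[0, k) and mate 2 = read[O, min(O+k, L)), defaults k = 20 and
O = 50 for ≥76-nt reads (O = 30 for 50-nt reads). Reads with either mate
≤ 18 nt are rejected (counted, not errors). Mates are located on the locus
window — both as-is (+ strand) and reverse-complemented (− strand) — by an
internal exact-match locator; a one-substitution mode extends each search
by anchoring on the error-free half of the mate. Exact matching of
19–20-mers on a ≤210-kb window is near-lossless and fully deterministic,
which is why it replaces an external seed-and-extend aligner here; an
N-containing mate in exact mode is simply unplaced.

Among all same-strand joint placements the one minimizing |d − O| is
selected (ties: smallest p1), i.e. the most parsimonious,
contiguous-favoring explanation; reads whose mates generate more than 10
combinations (low-complexity sequence — the focal exon carries dozens of
repeated miRNA seed matches) are unplaced. All geometry is computed in
transcript orientation of the target strand, so upstream/downstream are
meaningful for both + and − strand loci. Classification: d = O contiguous;
d > O forward splice with intron span d − O; d < O back-splice candidate.
The relation to the focal exon follows from the mate positions against the
exon's acceptor and donor: a back-splice with both mates inside the exon
in reversed order spans the circle junction; a forward splice from
upstream sequence into the acceptor, or from the donor into downstream
sequence, marks cryptic flanking exons.

**Known-junction matching.** A pseudo-pair spanning junction
(donor t_d, acceptor t_a) satisfies d − O = t_a − t_d, with mate 1 ending
by the donor and mate 2 starting at or after the acceptor. Calls matching
a known junction within ±2 nt are "explained"; the tolerance exists
because pseudo-mates bracket, rather than pinpoint, the breakpoint.
The re-discovery control — withholding the known circle junction from the
annotation and confirming its reads return as novel back-splices — is the
positive control for the whole pipeline.

**Blind spot.** A junction is observable only if its in-read breakpoint b
lies in [k, O]: outside that interval the breakpoint falls inside a mate,
the mate is chimeric, and (at exact matching) the read goes unplaced —
sensitivity is 0 by construction there. Breakpoints 1–2 nt outside [k, O]
occasionally still place when the reference coincidentally continues the
flank; the ±2-nt tolerance absorbs these as correct detections. The
simulator's truth labels record per read whether b is observable, so
recovery is always measured against the observable set.

## Synthetic data

**Cohort generator.** Defaults emulate the 34-cell-type matched
ChIP/RNA compendium the scan is designed for: a 175-kb target window in
500-bp bins (350 bins) and three 100-kb decoy windows (200 bins each).
Log-expression is Gaussian (location 2.0, scale 1.0 — roughly two orders
of magnitude of dynamic range). Enrichment per bin/sample comes from a
latent standard normal z mapped through exp(1.5 + 0.5·z) (median ~4.5-fold,
heavy right tail) and censored to 0 when z falls below the zero-inflation
quantile (default 0.3, matching the many-zeros phenomenology of narrowPeak
matrices). Planted bins share a Gaussian copula with the log-expression
latent at population correlation ρ (default: one 4-bin promoter block at
ρ = 0.8 on H3K4me3 + H3K27ac); censoring is tied to the same latent, so
peaks drop out exactly in low-signal samples, as real peak calls do.
Decoy and background bins are independent of expression. Note the raw-scale
Pearson r of a planted bin is attenuated below ρ by the exponential
marginals and the censoring; at ρ = 1 and equal log-scales the mapping is
exactly proportional and r → 1.

What the generator does *not* model: spatial autocorrelation between
neighbouring bins, mark-to-mark dependence within a cell type, batch
structure across ENCODE labs, and lognormal-mismatched expression noise.
Passing recovery tests therefore demonstrates the statistic and its
calibration under the designed sampling model, not robustness to every
correlation structure of real compendia.

**Read generator.** A uniform-random toy locus (default 5 kb) with a focal
exon at [2000, 3350) and three planted junctions (upstream cryptic donor
1000→2000, downstream 3350→4000, and the 3350→2000 circle junction).
Reads (default 76 nt, 2000 reads, class mixture 0.5/0.25/0.25
contiguous/forward/back) are drawn uniformly for contiguous reads; junction
reads concatenate donor-side and acceptor-side sequence with the
breakpoint uniform in [1, L−1]. Substitutions are i.i.d. per base (default
rate 0.002, Illumina-like); indels, quality scores, coverage and GC biases
are out of scope. Truth tables record class, junction, breakpoint and
observability, so evaluations never re-derive labels. Both generators are
byte-identical under a fixed seed.

## Problem sizes

The recovery and calibration runs use 100 and 1000 simulated cohorts
respectively (34 samples × 950 bins × 2–3 marks each) and 10⁴ reads on the
5-kb toy locus — sizes at which the Monte-Carlo error of the reported
rates is well below the margins being checked, while a full run of the
test suite and the acceptance script completes in well under a minute
each.

## Known limitations

* The promoter scan inherits the upstream peak caller's detection
  threshold; truly thresholded-out signal is invisible.
* The empirical FDR is per mark; co-significance rules are conjunctions of
  per-mark calls without an additional joint multiplicity correction.
* Junction discovery establishes the existence and approximate geometry of
  splices; it does not resolve breakpoints to the base, assemble
  transcripts, or handle indels.
* Gene-level sums and junction CPM take quantifier output at face value
  (no bias correction or bootstrap uncertainty). Sequencing depth for
  junction normalization is defined as total est_counts over the reference
  index; that choice is recorded in output metadata.
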