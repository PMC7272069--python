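# Methods

This note documents the models, conventions and numerical choices behind
`msdart`, and what the synthetic-data generator does and does not emulate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open.  BED is read and written
as-is; GFF3 and cytosine-report positions (1-based) are shifted by −1 on
the start on load.  BAM/SAM alignment spans are the reference bases
consumed by the alignment (CIGAR M/D/N/=/X), ignoring soft clips; strand
comes from the single-end orientation flag.  A MAPQ threshold is available
on the alignment loader but defaults to off (the file is taken as given).

## Restriction model and tag geometry

Enzymes are defined by recognition sequence, top/bottom-strand cut offsets
from the recognition start, and 5mC-blocking flags.  Conventions:
PstI CTGCA^G (top cut at start+5, bottom at start+1); MspI/HpaII C^CGG
(top at start+1, bottom at start+3).  All supported enzymes are
palindromic, so forward-strand scanning (with IUPAC classes expanded to
character classes, overlapping matches reported) finds every site.

Two fragment-coordinate conventions coexist and are both exposed:

* **cut coordinates** (default in `digest.predict_fragments`): fragment
  boundaries are the top-strand cut positions of the flanking enzymes.
* **tag coordinates** (`coordinates="tag"`): the read-strand retained
  sequence.  A rightward (‘+’) tag runs from PstI start+1 (reads begin
  with the TGCAG remnant) to CCGG start+1; a leftward (‘−’) tag runs from
  CCGG start+3 to PstI start+5.  MSD-tags use this convention, and the
  simulator's tag universe is defined in it, so the cross-module
  equivalence with fragment prediction is exact on intervals.

Only "mixed" fragments — one PstI end, one MspI/HpaII end — are retained;
the 100–600 bp size window is applied where the analysis calls for it
(colocalization, simulator sequenceability) and omitted otherwise.

Fragment-size deciles use linear interpolation between order statistics;
the standard deviation is the sample (n−1) estimate.  The two-sample
Kolmogorov–Smirnov comparison of size distributions uses a pooled-sample
bootstrap (resampling with replacement, sample sizes preserved, default
1,000 resamples) because the distributions are discrete; the p-value
carries a +1/+1 pseudocount and is therefore bounded below by
1/(n_boot+1).

## Tag derivation and counting

An alignment anchors a tag iff its read-strand 5′ end coincides with a
PstI boundary (tolerance 0 by default; a ±1 bp option exists because
end-repair chemistry can shift the observed start).  The terminating CCGG
is the first site whose read-strand boundary lies at or past the
alignment's 3′ end: a read extending past a CCGG implies that site was
uncut in that molecule, so the tag skips it.  Each (anchor, strand,
terminating CCGG) triple is one tag; the tag universe is the union over
all samples and libraries.  Reads are assigned to tags by the same
(anchor, first CCGG ≥ 3′ end) rule, so nested tags sharing an anchor never
compete for a read; unanchored reads go to a spill counter.

The nested-tag count correction — adding each longer tag's counts to every
shorter tag nested at the same anchor, per column — is provided as an
explicit, idempotence-guarded post-step (`correct_overlap_counts`,
`nested`/`off` in the workflow).  It makes a tag's count match the total
read evidence for its MSD-site from that anchor; with the anchored
assignment rule above it is redundant for disambiguation but kept as the
default to mirror the assay’s established counting convention.

Site-level status aggregates tag-level calls with an ANY rule (a site is
methylated if any associated tag is called); ALL is available.

## Methylation calling

Counts are normalized by median-of-ratios size factors (per-tag geometric
mean reference, zero-free tags only, factors scaled to geometric mean 1;
TMM available; total-count fallback with a warning when no zero-free tag
exists).  Both tests share the factors.

**Exact conditional NB test.**  Per-tag dispersion is estimated by
conditional maximum likelihood on size-factor-equalized pseudo-counts over
a log-spaced grid (1e-6…10, 57 points), shrunk toward the common
dispersion by weighted likelihood with prior df 10.  Given the dispersion,
the two library group sums are NB with sizes n_g/φ; conditioning on their
total cancels the mean and gives an exact distribution over the split,
from which a two-sided p-value is taken by doubling the smaller tail
(capped at 1).  As φ→0 this converges to the binomial split test.

**NB log-linear Wald test.**  Per tag, a log-link NB model with a library
indicator; group means are fitted by Newton iterations on the score with a
floor of half a read of total evidence so the fold change stays finite
when a group is all-zero.  Tag-wise profile-MLE dispersions are shrunk
log-normally toward a parametric trend α(μ)=a0+a1/μ (least squares on
informative tags, one robustness pass; tag-wise MLE fallback below 50
tags).  The prior variance is the variance of log-residuals minus the
trigamma sampling variance, floored at 0.25.  The Wald statistic uses the
observed-information standard error of the fitted log fold change.

A tag is called methylated iff both BH-adjusted FDRs are ≤ fdr_max *and*
log2FC ≥ min_log2_fold_change in the configured direction (defaults 0.05
and 1, i.e. FC ≥ 2).  The reverse direction (HpaII > MspI) uses the same
machinery and labels passing tags `reverse_significant`.  BH runs per
test, per tissue, over the tags surviving the filters.  The two tests are
deliberately of different construction; agreement of both is the contract.
Bit-compatibility with any particular differential-count package is a
non-goal — calibration (≤1% null calls at defaults) and recovery
(precision ≥0.95, recall ≥0.80 on 8-fold suppressed planted signal) are
the tested properties.

Filters mirror the assay workflow: tags must have ≥1 MspI read in every
tissue (no-missing rule), and the MspI evidence must reach min_count
(default 3) under the configured scope — default `tissue_total`, the
weakest reading of a "minimum depth" filter; `tissue_mean` and
`per_replicate` are available.  The parameter grid evaluates
FDR {0.05, 0.01, 0.001} × FC {1, 2} × min-count {3, 5, 10} against WGBS
states and selects, among combinations within 0.01 of the best validation
rate, the one calling the most sites (ties to the stricter FDR).

## WGBS validation

Per cytosine, the p-value is the upper binomial tail
P(X ≥ m | n, non-conversion rate); BH runs across every cytosine in the
report (the whole methylome is called first), and a cytosine is methylated
at FDR ≤ 0.01 with ≥ 3 reads.  The non-conversion rate is a required
input, estimated upstream from an unmethylated control (e.g. chloroplast
reads); no internal estimation is attempted.  A site's state comes from
its two internal CG cytosines (both methylated → fully; one → hemi, side
recorded; neither → unmethylated; either side under 3 reads → not
assessable); CHG records are never consulted for the state.  Concordance
restricts the denominator to called sites assessable by WGBS.

## Context classification and statistics

Sites (the CCGG interval) are assigned exactly one category in decision
order: overlapping genes; TE overlapping a gene (the TE intersects
exon/UTR space or straddles a gene boundary — kept conservative because
such overlaps often flag annotation errors); inside one gene (UTR takes
precedence over exon; exon; otherwise intron, or TE-in-gene when the
position also lies in a TE wholly contained in intronic/UTR space); TE in
intergenic space; intergenic.  Distances are edge gaps, 0 if overlapping.

Colocalization shuffles reposition query intervals uniformly within their
own chromosome, preserving lengths and counts and permitting overlaps;
metrics are intersection-segment count and intersected bases against the
merged reference set, with empirical upper-tail p-values (+1/+1
pseudocount).  Cochran's Q, exact pairwise sign tests (BH-corrected),
chi-square association with Pearson standardized residuals
(obs−exp)/√(exp·(1−row_frac)(1−col_frac)), the one-sided Fisher
genic-bias test, window-uniformity chi-square tests (expected proportional
to window length; a warning below 5 sites/window) and 10-kb
distance-to-feature profiles (1-kb bins against the background CCGG
distance distribution, empty expected bins floored at 0.5 with a warning)
complete the battery.

## Simulator: what it emulates, and what it does not

The generator plants CTGCAG and CCGG motifs at spaced random positions in
an i.i.d. background at 40% GC (accidental motif occurrences are scrubbed
first; planting is verified to introduce no extras), with CCGG placement
enriched in genic space (default 60%) to emulate the assay's bias toward
hypomethylated, gene-rich regions.  Defaults reflect the study conditions:
three tissues × three replicates, 77 bp single-end reads, mean tag depth
30, NB dispersion 0.05, a 100–600 bp sequenceable window, bisulfite
non-conversion rate 0.005 and mean WGBS coverage 30.  Roughly 18% of CCGG
sites carry internal methylation (15% fully, 3% hemi, reflecting the large
fully:hemi imbalance such assays observe); external CHG methylation
co-occurs with internal methylation (P=0.2 given methylated, P=0.002
otherwise), because CHG-only CCGG sites are rare in plant genomes; PstI
sites are methylation-blocked with probability 0.05; non-reference tissues
flip each site's internal state with probability 0.03.  Methylation states
are per-site-per-genome (a homogeneous molecule population) — cell-type
mixtures within a sample are not modeled.

Enzymology per molecule: PstI cuts unless blocked; MspI cuts CCGG unless
the external cytosine is CHG-methylated; HpaII additionally requires the
internal cytosine pair to be unmethylated (hemi-methylation blocks it).
The realized fragment from each anchor runs to the nearest cuttable CCGG,
so methylation-skipped sites lengthen HpaII fragments, often past the size
window — exactly the signal the caller detects.  Replicate counts are
NB (gamma-Poisson); dispersion 0 is a deterministic degenerate mode that
emits exactly the rounded mean, giving a noise-free setting in which the
derived tag universe, site set and counts must equal the planted truth
bit for bit.  The WGBS report covers the four cytosines of every CCGG site
(internal CG pair, external CHG pair) rather than the whole genome; reads
are error-free apart from the non-conversion and bisulfite-error rates,
and PCR duplicates, adapter chimeras and base-level sequencing errors are
not modeled.  Passing tests on this generator therefore demonstrate the
pipeline's logic and statistical calibration, not robustness to mapping
artifacts or library-preparation pathologies in real data.

Known limitation: a CCGG site whose external cytosine is CHG-methylated
while its internal pair is unmethylated is invisible to both enzymes; the
77 bp reads of the MspI skip-fragment are then attributed to the tag
ending at that site while the HpaII fragment may leave the size window,
producing a confident but WGBS-unconfirmed call.  The co-occurrence model
keeps such sites rare, matching their rarity in real plant methylomes, but
the attribution artifact is inherent to fixed-length tag counting.

## Problem sizes

Tests and the acceptance script run at desk scale: two 200-kb chromosomes
(≈400 CCGG and 240 PstI sites), ~90k reads, and 2,000-tag count matrices
over five seeds for caller calibration/recovery.  These sizes were chosen
so every stochastic bound is measured on thousands of tags while the whole
suite completes in minutes on one CPU.
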