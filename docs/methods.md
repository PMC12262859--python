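# Methods

## The problem and the model

Plasma cfDNA is a mixture: in a tumor-bearing organism it contains both
tumor-derived ctDNA and cfDNA from non-tumor (largely hematopoietic)
cells. Fragmentation features — fragment size, end motifs, breakpoint
context, binned coverage — differ between these streams, but in patient
plasma they cannot be separated. In a xenograft the two streams come from
different genomes, so they can be isolated bioinformatically and
characterized independently. `xenofrag` implements that workflow, together
with a generative model rich enough to exercise every stage without any
external data.

The study design is fixed at 2 tumor cell lines x 2 implantation sites x 3
replicates (12 CDX samples) plus 3 tumor-free controls. The scientific
contrast of interest is factor recovery: fragment-size effects placed on
the host cfDNA by *cell line* and on the ctDNA by *site* should be
detected by the permutation machinery for the matched factor and not for
the swapped one.

## Fragment-length model

Each population's fragment lengths are drawn from a discrete distribution
over integer bp in a support window (default 50–420 bp), built from:

* an asymmetric exponential kernel around the mode — slow decay below
  (`tail_left`, default 18 bp host / 20 bp tumor), fast decay above
  (`tail_right`, 7 / 9 bp) — mimicking the steep right shoulder of the
  mononucleosome peak;
* a cosine comb below the mode with the population's period (10 bp host,
  7 bp tumor) and depth (0.55 / 0.6), producing the nucleosome-protection
  ladder of local maxima at mode − k·period;
* a smooth logistic short-fragment boost (`short_boost`, 1.0 host / 1.8
  tumor) that reaches full strength well below the mode and fades out
  about two periods beneath it. The fade-out is deliberate: a hard cutoff
  just below the mode creates a spurious global maximum and displaces the
  modal length, contradicting the defining property of the profile
  (host mode 167 bp, tumor mode 143 bp);
* a Gaussian dinucleosome bump at twice the mode (mass 0.04 / 0.02,
  sd 25 bp) and a 2 % uniform floor so inter-nucleosomal sizes are
  populated.

Group-specific FSD effects are multiplicative enrichments of a length
range, applied to the pmf before renormalization. The defaults place the
effects at the ranges the analysis is designed to detect: on host cfDNA,
150–174 bp x1.25 for one cell line and 220–309 bp x2.0 for the other; on
ctDNA, 120–129 bp x2.0 for pancreas and 185–214 bp x1.8 for rectum.
Multipliers were chosen once, by a power sketch at the default cohort
scale, to give clearly detectable but not degenerate effects; they are
ordinary parameters of `CohortDesign`.

## Cohort generation

Controls contain host fragments only. Each CDX sample draws its ctDNA
fraction log-uniformly from [0.0021, 0.1896] (the fractions span two
orders of magnitude, making a log-uniform draw the natural
maximum-ignorance choice over the known range) and splits its
400,000 fragments binomially between graft and host. The default depth is
a deliberate scale-down of the real experiment (~10^8 fragments per
sample) chosen so that a full 15-sample cohort generates in ~2 s while the
lowest-fraction samples still carry several hundred ctDNA fragments —
qualitatively the regime of the original design, where even the
lowest-fraction sample contributed ~3x10^5 ctDNA fragments.

Host fragments are placed uniformly within chromosomes; graft fragments
are placed bin-wise, with per-1 Mb-bin weights multiplied by the sample's
cell-line CNA profile (segments in fractional chromosome coordinates;
defaults give each cell line one gain and one loss). Fragment end motifs
are read from the generated reference at the sampled positions, so motif
spectra reflect reference composition plus placement bias; no mutation or
nuclease-preference model is layered on top.

Two classifiers ("A", "B") emit per-read verdicts in
{human, mouse, both, neither} with independent per-read errors:
sensitivity P(human | graft) of 0.98/0.95 and false-human rate
P(human | host) of 0.012/0.008. Host reads mislabeled human are assigned a
human-genome alignment inside fixed per-chromosome homology windows — the
synthetic analogue of mouse reads mapping to homologous human loci. The
same mechanism acting on control samples is what the blacklist is built
from, so with default noise the isolated ctDNA is nearly pure, and with
`zero_noise` it equals the generative truth exactly. A 3 % low-MAPQ rate
(MAPQ drawn in 0–29) exercises the quality filter.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning; identical (design, genomes, seed) re-runs are byte-identical.

## Isolation logic

The blacklist rule evaluates support per base: a position is blacklisted
iff covered by merged human-prone regions of at least two distinct control
samples or at least two distinct methods; maximal blacklisted runs become
intervals (verified against a per-base brute-force oracle in tests).
Candidate ctDNA alignments are the union of reads called human by either
method. Filtering removes alignments with MAPQ < 30 or any overlap (>= 1
bp) with a blacklist interval — the strictest reading of "not falling
within" the blacklist; because the module invariant forbids any retained
fragment from overlapping the blacklist, the filter is applied to the
fragment-span alignments before mate-pair expansion. Fragments are the
outer span of each mate pair; pairs with discordant chromosomes and
orphaned reads are skipped with logged counts, and lengths outside
[50, 1000] bp are dropped. The host stream is the complement (reads never
called human) with the same MAPQ/length rules; the blacklist is a
human-genome construct and does not apply. Downsampling is uniform without
replacement; an overshooting target returns everything with a warning so
small synthetic runs stay usable.

## Features

* **S2L**: inclusive windows, 80–160 over 161–200 bp; a zero long-count is
  an explicit error, not 0 or infinity.
* **Size histogram**: integer counts; modal length breaks ties toward the
  smaller length.
* **Periodicity**: centered 3 bp moving average, then local maxima in the
  90–160 bp search window; peaks must have prominence >= 15 % of their own
  height (an absolute prominence threshold would drop the small deep-tail
  peaks while a pure local-maximum rule admits Poisson wiggles); the
  estimate is the mean spacing of successive peaks, requiring >= 2 peaks.
* **Motifs**: both ends are reported 5'->3' into the fragment. EDM is the
  first 6 reference bases inside each end (downstream end
  reverse-complemented); BPM spans the break, 3 bases outside + 3 inside.
  Windows off the chromosome or containing N are skipped and counted; the
  denominator excludes them. All 4,096 keys are always present.
* **FSD**: 67 inclusive 5 bp bins from 65 to 399 bp per chromosome arm,
  normalized within each arm; fragments are assigned to arms by start
  position (boundary-spanning fragments are not split); arms with no
  in-range fragment yield flagged zero rows. The mouse convention has 21 q
  arms (1,407 features). The human convention excludes the acrocentric
  short arms (13p, 14p, 15p, 21p, 22p), chrY, and additionally chrXp,
  giving 40 arms (2,680 features); the chrXp exclusion is this package's
  resolution of an ambiguity in the published feature count and is
  configurable rather than asserted.

## CNA features

Fragments are assigned to fixed-width bins (default 1 Mb) by midpoint,
boundary midpoints to the higher bin. Bins overlapping excluded regions
are masked out of the matrix. Each sample's counts are scaled to one
million over unmasked bins, and the log2 ratio against the expected
coverage (mean of normalized controls when available, else the sample's
own median bin) uses a pseudocount of 0.5 — at the counts-per-million
scale the pseudocount only guards empty bins and the log2 vector is
exactly invariant to overall depth. Segmentation, GC correction and
tumor-fraction estimation are out of scope; the matrix feeds clustering
and PCA (column-centered; variance-explained percentages sum to 100).

## Marker statistics

Per-marker AUC is computed from midranks —
`(R1 − n1(n1+1)/2)/(n1·n2)` — which equals pair counting with half-credit
ties, then folded to `max(A, 1−A)` so the statistic is
orientation-agnostic (matching auto-direction ROC behavior) and the
permutation null is symmetric. Informative markers use strict `AUC >
threshold`: 0.9 for observed reporting, 0.8 inside the permutation null;
the asymmetry is preserved as defined, not reconciled. The permutation
test requires balanced two-level labels, draws uniformly random balanced
relabelings with replacement across its (default 1,000) iterations,
recomputes every marker AUC from the pre-computed rank matrix, and reports
`p = #(null >= observed)/n_perm` (which may be exactly 0; a
`(count+1)/(n_perm+1)` estimator is available but off by default) plus the
95 % empirical quantile of the null counts as the one-sided reference
bound.

The two-group test is the rank-sum (U) test — exact when `n1·n2 <= 400`
with no ties, normal approximation otherwise — with a Hodges–Lehmann
location-shift estimate and 95 % interval from order statistics of the
pairwise differences; the exact critical values come from a
dynamic-programming evaluation of the null U distribution. Paired data
use the signed-rank test (or paired t); zero-variance inputs return p = 1
with a degeneracy flag. BH adjustment delegates to the standard step-up
implementation. Hierarchical clustering z-scores markers (dropping
constant ones), then applies average linkage on Euclidean distances.

## What the generator does and does not emulate

The synthetic cohorts reproduce the *statistical structure* the analysis
relies on: two size populations with modes/periodicities/short-fragment
enrichment, group-specific FSD effects, CNA-weighted placement, mixture
fractions over the stated range, classifier noise with a
blacklist-recoverable error mechanism, and MAPQ noise. They do not emulate
sequence-dependent nuclease preferences (motif spectra are
reference-composition driven), GC and mappability bias, UMI duplicates,
pre-analytical degradation, or biological replicate-to-replicate
variability beyond sampling noise. Passing tests therefore demonstrate
that the pipeline's logic and statistics behave correctly under the
modeled mechanisms — not that the biological effect sizes in real plasma
match the defaults chosen here.

## Numerical and design choices

* Coordinates are 0-based half-open throughout; BED on disk.
* Histogram-mode ties break to the smaller length; periodicity smoothing
  window is 3 bp.
* The sampler inverts the exact discrete CDF, so supports are hard bounds.
* Permutation resampling is with replacement across iterations (not
  exhaustive enumeration), as a shuffling null.
* Sub-seeds are spawned per sample, so per-sample data are independent of
  cohort composition order.
* `run_study` problem sizes: the default configuration (400k
  fragments/sample, 3+2 chromosomes of 3 Mb, 1,000 permutations) runs in
  a few minutes on one core; the test suite uses smaller cohorts (300 kb
  chromosomes, 15–20k fragments) chosen to keep every mechanism active.

## Known limitations

* The blacklist support rule is evaluated on merged per-(sample, method)
  regions; alternative region definitions (e.g., per-read without merging)
  would shift interval boundaries by a few bases.
* FSD on very low-fraction ctDNA samples (hundreds of fragments over all
  arms) is noisy; at the default depth the matched-factor contrast is
  reliably recovered, but single markers should not be over-read.
* The exact U-test is limited to `n1·n2 <= 400`; beyond that the normal
  approximation (with tie correction via scipy) is used.
* `estimate_periodicity` assumes at least two ladder peaks inside the
  search window; distributions without a comb raise an explicit error.
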