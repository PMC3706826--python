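# Methods

## Island model and background

Tags for one histone mark are reduced to strand-aware 5′ positions and
counted in non-overlapping windows of *w* = 200 bp.  The background is a
single genome-wide Poisson rate per window,

    lambda = total_tags * w / (genome_length * effective_fraction),

with no control/input track: enrichment is judged against the genome-wide
expectation only.  `effective_fraction` (default 1.0 for synthetic
genomes; 0.74 is the conventional mappable fraction for human) rescales
the denominator for unmappable sequence.  Because lambda is estimated from
*all* tags, enriched regions inflate it slightly (≈ 10 % at the default
synthetic scale); this makes calling mildly conservative, which is shared
by any single-library island caller and accepted here.

A window with count *k* is **eligible** when P(X ≥ k | lambda) < p0 with
p0 = 0.2.  Maximal runs of eligible windows, bridging internal ineligible
runs of at most *g*/*w* windows, form candidate islands; the island score
is the sum of −ln P(X = k_i | lambda) over its *eligible* windows (bridged
windows contribute nothing).  Calling is repeated independently at
*g* ∈ {200, 400, 600, 800, 1000} bp.

## E-value calibration

The score threshold is calibrated by Monte Carlo rather than an analytic
asymptotic: `mc_reps` (default 100) pure-Poisson window fields of the
genome's size are simulated, candidate islands formed and scored, and the
threshold is the smallest score s such that the mean number of background
islands scoring ≥ s is at most E (default 0.1 expected background islands
genome-wide).  The estimator returns the next float above the
floor(E·mc_reps)+1-th largest background score; it is deterministic given
a seed, non-increasing in E, and returns 0 when E is large enough that no
filtering is needed.  The calibration is re-run per gap size because
candidate islands differ; per-(mark, gap) seeds are derived
deterministically from the caller seed so a pipeline run is reproducible
end to end.  Monte-Carlo calibration error is the price of transparency:
the self-consistency check (fresh background at the calibrated threshold)
bounds the realised background rate at ~3×E.

Choosing the Monte-Carlo route over the published analytic island-score
asymptotics was the main genuinely open design decision in the caller; it
makes the threshold's meaning directly testable by re-simulation and keeps
the whole caller free of asymptotic approximations, at the cost of a small
seed-dependent threshold variance.  The implementation is a faithful
parameterisation of the island-calling approach (same window size, gap
sizes, E-value and eligibility tail), not a bit-exact clone of any
existing tool.

## TSS windows and the bivalency score

The promoter window is read as the **closed** symmetric ±`flank` interval
around the TSS (default flank 2 kb), i.e. the half-open interval
[TSS − 2000, TSS + 2001) of 4,001 bases, clamped to the chromosome; the
inclusivity convention is recorded in the pipeline manifest.  One TSS per
gene is used (+ strand → start; − strand → end − 1); when a gene
annotation carries several feature lines the 5′-most start on the coding
strand is taken and a warning logged.  Overlap requires ≥ 1 bp with
half-open semantics (touching endpoints do not overlap) and no
minimum-fraction rule.  A gene is bivalent at a gap size when its window
overlaps ≥ 1 domain of *each* mark — the two marks' domains need not
overlap each other.  The bivalency score is the count of gap sizes (0–5)
at which the gene is bivalent.

## Expression stage

Processing order is background subtraction (mean of negative-control
probes per sample, floored at 1.0 so ratios stay defined) followed by
quantile normalisation (columns forced onto the mean empirical
distribution; ties share the mean of their rank range); both steps are
optional and configurable.  Standard errors are carried through unchanged
— normalisation of the intensity scale is treated as a location
adjustment, not a re-estimation of measurement error.

The per-probe test is a weighted one-way ANOVA with weights 1/se²;
see the README for the statistic.  Two anchors justify it as a transparent
replacement for vendor "error-weighted ANOVA" implementations: with all
SEs equal it reduces exactly (to 1e-10 in tests) to ordinary one-way
ANOVA, and with correctly specified per-observation noise the F statistic
is exactly F(k−1, N−k)-distributed, so null p-values are uniform (verified
by simulation).  Zero within-group variability with a real group effect is
reported as (F = inf, p = 0) rather than an error.  FDR control is
Benjamini–Hochberg within each contrast separately; fold changes are
signed linear ratios of inverse-variance-weighted group means.  The
"timepoint-specific" set defaults to probes significant in the focal
contrast (day 2 vs day 0) and in no other supplied contrast; intersection
and union modes are available and the mode used is written to run
metadata.  PCA sample scores (centred, optionally scaled, via SVD) are
reporting-only.

## qPCR

The comparative method assumes doubling per cycle (no efficiency
correction).  Replicates are averaged on the Ct scale before
exponentiation; RQ = 2^−(ΔCt_sample − ΔCt_calibrator), so the calibrator's
RQ is identically 1 and RQ is invariant to adding a constant to every Ct.
ChIP enrichment: fold enrichment 2^(Ct_IgG − Ct_IP) (the IgG control
self-normalises to 1), percent input 100·2^(Ct_input − log2(1/fraction) −
Ct_IP).  Replicate spread is reported as the SEM over whatever replicate
rows are supplied.

## Synthetic data: what it emulates and what it does not

The generator plants non-overlapping 2 kb enriched regions on a regular
grid (spacing 2·(region_width + 4 kb), so promoter windows never interact)
across a 1 Mb two-chromosome toy genome, assigns each slot a class
(bivalent / k4-only / k27-only / unmarked; 5 of each by default) and a
gene whose TSS sits at the region centre; bivalent genes get co-located
regions of both marks.  Window-level tag counts are Poisson with
background 0.25 tags/window and 8-fold enrichment inside planted regions;
tags are placed uniformly within their window and emitted directly at the
counted location (no fragment-shift modelling — the caller's shift option
is exercised with hand-built records instead).  Expression matrices use
log-normal per-probe baselines, scaled-chi per-value SEs whose magnitude
equals the actual observation noise (so inverse-variance weights are
correctly specified), and multiplicative 2^lfc effects in the designated
group.  Ct tables place the true relative quantity in the target Ct with
optional Gaussian cycle noise.

Not emulated: read-level sequence, mappability structure, duplicate reads,
batch effects, probe cross-hybridisation, amplification-efficiency
variation.  Passing tests therefore demonstrate correctness of the
algorithms under their own stated model, not robustness to those
real-data artefacts.

## Problem sizes and numerical choices

Default synthetic scale is a 1 Mb genome (5,000 windows), 20 genes, 100
calibration replicates, 2,000-probe expression matrices with 3 samples per
group — chosen so every stage runs in seconds while keeping Poisson and
FDR behaviour in their asymptotic regimes.  Known limitation: at this
scale a planted 2 kb region carries only ~20 expected tags while the
E = 0.1 threshold over 5,000 windows demands an island score around 16–18,
so roughly the weakest ~3 % of region draws per mark and gap size fall
below threshold; a gene bivalent at all five gaps for both marks
consequently scores exactly 5 in ~75 % of draws, and per-gene
score exactness across all classes averages ~93–94 %.  Deeper simulated
libraries or wider regions would remove this, but the defaults above are
the package's study conditions and are not tuned per test.

Degenerate inputs: empty tag collections, single-group designs, empty
p-value vectors, non-positive rates/fractions and mismatched gap
collections all raise `ValueError` with the offending field named; an
all-ineligible genome yields an empty domain set, not an error.  Gene
tables may be BED6 or minimal GTF (1-based closed, converted on read).
Coordinates are 0-based half-open everywhere internally and in BED output.
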