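# bivalscore

Bivalent chromatin domains — promoter regions carrying both the activating
H3K4me3 and the repressive H3K27me3 histone marks — poise developmental
regulator genes in pluripotent cells for rapid activation or silencing on
differentiation.  `bivalscore` is a toolkit for predicting promoter
bivalency from ChIP-seq tag data and integrating those predictions with
microarray differential expression and qPCR validation.  It is aimed at
computational biologists studying epigenetic priming during stem-cell
differentiation, and at anyone who needs a transparent, seedable island
caller with an explicit background model.

## What it computes

**Island calling.**  Each chromosome is split into fixed windows of
*w* = 200 bp and tags are counted per window against a genome-wide Poisson
background with rate

λ = *N*·*w* / (*L*·*f*),

where *N* is the tag count, *L* the genome length and *f* the effective
(mappable) fraction.  Windows with count *k* such that P(X ≥ k | λ) < 0.2
are *eligible*; runs of eligible windows bridged across ineligible gaps of
at most *g* bp form candidate islands, scored
S = Σᵢ −ln P(X = kᵢ | λ) over eligible windows.  Islands survive when S
reaches a threshold calibrated by Monte-Carlo simulation so that the
expected number of surviving background islands genome-wide is at most
*E* = 0.1.  Calling is repeated at the five conventional gap sizes
*g* ∈ {200, 400, 600, 800, 1000} bp.

**Bivalency score.**  For each gene, the promoter window is the closed
±2 kb interval around the TSS.  At a given gap size the gene is *bivalent*
if that window intersects (≥ 1 bp) an enriched domain of each mark; the
**bivalency score** (0–5) counts the gap sizes at which this holds — 0
means never bivalent, 5 means bivalent regardless of gap size.

**Expression stage.**  Probe × sample intensity matrices with per-value
standard errors are background-subtracted, quantile-normalised, and tested
per probe with an error-weighted one-way ANOVA (weights 1/se²; with equal
SEs this reduces exactly to ordinary ANOVA) under Benjamini–Hochberg FDR
control at 0.05 per contrast.  Fold changes are signed linear ratios
(|FC| ≥ 1, down-regulation negative).  A timepoint-specific gene set
(significant at day 2 vs day 0 and nowhere else) is joined with bivalency
scores and a transcription-factor list into a per-gene report.

**qPCR.**  Comparative (ΔΔCt) relative quantitation (RQ = 2^−ΔΔCt) and
ChIP-qPCR enrichment as IgG-normalised fold enrichment 2^(Ct_IgG − Ct_IP)
or percent of fraction-adjusted input.

A synthetic-data module generates toy genomes with planted enriched
regions, gene models of known promoter class, expression matrices with
planted fold changes, and Ct tables — so the whole pipeline runs and is
tested without any external data.

## Worked example

```sh
bivalscore simulate --seed 3 --out data
bivalscore call --tags data/H3K4me3.tags.bed --genome data/genome.tsv \
    --mark H3K4me3 --gaps 600 --seed 3 --out calls
# H3K4me3 g=600: 9 domains (lambda=0.2848, s_thr=17.821)
```

The caller estimated a background of 0.2848 tags per 200-bp window,
calibrated an island-score threshold of 17.8 for E = 0.1, and called 9
domains — 9 of the 10 planted H3K4me3 regions on this seed (one region
drew too few tags to clear the threshold; background stayed clean).

```sh
bivalscore bivalency --k4 data/H3K4me3.tags.bed --k27 data/H3K27me3.tags.bed \
    --genes data/genes.bed --genome data/genome.tsv --seed 3 --out biv.tsv
head -6 biv.tsv
# gene_id  flag_g200  flag_g400  flag_g600  flag_g800  flag_g1000  bivalency_score
# g0001    False      False      False      False      False       0
# ...
# g0005    True       True       True       True       True        5
```

Gene `g0005` — planted bivalent — overlaps domains of both marks at every
gap size (score 5); monovalent and unmarked genes score 0.

```sh
bivalscore qpcr --table data/ct_table.tsv --calibrator calibrator
# calibrator    1.00000
# test          1.84315
```

The Ct table was simulated with a true relative quantity of 2.0 and 0.1
cycles of noise; the comparative method recovers RQ ≈ 1.84 for the test
sample and exactly 1 for the calibrator.

The full pipeline (`bivalscore run --config config.yaml`) chains
expression DE → day-2-specific set → probe-to-gene mapping → bivalency
scoring → report, writing all intermediates, a stage-timing log and a JSON
manifest.

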