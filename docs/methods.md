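# Methods

This note documents the models and procedures `cistrodiff` implements, the
defaults it ships with, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Coordinate and data conventions

All coordinates are 0-based half-open (BED convention) everywhere in the
library; conversions to 1-based happen only in display strings. A DNase I
cut site is the 5' end of a read, supplied as a strand-specific single-base
BED record; reverse-strand reads are expected to have been converted to
their 5' position by the upstream preprocessor. Cut profiles are stored
per chromosome and strand as sorted position/count arrays, so window
queries are binary searches.

PWMs are built from JASPAR-style count matrices with a pseudocount
(default 0.8) distributed across bases proportionally to the background
(default uniform) before per-column normalisation. Scores are log2-odds
against the background.

## Peak-set comparison and clustering

Peak sets are sorted and merged (book-ended intervals merge). The overlap
of 2–3 sets is decomposed over the merged union: each union region is
assigned the subset of inputs overlapping it by at least 1 bp. The 1-bp
criterion is the least-assumption default; no summit-distance alternative
is assumed because none is universally right. Per-pair overlap fractions
(fraction of A's own peaks touching any peak of B) are reported alongside.

Sample comparison uses tag counts over the union: per-sample counts are
scaled to tags-per-10-million, log2(x+1)-transformed, Pearson-correlated,
and clustered with average linkage on 1 − r. Samples are pre-sorted
lexicographically so ties resolve identically on every run. These are
conventional choices, exposed in the configuration rather than hard-coded
as truths.

Region annotation is center-based: promoter within ±1,500 bp of a TSS
(config-exposed; "distal" has no universal cutoff), intragenic if inside a
supplied gene-body span, else distal. Nearest-gene assignment takes the
TSS minimising |center − TSS| with lexicographic tie-break, signed by the
TSS strand.

## Motif scanning

`scan_pwm` scores every window on both strands and reports hits with
score ≥ rel_threshold × (max − min) + min, where max/min are the best and
worst attainable scores of the matrix. Windows containing N are skipped;
a matrix identical to the background (zero score range) yields no hits.
The library default rel_threshold is 0.8, a conventional known-motif
setting. The analysis drivers scan at 0.9 because the generator plants
exact consensi: at 0.9 only exact matches of the built-in near-consensus
matrices score, which makes planted/background contrast clean; at 0.8 a
single mismatch also scores.
All overlapping hits are kept (density tracks are count-based; greedy
pruning would bias them). `match_iupac` does exact degenerate matching of
IUPAC consensi on both strands, including the published EVI1 zinc-finger
selection consensi provided as constants.

## Enrichment statistic

Unique (or shared) peaks of a pairwise comparison are a subset of the
merged union, so motif presence (≥ 1 hit midpoint inside the region) is
tested by sampling without replacement: an exact hypergeometric test, not
a binomial. Both tails are computed and the smaller is reported as a
signed −log10 p (positive = over-represented). p-values are floored at
1e-300, capping scores at 300. Benjamini–Hochberg q-values are reported
across motifs within a comparison. The score matrix is clustered with
average linkage on Euclidean distance, rows and columns pre-sorted for
deterministic tie-breaks. The exact statistic behind the original
published heatmaps is described only verbally in the literature this
mirrors; the signed hypergeometric score is this package's definition.

## Footprinting

Candidate footprint sizes default to {11, 13, …, 25} bp with 35-bp
shoulders and a combined score cutoff of −10, the range of published
defaults for shoulder-versus-footprint binomial footprinting. For each
start position and size, forward cuts in the footprint are tested against
the upstream shoulder and reverse cuts against the downstream shoulder
(lower-tail binomial, success probability f/(f+shoulder)); the combined
log10 p is the score. Positions whose footprint-plus-shoulders window
leaves the region are skipped; zero-trial tests score 0. The best size
per position is kept and non-overlapping calls are selected greedily in
ascending score order. Scores are invariant under coordinate reversal
with strand swap (tested).

Occupied motifs are hits overlapping a footprint by ≥ 1 bp, annotated with
the best overlapping footprint score.

## Bootstrap co-occupancy

The observed statistic for motif m is the number of anchor peaks whose
center lies within 50 bp (center-to-hit-midpoint) of an occupied motif of
m. The null resamples |anchors| regions uniformly without replacement
from the accessible-region universe (the union DHS set, the conservative
choice over genome-wide shuffling — both the window anchoring and the
resampling unit are this package's definitions, config-exposed).
`n_boot` draws (default 1,000) give null moments, z, and
`p_emp = (1 + #null ≥ obs)/(1 + n_boot)`. The empirical p is valid but
conservative when the count distribution is coarse; calibration checks
therefore use layouts with enough anchors (400 of a 2,000-region universe)
that tie mass is small. With anchors identical to the universe every draw
reproduces the anchors, the null sd is 0, z is undefined and p is 1.

## Knockdown analyses

Regions are classified lost / shared / gained by pseudocounted fold change
(default pseudocount 1 on normalized tags, threshold 2; the source
analyses print no boundary number, so the threshold is config-exposed).
The classification is a partition and swapping the condition labels swaps
lost and gained exactly.

Expression filtering averages replicates per arm and timepoint, takes
log2((kd + 1)/(ctrl + 1)), and keeps genes with |log2 FC| ≥ log2(1.5) at
≥ 1 timepoint (closed boundary; the per-timepoint-versus-whole-course
choice is not pinned by the source, and ≥ 1 timepoint is the inclusive
reading). Qualifying genes' FC profiles are clustered for display.
Peak-to-gene assignment for target fractions uses the nearest TSS to each
peak center within 50 kb (config-exposed; no universal rule exists).

## Synthetic-data generator

The generator is the package's study definition, not a tuning knob. The
default design emulates a two-condition cistrome study:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 500 kb, i.i.d. uniform ACGT | keeps PWM nulls analytically tractable |
| peaks | 1,000 per condition, 130 bp, ≥ 60 bp apart | DHS-scale elements; non-overlapping by construction |
| shared_fraction | 0.30 | designed overlap between conditions; condition-2 copies of shared peaks get ±25 bp boundary jitter |
| unique motifs | GATA-like in condition-1-unique; C/EBP-like (all) + E-box-like (60%) in condition-2-unique | condition-specific motif partitioning; the partial E-box frequency reflects that secondary motifs co-occur at a fraction of sites and keeps the gained-group top hit unique |
| shared motifs | RUNX-like (all), ETS-like (70%), AP-1-like (50%) | the common myeloid core |
| occupancy | 0.70 of planted motifs | footprinted fraction |
| protected span | 21 bp centered on the motif | protein protection is wider than the core motif |
| cut rates | 1.5 /bp/strand in peaks (pooled over 2 replicates), 0.01 background, ×0.05 in protected spans | deep footprinting-grade coverage |
| expression | 1,000 genes; 50 up + 50 down responders; max fold U(2, 4) reached geometrically over 4 timepoints; 2 replicates/arm; log-normal noise σ = 0.1 | progressive knockdown time course with ≥ 1.5-fold myeloid-program rise |
| gene placement | responders near the unique peaks of their condition (70%, ±10 kb) | makes responders preferentially peak targets |

Motifs are planted as exact consensus words (config allows PWM sampling),
on a random strand, with midpoints kept ≥ 46 bp from peak edges so a
footprint plus both shoulders fits inside the peak. Everything is
deterministic in (seed, design); the manifest written with each fixture
reproduces it byte-identically.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: GC structure and sequence-dependent
DNase cut bias (uniform base background, unbiased Poisson cuts), motif
degeneracy in planted sites (exact consensi by default), irregular peak
shapes and widths, read-level artifacts (no FASTQ simulation), replicate
batch effects, and biological covariance between chromatin and expression
beyond the designed placement of responder genes.

## Problem sizes

The default design (1 Mb genome, 2 × 1,000 peaks, ~2,500 planted motifs,
4 replicate profiles of ~220k cuts, 1,000 genes) was chosen so the entire
fixture builds in about a second in memory, writes under 20 MB, and the
full analysis — scanning seven motifs genome-wide, footprinting a
condition, 100 bootstrap calibration batches of 500 draws — completes in
tens of seconds. The bootstrap calibration experiment uses 100
independent layouts × 4 motif sets (400 p-values) at n_boot = 500.

## Known limitations

- The footprint scanner assumes footprint-plus-shoulder windows fit inside
  the supplied regions; elements narrower than f + 2×35 bp are never
  scanned at size f.
- The empirical bootstrap p is conservative for coarse count
  distributions (few anchors); z-scores are more informative there.
- Enrichment treats motif presence as binary per region; position within
  the region and hit multiplicity are ignored.
- No statistical DE model with replicate variance (the 1.5-fold filter is
  a filter, not a test), matching the scope of the analyses it reproduces.
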