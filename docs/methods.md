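# Methods

## The analysis in one paragraph

`crypticscan` quantifies genome-wide cryptic RNA polymerase II transcription
from strand-specific mutant vs. wild-type signal tracks. Two arms mirror the
two ways such experiments are read out. The *tiling-track* arm forms a
per-base mutant/WT ratio track and averages it over genes on an anchored,
body-scaled metagene abscissa, stratified by gene class (canonical coding,
TATA vs. TATA-like promoters, SUTs, CUTs), separately for the sense and
antisense strands of each gene; cryptic transcription appears as sense
ratio peaks over the 5′/3′ nucleosome-free flank regions and as an
antisense elevation across the gene body. The *macroarray* arm collapses
each ORF to one expression value per strain, counts at-least-two-fold
changes, ranks ORFs by decreasing fold change, and asks — by an upper-tail
hypergeometric test — whether ORFs annotated as "dubious" crowd the top
windows of the ranking, the expected footprint of cryptic transcripts that
overrun ORF boundaries onto probes covering flank-overlapping dubious ORFs.

## Metagene geometry

The abscissa has `flank_units + body_units + flank_units` bins
(default 20 + 20 + 20 = 60) at `unit_bp = 20` bp per flank unit:

* bins 0–19: fixed 20-bp windows walking upstream from the TSS (bin 0 is
  the most upstream, 400 bp out);
* bins 20–39: the gene body [TSS, pA) rescaled onto 20 equal-length
  segments — base *k* of an *L*-base body belongs to body bin
  `k * 20 // L`;
* bins 40–59: fixed 20-bp windows walking downstream from the pA site.

A bin's value is the mean per-base ratio over its span, on the gene's own
strand (sense) and the opposite strand (antisense). Minus-strand genes are
processed as reversed slices of the genome vectors, so the computation is
*exactly* mirror-symmetric: reflecting all coordinates and swapping strands
reproduces every output bit. Flank windows clipped at chromosome ends
become NaN (not zero) and drop out of the class average. Genes with bodies
shorter than `min_body_bp = 60` (3 bp per scaled bin) are excluded and
itemized in the run log.

The flank span of 400 bp per flank (rather than 200 bp) follows from the
20 bp/unit abscissa with the body occupying units 20–40; the whole geometry
is one `BinningConfig`, so a 10-unit/200-bp flank is a single flag away.

Class aggregation defaults to *mean of ratios* (each gene's pseudocounted
ratio profile, averaged with equal gene weight, stderr = SD/√n per bin);
*ratio of means* (ratio of across-gene mean mutant bin signal to mean WT
bin signal, delta-method stderr) is available where intensity-weighted
averaging is preferred. Flank windows are deliberately not masked for
neighbouring genes: flanks of real genes contain neighbours and flank-
resident ncRNAs, and the profiles should show what the arrays saw.

### Peak summaries

`summarize_profile` reports the 5′ peak over the upstream flank plus the
first body quarter, the 3′ peak over the last body quarter plus the
downstream flank, and sense/antisense body means. Peak *height* is the
regional maximum; peak *position* is the centre of the contiguous run of
bins within 2% (relative) of that maximum. For a single-bin peak this is
the argmax; for a flat-topped source (a boxcar-shaped cryptic transcript
population) it reports the plateau centre instead of an arbitrary edge,
which is the position a reader takes from such a profile. Ties therefore
resolve to the plateau centre, deterministically.

## Signal model and normalization

Tracks are dense per-base, per-strand non-negative vectors (the limiting
case of a tiling array as probe spacing → 1 bp; the probe layout of the
original custom array is not public, and base resolution lets the
simulator coarsen rather than the analysis guess). Between-sample scaling
divides each sample by its genome-wide median over bases covered in any
input sample (target 1.0) — a pure rescale, idempotent, preserving all
within-sample structure. Replicates are averaged per base *after*
normalization and *before* ratio formation (replicate-averaged strains are
what the downstream analysis consumes). The ratio is `(mut + ε)/(wt + ε)`
with ε defaulting to 1% of the WT genome-wide median — unit-free, and
protective exactly where signal is lowest (nucleosome-free regions).

**Scale caveat.** Median scaling pins each array's median, so a mutant
whose cryptic signal covers a large genome fraction (e.g. an antisense
elevation over every gene body, ~38% of each strand) is legitimately
scaled down as a whole, multiplying the entire ratio track by a constant
< 1. No between-array normalization can resolve this without an assumed
invariant set. Effect amplitudes are therefore *measured* scale-invariantly
(`workflows.recovery_metrics`): the 5′ peak ratio and the antisense body
elevation are quoted relative to the same profile's sense-body mean, which
carries no injected effect in the recovery scenarios. Under a null or
small-footprint mutant the baseline is 1 and the distinction vanishes.

## Fold-change and enrichment arm

Per-ORF expression = mean sense-strand intensity over [start, end) of the
replicate-averaged track (or an externally supplied per-ORF table). A
feature is *detected* when either strain reaches the detection floor,
default 10% of the pooled genome-wide median intensity; the table's
pseudocount defaults to the same floor, so ratios of near-background
features shrink toward 1 rather than exploding — the usual low-intensity
ratio stabilization for array data, and it makes the ranked-list analysis
conservative for dim features. "At least two-fold" is inclusive (≥ 2.0 or
≤ 0.5) among detected features. Ranking is by decreasing ratio with ties
broken lexicographically by gene id (deterministic); windows of 500 are
counted for flagged (dubious) members, the top window is tested by the
upper-tail hypergeometric `P(X ≥ observed)`, and Benjamini–Hochberg is
applied across windows when the whole histogram is tested.

## What the simulator emulates — and what it does not

`SimConfig` defaults encode the study conditions: 2000 canonical genes on
4 chromosomes (log-normal lengths, median 1200 bp, σ = 0.65; intergenic
median 400 bp, σ = 0.6), strands alternating so flank contexts include
both convergent and divergent neighbours; 18% TATA promoters; SUTs (15.6%)
and CUTs (17.1% of the gene count) in intergenic gaps at 0.3× coding
expression; dubious ORFs (7.4%, ≈ the 431/5803 census of the macroarray
annotation) overlapping the 3′ flank of random host genes, expressing
nothing themselves; a uniform background of 0.2 against a median coding
expression of 1.0; three replicates per strain.

Noise is multiplicative log-normal with E = 1 (σ² = ln(1+CV²)) at the
granularity of the measuring device: per base for tiling tracks
(CV = 0.2), per ORF feature for the spotted macroarray (CV = 0.2). The
distinction matters: per-base noise averaged over an ORF shrinks with ORF
length, which would make short dubious ORFs artificially noisy *rankers*
in a macroarray emulation, whereas a spotted array has one feature — one
noise draw — per ORF regardless of length.

Mutant effects are boxcars and uniform elevations, not Gaussians, so every
expected bin value is exact: a 5′ sense boxcar (default 150 bp wide,
centred 100 bp upstream of the TSS) of amplitude *a* × background gives a
flank ratio of exactly 1 + *a*; symmetric 3′ boxcar; uniform antisense
body elevation; optional multiplicative sense up-regulation of TATA-gene
bodies. Presets: `null` (nothing), `ydr1-like` (flank peaks 3′ > 5′,
modest antisense, TATA body ×1.5), `bur6-like` (stronger flank peaks,
antisense elevation 1.5, no TATA effect). Preset magnitudes encode the
qualitative ordering of the two phenotypes, not measured values.

Not emulated: probe-level chip artifacts (cross-hybridization, GC bias,
saturation), ncRNA turnover (CUT degradation), transcription-level
correlations between neighbouring genes, and any sequence content at all.
Passing recovery tests therefore demonstrates correctness of the analysis
under the stated statistical structure, not robustness to every artifact
of real arrays.

One integer seed drives separate fixed-order substreams (annotation,
expression, track noise, feature noise), so every artefact is reproducible
byte-for-byte.

## Numerical choices and degenerate inputs

* Bin means by index-ordered summation (`bincount` / windowed sums), which
  together with the reversed-slice strand handling gives bit-identical
  mirror symmetry.
* Stderr uses ddof = 1; a single gene yields stderr 0.
* `(0 + ε)/(0 + ε) = 1` exactly for any ε > 0.
* Empty class queries, all-zero samples, overlapping bedGraph intervals,
  inconsistent enrichment counts, non-positive pseudocounts and thresholds
  ≤ 1 all raise before any output is written; pipeline outputs are written
  temp-then-rename so a failed run never leaves a truncated table.
* Argmax ties inside `_plateau_peak` resolve to the plateau centre
  (deterministic); the regional maximum itself takes the first (lowest)
  bin when compared for membership.

## Problem sizes used by the shipped analyses

The analysis drivers and the acceptance script run 2000-gene simulations
(≈ 4 Mb genome, 12 replicate strand-tracks) for calibration and recovery,
5 seeds for seed-averaged recovery, and 20 seeds for the null arm of the
enrichment control; the demonstration fixture bundle on disk is a 300-gene
noise-free genome, which run-length-encodes to small bedGraphs while
having exactly the model's expected ratios.

## Known limitations

* Median scaling assumes the median base is effect-free; the scale caveat
  above applies to strongly genome-wide phenotypes.
* The 5423-canonical-gene vs. 5803-array-ORF distinction of real yeast
  annotations is configurable (biotype selection) but both sets are
  synthetic here; no real coordinates ship with the package.
* The hypergeometric test treats ORFs as exchangeable draws; spatial
  correlation between a dubious ORF and its host gene's fold change is
  exactly the signal sought, so the test is a detection device, not an
  unbiased effect estimate.
* `ratio_of_means` aggregation propagates stderr by a first-order delta
  method, which understates uncertainty for noisy WT bins near zero.
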