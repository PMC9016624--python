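# Methods

## Coordinate and signal model

All coordinates are 0-based half-open; any 1-based external annotation must
be converted at read time, so a single convention holds internally.  For a
`+` gene the TSS is `start` and the TES `end - 1`; on `-` the TSS is
`end - 1` and the TES `start`.  Transcription-oriented windows
`(offset_5p, offset_3p)` around an anchor mirror onto the reference strand
as `[anchor - offset_3p + 1, anchor - offset_5p + 1)` for `-` genes, which
makes the minus-strand window the exact base-pair mirror image of the plus
case.

Coverage is held as fixed-bin vectors (50 bp by default), the in-memory
surrogate of a binned, input-subtracted bigWig.  Mean signal over an
arbitrary interval is the overlap-weighted mean per base pair: bins only
partially covered contribute in proportion to the bases overlapped.  This
pro-rating is a pinned choice — a sum "normalized to region width" does not
itself specify partial-bin behaviour — and makes region signal exactly
additive over adjacent disjoint intervals, a property the test suite
verifies against per-bp expansion.

Input-subtracted tracks can be negative.  Ratio statistics (the pausing
index) are computed on clamped tracks (`max(value, 0)` bin-wise); clamping
is idempotent and never applied implicitly.

## Pausing index

`PI = d_prom / d_body`, the mean per-bp Pol II density in the oriented
(-30, +300) bp window around the TSS over the density from TSS + 300 bp to
the TES.  Exclusions, in order: gene width < 1 kb; promoter density < 1.2
(no appreciable Pol II binding — PI undefined rather than small);
non-positive body density (division guard; on a clamped track a negative
body density is unreachable, so this reduces to d_body = 0).  Genes with
PI > 2 are paused, PI < 2 not paused.  A PI of exactly 2 falls in neither
published definition; we pin it to *not paused*, reading "paused" strictly.
The promoter window is oriented along transcription even though it is
asymmetric; orienting is the only reading consistent with a window that
extends 10x further downstream than upstream.

PI is scale-invariant (for genes passing the promoter-density floor at both
scales) and exactly 1 on flat coverage; both are tested.  Quantile binning
of PI (default 5 bins) is a stable sort-then-slice by `(PI, gene_id)`, so
bin sizes differ by at most one even under heavy ties.

## Expression

`FPKM_g = RC_g * 1e6 / (RC_p * L_g)` with `RC_p` the summed counts of the
supplied gene set.  Expression tiers are rank-based quartiles of FPKM with
ties broken by gene id.  Differential-expression fitting is out of scope by
design: model fits belong to dedicated DE packages, and this layer only
consumes their statistics table.  Fold changes are read as linear ratios
(down = ratio < 1/1.5); published cutoffs of the form |FC| > 1.5 are
ambiguous about log space, so the linear dialect is pinned and a
`log2=True` switch tolerates the other.  Both cutoffs are strict
inequalities.  Activated genes (AG) are those DOWN upon factor knockdown —
the factor promoted their expression; repressed genes (RG) are UP.

## Heterochromatin scoring

A domain's score is `D = mean(H3K27me3) - mean(H3K9me3)`; facultative-like
iff `D > 0`, constitutive-like otherwise.  The zero boundary is a pinned
choice on input-normalized tracks: the underlying observation is a trend
(the two marks anti-correlate across domains), not a published threshold.
Domain boundaries are an explicit input — how to delimit heterochromatin
domains is a peak-calling question outside this package.

## Enhancers and super-enhancers

H3K27ac peaks overlapping any `TSS +- flank` window are removed as promoter
signal.  Two published flank dialects exist (2 kb in enhancer calling,
2.5 kb in super-enhancer options); the operation takes the flank as a
parameter with 2 kb default, and the pipeline's SE preset uses 2.5 kb.
Surviving seeds are stitched transitively when the half-open gap is
<= 12.5 kb (the "equal merges" direction is pinned).  Stitched signal is
the sum of constituent scores.

The super-enhancer cutoff is the standard ROSE geometry: sort total
signals ascending, scale ranks and signals to the unit square, and cut at
the point minimizing `y - x` — the point where the unit-slope line is
tangent to the curve from below; regions strictly above the cutoff signal
are super-enhancers.  All-equal signal vectors have no elbow and flag
nothing; fewer than three regions is an error.  Note the cutoff is *not*
monotone in the naive direction: shrinking the top signal flattens the
elbow, lowers the scaled cutoff and can only flag more of the remaining
regions (the tests pin this direction).

## Enrichment

2x2 tables are `a = |A n B|`, `b = |A \ B|`, `c = |B \ A|`,
`d = |U \ (A u B)|`.  The p-value is the standard two-sided Fisher exact
test (sum of hypergeometric probabilities not exceeding the observed
table's); the test suite checks it against an exhaustive fixed-margin
enumeration to 1e-10.  The association score is `LOR = log2(ad/bc)`.
Zero-cell tables receive a Haldane-Anscombe +0.5 display correction for
the odds ratio only, flagged on the cell; the exact p is untouched.  Star
bands (`*` <= 0.05 down to `****` <= 1e-4) use raw p-values; no multiple
testing layer is added, matching the heatmap convention this reproduces —
consumers needing FDR control should apply it to the exported p column.

Gene-set overlap percentages are reported both unrounded and rounded to the
nearest integer; combined percentages are `100 * (sum of overlaps) / total`.

## Profiles

Anchor matrices hold binned signal over `TSS +- flank` per gene.  Oriented
minus-strand rows are reversed, with the window shifted by +1 bp so the TSS
base occupies the same column as on plus strands; unoriented mode (gene
bodies artificially placed rightward) leaves rows in reference direction.
Rows partially off-chromosome are zero-padded and flagged rather than
dropped.

Metagene outlier removal operates per region: a row is dropped when its
row-mean deviates from the grand mean of row-means by more than 2 s.d. (of
the row-means).  Whether such a filter should act per bin or per region is
ambiguous; per-region is pinned because the profile is a mean over genes,
and removal should not fragment a gene's row.  The profile is the per-bin
mean and s.e.m. (`sd / sqrt(n)`, ddof 1) over retained rows.

## PCHiC post-processing

Interactions are kept when both replicate counts strictly exceed 5 and the
bait-midpoint to other-end-midpoint distance is strictly below 1.5 Mb.
Anchor points for "distance" are pinned to midpoints.  Filtering happens on
raw counts, before normalization.  Quantile normalization replaces each
column's sorted values by the across-column mean of sorted values; a tie
spanning ranks `[rmin, rmax]` receives the mean of the reference values
over that span.  With ties, per-column tie patterns can make the final
sorted columns differ slightly; on tie-free input the sorted columns are
exactly equal, and that exactness is what the tests assert.  Intensity is
the mean of the two normalized replicates; when two conditions are
compared, all four replicate columns are normalized jointly so conditions
share one scale (condition-specific normalization would absorb exactly the
differences being tested).

Per-bait summaries are interaction counts and mean intensities; paired
Wilcoxon signed-rank tests compare matched baits across conditions
(identical inputs, having no signed ranks, report p = 1), and Mann-Whitney
tests compare gene groups within a condition.  Groups with fewer than two
usable baits are refused rather than silently reported.

## Synthetic data

The generator emulates the data shapes the analyses assume, not reads:

- **Genome**: non-overlapping genes with strictly alternating strands,
  widths 2-10 kb and gaps 2-8 kb (all multiples of the bin size, so
  promoter and body windows sit on the coverage grid and zero-noise
  density ratios are exact by construction).
- **Pol II**: body density 2.0 per bp; promoter-region density =
  pause-ratio x body (5 for paused genes, 1 for elongating; 68% of genes
  paused by default).  Gaussian i.i.d. bin noise with s.d. 20% of the body
  mean, allowed to go negative like real input-subtracted tracks.
- **Histone variant**: a Gaussian TSS bump (s.d. 200 bp) on activated
  genes, a promoter-plus-body plateau on repressed genes, a small bump on
  neutral genes.  AG:RG fractions default to 15%:12% (the ~56:44 split of
  deregulated genes, scaled up so a 1,000-gene simulation yields workable
  group sizes).
- **Heterochromatin**: 20-100 kb domains of alternating type with
  anti-correlated H3K27me3 / H3K9me3 means (3.0 vs 0.5).
- **H3K27ac**: peak clusters of 1-4 peaks planted in a third of the
  intergenic gaps with log-normal amplitudes, giving the heavy-tailed
  signal distribution a super-enhancer elbow needs.
- **Expression**: negative-binomial counts with mean = tier rate x length
  (rates 0 / 2 / 20 / 200 per kb, dispersion 0.1); tier 0 is silent.
- **Contacts**: per-bait interaction numbers are Poisson (means 8 / 4 / 5
  for AG / RG / neutral — AG baits twice the RG mean) and per-replicate
  counts are NB around `intensity x (d / 500 kb)^-0.3` with intensities
  15 / 30 / 22 (AG half of RG), distances uniform 20 kb-2 Mb so the
  1.5-Mb filter is exercised.

One integer seed expands through `numpy.random.SeedSequence` into fixed
substreams (genome, per-kind tracks, expression, per-condition contacts),
so components regenerate independently and adding a generator never
perturbs earlier streams.  What the generator does *not* model: mappability
and GC artefacts, replicate-level track variability, correlated noise,
peak-calling uncertainty, genuine enhancer-promoter wiring, copy-number
effects.  Passing recovery tests therefore demonstrates correctness of the
computations under their assumed structure, not robustness to every
pathology of real sequencing data.

## Problem sizes and numerical choices

Recovery analyses run at 1,000 genes on a 20-Mb toy chromosome (pausing
classification), 600 genes at 300 per regulation group (PCHiC contrasts),
and a 200-gene fixture for end-to-end determinism — sizes at which every
targeted effect is detected with rank-test p far below 0.01 while the full
suite stays fast.  The Fisher implementation is checked exhaustively
against enumeration for universes up to 40 plus a seeded sample up to 60.
Tolerances: per-bp oracle agreement to 1e-9 relative (observed ~1e-15);
enumeration agreement to 1e-10 absolute; quantile-normalized sorted
columns compared exactly.  Ties everywhere break by identifier, keeping
every ranking and binning deterministic.

## Known limitations

- bigWig binary I/O is not built in; tracks enter as grid-aligned bedGraph.
- Peak annotation precedence (promoter > gene body > distal) is a pinned
  convention; annotation tools differ in how multi-feature peaks resolve.
- The DE filter consumes externally fitted statistics; it performs no
  shrinkage or re-normalization.
- Interaction calling itself (and Hi-C matrix normalization) is out of
  scope; inputs are called interaction tables.
- GO term retrieval is out of scope; overlap percentages operate on
  supplied gene sets or printed overlap counts.
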