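# Methods

## Model

`zonalspace` treats zonation of articular cartilage as a one-dimensional
latent axis recoverable from expression alone. The assumptions are:

1. A set of superficial-zone marker genes (ZMG_S) and a disjoint set of
   deep-zone marker genes (ZMG_D) are known a priori (from serial-section bulk
   transcriptomics/proteomics) and are monotone in tissue depth in opposite
   directions.
2. After per-cell normalization and per-gene z-scoring, the difference of
   marker-list mean z-scores,
   `Z_c = mean_{g∈S}(E_{g,c}) − mean_{g∈D}(E_{g,c})`,
   orders cells along the superficial→deep axis. With per-gene weights the
   two terms become weighted means; unit weights are the default and the
   documented behavior.
3. Zone membership is a band structure symmetric around zero: superficial for
   `Z_c > τ`, deep for `Z_c < −τ`, middle otherwise. Ties at ±τ go to middle
   (conservative calls).

The score is a relative, not absolute, position: it is invariant to global
rescaling of the data and antisymmetric under exchange of the two marker
lists, and it carries no calibration to physical depth in micrometres.

## Normalization

UMI counts are scaled per cell so that a chosen quantile (default 0.75) of
each cell's *nonzero* counts is constant across cells. Before taking the
quantile, the top `trim_frac` (default 0.05) fraction of genes ranked by
dataset-wide total count is excluded, so a few very abundant transcripts
cannot dominate the scale factors; the scale is then applied to *all* genes
of the cell. Scale factors are strictly positive, so zeros stay zeros and the
dropout mask (raw count = 0) is preserved exactly on the normalized scale.
Both parameters are exposed so users preferring another member of the
upper-quantile normalization family can substitute their own. A cell with no
nonzero counts among untrimmed genes cannot be scaled and is a hard error
naming the barcode.

## z-scores and dropouts

Per gene, `z = (value − mean) / sd` with mean and *population* sd (ddof = 0)
taken over **all** cells, dropouts included. This convention makes z = 0
exactly the population mean of the gene, which pins the "mean with dropouts"
guide line of the zonal scatter at x = 0. The alternative (moments over
expressing cells only) is deliberately not implemented; the expressing-cell
mean is instead reported alongside and drawn as the second guide line at its
z-position. Genes with zero variance get z ≡ 0 and a non-informative flag
rather than NaNs, so they contribute nothing to the zonal score instead of
poisoning it. Marker genes absent from a matrix are dropped from their list
with a warning — the list-size divisor shrinks accordingly — and an emptied
list is an error, because silently zero-filling absent markers would bias
every score toward zero.

## The zone threshold τ

τ has no canonical value; the default is `0.5 × sd(Z_c)` over all cells,
which keeps the middle band symmetric about zero and adapts to how strong the
marker signature is in a given dataset. An absolute τ can be passed instead
(CLI `--tau --tau-mode absolute`). With the default, roughly the central
~30–40% of a unimodal score distribution is called middle. Constant scores
make the relative default undefined and raise an error asking for an absolute
value.

## Tables and the zonal scatter

For a chosen gene every cell falls in exactly one of nine compartments:
zone × {non-expressing, expressing z < 0, expressing z > 0}. Expressing cells
at exactly z = 0 (possible for genes constant across expressing cells) count
as above-mean, keeping nine categories without a tenth "at mean" bucket. The
percentage table reports per-zone percent expressing and the total/mean
expression on the **normalized** scale (not raw counts, not z). Note that
per-assigned-zone percentages condition on the zone *call*, which itself uses
the gene's covariation with the markers; e.g. a superficial marker's dropout
lowers a cell's chance of being called superficial, inflating the
superficial-zone percent expressing relative to a per-true-zone tally. The
scatter's dropout lane sits at x = 0 in the data; renders jitter it
horizontally by ±0.02 for visibility, in the figure only. Overlay mode colors
expressing cells by a second gene's z on a diverging scale centered at 0 and
clipped at ±3. SVG output is byte-deterministic (fixed hash salt, no
timestamp metadata); the HTML format is a static page embedding that SVG.

## Co-expression discovery

Spearman correlation between a sentinel gene and every candidate gene
expressed in at least `min_expressing_frac` (default 0.1) of the chosen cell
subset, computed as Pearson on average-tie ranks of the **normalized** values
(per-gene z-scoring is monotone, so ranks and hence rho are identical on
either scale). Two-sided p-values use the t approximation with n − 2 degrees
of freedom; q-values are Benjamini–Hochberg across the tested candidates —
the ranking is exploratory and needs an error-rate column even though the
original workflow reported none. Rows are ordered by |rho|; the fraction of
subset cells where sentinel and candidate are both nonzero is reported as a
secondary, count-based sort key (`co_positive_frac`) for users who read
"most frequently co-expressed" literally. "Sentinel-high" subsets use the
z > 1 strong-expression convention, and multi-gene cluster masks are strict
conjunctions of z > threshold, so adding genes can only shrink a cluster.
Candidates constant within the subset have no rank variance and are skipped;
subsets below 10 cells are refused.

## Synthetic data

The simulator emulates exactly the structure the method assumes: each cell
has a latent depth d ~ U(0, 1); superficial markers have negative-binomial
mean `μ0·exp(−k·d)`, deep markers `μ0·exp(−k·(1−d))`, all other genes
depth-independent lognormal baselines (log-mean 0.7, log-sd 1.0, i.e. median
~2 counts); counts are NB with per-gene dispersion θ ~ U(2, 10) and
independent Bernoulli dropout. Defaults: 2000 cells, 200 genes, 4 + 4 markers
named after the packaged ZMGs, gradient k = 2, dropout rate 0.3. The marker
surface abundance μ0 = 100 reflects the per-cell normalized expression
magnitudes (~80–240) that abundant cartilage transcripts show in real data,
and θ ∈ [2, 10] the moderate overdispersion of well-expressed UMI genes;
θ ≈ 1 would be the noise level of near-silent genes. True zones are depth
tertiles (empirical, hence exactly balanced), matching the three-zone
histology without inventing zone proportions.

The optional planted cluster models a co-regulated gene program: 8 genes with
baseline mean 30 whose NB means in a random 30% of cells are multiplied by a
*shared* per-cell activity factor (lognormal, median 8, log-sd 1.0). The
shared factor — rather than a flat boost — is what makes the program members
rank-correlated even *within* a high-expression subset, where a flat boost
would leave only independent noise; conditioning on one member being high
(z > 1) truncates but does not remove the shared variance. Program size and
prevalence mirror discovered multi-collagen programs spanning ~8 genes in
sizeable chondrocyte subpopulations.

Dropout rate 1.0 is rejected outright (it would produce all-zero cells that
violate the normalization precondition), as is any configuration that happens
to generate an all-zero cell. All randomness flows from a single seed through
one `numpy.random.Generator`; identical seed and parameters give bit-identical
counts.

What the simulator does **not** model: realistic cartilage transcriptome
composition, mean–variance trends, library-size variation between cells,
batch effects, doublets, or ambient RNA. Passing tests therefore demonstrate
the pipeline's correctness and its behavior under idealized zonal structure
with NB noise and dropout — not performance on any particular real dataset.

## Recovery metrics and observed behavior

`evaluate_recovery` reports Spearman(Z_c, −depth), the fraction of cells
whose assigned zone matches their true depth tertile, and the 3×3 confusion
matrix. Under the default conditions the pipeline reaches Spearman ≈ 0.85–0.87
and zone accuracy ≈ 71–74% across seeds (recomputed, not asserted, by
`scripts/acceptance.py`); with gradient k = 0 the mean |Spearman| over 20
seeds sits well inside the 95% envelope of zero correlation (≈ 1.96/√(n−1)).
Accuracy is bounded by the ordering quality, not by τ: relabeling by score
tertiles gives nearly the same agreement.

## Numerical conventions

- Population (ddof = 0) standard deviations throughout.
- Trimming uses a stable sort, so ties in gene totals trim deterministically.
- Spearman rho is clipped to [−1, 1] after the rank-Pearson computation;
  |rho| = 1 maps to p = 0 exactly.
- Ranking sort is stable with gene symbol as tie-break, so outputs are
  byte-reproducible run to run.
- Gene symbols are uppercased at every ingestion point; duplicate symbols are
  an error unless row-summing is requested explicitly
  (`collapse_duplicates`), because silent collapsing changes the z-scores fed
  into the zonal score.
- MatrixMarket files use 1-based indices on disk, 0-based in memory.

## Problem sizes used in the test suite

Unit tests run on matrices up to ~60 × 30 plus an 80-cell simulated fixture;
the end-to-end checks use the full default conditions (2000 × 200) for single
seeds, 10–20 seeds for the qualitative-gradient and null checks, and a
120-cell dataset for CLI round trips. These sizes were chosen as the smallest
that exercise each property's statistics convincingly.

## Known limitations

- The zonal axis is relative; scores are not comparable across datasets
  without identical marker lists and preprocessing.
- Only three zones are supported; the transitional/middle zone is defined
  purely by exclusion.
- The normalization is a single-factor per-cell scaling; compositional
  effects between very different cell states are not corrected.
- Spearman discovery is pairwise and exploratory; it is not partial
  correlation and implies no network structure.
- Marker lists are consumed as configuration; learning better ZMGs from data
  is out of scope.
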