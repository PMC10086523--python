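# Methods

`chromarch` compares the hierarchical chromatin architecture of two cell
populations (labelled *young* and *aged* throughout, after the muscle
stem-cell aging setting that motivates the defaults) at four scales:
megabase A/B compartments, topologically associated domains (TADs), focal
chromatin loops, and the regulatory-element networks visible in single-cell
multiome data (co-accessibility networks and peak-to-gene linkages). Every
stage is paired with a synthetic-data generator that plants the structure
the stage is supposed to find, so the whole pipeline is testable without
any sequencing data.

## Contact-map model and balancing

Contact maps are per-chromosome symmetric matrices of raw counts, stored
upper-triangular at a fixed bin size; only cis contacts are modelled.
Knight–Ruiz balancing finds weights `w` with `diag(w) C diag(w)` doubly
stochastic (inner–outer Newton with conjugate gradients; a symmetric
Sinkhorn fixed point is the fallback when Newton stalls). Bins with fewer
than 10% non-zero pixels are masked before balancing — the standard
sparsity filter; tolerance 1e-8, at most 1000 matrix–vector products.
Balancing is scale invariant: `kr_balance(k·C)` gives the same balanced
matrix for any `k > 0`.

The distance-decay expectation is the mean balanced value per diagonal over
unmasked pixel pairs; observed/expected (O/E) divides each pixel by that
profile, so every non-empty diagonal of O/E has mean exactly 1.

## A/B compartments

Per chromosome at 100 kb, the Pearson correlation matrix of O/E rows is
formed and its leading eigenvector (largest algebraic eigenvalue, as in
FAN-C's `compartments`, not a PCA of O/E) gives E1. The sign is oriented so
bins with positive E1 have the higher unweighted mean GC content; positive
bins are A, negative B. Chromosomes with fewer than 10 unmasked bins are
skipped. Switch fractions between two calls are computed over bins labelled
in both, so `A→B(young, aged) = B→A(aged, young)` exactly.

The saddle statistic ranks bins by E1 into `q` quantiles (default 50) and
averages O/E over quantile pairs. Compartment strength is
`(mean AA corner + mean BB corner) / (sum of the two AB corners)` with
corners the extreme 20% of quantiles — a fixed convention, since "strength"
has no universal numeric definition; on an exact two-block O/E of 2.0
within / 0.5 between this gives 4.0. The arithmetic is exposed on a raw O/E
matrix (`saddle_from_oe`) as well as on a balanced map, because a map-level
O/E can never equal an idealized checkerboard: its per-diagonal expectation
mixes within- and between-block pixels by construction.

## TADs

The TAD separation score averages, over window sizes {4, 6, 8, 10} bins at
40 kb, the z-scored mean of the "diamond" submatrix spanning each bin
(pixels `(a, b)` with `i−w ≤ a < i ≤ b < i+w`). Boundary significance is a
one-sided rank-sum test of each bin's pooled diamond pixels against the
diamonds one window away on either side, BH-corrected genome-wide.
Boundaries are local score minima with BH-adjusted p below the FDR (default
0.01) whose drop against the flanking local maxima exceeds 0.01 score
units; domains tile the spans between consecutive boundaries (and
chromosome ends) and must be at least 3 bins long.

Cross-condition boundary stability uses greedy mutual-nearest one-to-one
matching within a 1-bin tolerance (distance ties resolve to the leftmost
boundary): matched → stable, unmatched young → lost, unmatched aged →
gained. Domain rearrangements are classified from connected components of
the overlap graph: 1↔1 within tolerance → stable, 1↔1 beyond → shift,
1↔many → split, many↔1 → merge, anything else → indeterminate, so splits
and merges exchange exactly under swapping the two conditions.

Intra-TAD connectivity is the mean raw count per intra-TAD pixel (upper
triangle including the diagonal) divided by the total raw counts linking
the TAD to its immediate neighbours; edge TADs use their single flank and a
zero denominator flags the record missing. The phrase "as a fraction of
reads" is read as a read total; a per-pixel-mean denominator is available
via `denominator="mean"`. The statistic is invariant to uniform count
scaling.

The degree of disorder (DoD) of a TAD takes the off-diagonal pixels whose
O/E is at or above the 0.7 quantile among the TAD's pixels ("top 30%"), and
averages each such pixel's mean Euclidean distance (bin units) to its k = 3
nearest significant peers; fewer than k+1 significant pixels → missing.
Quantile-based selection makes DoD invariant to uniform scaling. The
configuration accepts the conventional parameter set (k, ww, pw, top,
ratio, gap) but only k and top drive this statistic; the other four belong
to the originating software's internals and are logged unused.

## Loops

Loop calling follows the donut-filter scheme: per resolution (defaults 5,
10, 25 kb with peak widths 4/2/1 and windows 7/5/3 bins), each candidate
pixel beyond the minimum diagonal distance (20/20/50 kb) is tested against
the *maximum* of four local expectations — donut annulus, horizontal and
vertical stripes, lower-left quadrant — each computed from the balanced
matrix via 2-D convolution, rescaled by the decay expectation and mapped
back to raw-count space through the balancing weights. The p-value is the
Poisson upper tail of the observed raw count; BH is applied globally across
tested pixels (simpler and more conservative than per-lambda chunking,
which is a GPU-implementation detail). Candidates are restricted to pixels
with O/E > 1 to bound the test count; this cannot lose a focal peak.
Significant pixels are clustered by 8-connectivity; the count-weighted
centroid is emitted if it passes the post-hoc enrichment filters
(q ≤ 0.02; observed ≥ 1.5× the stripe expectations, ≥ 1.75× the donut,
≥ 2× the lower-left — the conventional threshold vector, applied here as
explicit ratio filters). Calls merge across resolutions preferring the
finest call within the per-resolution merge distance.

A count-based Poisson caller is *not* invariant to multiplying all raw
counts by a constant: the scaled counts are no longer Poisson and every
p-value sharpens. What is invariant is the balanced-matrix scale (the
caller converts through the weights), and planted structure recovery at
the generative depth; both are tested.

APA extracts the (2W+1)² O/E submatrix centred on each loop pixel (W = 10),
normalizes each submatrix to mean 1, and averages element-wise; the score
is the centre value over the mean of the 6×6 lower-left (diagonal-proximal)
corner block, the conventional corner. Loops within 2W+1 bins of the
diagonal or clipped by the matrix edge are skipped.

Loop-vs-TAD classification: within-TAD iff both anchor midpoints share a
TAD; otherwise boundary-anchored if an anchor interval overlaps a boundary
position within tolerance; else cross-TAD. Cross-condition loop matching is
mutual-nearest one-to-one with both anchors required to agree within
tolerance.

## Co-accessibility networks

CCANs are Louvain communities (resolution 1.0, fixed seed; nodes and edges
inserted in sorted order so the partition is independent of input ordering)
of the graph whose edges are site pairs scoring at or above the cutoff
(default 0.1); communities need ≥ 3 sites. The data-driven cutoff selector
returns the candidate maximizing the summed CCAN count over both
conditions, ties to the smallest. Cross-condition CCAN matching is
maximum-weight bipartite matching on shared-site counts (verified against
brute-force enumeration in tests); the shared fraction is the Jaccard index
of member sets — symmetric and bounded, where a one-sided denominator would
depend on condition order. Containment in TADs or loop spans requires every
member-site midpoint inside one interval.

The within-TAD enrichment statistic groups cis pairs into 25-kb separation
bins; per bin, fold enrichment = pairs with both sites in one TAD over
pairs spanning different TADs (infinite and flagged when the denominator is
zero). The null re-assigns links uniformly at random among the bin's
participating sites, per chromosome, preserving each site's link count
*and* the constraint that re-paired separations stay inside the bin; 500
replicates give the null band. The distance constraint matters: an
unconstrained endpoint permutation draws pairs with the wrong separation
distribution and biases the null enrichment low, which would make even
TAD-indifferent data look enriched. With the constrained shuffle, data
placed with no regard to TADs fall inside the central 95% of their own null
in ≈100% of bins.

## Aggregation and peak-to-gene linkages

Single-cell accessibility is too sparse for per-cell correlations, so cells
are summed over aggregates of k = 40 cells drawn from a single condition
(condition purity is asserted on every output). Candidates are the k
nearest neighbours of sampled seed cells in a 10-component PCA of log1p
accessibility; they are accepted by a cheapest-first greedy — at each step
the candidate adding the least total overlap (ties: fewest newly
overlapping pairs) — while the running constraints hold: median pairwise
shared-cell count 0 and mean pairwise shared fraction ≤ 10%. Cheapest-first
matters: naive acceptance order spends the overlap budget on mid-overlap
candidates and stalls far below the target count. If the target (default
50 per condition) cannot be approached the builder raises, reporting the
overlap achieved.

Peak-to-gene correlations are Pearson on log1p-normalized aggregate sums
(each aggregate scaled to a fixed total of 1e4 — a fixed target keeps the
transform exactly invariant to global count scaling), computed across the
pooled young+aged aggregate set so age-specific contributions stay visible;
a pair is tested when the gene TSS lies within 500 kb of the peak centre.
Linkages are retained at correlation > 0.45 and genome-wide BH FDR < 1e-4,
then k-means clustered (k = 5, 10 restarts, fixed seed) on concatenated
row-standardized per-aggregate accessibility and expression profiles.
The simplified co-accessibility scorer applies the same correlation to
same-chromosome peak pairs within 500 kb and keeps positive scores; it
replaces a graphical-lasso estimator deliberately — the network, matching
and enrichment layers are the point here, not the sparse-precision model.

## Synthetic data

The Hi-C generator draws Poisson counts around a multiplicative
expectation: `λ(i,j) ∝ (1+|i−j|)^−α · c_comp^[same compartment label] ·
c_tad^[same TAD] · c_loop^[within the peak window of a planted loop]`,
normalized so the expected upper-triangle total equals the requested depth.
Defaults are a single 20 Mb chromosome at 40 kb (500 bins), α = 1, ten
alternating compartment blocks, ten equal TADs, depth 1e6 — desk-scale
while leaving every structure class placeable. The GC track is elevated by
0.05 in planted A bins so sign orientation is testable. The truth set
carries labels, boundaries, loop pixels and the full λ, so the generator is
re-runnable from its own output.

The multiome generator puts each cell on a low-dimensional latent state
(5 programs by default). A planted linkage's shared factor z is one state
coordinate; the peak's accessibility latent and the gene's expression
latent are `sqrt(ρ)·z + sqrt(1−ρ)·noise` with iid per-cell noise, so the
latent correlation is ρ. Accessibility is Bernoulli through a logit
(baseline 0.3, slope 2.5), expression Poisson through a log rate (baseline
5 counts). Unlinked peaks also load (strength 1.0) on randomly chosen
programs: real scATAC peaks ride global accessibility programs, and this
background structure is what lets the PCA embedding group cells coherently
— the same assumption the LSI-based workflows this emulates make. Without
it, k-NN aggregation cannot beat the cell-level sampling noise and
aggregate-based correlation analysis has nothing to work with. CCAN
communities load member peaks jointly on extra state coordinates.
Condition-specific links load only in their condition.

What the generator does *not* emulate: sequencing artifacts (duplicates,
mappability), batch effects, doublets, inter-chromosomal contacts, copy
number, or realistic peak-width/GC biases. Passing recovery tests therefore
demonstrates the statistical machinery under the model's assumptions, not
robustness to the full messiness of real libraries.

## Numerical and edge-case conventions

- Coordinates are 0-based half-open everywhere; bin index = ⌊pos/res⌋.
- Inter-chromosomal input is out of scope; parsers reject unknown
  chromosomes and negative counts, citing the offending line.
- Zero denominators yield missing values (NaN) rather than infinities,
  except the enrichment fold where an infinite observed value is
  meaningful and flagged with percentile 100.
- Every stochastic stage (simulation, Louvain, k-means, aggregation,
  shuffles) takes an explicit seed and reproduces byte-identical output.
- Problem sizes used by the test suite and the acceptance script: 500-bin
  contact maps at depth 1e6–2e6, 500 cells per condition, 50 aggregates of
  40 cells, 200 matching instances, 10–20 calibration replicates with
  200–500 shuffles.

## Known limitations

- The boundary p-value scheme (rank-sum of diamond pixels vs one-window
  flanks) mirrors the common multi-scale insulation approach but is not a
  byte-level reimplementation of any published tool.
- The enrichment-threshold vector for loop filtering is applied as post-hoc
  ratio filters; the originating tool's internal semantics differ in
  detail.
- Compartment strength and the APA corner are fixed conventions among
  several in circulation; compare values only within this package.
- With 500 cells and k = 40, the overlap constraints admit ~50 aggregates
  only because the latent manifold concentrates neighbourhoods; datasets
  without such structure will yield fewer aggregates and weaker linkage
  power, and the builder reports this rather than silently relaxing
  constraints.
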