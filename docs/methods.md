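# Methods

This note documents the models and procedures implemented in `endemap`,
the conventions and numerical choices behind them, what the synthetic
landscapes do and do not emulate, and the package's known limitations.

## Metrics

All metrics are computed on a cells × species binary presence matrix and
a rooted phylogeny whose tips map one-to-one onto the matrix's species.
Internally the tree is indexed into a branch table: a species × branch
membership matrix from which per-cell branch incidence, branch range
sizes, PD and PE all follow as two matrix products. The test suite
checks this vectorized path against a naive per-cell per-branch double
loop on random landscapes.

**Root branch convention.** The branch subtending the root is excluded
from PD, PE and the alternate tree's mean. It lies on no root-to-tip
path distinctly and, being incident to every occupied cell, would only
add a constant. This is the standard Faith-PD convention; the helper
functions accept the tree as given, so a user who wants the root branch
counted can attach it as an explicit basal branch.

**The alternate tree** used for RPE has the same topology with every
non-root branch set to the mean non-root branch length. Total tree
length is preserved exactly, which gives two useful identities asserted
in the tests: Σ<sub>cells</sub> PE equals total tree length for both
trees, and RPE ≡ 1 everywhere when the input tree already has equal
branches.

**Undefined values.** Empty cells have PD = PE = 0 and RPE is NaN
(flagged undefined, never 0): downstream classification treats undefined
as non-significant, and the masking step relabels empty cells outright.

## The null model

Significance is assessed against a *fixed-fixed* null: every
randomization preserves each cell's richness (row sums) and each
species' number of occupied cells (column sums) exactly. Such matrices
cannot be sampled by independent draws, so the package uses a curveball
Markov chain: each trade picks two species and randomly reallocates the
cells unique to either one between them, which preserves both margins by
construction and mixes much faster than single checkerboard swaps.

Chain budgets are counted in exchanged presence pairs — one trade that
moves *k* cells between two species consumes *k* units, and an
unproductive trade consumes one (this keeps runtime bounded on
near-frozen matrices and avoids parity artifacts on tiny ones). Defaults
are burn-in = 10 × fill and thinning = 1 × fill between replicates,
where fill is the total number of presences; all replicates come from
one sequential thinned chain. Branch range sizes are recomputed for
every replicate, since the randomized matrix changes them.

**Rank test.** p<sub>high</sub> = (1 + #{null ≥ obs}) / (n + 1), and
symmetrically for p<sub>low</sub>; ties count as extreme, which makes
the p-value valid (conservative) under the permutation null. A cell is
significant at level α when either tail's p ≤ α/2, matching the
"highest or lowest 2.5%" rank convention for α = 0.05 with 999
replicates. Significance at 0.01 is nested inside 0.05 by construction.

## CANAPE classification

A cell is a candidate center of endemism only if its PE is two-tailed
significant. Candidates with significantly high RPE are paleo-endemic,
significantly low RPE neo-endemic; if the ratio is not significant but
numerator (PE) and denominator (PE_alt) both are, the cell is mixed —
upgraded to super when both are significant at the stricter α = 0.01.
Super is evaluated before mixed, and the ratio classes before both,
since super-endemism is by definition mixed endemism at a higher
significance level.

The PE-only gate is a deliberate choice; the original CANAPE gates
one-tailed on PE *or* PE_alt being significantly high. The
`strict_canape` switch provides that behavior, but the default follows
the two-tailed PE gate, with the masking step cleaning up its known
artifacts: cells with zero richness (e.g. removed cropland/urban cells)
rank among the *lowest* PE values and would otherwise appear as spurious
neo centers, and cells holding only a designated widespread species
appear as spurious paleo centers through that species' phylogenetic
distinctiveness. Both are relabeled `masked`. No multiple-testing
correction is applied across cells, consistent with standard CANAPE
practice.

## Range estimation

Occurrence records become gridded ranges via: single-linkage spatial
clustering (default cutoff 50 km; configurable, and skipped for species
flagged continuously distributed), one minimum convex polygon per
cluster, an outward buffer of one grid-cell width, center-in-polygon
rasterization with a record-cell guarantee, then an elevation-envelope
filter (cells outside the [min, max] of the species' record elevations
are dropped) and an exclusion mask (cropland/urban cells, taken as given
input). Cells containing a record are never removed, so every species
retains at least one cell.

Degenerate geometries — two-record clusters and collinear point sets —
use a randomized-disc rule: 100 points are drawn uniformly inside a
one-cell-width disc around each record and the hull of the draws is the
MCP, reflecting positional uncertainty at the grid scale. Distances are
computed on an equirectangular local projection (km); at the few-km
scales involved the planar error is negligible. Buffers use 16 segments
per quadrant (area error of a buffered disc < 0.2%).

Grid cells are half-open intervals: a point on a shared edge belongs to
the cell with the larger index coordinate, so rasterization partitions
points unambiguously.

## Prioritization

The greedy core-area rule removes, at each iteration, the cell with the
lowest marginal loss δ<sub>i</sub> = max<sub>j</sub>(w<sub>j</sub> ·
q<sub>ij</sub>) / c<sub>i</sub>, with q recomputed over the remaining
landscape every iteration. Cell rank is removal position / n, so the
top-f fraction is the ⌈f·n⌉ last-removed cells and top fractions are
nested. Ties — including featureless cells, whose δ is 0 — are broken by
one fresh uniform draw of length n per iteration, ordered by (δ, draw);
this makes runs reproducible per seed and is the exact contract the
naive reference implementation in the tests follows. A `warp` factor
removes several lowest-δ cells per iteration as a speed device (default
1, i.e. the pure rule). Connectivity and boundary-length penalties are
out of scope, and costs default to 1 everywhere.

Scenario composition: Tx = unit-weight binary taxon ranges; Br = one
feature per non-root branch with weight L<sub>b</sub>/ΣL and the lumped
descendant distribution; BrCE = Br plus unit-weight binary features for
the neo, mixed and super center classes. Paleo centers are excluded as
features because their long branches already make them high-value under
Br; if no center cells exist, BrCE falls back to Br with a warning.

## Evaluation

Solution overlap is reported as |A ∩ B| and its percent of the first
set (solutions at equal fractions have equal sizes, so the percent is
symmetric in practice). Center coverage per class and fraction is the
share of that class's cells inside the top set, non-decreasing in the
fraction. The protection-class map crosses {top 17%, 17–30%, unselected}
with the protected flag (coverage ≥ 25% of the cell, boundary included);
unselected-unprotected cells form the residual class. Per-species
protection uses strict inequalities for the "< 50%" and "< 10%" counts.

## Synthetic landscapes

The generator plants known structure so recovery can be scored exactly:

- **Background species** (default 40) occupy random cell sets covering
  25% of the grid (a `contiguous` option grows ranges by adjacency
  instead, for experiments under spatial autocorrelation).
- **Neo clades** (default 2 clades of 4 tips) are grafted onto a
  birth–death base tree (birth 1.0, death 0.5). Terminal branches are
  scaled to 0.2 × the base tree's mean branch length and each clade is
  confined to one shared 2 × 2 block. The clade keeps a stem branch of
  2 × the mean: a recently radiated local clade descends from an old stem
  lineage whose range is the clade's block. This matters quantitatively —
  PE weighs branch length by range, so a uniformly short-branched
  restricted clade contributes no more per presence than a widespread
  long branch (short length / small range cancels against long length /
  large range); it is the restricted, full-length stem that concentrates
  PE in the block, while the short terminals drive RPE below 1.
- **Paleo relicts** (default 2) keep their tip but get a terminal branch
  stretched to 3 × the mean and a contiguous range of 1–3 cells.
- The default grid is 20 × 20. Grid size interacts with the null model:
  the upper tail of a cell's null PE is dominated by the chance that a
  relict's presences land in that cell, which is (relict presences /
  n_cells) per replicate. At 400 cells this is ~1%, safely below the
  2.5% tail, so the test can resolve genuine centers; on much smaller
  grids relict landings contaminate the tail and mask them.
- A clumped protected-area mask (20% of cells, grown from random seeds
  by adjacency) and a smooth south-north elevation gradient (0–1500 m,
  Gaussian noise σ = 50 m) complete the landscape.

What the generator does *not* emulate: dispersal kernels, niche
evolution, spatially autocorrelated richness gradients, real coastline
geometry, or sampling bias. Passing recovery tests therefore shows the
chain detects the planted contrast under clean conditions, not that it
is robust to the sampling artifacts of real occurrence databases.

## Problem sizes and runtime

The test suite and the acceptance script size their simulations for a
single CPU: landscapes of 400 cells and ~50 species, 199 null replicates
per test (999 remains the analysis default in `NullModelConfig` and the
pipeline), 10–30 landscape seeds per property. The full suite runs in a
few minutes; `scripts/acceptance.py` in about one.

## Known limitations

- Branch lengths must be strictly positive after pruning; zero-length
  branches are rejected rather than collapsed.
- The curveball chain's burn-in/thinning defaults are standard practice,
  not a formal mixing guarantee; severely constrained margins (nearly
  full or nearly empty matrices) mix slowly, though the budget-counting
  rule keeps runtime bounded.
- Tree uncertainty is not propagated: one tree in, one classification
  out. Abundance-weighted PD/PE variants are not implemented.
- The equirectangular projection is inappropriate for ranges spanning
  tens of degrees of latitude; the intended scale is regional grids.
- Exact-optimal reserve selection (integer programming) is out of scope;
  the greedy rule is the method under study.
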