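# Methods

This note documents the models behind `phylogrid`, the defaults that
matter, the design choices that were genuinely open, and what the
synthetic data do and do not establish about real analyses.

## Grid and community conventions

Grids are planar and equal-area with coordinates in kilometres: square
cells, row-major dense cell ids, origin at the lower-left corner, and
half-open cell intervals `[left, right) × [bottom, top)` so every point
belongs to at most one cell. No geographic projection is performed; real
coordinates are assumed to have been projected to an equal-area system
upstream.

Polygon rasterization marks a species present in every cell its range
polygon overlaps with **nonzero area**. Cell-centre containment was the
alternative; any-overlap was chosen because expert range maps are drawn to
include the area they cover, and the choice is localized in
`community.rasterize_ranges` should a sensitivity analysis want the other
rule. Species whose polygon misses the grid are kept as all-zero columns
and reported; all-zero columns are dropped (with a log record) before
endemism and null-model analysis because the inverse range 1/r_i is
undefined at r_i = 0.

NODF is computed on unordered row/column pairs with strictly unequal
marginal totals (equal totals contribute zero), which makes it invariant
to row/column order and identical to computing it on the matrix sorted by
decreasing fill.

## Phylogenetic metrics

All metrics run on a flat-array tree representation; Newick parsing is
delegated to dendropy. Zero-length branches are rejected with guidance to
collapse them first, because PE divides branch presence among occupied
cells and a zero branch carries no information while still inflating
branch counts.

* **PD** uses the *rooted* convention: the spanning subtree includes the
  path to the root, so a single-species cell scores that species'
  root-to-tip length rather than zero. This is the convention the CANAPE
  literature assumes and is required for PE's cell-sum conservation
  (Σ_cells PE = total occupied branch length), which the tests verify
  exactly.
* **The comparison tree** for RPD/RPE keeps the topology and replaces
  every branch length by the mean, preserving total tree length. The
  alternative (unit branches) rescales the denominator arbitrarily;
  preserving the total makes RPD/RPE dimensionless ratios centred near 1,
  and both tests and the equal-branch identity (RPD = RPE = 1) rely only
  on the topology-preservation property.
* **TILD** integrates ln N(t) from the *cell subtree's own root* (the
  MRCA of the cell's species) to the present, with natural log. The
  source method is summarized tersely in the literature; the MRCA origin
  and log base e were chosen and are documented here because both only
  rescale or shift the metric monotonically within a cell set. Requires
  an ultrametric tree (node ages must be well defined).
* Empty cells: PD, PE and TILD are 0; RPD and RPE are missing (NaN).

## Null models and CANAPE

`swap` samples 2×2 submatrices uniformly and swaps checkerboards;
`n_itr` counts **successful swaps** (rejected candidates are not
counted), which is the convention that mixing-time recommendations are
phrased in. A matrix with no checkerboard is returned unchanged with a
warning. `curveball` trades the species unique to a random row pair,
implemented on bit-packed rows (a few microseconds per trade), which is
what makes calibration experiments with tens of thousands of
randomizations tractable. `r0` redraws each row as a uniform species
subset of the same size.

Each null replicate re-randomizes the *observed* matrix independently
(not a thinned single chain). Monte-Carlo p-values use the +1 rank
correction, p = (1 + #{null ≥ obs}) / (n_reps + 1), so p is never exactly
zero. The RPE two-tailed test at level α uses α/2 in each tail.

CANAPE follows the two-step rule: a cell is a candidate if the PE
numerator (original tree) or denominator (comparison tree) is
significantly high one-tailed at α = 0.05; candidates with significantly
high RPE are *paleo*, significantly low *neo*; candidates with both
components high but RPE non-significant are *mixed*, upgraded to *super*
when both components are high at α = 0.01. Library and CLI defaults are
n_reps = 999 and n_itr = 1000; published large-scale analyses at 25-km
grids use the same n_itr with n_reps up to 2·10⁵, and the convergence
diagnostic is provided to size both per dataset. Tests and the
acceptance script use hundreds of replicates, which the diagnostic shows
is adequate at these matrix sizes.

Two statistical facts surfaced by the calibration experiments are worth
recording. First, rank tests on a *discrete* statistic are conservative:
with few species the per-cell PD null distribution carries ~10% tie mass
against the observation and the realized type-I error drops well below
α; with ~20 species tie mass falls to ~1% and the test is calibrated.
Second, per-cell power against a fixed-fixed null comes from the
*co-occurrence* of restricted branches, not from any single species: a
cell must concentrate a substantial share of the assemblage's
small-range, long-branch material before its observed PE escapes the
null's heavy right tail.

## Synthetic data

The generators emulate the statistical structure the metrics assume, not
the biology that produces it.

* **Phylogenies** are pure-birth (Yule): with k lineages the waiting time
  is exponential with rate k·b, stopped after the interval spent at n
  lineages, so E[root age] = Σ_{k=2..n} 1/(k b) — verified by Monte
  Carlo against this closed form.
* **Ranges** are contiguous blocks grown in Chebyshev rings from a random
  centre (ties broken by ring order then cell index), with
  negative-binomial (gamma-Poisson) sizes: mean 18 cells, dispersion 2 on
  the default 12×12 grid of 25-km cells. Block growth near the grid edge
  keeps growing outward rings, so interior cells are systematically
  richer in wide-ranging residents — an edge effect real grids share;
  exchangeability holds between congruent interior regions, which is how
  the tests phrase it.
* **Hotspots**: the default scenario holds 80 species with q = 0.2 (16
  species) confined to a 3×3 interior block with small ranges (mean 6
  cells). For *neo* hotspots the confined species are those on the
  shortest terminal branches. For *paleo* hotspots branches of all depths
  are visited in decreasing length order and whole descendant clades are
  confined while they fit the quantile budget — this makes long internal
  branches themselves range-restricted, which is the structure paleo
  endemism consists of; confining only long terminal branches produces a
  signal the fixed-fixed null largely absorbs. The dense 3×3 block gives
  each hotspot cell most of the endemic pool, matching how real endemism
  centres concentrate many restricted species per cell; with these
  defaults the majority of hotspot cells classify paleo/mixed/super at
  n_reps ≈ 500 while background false positives stay at the significance
  level.
* **Climate** series are linear in space and time plus iid Gaussian
  noise, with 100-year steps by default (a Last-Glacial-Maximum-style
  series is ~220 steps). Real paleoclimate fields are deterministic
  rasters; the noise exists only to exercise the estimators.
* **SAR responses** draw y = Xβ + u with u = λWu + ε by solving
  (I − λW)u = ε.

What passing tests on these data show: the estimators and
classifications recover known structure of exactly the kind they assume.
What they do not show: robustness to taxonomic error, sampling effort
gradients, range-map over-prediction, non-contiguous ranges, or
non-linear climate trends — none of which the generators emulate.

## Velocity

Temporal trend is the per-cell OLS slope over the full series (not
endpoint differences), in units per year. The spatial gradient is the
central-difference magnitude of the time-mean raster in units per km
(one-sided at edges). Velocity = |trend| / max(gradient, floor) in
km/yr; the floor (default 10⁻⁶ units/km) prevents blow-up over flat
fields and every floored cell is flagged in an audit mask. Normalization
to [0, 1] is min-max over non-missing cells — the unique monotone map
onto exactly [0, 1] — and combined layers are sums, hence in [0, 2].
Speed (|trend|) rather than signed velocity is used because layers for
different variables are combined additively.

## Spatial regression

Predictor screening is greedy: while any pairwise |r| ≥ 0.5 remains,
drop the predictor (among those in a violating pair) with the largest
mean absolute correlation; the rule is deterministic and reported along
with the correlation matrix. Predictors are standardized before fitting;
the response is left on its scale.

Distance-band weights connect pairs with 0 < d ≤ d_max, row-standardized
by default ("standard coding"); binary weights are available. The
recommended d_max is read off the Moran's I correlogram: the upper edge
of the last distance class before the first non-significant one.
Islands keep zero rows and are retained (their likelihood contribution
is non-spatial), with a logged count.

SAR error (u = λWu + ε) and lag (y = ρWy + Xβ + ε) models are fit by
profiled Gaussian maximum likelihood: for a candidate spatial parameter,
β and σ² have closed forms; the concentrated likelihood adds
ln|I − λW| = Σ ln(1 − λ e_i) using the eigenvalues of W, which are real
because row-standardized weights from a symmetric neighbour relation are
similar to a symmetric matrix. The parameter is optimized on
(1/min e, 1/max e) by bounded scalar minimization (tolerance 10⁻⁸). AIC
counts k = p + 1 (OLS: coefficients plus σ²) or p + 2 (SAR: plus the
spatial parameter), so models are comparable; ties rank the smaller k
first. The log-determinant agrees with dense `slogdet` to 10⁻⁸ in tests,
and λ = 0 reproduces OLS coefficients and likelihood to 10⁻⁸.

## Regionalization

K-means (Lloyd, best of 25 restarts by default) runs on the rows of the
dissimilarity matrix used as feature vectors — the common practice when
clustering a distance matrix directly; a principal-coordinate embedding
would be a reasonable alternative but is not the default. Cells with
undefined dissimilarities (empty cells) are excluded with a report. The
elbow is automated as the interior K maximizing the discrete second
difference of the WSS curve, ties toward smaller K; the curve itself is
returned (and plotted by the CLI) for visual inspection.

## Problem sizes

Defaults and test sizes were chosen as the smallest systems in which each
property is measurable: 12×12 grids with 80 species for scenario
recovery, 6×8 grids with 10–20 species for oracle and calibration work,
n = 400 with 50 seeds for SAR recovery, and hundreds of null replicates
where thousands would be used in production. The acceptance script states
each size in its output (`n` per quantity).

## Known limitations

* No geodesic support: all geometry is planar; project first.
* TILD is restricted to ultrametric trees.
* The swap sampler conditions on successful swaps, so its stationary
  distribution weights each matrix in the marginal class by its number of
  checkerboard units; where that count varies strongly across the class
  the null is not exactly uniform — curveball is the default everywhere
  for this reason.
* SAR fits are dense in the eigenvalue step (O(n³) once per weights
  matrix); fine to a few thousand cells, not for continental 1-km grids.
* The Grade-of-Membership community clustering used alongside K-means in
  some studies is out of scope.
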