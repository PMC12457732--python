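# Methods

This note documents the modeling choices behind nicheforge: what each stage
assumes, which parameters matter, the numerical conventions that make runs
bit-reproducible, and what the synthetic validation does and does not show.

## Modeling units and grids

All computation happens on regular lon/lat grids in WGS 84 (EPSG:4326) with
square cells; row 0 is the northernmost row. A point belongs to the cell
whose half-open box [west, east) × [south, north) contains it, so a record
exactly on a shared edge is assigned deterministically to the cell for which
that edge is the west/south boundary. The modeling unit is the *presence
cell* — multiple records inside one cell collapse to a single presence —
which removes pseudo-replication from densely collected localities without
applying any spatial thinning (deliberately: no accessible-area masks or
rarefaction are used, so all species are treated uniformly).

Nodata is NaN throughout; all variables of a stack must share the nodata
mask.

## Occurrence cleaning

Removal order per record: missing coordinates (NaN, or the exact (0, 0)
point — the standard marker of failed georeferencing), coordinates outside
[−180, 180] × [−90, 90], then exact duplicates on (species, longitude,
latitude) keeping the first in input order. The duplicate key is exact
rather than fuzzy: conservative and reproducible, at the cost of keeping
near-duplicate records (which the presence-cell collapse then absorbs at
modeling resolution). The cleaning report reconciles exactly:
n_input = n_retained + all removals. Cleaning is idempotent.

## Resolution adjustment and variable pruning

Fine-resolution layers are block-aggregated to the modeling resolution by
the mean of non-nodata source cells (output nodata only when a whole block
is nodata); the target cell size must be an integer multiple of the source.

Collinearity pruning uses Spearman rank correlation (mid-ranks for ties)
over all valid cells of the stack — not just occurrence cells — so the same
variable set serves every species. The greedy scan visits variables in a
caller-supplied priority order (default: stack order) and keeps a variable
iff |ρ| ≤ 0.6 (inclusive) against every variable already kept. The choice of
which member of a correlated cluster survives is therefore explicit and
auditable rather than left to an unspecified heuristic. Constant layers have
undefined rank correlation and are excluded with a warning. Two-pass
selection (e.g., climate+elevation separately from soils) is supported by
running the operation on sub-stacks via `RunConfig.selection_groups`.

## The five algorithms

All are exposed as scikit-learn-style estimators (`fit`, `suitability`,
`get_params`); GLM, SVM and random forest wrap scikit-learn.

- **BIOCLIM envelope** (presence-only). Per variable, the query's percentile
  among training presences is p = (c_less + 0.5·c_equal)/n (mid-rank
  convention); the per-variable score 2·min(p, 1−p) is 1 at the median and 0
  outside the training range; overall suitability is the minimum over
  variables. Rank-based, hence invariant to monotone transforms and to
  variable order.
- **Domain** (presence-only). Gower distance to each training presence —
  mean over variables of |q − b| scaled by the variable's training range; a
  zero-range variable contributes 0 when equal, else 1 — and suitability
  max(0, 1 − min distance): 1 at any training point, 0 beyond one full
  average range.
- **GLM.** Binomial family, logit link, linear terms, maximum likelihood
  (no regularization). A linear logit cannot represent a unimodal response,
  so this algorithm is expected to pass the skill filter least often on
  niche-shaped data; it is retained for comparability, and the TSS² weights
  then discount it naturally.
- **SVM.** Radial kernel, C = 1, gamma = "scale". The signed margin is
  unbounded, so the raster projection is range-normalized to [0, 1]; the
  normalization is monotone, leaving AUC/TSS unchanged.
- **Random forest.** 500 trees by default (`RunConfig.rf_trees`); score =
  fraction of trees voting presence; seeded per replicate.

## Replication protocol

Per (algorithm, repetition): round(0.7·n) presence cells to calibration, the
rest to test; pseudoabsences drawn uniformly without replacement from valid
cells with no record of the species (the pool excludes *all* the species'
presence cells, train and test), one per presence cell in each partition
(1:1). Partitions are redrawn independently for every algorithm × repetition
from child seeds of the species seed (`SeedSequence([seed, algorithm_index,
repetition])`), maximizing the sampling variance the ensemble averages over.
Species seeds derive from the master seed and a CRC-32 of the species name,
so adding a species never perturbs another's results.

Test metrics are read off the projected prediction raster at the test cells,
guaranteeing the persisted rasters and the reported AUC/TSS always agree.
A replicate whose fit raises (degenerate training data) is dropped with a
warning; GLM non-convergence does not drop a replicate, since the returned
probabilities are still rankable.

## Evaluation conventions

AUC is the Mann–Whitney statistic (ties 0.5). The TSS threshold maximizes
sensitivity + specificity over every unique observed score with prediction
positive iff score ≥ t (inclusive); ties among maxima break to the smallest
threshold. Sensitivities are computed as integer-count ratios so the scan is
bit-identical to an exhaustive oracle. The alternative sens = spec crossing
rule is not implemented; max-TSS is the standard reading of
sensitivity–specificity threshold selection. The retention filter is
inclusive on both margins: AUC ≥ 0.75 and TSS ≥ 0.7.

## Ensembling

Each retained replicate is range-normalized over its own full prediction
raster (not pooled), then combined by the TSS²-weighted mean. Nodata
handling is mask intersection by default — a cell missing in any member is
nodata in the consensus — avoiding silent weight renormalization; per-cell
renormalization is available via `renormalize_partial=True`. The consensus
is a convex per-cell combination, invariant to member order and to scaling
all weights.

For scenario periods the same retained models are projected onto each
scenario stack. The default "overall" consensus pools all retained
replicates across GCMs (each GCM's projection enters as a member); per-GCM
consensus maps are always produced alongside. A projection that comes out
constant (e.g., an envelope scored entirely outside its training range)
cannot be range-normalized and is skipped with a warning.

## Range maps, change, and areas

The LPT is computed once per species, on the *present* consensus at the
cleaned occurrence cells, and the same threshold binarizes every period's
consensus; binarization is inclusive (≥ LPT) so all occurrences fall inside
the predicted present range by construction. Change maps classify cells as
stable (1,1), lost (1,0), gained (0,1) or absent (0,0); because areas are
summed over the same cells with the same per-cell values,
stable + lost = present area and stable + gained = scenario area hold
exactly, and an identity scenario yields percent change 0 and percent
maintained 100 exactly (the maintained ratio is computed ratio-first to keep
the identity exact in floating point).

Cell areas use the spherical band formula A = R² Δλ (sin φ_N − sin φ_S) with
the authalic radius R = 6371.0072 km. The spherical model is closed-form and
testable against direct integration of the surface element; it is within
about 0.3% of ellipsoidal areas, which is far below the variance introduced
by pseudoabsence sampling.

## Uncertainty

Per-cell sample standard deviation (divisor n − 1, configurable via `ddof`)
across members; a cell needs at least two valid members, else nodata. Two
families are produced: across per-GCM consensus maps (climate-source
uncertainty, scenario periods with ≥ 2 GCMs) and across per-algorithm
sub-ensembles (method uncertainty, every period). Per-algorithm
sub-ensembles, rather than raw replicates, are the members of the second
family so that each algorithm contributes one surface regardless of how many
of its replicates survived the filter.

## Economics

value = area(km²) × 100 ha/km² × volume × price, with defaults 1.74 m³/ha
(inventory estimate for large-diameter cumaru stems) and 1000 USD/m³
(approximate export price). Net per species = value(lost) − value(gained);
gains appear as negative money. Both the net total and the gross-loss total
are emitted, since a "total loss" can be read either way. The model is
deliberately static: no discounting, price dynamics, or stand-structure
variation — an illustrative scale estimate, not a forecast.

## Synthetic data and what validation shows

`generate_environment` builds each variable as a standardized field of
linear lat/lon gradients plus Gaussian-smoothed white noise, scaled to SD 10
with distinct offsets per variable. Imposed rank correlations use
Gaussian-copula mixing with Pearson weight r = 2·sin(πρ/6); the realized
Spearman ρ lands within ±0.1 of the target on grids of a few thousand cells.
Virtual species have Gaussian-product niches; occurrences sample cells
without replacement with probability proportional to suitability (or the
top-suitability cells), placed at cell centers — sub-cell jitter would add
nothing since modeling operates on presence cells.

The default validation species (`nicheforge.validation`) uses two
informative variables with optima half an environmental SD off-center and
breadths 0.3 of the environmental SD, and 120 presences: a well-identified
niche, the regime the AUC ≥ 0.75 / TSS ≥ 0.7 filters are designed for.
Recovery is scored as Spearman correlation between consensus and true
suitability, mean test AUC of retained replicates, and TSS of the LPT binary
map against the true range (cells with S ≥ 0.5).

What this does **not** show: the generator has no dispersal limitation,
no sampling bias, no spatial autocorrelation in the sampling process, no
interactions between variables in the niche, and scenario stacks are simple
additive shifts rather than physically consistent climate projections.
Passing validation therefore demonstrates the *pipeline machinery* recovers
a recoverable niche — not that any real species' projection is accurate.

## Problem sizes and defaults

The package defaults mirror the standard protocol (100 repetitions ×
5 algorithms, Spearman 0.6, 70/30 split, 1:1 pseudoabsences, AUC ≥ 0.75,
TSS ≥ 0.7, RF 500 trees). The validation suite runs the full 5 × 100
protocol on a 50–60² grid and the niche-recovery experiments on 100×100
grids with 12 repetitions per algorithm over three independent landscapes —
recovery quality saturates well below 100 repetitions, so the smaller
replicate count is used for the recovery experiments while the structural
checks keep the full protocol.

## Known limitations

- Only additive "scenario" perturbations are generated synthetically; real
  CMIP-derived stacks must be supplied by the user as ASCII-grid stacks.
- Reprojection between CRSs is out of scope; inputs must already be on a
  shared WGS 84 grid.
- The Spearman pruning threshold is applied over the full stack extent; an
  occurrence-region restriction is not implemented.
- Fitted models are held in memory for scenario projection; very large
  grids × many replicates are bounded by RAM, not disk.
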