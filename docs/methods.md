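# Methods

This note documents the models behind `patchlink`, the parameters that
matter, what the synthetic world does and does not emulate, and the numerical
choices made where the design was genuinely open. It states no empirical
result that the test suite or the analysis scripts do not themselves compute.

## The scientific setting

A bird with three non-substitutable habitat needs — nesting in open
shrubland, daytime roosting in pinewood, nocturnal foraging mainly on roads —
breeds in two contrasting plots: a protected area where habitats occur as
large clumped blocks, and a managed farmland mosaic where remnants and
plantations are interspersed, at a nearly equal overall fraction of usable
habitat (0.609 vs 0.741). Landscape complementation theory predicts that the
mosaic shortens the daily commute linking nest, roost and foraging site, and
that in a fine-grained mosaic nest-to-roost and nest-to-forage distances rise
and fall together (both are small near mosaic junctions and grow as a nest
sits deeper inside its breeding patch), whereas under clumping the two
distances point at different distant blocks and decouple.

## Rasters and coordinates

All layers are categorical rasters, 10-m cells by default. Coordinates are
metres, origin at the lower-left corner, y northward, cell centres at
`origin + (index + 0.5) * cell`; indices are 0-based and row 0 is the
southern row. Esri ASCII grids (top row first) are flipped on read/write and
carry a JSON legend sidecar. A vector GIS was deliberately avoided: every
downstream quantity (area fractions, distance transforms, block-aggregated
autocorrelation) is grid-computable, testable, and free of heavy geometry
dependencies.

## Synthetic landscapes

`LandscapeSpec` fixes dimensions, per-class target fractions, configuration
(`clumped` / `interspersed`) and a characteristic patch diameter per class.
The class with the largest target becomes the background matrix.

*Clumped*: each non-background class is grown as ≤ 5 random-accretion (Eden)
blobs on the unassigned grid, with exact cell quotas, largest classes first.
Default patch scale 600 m caps blob counts at 5, giving multi-km² blocks.

*Interspersed*: square blocks are placed at positions drawn uniformly at
random on a lattice aligned to each class's own patch size. The non-usable
class samples its 100-m slots uniformly from **all** lattice positions and
overwrites earlier classes (later-wins); usable classes painted before it are
over-provisioned by 1/(1 − f_nonusable) to compensate, and classes painted
after it avoid occupied cells by rejection. Lattice snapping (rather than
free positions) is load-bearing: freely placed patches straddle aggregation
blocks and autocorrelate the usable-habitat field, with a Z score that grows
as √n_blocks, so a "random" mosaic would read as significantly clumped at any
realistic plot size. With snapped, uniformly sampled non-usable slots the
usable/non-usable indicator is exactly exchangeable across 100-m blocks, and
Moran's Z is pivotal N(0, 1)-like regardless of plot size.

Plot recipes (compositions are the study's): natural = clumped, 700 × 694
cells (~4858 ha), {non-usable 0.391, breeding 0.475, roosting 0.114,
foraging 0.020}; managed = interspersed, 454 × 454 cells (~2061 ha),
{0.259, 0.140, 0.543, 0.058}. The managed breeding remnants use a 450-m
patch scale (~20 ha blocks, ≥ 20 per plot). That value was calibrated once,
at design time, against the study-like movement regime: it reproduces
d_roost ≈ 120 ± 90 m, d_forage ≈ 270 ± 110 m and a d_roost–d_forage
correlation near 0.4 in the mosaic, and was frozen before the acceptance
tests were written. Patch sizes are exposed in the config and were not
revisited afterwards.

## Structural layer and telemetry

Each functional class is refined per-cell into cover typologies with stated
weights (10 typologies overall; pinewood is mature in the natural plot and
plantation in the managed plot; secondary foraging is sandy paths in the
natural plot and orange groves in the managed one; roads are 0.2–0.9 % of
each plot's surface). The refinement returns the truth mapping used by
recovery tests.

Simulated birds follow the generator's behavioural rules: one nest point in a
breeding cell (drawn from the quartile of breeding cells nearest roosting
habitat — commuting breeders hold territories near their roosts); daylight
fixes at roost points in roosting cells within 1.5 km of the nest; night
foraging fixes on foraging cells, 31 % of them on road cells. Fix error is
heteroscedastic, as in the field protocol the world emulates: off-road
foraging fixes get isotropic Gaussian error with 35 m per-axis SD
(biangulation; mean radial displacement 35·√(π/2) ≈ 43.9 m), while nests,
roosts and on-road birds are physically sighted and get 2 m (GPS). A single
error SD for all fixes would make per-typology recovery of 10-m road cells
impossible in principle — the reported location of a road fix would almost
never fall on a road cell — so the sighted/biangulated split is part of the
stated world. The behaviour mix defaults to 0.35/0.30/0.35
(nest/roost/forage) of each bird's 55–64 fixes, the sample sizes at which the
Bonferroni-adjusted per-typology intervals below have adequate power.

What the generator does **not** emulate: linear road geometry (road cells are
scattered within foraging patches), roost-site fidelity (each daylight fix
re-draws a roost point), temporal autocorrelation of fixes, and
heterogeneous per-bird behaviour. A green recovery test therefore
establishes that the selection pipeline inverts *this* world's rules, not
that it would resolve arbitrarily rare or spatially degenerate typologies.

## Home ranges

The utilization distribution is the equal-weight mixture of isotropic
bivariate normal kernels (per-axis SD h = 200 m, fixed — no cross-validated
bandwidth) evaluated on a 25-m grid padded 4·h beyond the fix bounding box;
truncated mass is below 1e-3 and the gridded mass is asserted within 1e-3 of
1. The home range is the smallest set of highest-density cells enclosing
95 % of the (gridded) mass; the isopleth is configurable because the level
behind "home range area" is an open choice — 0.95 is the field's standard.

## Habitat selection and the functional map

Availability is the per-typology fraction of landscape cells whose centres
fall inside the home-range mask. Per behaviour, observed fix counts per
typology are tested against expected `n · availability` with a Pearson
chi-square (df = tested types − 1; types with zero availability and zero use
are dropped; used-but-unavailable types are flagged selected and excluded
from the chi-square). Each typology gets an Agresti–Coull interval
(p̃ = (x + z²/2)/(n + z²), half-width z·√(p̃(1−p̃)/(n+z²))) at the
Bonferroni-adjusted level 1 − (1 − 0.95)/k for the k tested types; the call
is *selected* when availability falls below the interval's lower limit and
*avoided* when above the upper limit. Agresti–Coull with Bonferroni was
chosen over simultaneous Goodman intervals as the simplest method consistent
with per-proportion confidence limits; the choice is confined to one helper.

A typology is assigned to a behaviour's functional class when a strict
majority of the individuals tested for that behaviour selected it; a
typology claimed by two behaviours goes to the higher vote share, ties and
everything unclaimed to non-usable. The majority threshold is a design
choice (the pooling rule behind a published functional map is rarely
stated); strict majority is conservative and deterministic.

## Moran's I

Usable fraction per 100-m block (partial edge blocks dropped), binary rook
contiguity, not row-standardized: I = (n/W)·Σ w_ij z_i z_j / Σ z_i²,
E[I] = −1/(n−1), variance from the standard closed forms under either the
randomization (default) or normality null, two-sided normal p. A Monte-Carlo
permutation p is provided and agrees with the analytical randomization p
within 0.02 on random fields. The block size and weight scheme are design
choices (any GIS default would be equally arbitrary) and are recorded in
`MoranResult.weights_spec`; absolute I/Z values are therefore comparable only
within this package, which is why the pipeline tests direction and
separation, not printed magnitudes.

## Movement needs

Nests are uniform-random points within breeding cells accepted by rejection
against the 50-m minimum spacing (per-point attempt budget with global
restart; failure reports how many nests fit). Distance to the nearest
roosting/foraging habitat is the exact Euclidean distance transform (cell
centre to nearest target cell centre, scipy's exact EDT), matching the
assumption that commutes are straight minimum routes; d_total is their sum
at the nest's cell. `cost_distance` provides the grid-geodesic
generalization (8-connected Dijkstra, step length × mean cell cost, ∞ =
barrier); with uniform cost it exceeds the Euclidean distance by at most
1/cos(π/8) ≈ 8.24 %. Only nearest facilities are considered — birds using
non-nearest sites are outside scope.

## Comparison statistics

* `poisson_rate_comparison` — the between-plot contrast of summed distances
  as a Poisson GLM with log link and a binary factor. Applying Poisson errors
  to continuous metre distances is statistically unusual but is the
  comparison this pipeline mirrors; with a binary factor the score equations
  close to group means, so the fit is quasi-likelihood in closed form
  (log RR = ln(mean_B/mean_A), SE = √(1/Σy_A + 1/Σy_B)) and matches an IRLS
  fit to < 1e-6. The SE is meaningful only under the (wrong) Poisson variance
  assumption; it is reported as the model's Wald SE, nothing more.
* `bootstrap_pearson` — percentile CI over paired resamples (B = 10,000 in
  the pipeline); zero-variance resamples are redrawn. Percentile (not BCa)
  is the simplest faithful bootstrap; measured coverage at ρ = 0.4, n = 60
  is ~94 %.
* `fisher_z_difference` — (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)),
  two-sided normal p.
* `wilcoxon_signed_rank` — double-zero pairs and zero differences dropped
  (not Pratt), average ranks for ties; exact sign-flip enumeration (subset-sum
  DP over doubled ranks) for n ≤ 12, else normal approximation with
  continuity correction and tie-corrected variance. The worst-case gap
  between the exact and the continuity-corrected normal p at n = 12,
  enumerated over all rank sums, is 0.0137; mid-range p-values can therefore
  differ by more than 0.01 between the two modes, which is a property of the
  normal approximation, not an implementation artifact.

## Determinism

Every stochastic operation takes a seed or Generator; the pipeline spawns
per-stage seeds from the root `SeedSequence` in a fixed order, and the run
report is serialized with sorted keys and no timestamps, so two runs of one
config are byte-identical.

## Known limitations

* One landscape per configuration per run — like the study it mirrors, the
  design has no replication at the plot level; the acceptance suite
  compensates with 50 replicate worlds.
* The interspersed generator's lattice snapping makes block positions
  discrete; patch shapes are squares, not field polygons.
* Abundance counts share a single weekly environment effect; no seasonality.
* The Poisson-distance GLM inherits the original analysis's variance
  misspecification by construction.
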