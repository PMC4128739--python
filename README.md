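# patchlink

Landscape complementation analysis for species with multiple habitat
requirements: when an animal needs different, non-substitutable habitats for
nesting, daytime roosting and foraging, the *configuration* of a landscape —
clumped blocks versus an interspersed mosaic — controls how far breeders must
commute every day, even at equal habitat *composition*.

The package re-implements, on synthetic data with known ground truth, the
full analysis chain of a two-plot radio-tracking study of a crepuscular
insectivorous bird (nesting in open shrubland, roosting in pinewood, foraging
mainly on roads) in a protected "natural" area with clumped habitat and a
"managed" farmland mosaic nearby:

1. **Synthetic world** (`patchlink.synthetic`) — categorical landscape rasters
   (clumped blob growth vs interspersed block placement at matched
   composition: 60.9 % vs 74.1 % usable habitat), cover-typology refinement,
   radio fixes with realistic positional error (35 m SD biangulation, 2 m GPS
   for sighted locations), and paired weekly abundance counts.
2. **Home ranges** (`patchlink.home_range`) — utilization distributions as
   equal-weight mixtures of bivariate normal kernels (h = 200 m) and their
   95 % volume contours.
3. **Habitat selection** (`patchlink.selection`) — per-bird, per-behaviour
   chi-square tests of use against availability within the home range, with
   Bonferroni-adjusted Agresti–Coull confidence intervals for the proportion
   of locations; selected typologies are pooled by strict majority into the
   four-class functional map (breeding / roosting / foraging / non-usable).
4. **Spatial configuration** (`patchlink.moran`) — global Moran's I of the
   usable-habitat fraction on 100-m blocks, binary rook contiguity,
   randomization-null Z score.
5. **Movement needs** (`patchlink.movement`) — 60 simulated nests per plot at
   ≥ 50 m spacing; for each nest the exact Euclidean distance to the nearest
   roosting and foraging habitat and their sum d_total (an 8-connected
   Dijkstra cost distance generalizes this to non-uniform cost surfaces).
6. **Comparison statistics** (`patchlink.stats`) — Poisson-GLM (log link)
   rate contrast of d_total between plots, bootstrap Pearson correlations of
   d_roost vs d_forage with the Fisher-z difference test, chi-square tests,
   and the Wilcoxon signed-rank test (exact sign-flip enumeration at n ≤ 12)
   for weekly abundance.

`patchlink.pipeline.run_experiment` composes all stages deterministically
under one root seed; the numbered scripts in `analysis/` run the same chain
step by step, exchanging Esri ASCII grids and CSV tables under `results/`.

## Worked example

```bash
python analysis/01_build_landscapes.py
python analysis/02_simulate_telemetry.py
python analysis/03_home_ranges_selection.py
python analysis/04_spatial_configuration.py
python analysis/05_movement_needs.py
python analysis/06_abundance.py
```

prints (root seed 2011):

```
natural  (clumped     ):    4858 ha, usable fraction 0.609
managed  (interspersed):    2061 ha, usable fraction 0.741
natural : I =  0.9601, Z =  93.72, p = 2.23e-308 (4830 blocks)
managed : I =  0.0042, Z =   0.30, p = 0.767 (2025 blocks)
natural : d_roost    991±95 m, d_forage   1809±148 m, d_total   2799±205 m (mean±SE)
managed : d_roost    103±9 m, d_forage    272±16 m, d_total    375±20 m (mean±SE)
natural/managed distance ratio 7.46x (log-rate 2.010±0.007, p = 0)
Wilcoxon signed-rank: T = 346, n = 68, p = 4.4e-07
```

Reading: the two plots offer nearly the same *amount* of usable habitat
(0.609 vs 0.741), but only the clumped plot is spatially autocorrelated at
the 100-m scale (Z = 93.7 vs 0.30). As a consequence a breeding pair in the
clumped plot must link nest, roost and foraging site over several kilometres
per day, versus a few hundred metres in the mosaic — configuration, not
composition, drives the movement burden. Step 3 also shows that the
functional map recovered from the simulated telemetry (shrubland → breeding,
pinewood → roosting, roads and secondary sites → foraging) matches the
generator's ground truth in both plots. Single-replicate d_roost–d_forage
correlations are noisy at 60 nests; the distributional prediction (positive
correlation in interspersed mosaics, sign instability under clumping) is
exercised over 50 replicate worlds in the acceptance suite.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete default experiment from scratch under the given seed
(landscape generation through comparison statistics, artifacts under
`results/experiment/`). The study that this package mirrors published no
machine-readable numerical targets — its printed values depend on proprietary
GIS layers and unreleased telemetry — so the script writes an empty JSON
object and the quantitative checks live in `tests/test_acceptance.py` as
property-based criteria (oracle agreement, parameter recovery, and the
configuration → movement contrast).

## Layout

```
src/patchlink/      library (grids, synthetic, home_range, selection,
                    moran, movement, stats, pipeline)
analysis/           numbered narrative drivers writing results/
configs/default.yaml  the default experiment configuration
tests/              pytest suite incl. test_acceptance.py
docs/methods.md     model assumptions, parameters, numerical choices
```
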