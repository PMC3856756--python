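# gridphylo

Grid-based analysis of species richness and community phylogenetic structure
for floras recorded the way regional plant surveys actually record them: a
species' horizontal range as a list of administrative units ("counties") plus
an elevational interval.  The package is aimed at biogeographers and
community phylogeneticists who want a tested, reproducible implementation of
the classic pipeline — rasterize coarse ranges onto a grid, derive climate
and habitat-heterogeneity predictors per cell, measure phylogenetic
diversity and structure, and partition what explains the richness pattern —
together with a seeded synthetic study system on which every stage can be
validated against known ground truth.

## What it computes

**Rasterization.** A species is present in a grid cell iff one of its
counties intersects the cell *and* its elevational interval `[e_lo, e_hi]`
overlaps the cell's elevational range (closed intervals).  Richness is the
per-cell species count, total and per life form (woody / herbaceous).

**Environment.** Fifteen per-cell predictors from twelve monthly mean
temperatures MT and precipitations MP:

- energy: MAT, MTCM, MTWM, Kira's warmth index WI = Σ<sub>MT&gt;5</sub>(MT − 5),
  coldness index CI = Σ<sub>MT&lt;5</sub>(5 − MT), Thornthwaite PET;
- water: AP = Σ MP, RAIN = Σ<sub>MT&gt;0</sub> MP, AET from a
  Thornthwaite–Mather soil-water bucket (default capacity 100 mm, spun up to
  equilibrium);
- stability: ART = MTWM − MTCM, TSN and PSN (sample SD of the monthly series);
- heterogeneity: TOPO (within-cell relief), VT (vegetation types present),
  SWV = −Σ P<sub>i</sub> ln P<sub>i</sub> over vegetation area fractions.

**Phylogenetic structure.** Faith's PD (total branch length of the minimal
MRCA-rooted subtree spanning a cell's taxa) and the net relatedness index

NRI = −(MPD<sub>obs</sub> − mean MPD<sub>null</sub>) / sd MPD<sub>null</sub>,

where MPD is the mean pairwise patristic distance and the null shuffles tip
labels across the entire pool phylogeny (999 iterations by default),
preserving tree shape and per-cell richness.  Positive NRI = phylogenetic
clustering, negative = overdispersion.  BLADJ-style age calibration is
included for trees with a partial table of internal-node ages.

**Statistics.** Spearman screening of richness/PD against every predictor;
variance partitioning of richness between two predictor sets (climate vs.
heterogeneity, energy vs. water) via the R² of three nested OLS models with
Monte-Carlo permutation tests; single-breakpoint segmented regression of NRI
on climate (continuous hinge model, breakpoint by grid search plus
golden-section refinement); and Moran's I with inverse great-circle-distance
weights, before and after regressing richness on the full environment table.

**Synthetic study system.** A Yule tree, Brownian-motion thermal niche
optima, a gradient landscape (latitudinal temperature, longitudinal
precipitation, elevational lapse, seasonal sinusoid), contiguous county
blocks, a vegetation mosaic, and environmental filtering on standardized
MAT produce occurrence records in the native county+elevation format with
full ground truth — so clustering strength, sampling completeness, and
coarsening bias are all controllable.

## Worked example

```python
from gridphylo import SimulationConfig, generate_bundle, nri, piecewise_fit
from gridphylo.gridding import rasterize_ranges, ranges_from_frame, cells_from_frame
from gridphylo.environment import compute_environment

cfg = SimulationConfig(n_species=120, n_lon=15, n_lat=10, n_counties=30, seed=7)
bundle = generate_bundle(cfg)

matrix = rasterize_ranges(ranges_from_frame(bundle.occurrences),
                          cells_from_frame(bundle.landscape.grid))
env = compute_environment(bundle.landscape.climate, bundle.landscape.grid,
                          bundle.landscape.vegetation)
result = nri(matrix, bundle.tree, n_iter=999, seed=7)

print("mean NRI:", round(result["nri"].mean(), 2))
joined = env.join(result["nri"]).dropna(subset=["nri"])
print(piecewise_fit(joined["MAT"], joined["nri"]).summary())
```

prints

```
mean NRI: 4.06
Segmented fit: breakpoint psi = 1.0267
  left  (n=33):  slope= 0.6759, R2=0.473
  right (n=117): slope=-0.3577, R2=0.773
  overall R2 = 0.713
```

The strongly positive mean NRI says the filtered communities hold species
far more related than random pool draws; the segmented fit finds the mean
annual temperature beyond which clustering relaxes (NRI declines at
−0.36 per °C above ~1 °C here), the signature of environmental filtering
easing off in the warm part of the landscape.

## Command line

Every stage is also a subcommand over one flat `key = value` config:

```sh
gridphylo all --config run.cfg --seed 42
# or stage by stage:
gridphylo simulate --config run.cfg
gridphylo grid --config run.cfg
gridphylo nri --config run.cfg
```

Stages exchange headered CSVs (plus Newick trees) in the configured working
directory and each writes a JSON manifest with its seed, row counts and
timing.  Per-stage seeds are derived from the master seed, so any stage can
be re-run alone and is bit-reproducible.

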