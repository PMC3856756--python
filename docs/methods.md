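# Methods

This note documents the models and procedures implemented in `gridphylo`,
the choices made where a design was genuinely open, and what the synthetic
study system does and does not emulate.

## The synthetic study system

The generator builds a self-contained analogue of a county-level mountain
flora survey, with every stochastic element driven by one integer seed
(identical configs give byte-identical bundles).

**Phylogeny.** A pure-birth (Yule) tree: lineages split at per-lineage rate
`birth_rate` (default 1 per unit time); after the pool reaches `n_species`
(default 200) the clock runs one extra exponential waiting time so all
pendant edges are positive.  The tree is ultrametric and bifurcating.

**Niche evolution.** A one-dimensional thermal optimum evolves by Brownian
motion along the tree (rate `bm_sigma2`, default 0.5 trait²/time).  Optima
are standardized across the pool, so `bm_sigma2` controls only how strongly
relatives share optima (phylogenetic signal), not the pool's spread.

**Landscape.** An `n_lon × n_lat` grid (default 20 × 10 half-degree cells).
Monthly temperature is a latitudinal mean gradient (`temp_gradient`,
default 1 °C per cell) minus an elevational lapse term (6.5 °C/km over a
smooth central dome of relief `elev_relief`, default 3000 m), modulated by a
seasonal sinusoid `MT_m = MAT + A·cos(2π(m−7)/12)` (amplitude 10 °C,
warmest in July) — which makes WI, CI, RAIN, TSN and PET all nontrivial and
analytically checkable.  Annual precipitation follows a longitudinal
gradient (default 20 mm per cell over a 200 mm base) split across months
with the same summer-peaking seasonality.  Counties tile the grid as
contiguous axis-aligned blocks from the factor pair of `n_counties` closest
to the grid aspect; when no factor pair fits (e.g. a large prime), the
tiling falls back to contiguous row-major runs.  Each cell carries a
Dirichlet vegetation mosaic whose concentration tracks elevation, so
vegetation composition is spatially structured.

**Occupancy and records.** The niche axis is the standardized mean annual
temperature of the cells.  A species truly occupies every cell whose score
is within `niche_breadth` (default 0.75 SD) of its optimum; `detection_prob`
(default 1) then subsamples occupied cells independently, emulating survey
completeness.  The emitted record is the survey-native shape: every county
containing at least one detected cell, plus the min/max elevational bounds
over those cells.  Because counties are coarser than cells, rasterizing the
record back can only *add* cells (the coarsening bias of county-level data);
it can never lose a truly occupied one, and the test suite checks both
directions.

**Pool placement.** Species optima are centred `optimum_shift` = 1 SD *warm*
of the landscape mean.  This emulates a cold highland at the margin of its
flora's climatic tolerance: richness rises monotonically toward the warm
cells, while the cold interior holds small, closely related subsets of the
pool — which is what makes filtering produce positive NRI in the cold
extreme and lets a linear environment model capture the richness gradient.
With a centred pool, richness would be unimodal in temperature and the
cold/warm asymmetry of the clustering signal would vanish.

**Null regime.** With `niche_breadth → ∞` every cell is suitable for every
species, so communities only become *random draws from the pool* when
`detection_prob < 1` subsamples them (a deterministic all-species-everywhere
matrix has a degenerate, shuffle-invariant null).  The calibration tests use
breadth 10⁶ with detection 0.25.

**What it does not emulate.** Real geography (county shapes, projection
effects), range cohesion (occupancy is climate-sliced, not spatially
contiguous per species), observational error in elevation bounds, abundance,
and the real flora's range-size distribution.  Passing tests therefore show
the *methods* behave correctly under a known generative model, not that any
particular empirical dataset satisfies that model.

## Rasterization

Presence requires nonempty intersection in *both* domains: shared county and
overlapping closed elevational intervals (a shared endpoint counts).  Strict
containment was rejected: species' elevational spans typically exceed a
cell's relief, so containment would empty almost every cell.  Enlarging a
range (more counties, wider interval) can only add presences — monotonicity
is property-tested.

## Climate and heterogeneity indices

- TSN/PSN use the sample SD (n−1).  ART = MTWM − MTCM.
- CI is the non-negative Kira coldness magnitude Σ(5 − MT) over months
  below 5 °C, so larger CI = colder winter and CI correlates *negatively*
  with richness while WI correlates positively — the sign convention that
  makes the two indices complementary.
- PET is Thornthwaite's formulation: heat index I = Σ(MT/5)^1.514 over
  months above freezing, exponent α the standard cubic in I, monthly values
  scaled by mean daylength (mid-month solar declination) and days per month;
  months at or below 0 °C contribute zero.  Latitudes beyond ±66.5° are
  rejected (the daylength correction breaks down).
- AET is a Thornthwaite–Mather bucket with default capacity 100 mm: surplus
  months meet full demand and recharge storage; deficit months dry the soil
  exponentially, `W ← W·exp(−(PET−MP)/capacity)`.  The year is repeated from
  a full bucket until year-start storage converges (tolerance 0.01 mm), so
  the reported AET is the equilibrium annual total; AET ≤ PET always holds
  month by month.
- SWV uses the natural log (the Shannon–Wiener convention in vegetation
  science); zero fractions contribute nothing, and fractions must sum to 1
  within 1e−6.

## Phylogenetic metrics

- **PD** is the branch-length sum of the minimal subtree spanning the cell's
  taxa, rooted at their MRCA; the stem above the MRCA is excluded by default
  (`include_stem` adds the MRCA's own edge).  Cells with fewer than two taxa
  get PD = 0.  Note PD changes under re-rooting; MPD does not.
- **MPD** averages patristic distances over unordered pairs of distinct
  taxa (presence-weighted; abundance weighting is out of scope).
- **NRI** uses the tip-shuffle null: each of the `n_iter` (default 999)
  iterations draws one uniform permutation of all pool tip labels, shared by
  every cell.  Sharing the permutation gives each cell the identical
  marginal null at a fraction of the cost of per-cell shuffles and matches
  the convention of the standard community-phylogenetics software.  Null SD
  uses n−1.  The sign is chosen so positive NRI = clustering.  Cells with
  < 2 species, or whose null is shuffle-invariant (e.g. the full pool;
  detected via a 1e−9 relative tolerance on the null SD to absorb
  matrix-product rounding), are flagged as missing rather than reported.
- **BLADJ calibration**: nodes with table ages are fixed; tips sit at age 0;
  each undated node is placed, root-to-tip, between its (already dated)
  parent and its nearest dated descendant, evenly by edge count — so a chain
  of k undated nodes between two dated ones is spaced uniformly.  Ties in
  descendant distance resolve to the oldest age (the binding constraint).
  A dated child older than a dated ancestor is an error.

## Statistics

- **Variance partitioning**: with a univariate response, partial redundancy
  analysis reduces algebraically to partitioning OLS R², and it is
  implemented that way: R² of the response on A, on B and on A∪B gives
  pure-A = R²_full − R²_B, pure-B = R²_full − R²_A, shared = R²_A + R²_B −
  R²_full, residual = 1 − R²_full; the four sum to 1 exactly.  The shared
  fraction can legitimately be negative (suppression) and is reported as-is
  with a warning.  Unadjusted R² is the default (with ≲15 predictors on
  hundreds of cells the Ezekiel adjustment is small); `adjusted=True`
  applies it.  Designs are projected through an SVD column-space basis, so
  exactly collinear predictor sets (the synthetic landscape makes ART and
  TSN constant, and ART ≡ MTWM − MTCM always) get the pseudo-inverse fit
  with a warning instead of an inflated R².  Permutation tests permute
  response rows; p = (1 + #{R²_perm ≥ R²_obs}) / (1 + n_perm), default
  n_perm = 999.
- **Segmented regression** fits the continuous hinge model
  y = β₀ + β₁x + β₂·max(x − ψ, 0), scanning ψ over 100 interior x-quantiles
  (each side keeping ≥ 3 points) and refining by golden-section search; RSS
  ties resolve to the smallest ψ.  Per-side R² comes from independent
  straight-line fits on each segment (the conventional reporting style),
  alongside the joint model's overall R².  One breakpoint only.
- **Moran's I** uses inverse great-circle-distance weights (haversine,
  spherical Earth R = 6371 km — a documented approximation to WGS84),
  not row-standardized; expectation −1/(n−1); z and p from the normality
  approximation.  Coincident cell midpoints are an error (infinite weight),
  with offending pairs listed.
- The residual diagnostic regresses richness on the full 15-column
  environment table by OLS and reports Moran's I before and after, plus the
  model R² — the standard check that the predictors absorb the spatial
  structure (spatial autoregressive models are deliberately out of scope).

## Pipeline and reproducibility

Stages exchange headered CSVs and Newick text in one working directory;
each writes a JSON manifest (stage seed, row counts, elapsed time).
Per-stage seeds derive from the master seed via `numpy.random.SeedSequence`,
so re-running any stage alone reproduces what the full run produced, and the
whole pipeline is bit-reproducible under a fixed seed.

## Problem sizes

The shipped study conditions are a 200-species pool on a 20 × 10 grid with
40 counties — large enough that null calibration, clustering recovery and
the variance decomposition are measured on hundreds of cells, small enough
that the full test suite runs in well under a minute and a complete
pipeline run in seconds.  Null calibration is assessed on the pooled NRI
distribution of five replicate 200-cell random-community bundles: a single
bundle's across-cell mean has standard error ≈ 0.08 (the shared-permutation
null correlates the cells' estimates), so pooling is needed before a ±0.1
band on the mean is a sharp test of the SES construction rather than a coin
flip.  Breakpoint recovery uses 100 replicates of n = 500 points at noise
SD 0.3.

## Known limitations

- Occupancy is driven by a single thermal axis; precipitation shapes the
  predictor table but not species ranges, so water variables explain
  richness only through their spatial correlation with temperature.
- The tip-shuffle is the only null model (no independent-swap or
  frequency-preserving nulls), matching the scope of the analysis it
  implements.
- Thornthwaite PET is temperature-based; radiation-based formulations
  (Penman, Priestley–Taylor) are out of scope.
- County blocks are rectangles (or row-major runs), not realistic polygons;
  the coarsening bias they induce is qualitatively, not geometrically,
  faithful.
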