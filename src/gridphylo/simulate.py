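"""Synthetic study-system generator.

Emulates the input structure of a county-level mountain flora survey: a
species pool on a Yule phylogeny, thermal niche optima evolving by Brownian
motion along the tree, a rectangular landscape with latitudinal temperature
and longitudinal precipitation gradients plus an elevational lapse term,
contiguous county blocks coarser than the grid, a vegetation mosaic, and
occurrence records in the native "county list + elevation interval" shape.

Species occupancy is environmental filtering on a single thermal axis: a
species truly occupies every cell whose standardized mean annual temperature
lies within ``niche_breadth`` of its optimum.  Because optima are inherited
along the tree, filtering produces phylogenetically clustered communities at
the cold end of the landscape; setting ``detection_prob`` below 1 subsamples
occupancy, and in the wide-niche limit turns communities into random draws
from the pool (the calibration regime for the null model).

Everything is driven by one integer seed; identical configs produce
byte-identical bundles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .gridding import LifeForm

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Landscape",
    "Bundle",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "build_landscape",
    "derive_species_ranges",
    "generate_bundle",
    "write_bundle",
]

@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with defaults describing the study conditions.

    Units: rates per unit tree time, temperatures °C, precipitation mm,
    elevations m, niche quantities in standardized trait units.
    """

    n_species: int = 200
    n_lon: int = 20
    n_lat: int = 10
    birth_rate: float = 1.0
    bm_sigma2: float = 0.5
    niche_breadth: float = 0.75
    temp_gradient: float = 1.0          # °C per cell of latitude
    precip_gradient: float = 20.0       # mm of AP per cell of longitude
    elev_relief: float = 3000.0         # max synthetic elevation above base
    n_counties: int = 40
    woody_fraction: float = 0.27
    seed: int = 0
    # landscape details
    grid_step: float = 0.5              # degrees
    lon0: float = 80.0
    lat0: float = 28.0
    base_temp: float = 18.0             # MAT at lat0 and elevation 0
    seasonal_amplitude: float = 10.0    # °C, monthly sinusoid half-range
    lapse_rate: float = 6.5             # °C per km of elevation
    base_precip: float = 200.0          # mm, AP at lon0
    n_veg_types: int = 6
    # filtering details
    optimum_shift: float = 1.0          # species optima centred this many SD warm of landscape mean
    detection_prob: float = 1.0         # per (species, suitable cell) sampling completeness

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("grid dimensions must be positive")
        for name in ("birth_rate", "bm_sigma2", "niche_breadth", "grid_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 <= self.woody_fraction <= 1.0):
            raise ValueError("woody_fraction must lie in [0, 1]")
        if not (0.0 < self.detection_prob <= 1.0):
            raise ValueError("detection_prob must lie in (0, 1]")
        if self.n_counties < 1 or self.n_counties > self.n_lon * self.n_lat:
            raise ValueError("n_counties must lie in [1, number of cells]")

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    optima: dict[str, float]                 # species -> niche optimum (z units)
    true_cells: dict[str, frozenset[str]]    # species -> truly occupied cells
    richness: dict[str, int]                 # cell -> true richness
    env_score: dict[str, float]              # cell -> standardized MAT


@dataclass(frozen=True)
class Landscape:
    grid: pd.DataFrame          # cell, lon_min, lat_min, lon_mid, lat_mid, elev_min, elev_max, county_ids
    climate: pd.DataFrame       # cell, month, MT, MP
    vegetation: pd.DataFrame    # cell, type, fraction
    cell_elevation: pd.Series   # cell -> mean elevation (m)
    county_of_cell: pd.Series   # cell -> county id

    def cells(self) -> list[GridCell]:
        from .gridding import cells_from_frame

        return cells_from_frame(self.grid)


@dataclass(frozen=True)
class Bundle:
    config: SimulationConfig
    tree: dendropy.Tree
    traits: dict[str, float]
    landscape: Landscape
    occurrences: pd.DataFrame   # species, county_ids, elev_min, elev_max, life_form
    truth: GroundTruth


def _rng(seed, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


# ---------------------------------------------------------------------------
# Tree and traits

def simulate_yule_tree(n_species: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_species`` tips, ultrametric, labels s0001..

    Lineages split at per-lineage rate ``birth_rate``; after the pool reaches
    the target size the clock runs one extra exponential waiting time so that
    every pendant edge has positive length.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be strictly positive")
    rng = _rng(seed, 1)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # active lineages carried as (node, birth_time)
    active: list[tuple[dendropy.Node, float]] = [(tree.seed_node, 0.0)]
    split_time: dict[int, float] = {}
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        node, _ = active.pop(idx)
        split_time[id(node)] = t
        children = [dendropy.Node(), dendropy.Node()]
        for ch in children:
            node.add_child(ch)
        active.extend((ch, t) for ch in children)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))

    width = max(4, len(str(n_species)))
    for i, (node, born) in enumerate(active):
        node.taxon = taxa.new_taxon(label=f"s{i + 1:0{width}d}")
        node.edge.length = t_end - born
    for node in tree.preorder_node_iter():
        if id(node) not in split_time:
            continue
        for ch in node.child_nodes():
            if ch.is_internal():
                ch.edge.length = split_time[id(ch)] - split_time[id(node)]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree, root_value: float, bm_sigma2: float, seed: int
) -> dict[str, float]:
    """Brownian-motion trait evolution: increments ~ N(0, bm_sigma2 * branch length)."""
    if bm_sigma2 <= 0:
        raise ValueError("bm_sigma2 must be strictly positive")
    rng = _rng(seed, 2)
    values: dict[int, float] = {id(tree.seed_node): float(root_value)}
    traits: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            v = values[id(node)]
        else:
            bl = node.edge.length or 0.0
            if bl < 0:
                raise ValueError("branch lengths must be non-negative")
            v = values[id(node.parent_node)] + rng.normal(0.0, math.sqrt(bm_sigma2 * bl))
            values[id(node)] = v
        if node.is_leaf():
            traits[node.taxon.label] = v
    return traits


# ---------------------------------------------------------------------------
# Landscape

def _county_blocks(n_lon: int, n_lat: int, n_counties: int) -> np.ndarray:
    """County id per cell (n_lat x n_lon), contiguous blocks covering the grid.

    Prefers an axis-aligned rectangular tiling from the factor pair of
    n_counties best matching the grid aspect; falls back to contiguous
    row-major runs when no factor pair fits the grid dimensions.
    """
    best = None
    for a in range(1, n_counties + 1):
        if n_counties % a:
            continue
        b = n_counties // a
        if a <= n_lat and b <= n_lon:
            score = abs(math.log((a / n_lat) / (b / n_lon)))
            if best is None or score < best[0]:
                best = (score, a, b)
    ids = np.empty((n_lat, n_lon), dtype=int)
    if best is not None:
        _, a, b = best
        lat_edges = np.array_split(np.arange(n_lat), a)
        lon_edges = np.array_split(np.arange(n_lon), b)
        cid = 0
        for rows in lat_edges:
            for cols in lon_edges:
                ids[np.ix_(rows, cols)] = cid
                cid += 1
    else:
        flat = np.array_split(np.arange(n_lat * n_lon), n_counties)
        out = np.empty(n_lat * n_lon, dtype=int)
        for cid, chunk in enumerate(flat):
            out[chunk] = cid
        ids = out.reshape(n_lat, n_lon)
    return ids


def build_landscape(config: SimulationConfig) -> Landscape:
    """Deterministic gradient landscape plus seeded within-cell detail.

    Monthly temperature: latitudinal mean gradient minus an elevational lapse
    term, modulated by a seasonal sinusoid peaking in July,
    ``MT_m = MAT + A * cos(2*pi*(m - 7)/12)``.  Monthly precipitation: a
    longitudinal annual-total gradient split across months with the same
    summer-peaking seasonality.  Counties tile the grid in contiguous blocks;
    each cell carries a vegetation mosaic whose fractions sum to one.
    """
    cfg = config
    rng = _rng(cfg.seed, 3)
    n_lat, n_lon = cfg.n_lat, cfg.n_lon

    iy, ix = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
    # smooth dome of elevation, highest in the grid centre
    if cfg.elev_relief > 0:
        cy = (n_lat - 1) / 2 or 1.0
        cx = (n_lon - 1) / 2 or 1.0
        dome = np.cos(0.5 * np.pi * (iy - cy) / cy) * np.cos(0.5 * np.pi * (ix - cx) / cx)
        elev_mean = cfg.elev_relief * np.clip(dome, 0.0, 1.0)
        relief = rng.uniform(100.0, 600.0, size=elev_mean.shape)
    else:
        elev_mean = np.zeros((n_lat, n_lon))
        relief = np.zeros((n_lat, n_lon))

    mat = cfg.base_temp - cfg.temp_gradient * iy - cfg.lapse_rate * elev_mean / 1000.0
    ap = np.maximum(cfg.base_precip + cfg.precip_gradient * ix, 0.0)

    months = np.arange(1, 13)
    season = np.cos(2.0 * np.pi * (months - 7) / 12.0)          # +1 in July
    precip_weight = (1.0 + 0.8 * season)
    precip_weight = precip_weight / precip_weight.sum()

    n_cells = n_lat * n_lon
    width = max(4, len(str(n_cells)))
    cell_ids = np.array(
        [f"c{i + 1:0{width}d}" for i in range(n_cells)]
    ).reshape(n_lat, n_lon)

    county_idx = _county_blocks(n_lon, n_lat, cfg.n_counties)
    cwidth = max(3, len(str(cfg.n_counties)))
    county_ids = np.vectorize(lambda k: f"u{k + 1:0{cwidth}d}")(county_idx)

    grid_rows, clim_rows, veg_rows = [], [], []
    for r in range(n_lat):
        for c in range(n_lon):
            cid = cell_ids[r, c]
            half = relief[r, c] / 2.0
            grid_rows.append(
                {
                    "cell": cid,
                    "lon_min": cfg.lon0 + c * cfg.grid_step,
                    "lat_min": cfg.lat0 + r * cfg.grid_step,
                    "lon_mid": cfg.lon0 + (c + 0.5) * cfg.grid_step,
                    "lat_mid": cfg.lat0 + (r + 0.5) * cfg.grid_step,
                    "elev_min": elev_mean[r, c] - half,
                    "elev_max": elev_mean[r, c] + half,
                    "county_ids": county_ids[r, c],
                }
            )
            mt = mat[r, c] + cfg.seasonal_amplitude * season
            mp = ap[r, c] * precip_weight
            for m in range(12):
                clim_rows.append(
                    {"cell": cid, "month": m + 1, "MT": mt[m], "MP": mp[m]}
                )
            # vegetation mosaic: Dirichlet with elevation-shifted concentration
            rel = elev_mean[r, c] / cfg.elev_relief if cfg.elev_relief > 0 else 0.0
            centers = np.linspace(0.0, 1.0, cfg.n_veg_types)
            alpha = np.exp(-((centers - rel) ** 2) / 0.08) + 0.05
            frac = rng.dirichlet(alpha * 4.0)
            for t in range(cfg.n_veg_types):
                veg_rows.append({"cell": cid, "type": f"v{t + 1}", "fraction": frac[t]})

    grid = pd.DataFrame(grid_rows)
    climate = pd.DataFrame(clim_rows)
    vegetation = pd.DataFrame(veg_rows)
    cell_order = grid["cell"].tolist()
    cell_elev = pd.Series(elev_mean.reshape(-1), index=cell_order, name="elev_mean")
    county_of_cell = pd.Series(county_ids.reshape(-1), index=cell_order, name="county")
    return Landscape(grid, climate, vegetation, cell_elev, county_of_cell)


# ---------------------------------------------------------------------------
# Environmental filtering -> occurrence records

def _environment_score(landscape: Landscape) -> pd.Series:
    """Standardized mean annual temperature per cell (the niche axis)."""
    mat = landscape.climate.groupby("cell", sort=False)["MT"].mean()
    sd = mat.std(ddof=1)
    if sd == 0:
        return mat * 0.0
    return (mat - mat.mean()) / sd


def derive_species_ranges(
    traits: dict[str, float],
    landscape: Landscape,
    niche_breadth: float,
    woody_fraction: float,
    seed: int,
    optimum_shift: float = 0.0,
    detection_prob: float = 1.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Turn niche optima into county-level occurrence records.

    Tip traits are standardized across the pool and shifted by
    ``optimum_shift`` so that the pool's thermal centre can sit off the
    landscape mean; a species' true cells are those whose environment score is
    within ``niche_breadth`` of its optimum.  The emitted record lists every
    county containing at least one (detected) true cell and the min/max
    elevational bounds over those cells; species with no occupied cell get an
    empty record.
    """
    if niche_breadth <= 0:
        raise ValueError("niche_breadth must be strictly positive")
    rng = _rng(seed, 4)
    z = _environment_score(landscape)
    species = sorted(traits)
    vals = np.array([traits[s] for s in species], dtype=float)
    sd = vals.std(ddof=1)
    optima = (vals - vals.mean()) / (sd if sd > 0 else 1.0) + optimum_shift

    grid = landscape.grid.set_index("cell")
    county = landscape.county_of_cell
    cells = z.index.to_numpy()
    zv = z.to_numpy()

    forms = np.where(
        rng.random(len(species)) < woody_fraction,
        LifeForm.WOODY.value,
        LifeForm.HERBACEOUS.value,
    )

    occ_rows = []
    true_cells: dict[str, frozenset[str]] = {}
    rich = np.zeros(len(cells), dtype=int)
    for i, sp in enumerate(species):
        mask = np.abs(zv - optima[i]) <= niche_breadth
        if detection_prob < 1.0:
            mask = mask & (rng.random(len(cells)) < detection_prob)
        occupied = cells[mask]
        true_cells[sp] = frozenset(occupied)
        rich += mask.astype(int)
        if occupied.size:
            counties = sorted(set(county.loc[occupied]))
            emin = float(grid.loc[occupied, "elev_min"].min())
            emax = float(grid.loc[occupied, "elev_max"].max())
        else:
            counties, emin, emax = [], 0.0, 0.0
        occ_rows.append(
            {
                "species": sp,
                "county_ids": ";".join(counties),
                "elev_min": emin,
                "elev_max": emax,
                "life_form": forms[i],
            }
        )

    occurrences = pd.DataFrame(occ_rows)
    truth = GroundTruth(
        optima=dict(zip(species, optima.tolist())),
        true_cells=true_cells,
        richness={c: int(k) for c, k in zip(cells, rich)},
        env_score={c: float(v) for c, v in zip(cells, zv)},
    )
    return occurrences, truth


def generate_bundle(config: SimulationConfig) -> Bundle:
    """Full fixture bundle: tree, traits, landscape, occurrences, ground truth."""
    tree = simulate_yule_tree(config.n_species, config.birth_rate, config.seed)
    traits = simulate_bm_traits(tree, 0.0, config.bm_sigma2, config.seed)
    landscape = build_landscape(config)
    occurrences, truth = derive_species_ranges(
        traits,
        landscape,
        config.niche_breadth,
        config.woody_fraction,
        config.seed,
        optimum_shift=config.optimum_shift,
        detection_prob=config.detection_prob,
    )
    return Bundle(config, tree, traits, landscape, occurrences, truth)


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    """Write the interchange files: tree.nwk, occurrences.csv, grid.csv,
    climate_monthly.csv, vegetation.csv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(
        bundle.tree.as_string(schema="newick", suppress_rooting=True)
    )
    paths["occurrences"] = outdir / "occurrences.csv"
    bundle.occurrences.to_csv(paths["occurrences"], index=False)
    paths["grid"] = outdir / "grid.csv"
    bundle.landscape.grid.to_csv(paths["grid"], index=False)
    paths["climate"] = outdir / "climate_monthly.csv"
    bundle.landscape.climate.to_csv(paths["climate"], index=False)
    paths["vegetation"] = outdir / "vegetation.csv"
    bundle.landscape.vegetation.to_csv(paths["vegetation"], index=False)
    paths["truth"] = outdir / "truth.json"
    truth = bundle.truth
    paths["truth"].write_text(
        json.dumps(
            {
                "optima": truth.optima,
                "true_cells": {s: sorted(v) for s, v in truth.true_cells.items()},
                "richness": truth.richness,
                "env_score": truth.env_score,
            },
            indent=0,
            sort_keys=True,
        )
    )
    return paths
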