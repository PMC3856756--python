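"""Stage orchestration: simulate → grid → env → pd/nri → stats.

Each stage reads the CSV/Newick artifacts of its upstream stages from one
working directory and writes its own outputs there, plus a small JSON
manifest (seed used, row counts, elapsed time) so a run is auditable and any
stage can be re-run independently.  Per-stage seeds are derived from the
master seed with :class:`numpy.random.SeedSequence`, so re-running a single
stage reproduces exactly what the full run produced.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import environment as env_mod
from . import phylo as phylo_mod
from . import stats as stats_mod
from .gridding import CommunityMatrix, cells_from_frame, ranges_from_frame, rasterize_ranges, richness_table
from .simulate import SimulationConfig, generate_bundle, write_bundle

log = logging.getLogger("gridphylo")

STAGES = ["simulate", "grid", "env", "pd", "nri", "correlate", "varpart", "segmented", "moran"]

CLIMATE_VARS = ["MAT", "MTCM", "MTWM", "CI", "WI", "PET", "AET", "AP", "RAIN", "ART", "TSN", "PSN"]
ENERGY_VARS = ["MAT", "PET", "MTCM", "MTWM", "CI", "WI"]
WATER_VARS = ["AP", "AET", "RAIN"]
HETERO_VARS = ["TOPO", "VT", "SWV"]


@dataclass(frozen=True)
class PipelineConfig:
    """One flat configuration for every stage."""

    outdir: Path = Path("gridphylo_run")
    seed: int = 0
    n_iter: int = 999           # NRI null iterations
    n_perm: int = 999           # permutation-test draws
    soil_capacity: float = 100.0
    adjusted_r2: bool = False
    pd_include_stem: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text config (lines, '#' comments)."""
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line without '=': {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            raw[key] = val
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        def coerce(value: str, typ):
            if typ is bool:
                return str(value).lower() in ("1", "true", "yes", "on")
            return typ(value)

        top = {}
        sim = {}
        sim_fields = {f.name: f.type for f in fields(SimulationConfig)}
        sim_types = {
            f.name: (int if f.type == "int" else float if f.type == "float" else str)
            for f in fields(SimulationConfig)
        }
        for key, val in raw.items():
            if key == "outdir":
                top["outdir"] = Path(val)
            elif key == "seed":
                top["seed"] = int(val)
            elif key in ("n_iter", "n_perm"):
                top[key] = int(val)
            elif key == "soil_capacity":
                top[key] = float(val)
            elif key in ("adjusted_r2", "pd_include_stem"):
                top[key] = coerce(val, bool)
            elif key in sim_fields:
                sim[key] = coerce(val, sim_types[key])
            else:
                raise ValueError(f"unknown config key: {key!r}")
        cfg = cls(**top)
        if "seed" in top and "seed" not in sim:
            sim["seed"] = top["seed"]
        if sim:
            cfg = replace(cfg, simulation=replace(cfg.simulation, **sim))
        return cfg

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31))


def _manifest(cfg: PipelineConfig, stage: str, seed: int | None,
              counts: dict[str, int], elapsed: float) -> None:
    path = cfg.outdir / f"manifest_{stage}.json"
    path.write_text(
        json.dumps(
            {
                "stage": stage,
                "master_seed": cfg.seed,
                "stage_seed": seed,
                "n_iter": cfg.n_iter if stage == "nri" else None,
                "n_perm": cfg.n_perm if stage == "varpart" else None,
                "counts": counts,
                "elapsed_s": round(elapsed, 3),
            },
            indent=2,
        )
    )
    log.info("stage=%s seed=%s counts=%s elapsed=%.2fs", stage, seed, counts, elapsed)


def _need(cfg: PipelineConfig, name: str, producer: str) -> Path:
    path = cfg.outdir / name
    if not path.exists():
        raise FileNotFoundError(
            f"missing {name}; run the '{producer}' stage first (looked in {cfg.outdir})"
        )
    return path


def _load_matrix(cfg: PipelineConfig) -> CommunityMatrix:
    occ = pd.read_csv(_need(cfg, "occurrences.csv", "simulate"), keep_default_na=False)
    life = {str(r.species): str(r.life_form) for r in occ.itertuples(index=False)}
    return CommunityMatrix.from_csv(_need(cfg, "community_matrix.csv", "grid"), life)


def stage_simulate(cfg: PipelineConfig) -> None:
    t0 = time.perf_counter()
    sim = replace(cfg.simulation, seed=cfg.stage_seed("simulate"))
    bundle = generate_bundle(sim)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    write_bundle(bundle, cfg.outdir)
    _manifest(cfg, "simulate", sim.seed,
              {"species": sim.n_species, "cells": sim.n_cells}, time.perf_counter() - t0)


def stage_grid(cfg: PipelineConfig) -> None:
    t0 = time.perf_counter()
    occ = pd.read_csv(_need(cfg, "occurrences.csv", "simulate"), keep_default_na=False)
    grid = pd.read_csv(_need(cfg, "grid.csv", "simulate"))
    matrix = rasterize_ranges(ranges_from_frame(occ), cells_from_frame(grid))
    matrix.to_csv(cfg.outdir / "community_matrix.csv")
    richness_table(matrix).to_csv(cfg.outdir / "richness.csv")
    _manifest(cfg, "grid", None,
              {"cells": len(matrix.cells), "species": len(matrix.species),
               "presences": int(matrix.data.to_numpy().sum())},
              time.perf_counter() - t0)


def stage_env(cfg: PipelineConfig) -> None:
    t0 = time.perf_counter()
    climate = pd.read_csv(_need(cfg, "climate_monthly.csv", "simulate"))
    grid = pd.read_csv(_need(cfg, "grid.csv", "simulate"))
    veg = pd.read_csv(_need(cfg, "vegetation.csv", "simulate"))
    env = env_mod.compute_environment(climate, grid, veg, cfg.soil_capacity)
    env.to_csv(cfg.outdir / "environment.csv")
    _manifest(cfg, "env", None, {"cells": len(env)}, time.perf_counter() - t0)


def stage_pd(cfg: PipelineConfig) -> None:
    t0 = time.perf_counter()
    tree = phylo_mod.parse_newick(_need(cfg, "tree.nwk", "simulate").read_text())
    matrix = _load_matrix(cfg)
    table = phylo_mod.pd_table(tree, matrix, include_stem=cfg.pd_include_stem)
    table.to_csv(cfg.outdir / "pd.csv")
    _manifest(cfg, "pd", None, {"cells": len(table)}, time.perf_counter() - t0)


def stage_nri(cfg: PipelineConfig) -> None:
    t0 = time.perf_counter()
    tree = phylo_mod.parse_newick(_need(cfg, "tree.nwk", "simulate").read_text())
    matrix = _load_matrix(cfg)
    seed = cfg.stage_seed("nri")
    table = phylo_mod.nri(matrix, tree, n_iter=cfg.n_iter, seed=seed)
    table.to_csv(cfg.outdir / "nri.csv")
    _manifest(cfg, "nri", seed,
              {"cells": len(table), "valid": int(table["nri"].notna().sum()),
               "n_iterations": cfg.n_iter},
              time.perf_counter() - t0)


def stage_correlate(cfg: PipelineConfig) -> None:
    t0 = time.perf_counter()
    rich = pd.read_csv(_need(cfg, "richness.csv", "grid"), index_col="cell")
    pd_div = pd.read_csv(_need(cfg, "pd.csv", "pd"), index_col="cell")
    env = pd.read_csv(_need(cfg, "environment.csv", "env"), index_col="cell")
    table = stats_mod.spearman_table(rich, pd_div, env)
    table.to_csv(cfg.outdir / "correlations.csv")
    _manifest(cfg, "correlate", None, {"variables": len(table)}, time.perf_counter() - t0)


def stage_varpart(cfg: PipelineConfig) -> None:
    """Two decompositions of richness variance: climate vs. habitat
    heterogeneity, and (within climate) energy vs. water availability."""
    t0 = time.perf_counter()
    rich = pd.read_csv(_need(cfg, "richness.csv", "grid"), index_col="cell")
    env = pd.read_csv(_need(cfg, "environment.csv", "env"), index_col="cell")
    env = env.loc[rich.index]
    seed = cfg.stage_seed("varpart")
    rows = []
    specs = [
        ("climate_vs_heterogeneity", CLIMATE_VARS, HETERO_VARS),
        ("energy_vs_water", ENERGY_VARS, WATER_VARS),
    ]
    for group in ("all", "herbaceous", "woody"):
        y = rich[group]
        if y.std(ddof=0) == 0:
            continue
        for name, vars_a, vars_b in specs:
            part = stats_mod.variance_partition(
                y, env[vars_a], env[vars_b],
                n_perm=cfg.n_perm, seed=seed, adjusted=cfg.adjusted_r2,
            )
            rows.append(
                {
                    "group": group, "comparison": name,
                    "frac_a": part.frac_a, "frac_b": part.frac_b,
                    "frac_c": part.frac_c, "frac_d": part.frac_d,
                    "r2_full": part.r2_full, "r2_A": part.r2_A, "r2_B": part.r2_B,
                    "p_full": part.p_full, "p_A": part.p_A, "p_B": part.p_B,
                }
            )
    pd.DataFrame(rows).to_csv(cfg.outdir / "varpart.csv", index=False)
    _manifest(cfg, "varpart", seed, {"rows": len(rows)}, time.perf_counter() - t0)


def stage_segmented(cfg: PipelineConfig) -> None:
    """Breakpoint regressions of NRI on MAT, MTCM and log10(AP)."""
    t0 = time.perf_counter()
    nri = pd.read_csv(_need(cfg, "nri.csv", "nri"), index_col="cell")
    env = pd.read_csv(_need(cfg, "environment.csv", "env"), index_col="cell")
    joined = env.join(nri["nri"], how="inner").dropna(subset=["nri"])
    rows = []
    for var, transform in (("MAT", None), ("MTCM", None), ("AP", "log10")):
        x = joined[var].to_numpy()
        label = var
        if transform == "log10":
            keep = x > 0
            x = np.log10(x[keep])
            y = joined["nri"].to_numpy()[keep]
            label = "log10_AP"
        else:
            y = joined["nri"].to_numpy()
        try:
            fit = stats_mod.piecewise_fit(x, y)
        except ValueError as exc:
            log.warning("segmented fit failed for %s: %s", label, exc)
            continue
        rows.append(
            {
                "variable": label, "breakpoint": fit.breakpoint,
                "slope_left": fit.slope_left, "slope_right": fit.slope_right,
                "r2_overall": fit.r2_overall,
                "r2_left": fit.r2_left, "r2_right": fit.r2_right,
                "n_left": fit.n_left, "n_right": fit.n_right,
            }
        )
    pd.DataFrame(rows).to_csv(cfg.outdir / "piecewise.csv", index=False)
    _manifest(cfg, "segmented", None, {"fits": len(rows)}, time.perf_counter() - t0)


def stage_moran(cfg: PipelineConfig) -> None:
    t0 = time.perf_counter()
    rich = pd.read_csv(_need(cfg, "richness.csv", "grid"), index_col="cell")
    env = pd.read_csv(_need(cfg, "environment.csv", "env"), index_col="cell")
    grid = pd.read_csv(_need(cfg, "grid.csv", "simulate")).set_index("cell")
    env = env.loc[rich.index]
    grid = grid.loc[rich.index]
    w = stats_mod.great_circle_weights(grid["lon_mid"], grid["lat_mid"])
    raw, r2, resid = stats_mod.residual_autocorrelation(rich["all"], env, w)
    pd.DataFrame(
        [
            {"series": "richness", "moran_i": raw.I, "expected": raw.expected,
             "z": raw.z, "p": raw.p_value, "ols_r2": r2},
            {"series": "ols_residuals", "moran_i": resid.I, "expected": resid.expected,
             "z": resid.z, "p": resid.p_value, "ols_r2": r2},
        ]
    ).to_csv(cfg.outdir / "moran.csv", index=False)
    _manifest(cfg, "moran", None, {"cells": len(rich)}, time.perf_counter() - t0)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "grid": stage_grid,
    "env": stage_env,
    "pd": stage_pd,
    "nri": stage_nri,
    "correlate": stage_correlate,
    "varpart": stage_varpart,
    "segmented": stage_segmented,
    "moran": stage_moran,
}


def run(stage: str, cfg: PipelineConfig) -> None:
    """Run one stage, or every stage in order with ``stage='all'``."""
    if stage == "all":
        for name in STAGES:
            _STAGE_FUNCS[name](cfg)
    elif stage in _STAGE_FUNCS:
        _STAGE_FUNCS[stage](cfg)
    else:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES + ['all']}")
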