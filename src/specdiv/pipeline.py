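"""End-to-end orchestration: simulate -> preprocess -> diversity -> stats.

``run_all`` executes every stage into a run directory and writes a manifest
with a SHA-256 hash per output file, so identical configuration and seed
give an identical manifest. Stage failures abort with an error labeled by
the stage that raised it. A single root seed deterministically derives the
per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io, plants, preprocess, scene, spectral, stats

__all__ = ["RunConfig", "run_all", "StageError"]

log = logging.getLogger("specdiv")


class SceneSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_plots: int = 12
    n_species: int = 12
    plot_side: float = 20.0
    pixel_size: float = 1.0
    wavelength_start: float = 380.0
    wavelength_stop: float = 2510.0
    wavelength_step: float = 5.0
    gradient_strength: float = Field(12.0, ge=0)
    noise_sd: float = Field(0.005, ge=0)
    shade_fraction: float = Field(0.08, ge=0, le=1)
    bare_soil_fraction: float = Field(0.10, ge=0, le=1)
    decouple_inventory: bool = False

    def to_scene_config(self, seed: int) -> scene.SceneConfig:
        grid = np.arange(
            self.wavelength_start, self.wavelength_stop + self.wavelength_step / 2,
            self.wavelength_step,
        )
        return scene.SceneConfig(
            n_plots=self.n_plots,
            plot_side=self.plot_side,
            pixel_size=self.pixel_size,
            wavelengths=grid,
            gradient_strength=self.gradient_strength,
            noise_sd=self.noise_sd,
            shade_fraction=self.shade_fraction,
            bare_soil_fraction=self.bare_soil_fraction,
            seed=seed,
        )


class MaskSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ndvi_threshold: float = Field(0.5, ge=-1, le=1)
    vegetation_type: str = "forest"
    shade_thresholds: dict[str, float] = Field(
        default_factory=lambda: dict(preprocess.SHADE_THRESHOLDS)
    )
    min_valid_fraction: float = Field(0.5, ge=0, le=1)

    def to_mask_config(self) -> preprocess.MaskConfig:
        return preprocess.MaskConfig(
            ndvi_threshold=self.ndvi_threshold,
            shade_thresholds=dict(self.shade_thresholds),
            min_valid_fraction=self.min_valid_fraction,
        )


class RunConfig(BaseModel):
    """Schema-validated configuration for a full pipeline run; unknown keys
    are rejected."""

    model_config = ConfigDict(extra="forbid")
    scene: SceneSettings = Field(default_factory=SceneSettings)
    mask: MaskSettings = Field(default_factory=MaskSettings)
    variance_target: float = Field(0.95, gt=0, le=1)
    resolution: float = Field(0.1, gt=0, le=0.5)
    n_perm: int = Field(999, ge=1)
    seed: int = 0
    log_level: str = "INFO"


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def require_path(path: str | Path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"missing input path: {p}")
    return p


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # label the failing stage
                raise StageError(name, str(exc)) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("simulate")
def _simulate(config: RunConfig, out: Path, seed: int) -> dict[str, Any]:
    cfg = config.scene.to_scene_config(seed)
    scn, inventory, tree = scene.simulate_study(
        cfg,
        n_species=config.scene.n_species,
        seed=seed,
        decouple_inventory=config.scene.decouple_inventory,
    )
    cube = io.scene_to_cube(scn)
    io.write_cube(cube, out / "cube.tif")
    io.write_plot_polygons(cube.plot_polygons, out / "plots.geojson")
    io.write_tree_table(scn.tree_table, out / "trees.csv")
    species = scn.library.species
    under = pd.DataFrame(scn.understory, index=scn.plot_ids, columns=species)
    io.write_cover_matrix(under, out / "understory_cover.csv")
    inv = pd.DataFrame(inventory, index=scn.plot_ids, columns=species)
    io.write_cover_matrix(inv, out / "inventory_cover.csv")
    io.write_lai(pd.Series(scn.lai, index=scn.plot_ids), out / "lai.csv")
    io.write_phylogeny(tree, out / "phylogeny.nwk")
    return {"scene": scn, "tree": tree, "cube": cube}


@_stage("preprocess")
def _preprocess(config: RunConfig, out: Path, cube: io.SpectralCube) -> dict[str, Any]:
    kept, rejected = preprocess.preprocess_site(
        cube, config.mask.to_mask_config(), config.mask.vegetation_type
    )
    if not kept:
        raise ValueError("every plot was rejected by the valid-pixel rule")
    np.savez(
        out / "plot_pixels.npz",
        **{pid: m.pixels for pid, m in kept.items()},
        _wavelengths=next(iter(kept.values())).wavelengths,
    )
    (out / "rejected_plots.json").write_text(json.dumps(sorted(rejected)))
    return {"kept": kept, "rejected": rejected}


@_stage("spectral")
def _spectral(config: RunConfig, out: Path, kept) -> dict[str, Any]:
    model, scores = spectral.fit_pooled_pca(kept, config.variance_target)
    alpha = spectral.site_spectral_alpha(scores)
    means = spectral.plot_mean_spectra(kept)
    beta = spectral.spectral_beta_distances(means)
    alpha.to_csv(out / "spectral_alpha.csv")
    means.to_csv(out / "plot_mean_spectra.csv")
    beta.to_csv(out / "spectral_beta.csv")
    (out / "pca_model.json").write_text(
        json.dumps(
            {
                "n_retained": model.n_retained,
                "variance_fraction": model.variance_fraction.tolist(),
                "eigenvalues": model.eigenvalues.tolist(),
            }
        )
    )
    return {"model": model, "alpha": alpha, "means": means, "beta": beta}


@_stage("plantdiv")
def _plantdiv(config: RunConfig, out: Path, scn, tree, inventory: pd.DataFrame, kept_ids) -> dict[str, Any]:
    keep_rows = [p for p in inventory.index if p in kept_ids]
    if config.scene.decouple_inventory:
        # calibration mode: the inventory is an independent community draw
        # with no rendered counterpart, so it is used as-is
        combined = inventory.loc[keep_rows].copy()
    else:
        is_tree = np.array([f == "tree" for f in scn.library.growth_form])
        # plots rejected on the spectral side drop out of all joint analyses
        understory = inventory.loc[keep_rows, ~is_tree]
        combined = plants.combine_site_cover(
            scn.tree_table, understory, scn.config.plot_side, config.resolution
        )
    # species never seen anywhere would make Hellinger rows ill-defined
    combined = combined.loc[:, combined.sum(axis=0) > 0]
    C = plants.phylo_covariance(tree)
    div = plants.diversity_table(combined, C=C)
    hel = plants.hellinger_transform(combined)
    beta = plants.taxonomic_beta_distances(hel)
    io.write_cover_matrix(combined, out / "combined_cover.csv")
    div.to_csv(out / "diversity.csv")
    beta.to_csv(out / "taxonomic_beta.csv")
    return {"combined": combined, "diversity": div, "hellinger": hel, "beta": beta}


@_stage("stats")
def _stats(config: RunConfig, out: Path, spec_res, plant_res, scn, kept_ids, seed: int) -> dict[str, Any]:
    beta_s = spec_res["beta"]
    beta_t = plant_res["beta"].loc[beta_s.index, beta_s.index]
    pooled = stats.distance_regression(
        beta_s, beta_t, scope="pairwise-pooled", mantel=True,
        n_perm=config.n_perm, seed=seed,
    )
    per_plot = stats.distance_regression(beta_s, beta_t, scope="per-plot")

    X = spec_res["means"]
    Y = plant_res["hellinger"].loc[X.index]
    ci_model = stats.CoInertia(X, Y)
    ci = ci_model.fit(n_permutations=config.n_perm, seed=seed + 1)
    # variance explained on the first two co-inertia axes (the plane an
    # ordination plot shows); with all axes kept the statistic saturates
    # whenever plots <= features
    varex = stats.variance_explained(ci, ci_model, n_axes=2)

    lai = pd.Series(scn.lai, index=scn.plot_ids).loc[list(kept_ids)]
    table = plant_res["diversity"].join(spec_res["alpha"]).assign(lai=lai)
    lai_reg = stats.lai_class_regressions(table)

    rows = []
    for r in (pooled, per_plot):
        rows.append(
            dict(
                analysis="distance_regression", scope=r.scope, n=r.fit.n,
                slope=r.fit.slope, intercept=r.fit.intercept,
                r_squared=r.fit.r_squared, t_value=r.fit.t_value,
                p_value=r.fit.p_value, mantel_p=r.mantel_p,
            )
        )
    pd.DataFrame(rows).to_csv(out / "distance_regressions.csv", index=False)
    lai_reg.to_csv(out / "lai_class_regressions.csv", index=False)
    summary = {
        "pooled_slope": pooled.fit.slope,
        "pooled_r_squared": pooled.fit.r_squared,
        "pooled_p": pooled.fit.p_value,
        "pooled_mantel_p": pooled.mantel_p,
        "coinertia_total": ci.total_coinertia,
        "coinertia_rv": ci.rv,
        "coinertia_p": ci.p_value,
        "variance_explained": varex,
        "n_plots_retained": len(kept_ids),
    }
    (out / "stats_summary.json").write_text(json.dumps(summary, indent=1))
    return {"pooled": pooled, "per_plot": per_plot, "coinertia": ci,
            "variance_explained": varex, "lai_regressions": lai_reg,
            "summary": summary}


def run_all(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run the full pipeline into ``out_dir`` and write ``manifest.json``.

    Returns the in-memory results of every stage (keys: simulate,
    preprocess, spectral, plantdiv, stats, manifest).
    """
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(message)s")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    root = np.random.default_rng(config.seed)
    stage_seeds = root.integers(0, 2**31 - 1, size=3)

    sim = _simulate(config, out, int(stage_seeds[0]))
    pre = _preprocess(config, out, sim["cube"])
    spec_res = _spectral(config, out, pre["kept"])
    inventory = io.read_cover_matrix(out / "inventory_cover.csv")
    kept_ids = list(pre["kept"])
    plant_res = _plantdiv(config, out, sim["scene"], sim["tree"], inventory, kept_ids)
    stat_res = _stats(config, out, spec_res, plant_res, sim["scene"], kept_ids,
                      int(stage_seeds[2]))

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "simulate": sim, "preprocess": pre, "spectral": spec_res,
        "plantdiv": plant_res, "stats": stat_res, "manifest": manifest,
    }
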