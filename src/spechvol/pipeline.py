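"""End-to-end pipeline: simulate/load -> preprocess -> PCA -> hypervolumes
-> resampling protocol -> biodiversity-effect partition -> regressions.

A single master seed is fanned out to per-stage seeds through named
SeedSequence children, so reruns with the same config are bit-identical and
stages stay independent. Every output CSV embeds the stage seed in a header
comment; a JSON manifest records inputs, seeds and row counts per stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SpechvolError, InvalidArgumentError
from .partition import overyielding_table, yields_from_frame
from .pca import fit_pca, project
from .protocol import iterated_hypervolume, resample_table
from .regression import analysis_suite
from .simulate import SyntheticConfig, simulate_experiment
from .spectra import (read_spectra, resample_1nm, splice_correct, trim,
                      write_spectra)
from .hypervolume import fit_hypervolume

log = logging.getLogger("spechvol")

_STAGES = ("simulate", "preprocess", "pca", "hypervolume", "protocol",
           "partition", "regression")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([master, stage index])."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence(
        [int(master_seed), idx]).generate_state(1)[0] % 2 ** 31)


@dataclass
class PipelineConfig:
    """Flat, YAML-compatible configuration of one pipeline run."""

    out_dir: str = "spechvol_out"
    experiment: str = "BioDIV"
    spectra_path: str | None = None      # None -> simulate
    design_path: str | None = None       # required with spectra_path
    yields_path: str | None = None       # None -> simulated yields
    dialect: str = "wide"
    junctions: tuple[float, ...] = (1000.0, 1900.0)
    trim_lo: float = 400.0
    trim_hi: float = 2400.0
    k: int = 3
    mass_quantile: float = 0.95
    n_sub: int | None = None             # None -> protocol default per design
    n_iter: int = 50
    n_mc: int = 10_000
    seed: int = 42
    richness_levels: tuple[int, ...] = (1, 2, 4, 8)
    plots_per_level: int = 6
    n_species_pool: int = 14
    complementarity_beta: float = 0.08
    selection_beta: float = 0.0
    yield_noise_sd: float = 0.05

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**obj)
        for key in ("junctions", "richness_levels"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def _designs_from_csv(path) -> list:
    """PlotDesigns from a CSV with experiment, plot_id, richness, species_list."""
    from .protocol import PlotDesign
    df = pd.read_csv(path, comment="#")
    designs = []
    for _, row in df.iterrows():
        designs.append(PlotDesign(
            experiment=str(row["experiment"]), plot_id=str(row["plot_id"]),
            richness=int(row["richness"]),
            species_list=tuple(str(row["species_list"]).split(";"))))
    return designs


def _write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spechvol {__version__} seed={seed}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(config).items()},
                      "stages": {}}

    # --- simulate or load -------------------------------------------------
    experiment = None
    if config.spectra_path is None:
        sim_seed = stage_seed(config.seed, "simulate")
        syn = SyntheticConfig(
            experiment=config.experiment,
            richness_levels=tuple(config.richness_levels),
            plots_per_level=config.plots_per_level,
            n_species_pool=config.n_species_pool,
            complementarity_beta=config.complementarity_beta,
            selection_beta=config.selection_beta,
            yield_noise_sd=config.yield_noise_sd,
            seed=sim_seed)
        experiment = simulate_experiment(syn)
        collection = experiment.spectra
        spectra_csv = out / "spectra.csv"
        write_spectra(collection, spectra_csv, dialect="wide",
                      header_comment=f"spechvol {__version__} seed={sim_seed}")
        _write_csv(experiment.design, out / "design.csv", sim_seed)
        _write_csv(experiment.mixture_yields, out / "yields.csv", sim_seed)
        designs = experiment.plot_designs
        manifest["stages"]["simulate"] = {
            "seed": sim_seed, "n_spectra": len(collection),
            "n_plots": len(designs),
            "true_effects": experiment.true_effects}
        log.info("simulate: %d spectra in %d plots", len(collection),
                 len(designs))
    else:
        collection = read_spectra(config.spectra_path, dialect=config.dialect)
        if config.design_path is None:
            raise InvalidArgumentError(
                "design_path is required when loading external spectra")
        designs = _designs_from_csv(config.design_path)
        manifest["stages"]["load"] = {"path": str(config.spectra_path),
                                      "n_spectra": len(collection)}
        log.info("load: %d spectra from %s", len(collection),
                 config.spectra_path)

    # --- preprocess -------------------------------------------------------
    def prep(s):
        s = splice_correct(s, config.junctions)
        s = trim(s, config.trim_lo, config.trim_hi)
        return resample_1nm(s)

    collection = collection.map(prep)
    manifest["stages"]["preprocess"] = {
        "junctions": list(config.junctions),
        "trim": [config.trim_lo, config.trim_hi],
        "n_bands": len(collection[0]) if len(collection) else 0}

    # --- PCA --------------------------------------------------------------
    matrix = collection.to_matrix()
    model = fit_pca(matrix)
    scores = project(model, matrix, k=config.k)
    meta = collection.meta_frame()
    model.to_json(out / "model.json")
    score_df = pd.concat(
        [meta.reset_index(drop=True),
         pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(config.k)])],
        axis=1)
    _write_csv(score_df, out / "scores.csv", config.seed)
    var3 = float(model.variance_fraction[:config.k].sum())
    manifest["stages"]["pca"] = {"k": config.k, "n_fit": model.n_fit,
                                 "variance_fraction_k": var3}
    log.info("pca: first %d axes explain %.2f%% of variance", config.k,
             100 * var3)

    # --- full-sample hypervolumes (diagnostic) and protocol ---------------
    hv_seed = stage_seed(config.seed, "hypervolume")
    proto_seed = stage_seed(config.seed, "protocol")
    vol_rows, results, excluded = [], [], []
    for design in designs:
        mask = (meta["plot_id"] == design.plot_id).to_numpy()
        plot_scores = scores[mask]
        plot_meta = meta[mask].reset_index(drop=True)
        hv = fit_hypervolume(plot_scores, mass_quantile=config.mass_quantile,
                             n_mc=config.n_mc, seed=hv_seed)
        vol_rows.append({"plot_id": design.plot_id,
                         "n_points": int(mask.sum()), "dim": config.k,
                         "log_volume": hv.log_volume, "volume": hv.volume,
                         "threshold_density": hv.threshold_density,
                         "seed": hv_seed})
        try:
            results.append(iterated_hypervolume(
                plot_scores, plot_meta, design, n_sub=config.n_sub,
                n_iter=config.n_iter, mass_quantile=config.mass_quantile,
                n_mc=config.n_mc, seed=proto_seed))
        except SpechvolError as exc:
            excluded.append(design.plot_id)
            log.warning("protocol: excluding plot %s (%s)", design.plot_id, exc)
    _write_csv(pd.DataFrame(vol_rows), out / "volumes.csv", hv_seed)
    hv_table = resample_table(results)
    _write_csv(hv_table, out / "community_hv.csv", proto_seed)
    manifest["stages"]["protocol"] = {
        "seed": proto_seed, "n_iter": config.n_iter,
        "n_communities": len(results), "excluded_plots": excluded}

    # --- partition --------------------------------------------------------
    if config.yields_path is not None:
        yields_df = pd.read_csv(config.yields_path, comment="#")
    elif experiment is not None:
        yields_df = experiment.mixture_yields
    else:
        raise InvalidArgumentError(
            "yields_path is required when loading external spectra")
    nbe = overyielding_table(yields_from_frame(yields_df))
    _write_csv(nbe, out / "nbe.csv", config.seed)
    manifest["stages"]["partition"] = {
        "n_plots": len(nbe), "n_analyzed": int(nbe["analyzed"].sum())}

    # --- regressions ------------------------------------------------------
    richness = (yields_df.groupby("plot_id")["species_id"].nunique()
                .rename("richness").reset_index())
    total_yield = (yields_df.groupby("plot_id")["Y_O"].sum()
                   .rename("biomass").reset_index())
    covars = nbe.merge(richness, on="plot_id").merge(total_yield, on="plot_id")
    pairs = [("mean_log_volume", "NBE"), ("mean_log_volume", "CE"),
             ("mean_log_volume", "SE"), ("mean_log_volume", "richness"),
             ("mean_log_volume", "biomass")]
    fits = analysis_suite(hv_table, covars, pairs)
    _write_csv(fits, out / "fits.csv", config.seed)
    manifest["stages"]["regression"] = {"n_fits": len(fits)}

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
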