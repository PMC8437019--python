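"""Sampling designs and the fixed-size iterated-resampling protocol.

KDE hypervolume size grows with the number of points used to fit it, so
communities sampled with different intensities are not directly comparable.
The protocol removes that bias by fitting every community hypervolume on a
fixed-size random subsample — 9 spectra per plot in the tree-diversity (FAB)
design, 12 individuals (3 from each of 4 random subplots) in the prairie
(BioDIV) design — iterating the random selection (50 times by default) and
summarizing the mean and SD of log volume across iterates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ProtocolError
from .hypervolume import fit_hypervolume


def biodiv_subplots_sampled(richness: int) -> int:
    """Subplots sampled per BioDIV plot: 4 for richness <= 2, 6 below 8, else 8."""
    if richness <= 2:
        return 4
    if richness < 8:
        return 6
    return 8


@dataclass(frozen=True)
class PlotDesign:
    """Sampling design of one plot in either experiment.

    FAB plots record individuals_per_species and layers_per_individual;
    BioDIV plots record subplots_sampled and individuals_per_subplot.
    """

    experiment: str
    plot_id: str
    richness: int
    species_list: tuple[str, ...] = ()
    subplots_sampled: int | None = None
    individuals_per_subplot: int | None = None
    individuals_per_species: int | None = None
    layers_per_individual: int | None = None

    def __post_init__(self):
        if self.experiment not in ("FAB", "BioDIV"):
            raise InvalidArgumentError(f"unknown experiment {self.experiment!r}")
        if self.richness < 1:
            raise InvalidArgumentError("richness must be >= 1")
        if self.species_list and len(self.species_list) != self.richness:
            raise InvalidArgumentError(
                f"richness {self.richness} != |species_list| "
                f"{len(self.species_list)} for plot {self.plot_id}")


def fab_design(plot_id: str, species: tuple[str, ...],
               individuals_per_species: int = 3,
               layers_per_individual: int = 3) -> PlotDesign:
    return PlotDesign(experiment="FAB", plot_id=plot_id, richness=len(species),
                      species_list=tuple(species),
                      individuals_per_species=individuals_per_species,
                      layers_per_individual=layers_per_individual)


def biodiv_design(plot_id: str, species: tuple[str, ...],
                  individuals_per_subplot: int = 4) -> PlotDesign:
    r = len(species)
    return PlotDesign(experiment="BioDIV", plot_id=plot_id, richness=r,
                      species_list=tuple(species),
                      subplots_sampled=biodiv_subplots_sampled(r),
                      individuals_per_subplot=individuals_per_subplot)


def expected_sample_counts(design: PlotDesign) -> dict[str, int]:
    """Expected individuals and spectra per plot under the design rules.

    FAB: individuals = richness x individuals_per_species; spectra =
    individuals x layers_per_individual (one averaged spectrum per canopy
    layer). BioDIV: one averaged spectrum per individual; individuals =
    subplots_sampled x individuals_per_subplot.
    """
    if design.experiment == "FAB":
        ips = design.individuals_per_species or 3
        lpi = design.layers_per_individual or 3
        n_ind = design.richness * ips
        return {"n_individuals": n_ind, "n_spectra": n_ind * lpi}
    if design.experiment == "BioDIV":
        sp = design.subplots_sampled or biodiv_subplots_sampled(design.richness)
        ipp = design.individuals_per_subplot or 4
        n_ind = sp * ipp
        return {"n_individuals": n_ind, "n_spectra": n_ind}
    raise InvalidArgumentError(f"unknown experiment {design.experiment!r}")


@dataclass(frozen=True)
class ResampleResult:
    """Iterated fixed-size hypervolume summary for one plot."""

    plot_id: str
    n_sub: int
    n_iter: int
    mean_log_volume: float
    sd_log_volume: float
    per_iterate_volumes: np.ndarray = field(repr=False)


def subsample_community(meta: pd.DataFrame, design: PlotDesign,
                        n_sub: int | None = None,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Row indices of one fixed-size random subsample of a plot's spectra.

    meta is the metadata table of the plot's spectra (one row per spectrum;
    BioDIV rows need a subplot_id column). FAB: a simple random sample of
    n_sub rows without replacement (default 9). BioDIV: 4 subplots chosen
    uniformly without replacement, then 3 individuals per chosen subplot
    (n_sub = 12). Plots with too few members raise ProtocolError and are
    excluded from analysis.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(meta)
    if design.experiment == "FAB":
        n_sub = 9 if n_sub is None else int(n_sub)
        if n < n_sub:
            raise ProtocolError(
                f"plot {design.plot_id}: {n} spectra < n_sub={n_sub}")
        return np.sort(rng.choice(n, size=n_sub, replace=False))
    # BioDIV: 3 individuals from each of 4 subplots
    n_subplots, per_subplot = 4, 3
    if n_sub is not None and n_sub != n_subplots * per_subplot:
        raise InvalidArgumentError(
            "BioDIV protocol is fixed at 3 individuals x 4 subplots (n_sub=12)")
    if "subplot_id" not in meta.columns:
        raise InvalidArgumentError("BioDIV subsampling needs a subplot_id column")
    groups = meta.groupby("subplot_id", sort=True).indices
    eligible = {k: np.asarray(v) for k, v in groups.items()
                if len(v) >= per_subplot}
    if len(eligible) < n_subplots:
        raise ProtocolError(
            f"plot {design.plot_id}: only {len(eligible)} subplots with >= "
            f"{per_subplot} individuals (need {n_subplots})")
    keys = sorted(eligible)
    chosen = rng.choice(len(keys), size=n_subplots, replace=False)
    idx = [rng.choice(eligible[keys[c]], size=per_subplot, replace=False)
           for c in chosen]
    return np.sort(np.concatenate(idx))


def iterate_seed(master_seed: int, iterate: int) -> np.random.Generator:
    """Counter-based per-iterate RNG: SeedSequence([master_seed, iterate])."""
    return np.random.default_rng(np.random.SeedSequence(
        [int(master_seed), int(iterate)]))


def iterated_hypervolume(scores: np.ndarray, meta: pd.DataFrame,
                         design: PlotDesign, n_sub: int | None = None,
                         n_iter: int = 50, mass_quantile: float = 0.95,
                         n_mc: int = 10_000, seed: int = 0) -> ResampleResult:
    """Mean and SD of ln(hypervolume) across fixed-size resampling iterates.

    For iterate i a subsample is drawn with an RNG seeded from (seed, i),
    a hypervolume is fitted to the subsampled score rows, and ln(volume) is
    recorded; the result is deterministic given the master seed. The
    hypervolume fit is seeded from the subsample itself, so iterates that
    draw identical subsamples yield identical volumes and the reported SD
    reflects sampling variation only.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(meta):
        raise InvalidArgumentError("scores and meta must have equal row counts")
    if n_iter < 1:
        raise InvalidArgumentError("n_iter must be >= 1")
    log_vols = np.empty(n_iter)
    for i in range(n_iter):
        rng = iterate_seed(seed, i)
        idx = subsample_community(meta, design, n_sub=n_sub, seed=rng)
        hv_seed = int(np.random.SeedSequence(
            [int(seed)] + [int(j) for j in idx]).generate_state(1)[0] % 2 ** 31)
        hv = fit_hypervolume(scores[idx], mass_quantile=mass_quantile,
                             n_mc=n_mc, seed=hv_seed)
        log_vols[i] = hv.log_volume
    resolved_n_sub = (len(idx) if n_sub is None else int(n_sub))
    return ResampleResult(plot_id=design.plot_id, n_sub=resolved_n_sub,
                          n_iter=n_iter,
                          mean_log_volume=float(log_vols.mean()),
                          sd_log_volume=float(log_vols.std(ddof=1))
                          if n_iter > 1 else 0.0,
                          per_iterate_volumes=np.exp(log_vols))


def resample_table(results: list[ResampleResult]) -> pd.DataFrame:
    """Tabulate ResampleResults (one row per plot)."""
    return pd.DataFrame([{
        "plot_id": r.plot_id, "n_sub": r.n_sub, "n_iter": r.n_iter,
        "mean_log_volume": r.mean_log_volume,
        "sd_log_volume": r.sd_log_volume,
    } for r in results])
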