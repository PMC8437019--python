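"""Overyielding and the Loreau-Hector additive partition of the NBE.

For a mixture plot with N species, monoculture yields M_i, observed mixture
yields Y_Oi and expected relative yields RY_Ei (planting proportions summing
to 1):

    RY_Oi = Y_Oi / M_i                 observed relative yield
    dRY_i = RY_Oi - RY_Ei              relative-yield deviation
    NBE   = sum_i Y_Oi - sum_i RY_Ei M_i       net biodiversity effect
    CE    = N * mean(dRY) * mean(M)            complementarity effect
    SE    = N * cov(dRY, M)                    selection effect

with the population covariance (denominator N), which makes the identity
NBE = CE + SE exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

_RYE_TOL = 1e-8


@dataclass(frozen=True)
class MixturePlotYields:
    """Per-species yields of one mixture plot.

    RY_E defaults to equal planting proportions 1/N (substitutive design).
    """

    plot_id: str
    species: tuple[str, ...]
    M: np.ndarray
    Y_O: np.ndarray
    RY_E: np.ndarray | None = None

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        Y = np.asarray(self.Y_O, dtype=float)
        n = len(self.species)
        if M.size != n or Y.size != n:
            raise InvalidArgumentError(
                f"plot {self.plot_id}: species, M and Y_O lengths differ")
        if np.any(M <= 0):
            raise InvalidArgumentError(
                f"plot {self.plot_id}: monoculture yields must be positive")
        if np.any(Y < 0):
            raise InvalidArgumentError(
                f"plot {self.plot_id}: observed yields must be non-negative")
        ry = (np.full(n, 1.0 / n) if self.RY_E is None
              else np.asarray(self.RY_E, dtype=float))
        if ry.size != n or np.any(ry <= 0) or np.any(ry > 1):
            raise InvalidArgumentError(
                f"plot {self.plot_id}: RY_E must be in (0, 1] per species")
        if abs(ry.sum() - 1.0) > _RYE_TOL:
            raise InvalidArgumentError(
                f"plot {self.plot_id}: RY_E must sum to 1 (got {ry.sum():.10f})")
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "Y_O", Y)
        object.__setattr__(self, "RY_E", ry)

    @property
    def richness(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class PartitionResult:
    """Additive partition NBE = CE + SE plus per-species dRY."""

    plot_id: str
    richness: int
    NBE: float
    CE: float
    SE: float
    delta_RY: np.ndarray


def partition_nbe(p: MixturePlotYields) -> PartitionResult:
    """Loreau-Hector partition of the net biodiversity effect of one plot."""
    n = p.richness
    ry_o = p.Y_O / p.M
    d_ry = ry_o - p.RY_E
    nbe = float(p.Y_O.sum() - (p.RY_E * p.M).sum())
    ce = float(n * d_ry.mean() * p.M.mean())
    # population covariance (denominator N): required for NBE = CE + SE
    se = float(n * np.mean((d_ry - d_ry.mean()) * (p.M - p.M.mean())))
    return PartitionResult(plot_id=p.plot_id, richness=n, NBE=nbe, CE=ce,
                           SE=se, delta_RY=d_ry)


def overyielding_table(yields: list[MixturePlotYields]) -> pd.DataFrame:
    """Partition every plot; one row each.

    Monoculture plots (N = 1) cannot overyield against themselves: they are
    kept in the table with analyzed=False and NaN NBE/CE/SE.
    """
    rows = []
    for p in yields:
        if p.richness == 1:
            rows.append({"plot_id": p.plot_id, "N": 1, "NBE": np.nan,
                         "CE": np.nan, "SE": np.nan, "analyzed": False})
            continue
        r = partition_nbe(p)
        rows.append({"plot_id": r.plot_id, "N": r.richness, "NBE": r.NBE,
                     "CE": r.CE, "SE": r.SE, "analyzed": True})
    cols = ["plot_id", "N", "NBE", "CE", "SE", "analyzed"]
    return pd.DataFrame(rows, columns=cols)


def yields_from_frame(df: pd.DataFrame) -> list[MixturePlotYields]:
    """Build MixturePlotYields from a long table.

    Columns: plot_id, species_id (or species), M, Y_O, optional RY_E.
    """
    sp_col = "species_id" if "species_id" in df.columns else "species"
    required = {"plot_id", sp_col, "M", "Y_O"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise InvalidArgumentError(f"yield table missing columns: {missing}")
    out = []
    for plot_id, sub in df.groupby("plot_id", sort=False):
        out.append(MixturePlotYields(
            plot_id=str(plot_id),
            species=tuple(sub[sp_col].astype(str)),
            M=sub["M"].to_numpy(dtype=float),
            Y_O=sub["Y_O"].to_numpy(dtype=float),
            RY_E=sub["RY_E"].to_numpy(dtype=float)
            if "RY_E" in sub.columns else None))
    return out


def allometric_biomass(height: float, diameter: float,
                       coeffs: dict[str, float]) -> float:
    """Power-law stem biomass M = a * diameter^b * height^c.

    height in cm, diameter in mm, result in kg; coefficients are supplied per
    species by the user (a generic placeholder form — species-specific
    published allometries should be preferred when available). Productivity
    is the increment of this quantity between censuses (kg yr^-1).
    """
    a, b, c = coeffs["a"], coeffs["b"], coeffs["c"]
    if height <= 0 or diameter <= 0:
        raise InvalidArgumentError("height and diameter must be positive")
    if a <= 0:
        raise InvalidArgumentError("coefficient a must be positive")
    return float(a * diameter ** b * height ** c)
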