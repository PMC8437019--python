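"""Leaf reflectance spectra: containers, CSV I/O and preprocessing.

Preprocessing mirrors standard field-spectroscopy practice for leaf-clip
measurements taken with dual/triple-detector instruments: correction of the
offsets ("splices") at the detector overlap wavelengths (~1000 nm between the
Si and first InGaAs sensors, ~1900 nm between the two InGaAs sensors),
trimming of the noisy spectrum ends, linear interpolation onto a 1 nm grid,
and averaging of replicate leaf measurements per canopy layer or individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError

#: Metadata columns written to / read from spectral-library CSVs, in order.
META_COLUMNS = ("experiment", "plot_id", "subplot_id", "species_id",
                "individual_id", "layer")

#: Canopy layer labels; "NA" marks spectra already averaged per individual.
LAYERS = ("top", "mid", "bottom", "NA")

# Instrument slack accepted on input: raw reflectance may slightly undershoot
# 0 or overshoot 1 before preprocessing (white-reference noise).
_REFLECTANCE_MIN = -0.05
_REFLECTANCE_MAX = 1.5


@dataclass(frozen=True)
class Spectrum:
    """One reflectance spectrum R(lambda) with sample metadata.

    wavelengths are in nm, strictly increasing; reflectance is unitless and
    the same length. meta carries the sampling context (experiment, plot,
    species, individual, canopy layer).
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or rf.ndim != 1 or wl.size != rf.size:
            raise InvalidArgumentError(
                "wavelengths and reflectance must be 1-D arrays of equal "
                f"length (got {wl.shape} vs {rf.shape})")
        if wl.size == 0:
            raise InvalidArgumentError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise InvalidArgumentError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(rf)):
            raise InvalidArgumentError("reflectance must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)
        object.__setattr__(self, "meta", dict(self.meta))

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def with_values(self, reflectance: np.ndarray, wavelengths=None) -> "Spectrum":
        """Copy with new values (and optionally a new grid), keeping metadata."""
        wl = self.wavelengths if wavelengths is None else wavelengths
        return Spectrum(wl, reflectance, self.meta)


class SpectralCollection:
    """An ordered collection of spectra with tabular metadata.

    Members need not share a wavelength grid until resampling; matrix-based
    operations (PCA, aggregation) require a shared grid.
    """

    def __init__(self, spectra: Iterable[Spectrum]):
        self.spectra: list[Spectrum] = list(spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return SpectralCollection(self.spectra[i])
        return self.spectra[i]

    @property
    def shared_grid(self) -> np.ndarray | None:
        """The common wavelength grid, or None if members disagree."""
        if not self.spectra:
            return None
        wl0 = self.spectra[0].wavelengths
        for s in self.spectra[1:]:
            if len(s) != len(wl0) or not np.array_equal(s.wavelengths, wl0):
                return None
        return wl0

    def to_matrix(self) -> np.ndarray:
        """Stack reflectance rows (n_spectra x n_bands); requires shared grid."""
        if self.shared_grid is None:
            raise InvalidArgumentError(
                "spectra do not share a wavelength grid; resample first")
        return np.vstack([s.reflectance for s in self.spectra])

    def meta_frame(self) -> pd.DataFrame:
        """Metadata table, one row per spectrum, in collection order."""
        rows = [{k: s.meta.get(k, "") for k in META_COLUMNS} for s in self.spectra]
        return pd.DataFrame(rows, columns=list(META_COLUMNS))

    def map(self, fn) -> "SpectralCollection":
        """Apply a Spectrum -> Spectrum function to every member."""
        return SpectralCollection(fn(s) for s in self.spectra)

    def subset(self, indices: Sequence[int]) -> "SpectralCollection":
        return SpectralCollection(self.spectra[int(i)] for i in indices)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _check_reflectance_range(values: np.ndarray, where: str) -> None:
    bad = np.where((values < _REFLECTANCE_MIN) | (values > _REFLECTANCE_MAX))[0]
    if bad.size:
        raise FormatError(
            f"reflectance outside [{_REFLECTANCE_MIN}, {_REFLECTANCE_MAX}] "
            f"at {where}, position {bad[0]} (value {values[bad[0]]:g})")


def read_spectra(path, dialect: str = "wide") -> SpectralCollection:
    """Read a spectral-library CSV.

    dialect="wide": one row per spectrum; metadata columns (META_COLUMNS)
    followed by one numeric-named column per wavelength in nm.
    dialect="long": one row per (spectrum, wavelength); columns spectrum_id,
    metadata..., wavelength_nm, reflectance. Row order defines spectrum order.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if dialect == "wide":
        return _from_wide(df)
    if dialect == "long":
        return _from_long(df)
    raise InvalidArgumentError(f"unknown dialect {dialect!r}")


def _from_wide(df: pd.DataFrame) -> SpectralCollection:
    wl_cols, wl = [], []
    for c in df.columns:
        try:
            wl.append(float(c))
            wl_cols.append(c)
        except ValueError:
            continue
    if not wl_cols:
        raise FormatError("no wavelength columns found in wide CSV")
    missing = [c for c in ("plot_id", "species_id") if c not in df.columns]
    if missing:
        raise FormatError(f"missing metadata columns: {missing}")
    wl = np.asarray(wl)
    if not np.all(np.diff(wl) > 0):
        raise FormatError("wavelength columns are not strictly increasing")
    spectra = []
    for i, (_, row) in enumerate(df.iterrows()):
        values = row[wl_cols].to_numpy(dtype=float)
        _check_reflectance_range(values, f"row {i}")
        meta = {k: _clean(row[k]) for k in META_COLUMNS if k in df.columns}
        spectra.append(Spectrum(wl, values, meta))
    return SpectralCollection(spectra)


def _from_long(df: pd.DataFrame) -> SpectralCollection:
    required = {"spectrum_id", "wavelength_nm", "reflectance"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise FormatError(f"missing columns in long CSV: {missing}")
    spectra = []
    # preserve first-appearance order of spectrum ids
    for sid in df["spectrum_id"].drop_duplicates():
        sub = df[df["spectrum_id"] == sid]
        wl = sub["wavelength_nm"].to_numpy(dtype=float)
        if not np.all(np.diff(wl) > 0):
            raise FormatError(
                f"wavelengths not strictly increasing for spectrum {sid!r}")
        values = sub["reflectance"].to_numpy(dtype=float)
        _check_reflectance_range(values, f"spectrum {sid!r}")
        first = sub.iloc[0]
        meta = {k: _clean(first[k]) for k in META_COLUMNS if k in df.columns}
        spectra.append(Spectrum(wl, values, meta))
    return SpectralCollection(spectra)


def _clean(v) -> str:
    return "" if pd.isna(v) else str(v)


def write_spectra(collection: SpectralCollection, path, dialect: str = "wide",
                  header_comment: str | None = None) -> None:
    """Write a collection to CSV in the wide or long dialect."""
    if dialect not in ("wide", "long"):
        raise InvalidArgumentError(f"unknown dialect {dialect!r}")
    if dialect == "wide":
        grid = collection.shared_grid
        if grid is None:
            raise InvalidArgumentError("wide dialect requires a shared grid")
        meta = collection.meta_frame()
        mat = collection.to_matrix()
        cols = [_fmt_wl(w) for w in grid]
        df = pd.concat([meta, pd.DataFrame(mat, columns=cols)], axis=1)
    else:
        rows = []
        for i, s in enumerate(collection):
            meta = {k: s.meta.get(k, "") for k in META_COLUMNS}
            for w, r in zip(s.wavelengths, s.reflectance):
                rows.append({"spectrum_id": i, **meta,
                             "wavelength_nm": w, "reflectance": r})
        df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def _fmt_wl(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else f"{w:g}"


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def splice_correct(s: Spectrum, junctions: Sequence[float] = (1000.0, 1900.0)) -> Spectrum:
    """Remove additive discontinuities at detector-junction wavelengths.

    For each junction (processed in increasing wavelength order) the segment
    at and beyond the junction is offset so that its first band matches the
    linear extrapolation from the two bands just left of the junction.
    Detector steps in leaf-clip reflectance are offset-like, so an additive
    correction is used; it is exactly idempotent on corrected spectra.
    """
    wl, rf = s.wavelengths, s.reflectance.copy()
    for j in sorted(float(j) for j in junctions):
        if j <= wl[0] or j > wl[-1]:
            raise InvalidArgumentError(
                f"junction {j} nm outside the wavelength range "
                f"[{wl[0]}, {wl[-1]}]")
        right = int(np.searchsorted(wl, j, side="left"))
        if right < 2:
            raise InvalidArgumentError(
                f"junction {j} nm leaves fewer than two bands on the left")
        # linear extrapolation from the two bands just left of the junction
        x0, x1 = wl[right - 2], wl[right - 1]
        y0, y1 = rf[right - 2], rf[right - 1]
        slope = (y1 - y0) / (x1 - x0)
        predicted = y1 + slope * (wl[right] - x1)
        rf[right:] -= rf[right] - predicted
    return s.with_values(rf)


def trim(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep only bands with lo <= lambda <= hi (closed interval)."""
    if not lo < hi:
        raise InvalidArgumentError(f"trim window requires lo < hi (got {lo}, {hi})")
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise InvalidArgumentError(
            f"trim window [{lo}, {hi}] does not overlap the grid "
            f"[{s.wavelengths[0]}, {s.wavelengths[-1]}]")
    return s.with_values(s.reflectance[mask], s.wavelengths[mask])


def resample_1nm(s: Spectrum) -> Spectrum:
    """Linearly interpolate onto the integer-nm grid spanned by the data.

    The output grid runs ceil(min lambda) ... floor(max lambda) in 1 nm steps;
    values at original integer-nm nodes are preserved exactly and no
    extrapolation beyond the measured range is performed.
    """
    if len(s) < 2:
        raise InvalidArgumentError("resampling requires at least two bands")
    lo = math.ceil(s.wavelengths[0])
    hi = math.floor(s.wavelengths[-1])
    if hi < lo:
        raise InvalidArgumentError("no integer wavelength inside the grid")
    grid = np.arange(lo, hi + 1, dtype=float)
    if grid.size == len(s) and np.array_equal(grid, s.wavelengths):
        return s
    values = np.interp(grid, s.wavelengths, s.reflectance)
    return s.with_values(values, grid)


def aggregate_mean(collection: SpectralCollection,
                   by: Sequence[str]) -> SpectralCollection:
    """Average spectra per group of metadata keys (band-wise arithmetic mean).

    Typical uses: by=("plot_id","individual_id","layer") to average replicate
    leaves per canopy layer, or by=("plot_id","individual_id") to average per
    individual. Metadata is collapsed to the group keys; non-grouped metadata
    columns keep their value when constant within the group and are dropped
    ("" ) otherwise.
    """
    if collection.shared_grid is None:
        raise InvalidArgumentError("aggregate_mean requires a shared grid")
    by = list(by)
    grid = collection.shared_grid
    groups: dict[tuple, list[Spectrum]] = {}
    order: list[tuple] = []
    for s in collection:
        key = tuple(str(s.meta.get(k, "")) for k in by)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)
    out = []
    for key in order:
        members = groups[key]
        mean = np.mean([m.reflectance for m in members], axis=0)
        meta = dict(zip(by, key))
        for k in META_COLUMNS:
            if k in by:
                continue
            vals = {str(m.meta.get(k, "")) for m in members}
            meta[k] = vals.pop() if len(vals) == 1 else ""
        out.append(Spectrum(grid, mean, meta))
    return SpectralCollection(out)
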