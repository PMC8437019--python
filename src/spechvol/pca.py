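"""Principal-component reduction of the spectral matrix.

Leaf reflectance over 400-2400 nm is highly collinear; a covariance PCA
(centered, not per-band standardized) on the spectral matrix concentrates
nearly all variance in the leading axes, whose scores serve as the hypervolume
axes downstream. Raw reflectance is used so the physical amplitude structure
is preserved; a per-band standardized variant is available via `scale=True`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class PCAModel:
    """Fitted PCA: per-band center, orthonormal loadings, variance fractions.

    loadings has shape (n_components, n_bands); variance_fraction sums to 1
    over the full retained set. Component signs are fixed by making the
    largest-magnitude element of each loading positive, so fits are
    deterministic across BLAS implementations.
    """

    center: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    n_fit: int
    scale: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def to_json(self, path) -> None:
        obj = {
            "center": self.center.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "n_fit": self.n_fit,
            "scale": None if self.scale is None else self.scale.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(center=np.asarray(obj["center"], dtype=float),
                   loadings=np.asarray(obj["loadings"], dtype=float),
                   variance_fraction=np.asarray(obj["variance_fraction"], dtype=float),
                   n_fit=int(obj["n_fit"]),
                   scale=None if obj["scale"] is None
                   else np.asarray(obj["scale"], dtype=float))


def fit_pca(matrix: np.ndarray, scale: bool = False) -> PCAModel:
    """Fit covariance PCA (SVD-based) on a spectra x bands matrix.

    Centered but not scaled by default. All min(n-1, p) components are
    retained; use `project` with k to truncate. Deterministic up to the sign
    convention described on PCAModel.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidArgumentError("PCA requires a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("PCA input contains non-finite entries")
    sd = None
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise InvalidArgumentError("cannot standardize constant bands")
        X = X / sd
    model = _SkPCA(svd_solver="full")
    model.fit(X)
    loadings = model.components_.copy()
    # sign convention: largest-|.| element of each loading is positive
    flip = np.sign(loadings[np.arange(loadings.shape[0]),
                            np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    loadings *= flip[:, None]
    return PCAModel(center=model.mean_.copy(), loadings=loadings,
                    variance_fraction=model.explained_variance_ratio_.copy(),
                    n_fit=X.shape[0], scale=sd)


def project(model: PCAModel, matrix: np.ndarray, k: int | None = None) -> np.ndarray:
    """Project rows onto the first k components: (X - center) @ loadings_k^T."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[1] != model.center.size:
        raise InvalidArgumentError(
            f"band count {X.shape[1]} does not match the fitted model "
            f"({model.center.size})")
    if k is None:
        k = model.n_components
    if not 1 <= k <= model.n_components:
        raise InvalidArgumentError(
            f"k must be in [1, {model.n_components}] (got {k})")
    if model.scale is not None:
        X = X / model.scale
    return (X - model.center) @ model.loadings[:k].T


def k_for_variance(model: PCAModel, threshold: float) -> int:
    """Smallest k whose axes explain MORE than the threshold fraction.

    The criterion is strict ("more than 98%"); a small numerical guard keeps
    a cumulative sum that equals the threshold up to rounding from counting
    as exceeding it. Returns the full component count if no prefix does.
    """
    if not 0 < threshold <= 1:
        raise InvalidArgumentError("threshold must be in (0, 1]")
    cum = np.cumsum(model.variance_fraction)
    hit = np.nonzero(cum > threshold + 1e-9)[0]
    return int(hit[0]) + 1 if hit.size else model.n_components
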