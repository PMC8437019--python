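"""Gaussian-KDE n-dimensional hypervolumes with Silverman bandwidths.

The spectral space occupied by a set of points (PC scores of leaf spectra) is
delineated as a level set of a Gaussian kernel density estimate:

    f(x) = (1/n) sum_i N(x; p_i, diag(h^2)),

with per-dimension Silverman rule-of-thumb bandwidths

    h_j = sd_j * (4/(d+2))^(1/(d+4)) * n^(-1/(d+4)).

The hypervolume is the region {x : f(x) >= t} where the threshold t is the
empirical (1 - q) quantile of f evaluated at draws from f itself, so the
region retains a fraction q of the estimated probability mass (q = 0.95 by
default, i.e. a 5% quantile threshold). Its Lebesgue volume is estimated by
the importance-sampling identity

    Vol{f >= t} = E_{X~f}[ 1{f(X) >= t} / f(X) ],

evaluated over the same Monte Carlo draws. Sampling is performed in
bandwidth-standardized coordinates, which makes the estimate exactly
equivariant under axis scaling (volume(c*X) = c^d * volume(X) for the same
seed) and invariant under translation.

A brute-force grid-integration oracle is provided for d <= 2 to verify the
Monte Carlo estimator independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, InvalidArgumentError

_LOG_2PI = float(np.log(2.0 * np.pi))


def silverman_bandwidths(points: np.ndarray) -> np.ndarray:
    """Per-dimension Silverman bandwidths sd_j*(4/(d+2))^(1/(d+4))*n^(-1/(d+4)).

    sd_j is the per-dimension sample standard deviation (denominator n-1).
    Raises DegenerateDataError if any dimension has zero spread.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.ndim != 2:
        raise InvalidArgumentError("points must be an n x d matrix")
    n, d = X.shape
    if n < 2:
        raise InvalidArgumentError("bandwidth estimation requires n >= 2")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0]
        raise DegenerateDataError(
            f"zero sample SD in dimension(s) {bad.tolist()}; "
            "jitter the points or drop the dimension")
    factor = (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0))
    return sd * factor


def _log_density_std(query_std: np.ndarray, points_std: np.ndarray,
                     block: int = 8192) -> np.ndarray:
    """log f at query points, both in bandwidth-standardized coordinates.

    f_std(y) = (1/n) sum_i prod_j phi(y_j - q_ij). Squared distances are
    computed via the expansion |q - p|^2 = |q|^2 + |p|^2 - 2 q.p (BLAS);
    queries are blocked to bound memory at n*block doubles.
    """
    n, d = points_std.shape
    pp = (points_std ** 2).sum(axis=1)
    out = np.empty(query_std.shape[0])
    for start in range(0, query_std.shape[0], block):
        q = query_std[start:start + block]
        sq = (q ** 2).sum(axis=1)[:, None] + pp[None, :] - 2.0 * (q @ points_std.T)
        np.maximum(sq, 0.0, out=sq)
        m = sq.min(axis=1)
        out[start:start + block] = (
            -0.5 * m - 0.5 * d * _LOG_2PI - np.log(n)
            + np.log(np.exp(-0.5 * (sq - m[:, None])).sum(axis=1)))
    return out


@dataclass(frozen=True)
class Hypervolume:
    """A fitted KDE hypervolume: boundary threshold, volume and MC draws.

    mc_samples are the retained Monte Carlo draws (original units) with their
    densities mc_densities under this hypervolume's own kernel mixture; they
    support the importance-sampling overlap statistics.
    """

    dim: int
    points: np.ndarray
    bandwidths: np.ndarray
    threshold_density: float
    volume: float
    mc_samples: np.ndarray
    mc_densities: np.ndarray
    mass_quantile: float
    seed: int
    threshold_mode: str = "mass"

    @property
    def log_volume(self) -> float:
        """Natural log of the volume."""
        return float(np.log(self.volume))

    def density(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the kernel mixture f at query points (original units)."""
        q = np.atleast_2d(np.asarray(x, dtype=float))
        if q.shape[1] != self.dim:
            raise InvalidArgumentError(
                f"query dimension {q.shape[1]} != hypervolume dim {self.dim}")
        log_f = _log_density_std(q / self.bandwidths,
                                 self.points / self.bandwidths)
        return np.exp(log_f) / np.prod(self.bandwidths)

    def contains(self, x: np.ndarray) -> np.ndarray:
        """Boolean membership test: f(x) >= threshold."""
        return self.density(x) >= self.threshold_density


def fit_hypervolume(points: np.ndarray, mass_quantile: float = 0.95,
                    n_mc: int = 10_000, seed: int = 0,
                    bandwidths: np.ndarray | None = None,
                    threshold_mode: str = "mass",
                    jitter: float = 0.0) -> Hypervolume:
    """Fit a Gaussian-KDE hypervolume to an n x d point matrix.

    Parameters
    ----------
    points : n x d matrix of coordinates (e.g. PC scores); n >= 2.
    mass_quantile : probability mass retained inside the boundary (default
        0.95, i.e. a 5% quantile threshold).
    n_mc : Monte Carlo draws from the mixture, used both to set the
        threshold and to estimate the volume; >= 1000.
    seed : RNG seed; identical inputs and seed give bit-identical results.
    bandwidths : override the Silverman bandwidths (rarely needed).
    threshold_mode : "mass" (default; quantile of densities at draws from f)
        or "height" (quantile of densities at the data points themselves).
    jitter : if > 0 and a dimension is degenerate, add uniform noise of this
        half-width before fitting instead of raising.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidArgumentError("fit_hypervolume requires an n x d matrix, n >= 2")
    if not 0 < mass_quantile < 1:
        raise InvalidArgumentError("mass_quantile must be in (0, 1)")
    if n_mc < 1000:
        raise InvalidArgumentError("n_mc must be >= 1000")
    if threshold_mode not in ("mass", "height"):
        raise InvalidArgumentError(f"unknown threshold_mode {threshold_mode!r}")
    rng = np.random.default_rng(seed)
    if jitter > 0 and np.any(X.std(axis=0, ddof=1) == 0):
        X = X + rng.uniform(-jitter, jitter, size=X.shape)
    if bandwidths is None:
        h = silverman_bandwidths(X)
    else:
        h = np.asarray(bandwidths, dtype=float) * np.ones(X.shape[1])
        if np.any(h <= 0):
            raise InvalidArgumentError("bandwidths must be positive")
    n, d = X.shape
    Q = X / h  # standardized coordinates: mixture of unit-variance kernels
    idx = rng.integers(0, n, size=n_mc)
    draws_std = Q[idx] + rng.standard_normal((n_mc, d))
    # Work in standardized space throughout: the draws, densities and the
    # inside/outside classification are then identical for c*X and X (same
    # seed), which makes volume(c*X) = c^d * volume(X) exact up to the final
    # product of bandwidths.
    dens_std = np.exp(_log_density_std(draws_std, Q))
    h_prod = float(np.prod(h))

    if threshold_mode == "mass":
        t_std = float(np.quantile(dens_std, 1.0 - mass_quantile))
    else:
        t_std = float(np.quantile(np.exp(_log_density_std(Q, Q)),
                                  1.0 - mass_quantile))
    inside = dens_std >= t_std
    volume = float(np.mean(np.where(inside, 1.0 / dens_std, 0.0)) * h_prod)
    return Hypervolume(dim=d, points=X, bandwidths=h,
                       threshold_density=t_std / h_prod, volume=volume,
                       mc_samples=draws_std * h, mc_densities=dens_std / h_prod,
                       mass_quantile=mass_quantile, seed=int(seed),
                       threshold_mode=threshold_mode)


def grid_volume_oracle(points: np.ndarray, mass_quantile: float = 0.95,
                       grid_step: float = 0.05,
                       bandwidths: np.ndarray | float | None = None) -> float:
    """Brute-force level-set volume by dense grid integration (d <= 2 only).

    Evaluates the same kernel mixture on a regular grid padded by 4*max(h)
    beyond the data range, picks the density threshold so the grid-summed
    mass above it equals mass_quantile, and returns (cells above) * step^d.
    Serves as an independent check of the Monte Carlo estimator.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = X.shape
    if d > 2:
        raise InvalidArgumentError("grid oracle supports d <= 2 only")
    if grid_step <= 0:
        raise InvalidArgumentError("grid_step must be positive")
    if bandwidths is None:
        h = silverman_bandwidths(X)
    else:
        h = np.asarray(bandwidths, dtype=float) * np.ones(d)
    pad = 4.0 * float(h.max())
    axes = [np.arange(X[:, j].min() - pad, X[:, j].max() + pad + grid_step,
                      grid_step) for j in range(d)]
    if d == 1:
        grid = axes[0][:, None]
    else:
        A, B = np.meshgrid(axes[0], axes[1], indexing="ij")
        grid = np.column_stack([A.ravel(), B.ravel()])
    log_f = _log_density_std(grid / h, X / h) - float(np.log(h).sum())
    f = np.exp(log_f)
    cell = grid_step ** d
    order = np.argsort(f)[::-1]
    cum_mass = np.cumsum(f[order]) * cell
    k = int(np.searchsorted(cum_mass, mass_quantile))
    k = min(k, f.size - 1)
    t = f[order[k]]
    return float(np.count_nonzero(f >= t) * cell)


def overlap_jaccard(a: Hypervolume, b: Hypervolume,
                    seed: int | None = None) -> float:
    """Jaccard overlap V(A∩B)/V(A∪B) of two hypervolumes of equal dimension.

    The intersection volume is estimated by classifying each hypervolume's
    Monte Carlo draws with the other's threshold rule and averaging the two
    importance-sampling estimates; the union follows by inclusion-exclusion.
    `seed` optionally refits both sets of draws for an independent estimate.
    """
    if a.dim != b.dim:
        raise InvalidArgumentError(f"dimension mismatch: {a.dim} vs {b.dim}")
    if seed is not None:
        a = fit_hypervolume(a.points, a.mass_quantile, len(a.mc_densities),
                            seed=seed, threshold_mode=a.threshold_mode)
        b = fit_hypervolume(b.points, b.mass_quantile, len(b.mc_densities),
                            seed=seed + 1, threshold_mode=b.threshold_mode)
    est = []
    for own, other in ((a, b), (b, a)):
        in_own = own.mc_densities >= own.threshold_density
        in_other = other.density(own.mc_samples) >= other.threshold_density
        both = in_own & in_other
        est.append(float(np.mean(np.where(both, 1.0 / own.mc_densities, 0.0))))
    v_int = 0.5 * (est[0] + est[1])
    v_union = a.volume + b.volume - v_int
    if v_union <= 0:
        return 1.0
    return float(min(max(v_int / v_union, 0.0), 1.0))


def centroid_distance(a: Hypervolume, b: Hypervolume) -> float:
    """Euclidean distance between the centroids of the two point sets."""
    if a.dim != b.dim:
        raise InvalidArgumentError(f"dimension mismatch: {a.dim} vs {b.dim}")
    return float(np.linalg.norm(a.points.mean(axis=0) - b.points.mean(axis=0)))
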