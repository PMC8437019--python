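"""Simple OLS regressions linking hypervolume size to growth and yield.

The analysis surface is a set of univariate regressions of (mean log)
hypervolume size against growth proxies (height, diameter), the net
biodiversity effect and its components, species richness and biomass; each
fit reports slope, intercept, r^2 and the F(1, n-2) test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class RegressionResult:
    """One simple-OLS fit; F = r2/(1-r2) * (n-2) with df = (1, n-2)."""

    slope: float
    intercept: float
    r2: float
    F: float
    df: tuple[int, int]
    p: float
    n: int
    slope_se: float

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t, n-2 df)."""
        t = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
        return (self.slope - t * self.slope_se, self.slope + t * self.slope_se)


def ols_simple(x, y) -> RegressionResult:
    """Closed-form simple OLS of y on x with the F(1, n-2) test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise InvalidArgumentError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise InvalidArgumentError("simple OLS requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("x and y must be finite")
    if np.var(x) == 0:
        raise InvalidArgumentError("x has zero variance")
    fit = sps.linregress(x, y)
    r2 = float(fit.rvalue ** 2)
    if r2 >= 1.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = r2 / (1.0 - r2) * (n - 2)
        p = float(sps.f.sf(f_stat, 1, n - 2))
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r2=r2, F=float(f_stat), df=(1, n - 2), p=p, n=n,
                            slope_se=float(fit.stderr))


def analysis_suite(community_hv: pd.DataFrame, covariates: pd.DataFrame,
                   pairs: list[tuple[str, str]],
                   on: str = "plot_id") -> pd.DataFrame:
    """Run one simple OLS per requested (x, y) column pair.

    The two tables are inner-joined on plot_id; rows missing either variable
    of a pair are dropped for that pair and the retained count is reported.
    """
    merged = community_hv.merge(covariates, on=on, how="inner")
    rows = []
    for x_name, y_name in pairs:
        for name in (x_name, y_name):
            if name not in merged.columns:
                raise InvalidArgumentError(
                    f"unknown column {name!r}; available: "
                    f"{sorted(merged.columns)}")
        sub = merged[[x_name, y_name]].dropna()
        res = ols_simple(sub[x_name].to_numpy(), sub[y_name].to_numpy())
        rows.append({"x": x_name, "y": y_name, "slope": res.slope,
                     "intercept": res.intercept, "r2": res.r2, "F": res.F,
                     "p": res.p, "n": res.n, "slope_se": res.slope_se})
    return pd.DataFrame(rows)
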