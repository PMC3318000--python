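"""Ordinary kriging of point soil samples onto the quadrat lattice.

Workflow: empirical semivariogram -> weighted least-squares model fit ->
global-neighbourhood ordinary-kriging prediction at every quadrat centre.
The kriging system is written in semivariogram form with a Lagrange
multiplier, so the weights sum to one (unbiasedness) by construction; the
sum is still checked numerically on every prediction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

from .geometry import PlotGeometry
from .synthetic import SOIL_VARIABLES

_MODELS = ("exponential", "spherical", "gaussian")


def _gamma(model: str, h: np.ndarray, nugget: float, psill: float,
           range_m: float) -> np.ndarray:
    """Semivariogram gamma(h); gamma(0)=0 by convention (exact interpolation)."""
    h = np.asarray(h, float)
    if model == "exponential":
        struct = 1.0 - np.exp(-h / range_m)
    elif model == "gaussian":
        struct = 1.0 - np.exp(-((h / range_m) ** 2))
    elif model == "spherical":
        hr = np.minimum(h / range_m, 1.0)
        struct = 1.5 * hr - 0.5 * hr**3
    else:
        raise ValueError(f"unknown variogram model {model!r}; choose from {_MODELS}")
    out = nugget + psill * struct
    return np.where(h == 0, 0.0, out)


@dataclass(frozen=True)
class VariogramModel:
    model: str
    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown variogram model {self.model!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be non-negative")
        if self.range_m <= 0:
            raise ValueError("range must be positive")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        return _gamma(self.model, h, self.nugget, self.partial_sill, self.range_m)


class VariogramFitError(RuntimeError):
    """Fit failure; carries the best parameters seen and their residual."""

    def __init__(self, message: str, best: VariogramModel | None = None,
                 residual: float = np.nan):
        super().__init__(message)
        self.best = best
        self.residual = residual


def _check_variable(samples: pd.DataFrame, variable: str) -> None:
    valid = [c for c in samples.columns if c not in ("x", "y", "clipped")]
    if variable not in samples.columns:
        raise KeyError(
            f"unknown soil variable {variable!r}; available: {valid}"
        )


def deduplicate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Average samples sharing exact coordinates (logged via attrs)."""
    n0 = len(samples)
    cols = [c for c in samples.columns if c != "clipped"]
    out = samples[cols].groupby(["x", "y"], as_index=False, sort=False).mean()
    out.attrs["n_duplicates_merged"] = n0 - len(out)
    return out


def empirical_variogram(
    samples: pd.DataFrame,
    variable: str,
    n_bins: int = 15,
    max_dist: float | None = None,
    dists: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binned empirical semivariogram of one variable.

    Returns a frame with columns (dist, gamma, n_pairs); bins without pairs
    carry NaN gamma and n_pairs=0 and are never interpolated over.
    ``dists`` may carry precomputed condensed pairwise distances so the
    geometry cost is shared across the 13 variables.
    """
    _check_variable(samples, variable)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    pts = samples[["x", "y"]].to_numpy()
    if dists is None:
        dists = pdist(pts)
    if max_dist is None:
        max_dist = float(dists.max()) / 2.0
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    v = samples[variable].to_numpy(float)
    n = len(v)
    iu = np.triu_indices(n, k=1)
    sqdiff = 0.5 * (v[iu[0]] - v[iu[1]]) ** 2
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    idx = np.digitize(dists, edges) - 1
    keep = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.bincount(idx[keep], weights=sqdiff[keep], minlength=n_bins)
    dsums = np.bincount(idx[keep], weights=dists[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        dmean = np.where(counts > 0, dsums / np.maximum(counts, 1),
                         0.5 * (edges[:-1] + edges[1:]))
    return pd.DataFrame({"dist": dmean, "gamma": gamma, "n_pairs": counts})


def fit_variogram(empirical: pd.DataFrame, model: str = "exponential") -> VariogramModel:
    """Weighted least squares fit with pair-count weights."""
    ok = empirical["n_pairs"].to_numpy() > 0
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-empty bins to fit a variogram")
    h = empirical["dist"].to_numpy(float)[ok]
    g = empirical["gamma"].to_numpy(float)[ok]
    w = np.sqrt(empirical["n_pairs"].to_numpy(float)[ok])

    sill0 = max(float(np.mean(g[-max(1, len(g) // 3):])), 1e-12)
    x0 = np.array([max(g[0], 0.0) * 0.5, sill0, max(h.max() / 3.0, 1e-6)])

    def resid(p):
        return w * (_gamma(model, h, p[0], p[1], p[2]) - g)

    res = least_squares(
        resid, x0, bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    best = VariogramModel(model, float(res.x[0]), float(res.x[1]), float(res.x[2]))
    if not res.success:
        raise VariogramFitError(
            f"variogram fit did not converge: {res.message}",
            best=best, residual=float(np.sum(res.fun**2)),
        )
    return best


@dataclass(frozen=True)
class SoilGrid:
    """Kriged quadrat values: frame indexed by (row, col) with variable columns."""

    geometry: PlotGeometry
    values: pd.DataFrame

    def lattice(self, variable: str) -> np.ndarray:
        """One variable reshaped to the (n_qy, n_qx) quadrat lattice."""
        g = self.geometry
        arr = np.full((g.n_qy, g.n_qx), np.nan)
        rows = self.values.index.get_level_values("row")
        cols = self.values.index.get_level_values("col")
        arr[rows, cols] = self.values[variable].to_numpy()
        return arr


def krige_grid(
    samples: pd.DataFrame,
    models: VariogramModel | dict[str, VariogramModel],
    geometry: PlotGeometry,
    variables: list[str] | None = None,
) -> SoilGrid:
    """Ordinary-kriging prediction of every variable at every quadrat centre.

    All samples enter every kriging system (global neighbourhood; n is at
    most ~1000 here). Exact duplicate coordinates are averaged before the
    solve. Variables sharing a variogram model share one matrix
    factorisation.
    """
    samples = deduplicate_samples(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 distinct sample locations")
    if variables is None:
        variables = [c for c in samples.columns if c not in ("x", "y", "clipped")]
    if isinstance(models, VariogramModel):
        models = {v: models for v in variables}
    missing = [v for v in variables if v not in models]
    if missing:
        raise KeyError(f"no variogram model supplied for {missing}")

    pts = samples[["x", "y"]].to_numpy()
    n = len(pts)
    d_ss = squareform(pdist(pts))
    cx, cy = geometry.quadrat_centres()
    targets = np.column_stack([cx.ravel(), cy.ravel()])
    d_st = cdist(pts, targets)

    preds = {}
    by_model: dict[VariogramModel, list[str]] = {}
    for v in variables:
        by_model.setdefault(models[v], []).append(v)
    for model, group in by_model.items():
        a = np.ones((n + 1, n + 1))
        a[:n, :n] = model(d_ss)
        a[n, n] = 0.0
        b = np.ones((n + 1, targets.shape[0]))
        b[:n, :] = model(d_st)
        try:
            lu = lu_factor(a)
            wgts = lu_solve(lu, b)
        except Exception as exc:
            raise RuntimeError(f"singular ordinary-kriging system: {exc}") from exc
        wsum = wgts[:n, :].sum(axis=0)
        if not np.allclose(wsum, 1.0, atol=1e-8):
            raise RuntimeError(
                "kriging weights do not sum to 1 "
                f"(max deviation {np.abs(wsum - 1).max():.2e})"
            )
        for v in group:
            preds[v] = wgts[:n, :].T @ samples[v].to_numpy(float)

    rows, cols = np.divmod(np.arange(targets.shape[0]), geometry.n_qx)
    idx = pd.MultiIndex.from_arrays([rows, cols], names=["row", "col"])
    values = pd.DataFrame(preds, index=idx)
    return SoilGrid(geometry, values)


def krige_all(
    samples: pd.DataFrame,
    geometry: PlotGeometry,
    model: str = "exponential",
    n_bins: int = 15,
    max_dist: float | None = None,
    variables: tuple[str, ...] = SOIL_VARIABLES,
) -> tuple[SoilGrid, dict[str, VariogramModel]]:
    """Fit a per-variable variogram and krige all 13 soil variables."""
    samples = deduplicate_samples(samples)
    dists = pdist(samples[["x", "y"]].to_numpy())
    fitted = {}
    for v in variables:
        emp = empirical_variogram(samples, v, n_bins=n_bins, max_dist=max_dist,
                                  dists=dists)
        try:
            fitted[v] = fit_variogram(emp, model=model)
        except VariogramFitError as exc:
            if exc.best is None:
                raise
            fitted[v] = exc.best  # best-so-far parameters, logged by caller
    grid = krige_grid(samples, fitted, geometry, variables=list(variables))
    return grid, fitted
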