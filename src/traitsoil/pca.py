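"""Correlation-matrix PCA of kriged soil variables.

The 13 quadrat-level soil variables are standardised and the correlation
matrix eigen-decomposed, giving orthogonal fertility/acidity axes; the sum
of all eigenvalues equals 13 and percent-explained is 100*eigenvalue/13.
Axes can be re-oriented by sign conventions (e.g. Ca loading negative on
PC1, pH negative on PC2) without changing eigenvalues or score geometry.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kriging import SoilGrid


@dataclass(frozen=True)
class PcaResult:
    """Loadings (variables x axes, unit-norm eigenvectors), eigenvalues,
    percent variance explained, and per-quadrat axis scores."""

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    pct_explained: np.ndarray
    scores: pd.DataFrame

    @property
    def axes(self) -> list[str]:
        return list(self.loadings.columns)


def pct_explained(eigenvalue: float, n_variables: int = 13) -> float:
    """Percent variance explained by one axis of a correlation-matrix PCA."""
    return 100.0 * eigenvalue / n_variables


def run_pca(grid: SoilGrid | pd.DataFrame, variables: list[str] | None = None) -> PcaResult:
    """PCA of the correlation matrix of quadrat-level soil values.

    Quadrats with any missing value are dropped (they receive no scores and
    are excluded downstream). Raises on constant columns, naming them.
    """
    values = grid.values if isinstance(grid, SoilGrid) else grid
    if variables is not None:
        values = values[variables]
    values = values.dropna(axis=0, how="any")
    n, p = values.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} complete quadrats, got {n}")
    x = values.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        names = [values.columns[i] for i in const]
        raise ValueError(f"constant soil variable(s): {names}")
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # deterministic initial orientation: largest-|loading| entry positive
    for k in range(p):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1
    axes = [f"PC{i + 1}" for i in range(p)]
    loadings = pd.DataFrame(evecs, index=values.columns, columns=axes)
    scores = pd.DataFrame(z @ evecs, index=values.index, columns=axes)
    return PcaResult(
        loadings=loadings,
        eigenvalues=evals,
        pct_explained=pct_explained(evals, p),
        scores=scores,
    )


def select_axes(result: PcaResult, rule: str = "kaiser", k: int = 2) -> list[str]:
    """Retained axes: Kaiser rule (eigenvalue > 1, the default stand-in for
    'significant axes') or an explicit first-k override."""
    if rule == "kaiser":
        kept = [ax for ax, ev in zip(result.axes, result.eigenvalues) if ev > 1.0]
        if len(kept) < 2:
            import warnings

            warnings.warn(
                f"Kaiser rule retained only {len(kept)} axis/axes",
                stacklevel=2,
            )
        return kept or result.axes[:1]
    if rule == "first_k":
        return result.axes[:k]
    raise ValueError(f"unknown axis-selection rule {rule!r}")


#: Default orientation: the fertility axis increases as key nutrients
#: decrease (Ca loading negative on PC1) and the acidity axis increases as
#: pH decreases (pH loading negative on PC2).
DEFAULT_CONVENTIONS: tuple[tuple[str, str, str], ...] = (
    ("Ca", "neg", "PC1"),
    ("pH", "neg", "PC2"),
)


def orient_axes(
    result: PcaResult,
    conventions: tuple[tuple[str, str, str], ...] = DEFAULT_CONVENTIONS,
) -> PcaResult:
    """Flip axes (loadings and scores together) to satisfy sign conventions.

    Each convention is (variable, "neg"|"pos", axis). Orientation never
    changes eigenvalues or absolute loadings; applying a convention twice is
    the identity.
    """
    loadings = result.loadings.copy()
    scores = result.scores.copy()
    for variable, sign, axis in conventions:
        if variable not in loadings.index:
            raise KeyError(f"unknown anchor variable {variable!r}")
        if axis not in loadings.columns:
            continue  # convention for an axis that was not computed/retained
        if sign not in ("neg", "pos"):
            raise ValueError(f"sign must be 'neg' or 'pos', got {sign!r}")
        val = loadings.loc[variable, axis]
        if val == 0:
            raise ValueError(
                f"{variable} has zero loading on {axis}; choose another anchor"
            )
        want_neg = sign == "neg"
        if (val < 0) != want_neg:
            loadings[axis] = -loadings[axis]
            scores[axis] = -scores[axis]
    return replace(result, loadings=loadings, scores=scores)
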