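"""Pearson correlations, directional one-tailed p-values, and BH-FDR.

The testing convention throughout the pipeline: the p-value is one-tailed in
the direction of the observed correlation, p = P(T > |t|) with
t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom (half the two-tailed p;
r = 0 gives p = 0.5). Benjamini-Hochberg adjustment is applied across each
family of 10 trait x axis tests within one plot and one analysis level.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    trait: str
    axis: str
    r: float
    n: int
    p_raw: float
    p_adj: float = np.nan


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Product-moment correlation over pairwise-complete cases."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, _ = sps.pearsonr(x, y)
    return float(r), n


def p_one_tailed(r: float, n: int, df: int | None = None) -> float:
    """One-tailed p in the direction of the observed r (see module docstring).

    ``df`` defaults to n-2; through-origin regressions may pass their own.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if df is None:
        df = n - 2
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(sps.t.sf(t, df))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


#: The 10-test family: every trait crossed with the two retained axes.
def default_family(traits: tuple[str, ...], axes: tuple[str, ...] = ("PC1", "PC2"),
                   ) -> list[tuple[str, str]]:
    return [(tr, ax) for tr in traits for ax in axes]


def run_family(
    values: pd.DataFrame,
    scores: pd.DataFrame,
    family: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Correlation tests for a trait x axis family with BH across the family.

    ``values``: unit x trait frame (units are species or quadrats);
    ``scores``: unit x axis frame on the same index. Pairs whose test fails
    (e.g. zero variance) are dropped and the family size m reduced
    accordingly; the drop is recorded in ``attrs['dropped']``.
    """
    if family is None:
        family = default_family(tuple(values.columns), tuple(scores.columns))
    rows, dropped = [], []
    for trait, axis in family:
        try:
            r, n = pearson_r(values[trait].to_numpy(), scores[axis].to_numpy())
        except (ValueError, KeyError) as exc:
            dropped.append((trait, axis, str(exc)))
            continue
        rows.append(TestResult(trait, axis, r, n, p_one_tailed(r, n)))
    out = pd.DataFrame([vars(t) for t in rows])
    if len(out):
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out.attrs["dropped"] = dropped
    return out


def round3(x: float) -> float:
    """3-decimal display rounding, half away from zero (report tables only)."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
    )
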