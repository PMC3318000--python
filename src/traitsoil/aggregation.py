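"""Species x quadrat abundances and the two abundance-weighted aggregations.

F_S: the mean soil-axis score of a species, weighting each quadrat's score
by the species' stem count there, F_S = sum_Q N_SQ F_Q / sum_Q N_SQ.

T_Q: the community-weighted mean trait of a quadrat, weighting each
species' trait value by its stem count there, T_Q = sum_S N_SQ T_S / sum_S N_SQ,
with species lacking the trait excluded from numerator and denominator.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import PlotGeometry


def build_abundance_matrix(stems: pd.DataFrame, geometry: PlotGeometry) -> pd.DataFrame:
    """Count stems per (species, quadrat) with half-open 20 m binning.

    Returns a frame indexed by species with MultiIndex (row, col) columns;
    the total count equals the number of stems.
    """
    x = stems["x"].to_numpy(float)
    y = stems["y"].to_numpy(float)
    inside = geometry.contains(x, y)
    if not inside.all():
        bad = stems[~inside]
        raise ValueError(
            f"{len(bad)} stem(s) outside the plot, first: "
            f"{bad.iloc[0].to_dict()}"
        )
    row, col = geometry.quadrat_of(x, y)
    tab = (
        pd.DataFrame({"species": stems["species"].to_numpy(), "row": row, "col": col})
        .groupby(["species", "row", "col"])
        .size()
        .unstack(["row", "col"], fill_value=0)
    )
    tab.columns = pd.MultiIndex.from_tuples(tab.columns, names=["row", "col"])
    return tab.sort_index(axis=1)


def species_mean_soil(n_matrix: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted mean quadrat score per species (F_S), per axis.

    Quadrats without a score (e.g. dropped during PCA for missing kriged
    values) are excluded from both numerator and denominator. Species whose
    stems all fall in score-less quadrats are dropped.
    """
    common = n_matrix.columns.intersection(scores.index)
    n = n_matrix[common].to_numpy(float)
    f = scores.loc[common].to_numpy(float)
    tot = n.sum(axis=1)
    keep = tot > 0
    fs = (n[keep] @ f) / tot[keep, None]
    return pd.DataFrame(fs, index=n_matrix.index[keep], columns=scores.columns)


def quadrat_mean_trait(
    n_matrix: pd.DataFrame,
    traits: pd.DataFrame,
    trait: str,
    log10_transform: bool = False,
) -> pd.Series:
    """Community-weighted mean of one trait per quadrat (T_Q).

    Species with a missing value for this trait contribute neither stems nor
    values; quadrats left with zero contributing stems get NaN and are
    excluded downstream.
    """
    if trait not in traits.columns:
        raise KeyError(f"unknown trait {trait!r}; have {list(traits.columns)}")
    t = traits[trait].reindex(n_matrix.index)
    has = t.notna().to_numpy()
    tv = t.to_numpy(float)[has]
    if log10_transform:
        if np.any(tv <= 0):
            raise ValueError(f"log10 transform requires positive {trait} values")
        tv = np.log10(tv)
    n = n_matrix.to_numpy(float)[has]
    denom = n.sum(axis=0)
    with np.errstate(invalid="ignore"):
        tq = np.where(denom > 0, (tv @ n) / np.where(denom > 0, denom, 1), np.nan)
    return pd.Series(tq, index=n_matrix.columns, name=trait)


def quadrat_mean_traits(
    n_matrix: pd.DataFrame,
    traits: pd.DataFrame,
    log10_traits: tuple[str, ...] = (),
) -> pd.DataFrame:
    """T_Q for every trait column; ``log10_traits`` are log10-transformed
    before averaging (the convention for right-skewed traits such as leaf
    area and seed mass)."""
    out = {
        tr: quadrat_mean_trait(n_matrix, traits, tr, tr in log10_traits)
        for tr in traits.columns
    }
    return pd.DataFrame(out)
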