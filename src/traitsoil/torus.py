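"""Torus-translation null model for quadrat-level trait-soil correlations.

The soil-score map is shifted by every possible 20 m increment in both
dimensions with wrap-around (the stem map stays fixed), the Pearson
correlation with the quadrat trait means is recomputed for each of the
ncol x nrow distinct translations (identity included), and the observed
correlation's rank converts to a two-tailed p = rank / n_translations:
small p flags a stronger-than-expected negative correlation, large p a
stronger-than-expected positive one. Significance is p < 0.025 or
p > 0.975 after a folded FDR adjustment across the 10-test family.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust


def translate_map(scores: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Toroidal shift of a (nrow, ncol) lattice by (dx columns, dy rows)."""
    return np.roll(scores, shift=(dy, dx), axis=(0, 1))


@dataclass(frozen=True)
class TorusResult:
    trait: str
    axis: str
    r_obs: float
    rank: int
    n_translations: int
    p: float
    tail: str  # "lower" if p <= 0.5 else "upper"
    p_adj: float = np.nan


def torus_test(
    t_q: np.ndarray,
    scores: np.ndarray,
    trait: str = "",
    axis: str = "",
) -> TorusResult:
    """Exhaustive torus translation test of corr(T_Q, F_Q).

    ``t_q`` and ``scores`` are (nrow, ncol) lattices; NaN quadrats (e.g. no
    trait-bearing stems, or no kriged score) are excluded pairwise per
    translation. rank = #{translations with r <= r_obs} (ties count toward
    the rank, so an identity maximum attains rank n); p = rank / n.
    """
    if t_q.shape != scores.shape:
        raise ValueError(f"lattice shapes differ: {t_q.shape} vs {scores.shape}")
    nrow, ncol = t_q.shape
    n_trans = nrow * ncol
    tq_flat = t_q.ravel()
    rs = np.empty(n_trans)
    k = 0
    for dy in range(nrow):
        for dx in range(ncol):
            s = np.roll(scores, shift=(dy, dx), axis=(0, 1)).ravel()
            ok = np.isfinite(tq_flat) & np.isfinite(s)
            if ok.sum() < 2:
                raise ValueError("fewer than 2 valid quadrats in a translation")
            a = tq_flat[ok]
            b = s[ok]
            a = a - a.mean()
            b = b - b.mean()
            denom = np.sqrt((a @ a) * (b @ b))
            rs[k] = (a @ b) / denom if denom > 0 else np.nan
            k += 1
    r_obs = rs[0]  # (dy, dx) = (0, 0) is the identity translation
    if not np.isfinite(r_obs) or np.all(rs == rs[0]):
        raise ValueError("degenerate map: every translation gives the same r")
    rank = int(np.sum(rs <= r_obs + 1e-12))
    p = rank / n_trans
    return TorusResult(
        trait=trait, axis=axis, r_obs=float(r_obs), rank=rank,
        n_translations=n_trans, p=p, tail="lower" if p <= 0.5 else "upper",
    )


def folded_bh(p_values: np.ndarray) -> np.ndarray:
    """Two-tailed FDR display for rank-based torus p-values.

    Fold each p onto its near tail, q = min(p, 1-p); BH-adjust the q's
    across the family; lower-tail entries (p <= 0.5) display the adjusted q,
    upper-tail entries display 1 - adjusted q, preserving the p < 0.025 /
    p > 0.975 reading of the two-tailed decision.
    """
    p = np.asarray(p_values, float)
    q = np.minimum(p, 1.0 - p)
    adj = bh_adjust(q)
    return np.where(p <= 0.5, adj, 1.0 - adj)


def run_torus_family(
    t_q_lattices: dict[str, np.ndarray],
    score_lattices: dict[str, np.ndarray],
    family: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Torus tests for every trait x axis pair with the folded FDR display."""
    if family is None:
        family = [(tr, ax) for tr in t_q_lattices for ax in score_lattices]
    results = [
        torus_test(t_q_lattices[tr], score_lattices[ax], trait=tr, axis=ax)
        for tr, ax in family
    ]
    out = pd.DataFrame([vars(r) for r in results])
    if len(out):
        out["p_adj"] = folded_bh(out["p"].to_numpy())
    return out
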