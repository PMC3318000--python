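"""End-to-end orchestration: krige -> PCA -> aggregate -> correlate -> PIC -> torus.

``run_full`` executes the whole analysis on in-memory inputs (a synthetic
dataset bundle or tables loaded from disk) and returns an AnalysisReport
whose five tables mirror the standard reporting layout: soil PCA loadings,
species-level correlations, PIC regressions, quadrat-level correlations,
and the torus-translation null test.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .aggregation import build_abundance_matrix, quadrat_mean_traits, species_mean_soil
from .geometry import PlotGeometry
from .io import write_tsv
from .kriging import SoilGrid, krige_all
from .pca import DEFAULT_CONVENTIONS, orient_axes, run_pca, select_axes
from .pic import run_pic_family
from .stats import run_family
from .synthetic import TRAITS, SyntheticDataset
from .torus import run_torus_family


@dataclass
class RunConfig:
    """Analysis options (the data inputs are passed separately)."""

    variogram_model: str = "exponential"
    n_bins: int = 15
    max_dist: float | None = None
    axis_rule: str = "first_k"       # retained-axis rule for the test family
    n_axes: int = 2
    conventions: tuple[tuple[str, str, str], ...] = DEFAULT_CONVENTIONS
    species_log10: tuple[str, ...] = ("LA", "SM")
    quadrat_log10: tuple[str, ...] = ("LA", "SM")
    pic_seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(vars(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisReport:
    pca_table: pd.DataFrame
    species_table: pd.DataFrame
    pic_table: pd.DataFrame
    quadrat_table: pd.DataFrame
    torus_table: pd.DataFrame
    provenance: dict = dc_field(default_factory=dict)


def run_full(
    dataset: SyntheticDataset | None = None,
    *,
    stems: pd.DataFrame | None = None,
    traits: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
    tree: dendropy.Tree | None = None,
    geometry: PlotGeometry | None = None,
    config: RunConfig | None = None,
) -> AnalysisReport:
    """Run the complete analysis; see module docstring for the stage order."""
    config = config or RunConfig()
    if dataset is not None:
        stems, traits, samples = dataset.stems, dataset.traits, dataset.samples
        tree, geometry = dataset.tree, dataset.geometry
    for name, obj in (("stems", stems), ("traits", traits), ("samples", samples),
                      ("tree", tree), ("geometry", geometry)):
        if obj is None:
            raise ValueError(f"missing input: {name}")
    for tr in TRAITS:
        if tr not in traits.columns:
            raise KeyError(f"trait table missing column {tr!r}")

    # 1. kriging
    grid, fitted = krige_all(samples, geometry, model=config.variogram_model,
                             n_bins=config.n_bins, max_dist=config.max_dist)

    # 2. soil PCA on the kriged quadrat values
    pca = run_pca(grid)
    pca = orient_axes(pca, config.conventions)
    axes = select_axes(pca, rule=config.axis_rule, k=config.n_axes)[: config.n_axes]
    scores = pca.scores[axes]

    # 3. abundances and aggregations
    n_matrix = build_abundance_matrix(stems, geometry)
    f_s = species_mean_soil(n_matrix, scores)
    t_q = quadrat_mean_traits(n_matrix, traits, log10_traits=config.quadrat_log10)

    # 4. species-level correlations (log10 LA/SM per convention)
    t_s = traits.copy()
    for tr in config.species_log10:
        t_s[tr] = np.log10(t_s[tr])
    species_table = run_family(t_s, f_s)

    # 5. phylogenetically independent contrasts
    pic_table = run_pic_family(tree, traits, f_s,
                               log10_traits=config.species_log10,
                               seed=config.pic_seed)

    # 6. quadrat-level correlations
    scores_q = scores.reindex(t_q.index)
    quadrat_table = run_family(t_q, scores_q)

    # 7. torus translation null
    t_q_lattices = {tr: _to_lattice(t_q[tr], geometry) for tr in t_q.columns}
    score_lattices = {ax: _to_lattice(scores[ax], geometry) for ax in axes}
    torus_table = run_torus_family(t_q_lattices, score_lattices)

    pca_table = pca.loadings[axes].copy()
    pca_table.loc["Eigenvalue"] = pca.eigenvalues[: len(axes)]
    pca_table.loc["% explained"] = pca.pct_explained[: len(axes)]

    return AnalysisReport(
        pca_table=pca_table,
        species_table=species_table,
        pic_table=pic_table,
        quadrat_table=quadrat_table,
        torus_table=torus_table,
        provenance={
            "traitsoil_version": __version__,
            "config_hash": config.digest(),
            "variograms": {v: vars(m) for v, m in fitted.items()},
            "n_quadrats_scored": len(scores),
            "n_stems": len(stems),
        },
    )


def _to_lattice(series: pd.Series, geometry: PlotGeometry) -> np.ndarray:
    arr = np.full((geometry.n_qy, geometry.n_qx), np.nan)
    rows = series.index.get_level_values("row")
    cols = series.index.get_level_values("col")
    arr[rows, cols] = series.to_numpy(float)
    return arr


def emit_tables(report: AnalysisReport, directory: str | Path) -> list[Path]:
    """Write the five report tables plus a JSON summary; 3-d.p. rounding is
    applied only here, never to the in-memory report."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prov = [f"config_hash={report.provenance.get('config_hash', '')}"]
    written = []
    for name, table, use_index in (
        ("pca", report.pca_table, True),
        ("species_correlations", report.species_table, False),
        ("pic", report.pic_table, False),
        ("quadrat_correlations", report.quadrat_table, False),
        ("torus", report.torus_table, False),
    ):
        path = directory / f"{name}.tsv"
        out = table.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].round(3)
        write_tsv(out, path, provenance=prov, index=use_index)
        written.append(path)
    summary = directory / "summary.json"
    with open(summary, "w") as fh:
        json.dump(report.provenance, fh, indent=2, default=str)
    written.append(summary)
    return written
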