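"""Synthetic forest-plot generator.

Produces complete plot datasets — spatially autocorrelated soil fields, a
two-stage soil sampling design, a Yule phylogeny with Brownian trait
evolution, and a stem map whose species sort along a soil gradient with
controllable strength — so that every downstream analysis stage (kriging,
PCA, community-weighted means, independent contrasts, torus translation)
can be exercised and calibrated without field data.

All generators are pure functions of their arguments and a seed.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field as dc_field

import dendropy
import numpy as np
import pandas as pd

from .geometry import PlotGeometry

#: Canonical order of the 13 soil variables carried through the pipeline.
SOIL_VARIABLES = (
    "Fe", "Mn", "Zn", "Cu", "K", "P", "Ca", "Mg", "B", "Al", "N", "pH", "Nmin",
)

#: The five functional traits.
TRAITS = ("LA", "SLA", "SM", "WD", "Hmax")

_JITTER = 1e-10  # diagonal regularisation added before Cholesky; never more


@dataclass(frozen=True)
class SoilField:
    """Ground-truth lattice of one spatially continuous soil variable.

    ``values`` has shape (height/resolution, width/resolution); entry [j, i]
    is the value of the cell whose lower-left corner is (i*res, j*res).
    """

    geometry: PlotGeometry
    resolution: float
    values: np.ndarray

    def __post_init__(self) -> None:
        ny = round(self.geometry.height / self.resolution)
        nx = round(self.geometry.width / self.resolution)
        if self.values.shape != (ny, nx):
            raise ValueError(
                f"lattice shape {self.values.shape} != expected {(ny, nx)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("soil field contains non-finite values")

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup for continuous coordinates inside the plot."""
        ny, nx = self.values.shape
        ix = np.clip((np.asarray(x) / self.resolution).astype(int), 0, nx - 1)
        iy = np.clip((np.asarray(y) / self.resolution).astype(int), 0, ny - 1)
        return self.values[iy, ix]

    def quadrat_means(self) -> np.ndarray:
        """Average the lattice up to the quadrat grid (n_qy, n_qx)."""
        g = self.geometry
        block = round(g.quadrat_size / self.resolution)
        if block < 1:
            raise ValueError("resolution coarser than quadrat size")
        ny, nx = self.values.shape
        v = self.values[: (ny // block) * block, : (nx // block) * block]
        return v.reshape(ny // block, block, nx // block, block).mean(axis=(1, 3))


@functools.lru_cache(maxsize=4)
def _chol_factor(nx: int, ny: int, resolution: float, range_m: float,
                 sill: float) -> np.ndarray:
    """Cholesky factor of the exponential covariance on the cell-centre lattice.

    Memoised: multi-seed simulation studies on a fixed geometry re-use the
    factorisation and only redraw the Gaussian vector.
    """
    cx = (np.arange(nx) + 0.5) * resolution
    cy = (np.arange(ny) + 0.5) * resolution
    gx, gy = np.meshgrid(cx, cy)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    cov = sill * np.exp(-d / range_m)
    cov[np.diag_indices_from(cov)] += _JITTER
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
        raise np.linalg.LinAlgError(
            f"covariance matrix not positive definite even with {_JITTER} "
            f"jitter (n={nx * ny}, range={range_m}, sill={sill})"
        ) from exc


def generate_soil_field(
    geometry: PlotGeometry,
    range_m: float,
    sill: float,
    nugget: float = 0.0,
    seed: int = 0,
    resolution: float = 20.0,
) -> SoilField:
    """Simulate a stationary zero-mean Gaussian random field on the plot.

    Covariance is exponential, C(h) = sill * exp(-h / range_m), plus
    independent nugget noise of variance ``nugget`` per cell.
    """
    if range_m <= 0:
        raise ValueError("range_m must be positive")
    if sill < 0 or nugget < 0:
        raise ValueError("variance parameters must be non-negative")
    ny = round(geometry.height / resolution)
    nx = round(geometry.width / resolution)
    rng = np.random.default_rng(seed)
    vals = np.zeros(ny * nx)
    if sill > 0:
        L = _chol_factor(nx, ny, float(resolution), float(range_m), float(sill))
        vals = L @ rng.standard_normal(ny * nx)
    else:
        rng.standard_normal(ny * nx)  # keep the stream aligned across sills
    if nugget > 0:
        vals = vals + np.sqrt(nugget) * rng.standard_normal(ny * nx)
    else:
        rng.standard_normal(ny * nx)
    return SoilField(geometry, float(resolution), vals.reshape(ny, nx))


def sample_soil_design(
    fields: SoilField | dict[str, SoilField],
    basal_spacing: float,
    offsets: list[float],
    seed: int = 0,
    noise_sd: float = 0.0,
    mode: str = "all",
) -> pd.DataFrame:
    """Two-stage soil sampling: a basal grid plus short random-direction offsets.

    One sample is taken at every intersection of a ``basal_spacing`` grid
    (plot boundary included), and additional samples are taken ``offsets``
    metres away from each basal point along a random compass direction.
    ``mode="all"`` takes every offset at every basal point; ``mode="one"``
    picks a single offset per basal point (both field layouts are in use at
    real CTFS plots and neither is asserted as canonical here).

    Offset points falling outside the plot are clipped to the boundary
    (``clipped`` column records this) so sample counts stay deterministic.

    Returns a tidy frame with columns x, y, clipped, then one column per
    soil variable.
    """
    if not offsets:
        raise ValueError("offsets must be non-empty")
    if mode not in ("all", "one"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(fields, SoilField):
        fields = {"value": fields}
    if not fields:
        raise ValueError("no soil fields supplied")
    geom = next(iter(fields.values())).geometry

    rng = np.random.default_rng(seed)
    eps = 1e-9
    bx = np.arange(0.0, geom.width + eps, basal_spacing)
    by = np.arange(0.0, geom.height + eps, basal_spacing)
    gx, gy = np.meshgrid(bx, by)
    basal = np.column_stack([gx.ravel(), gy.ravel()])

    xs, ys, clipped = [basal[:, 0]], [basal[:, 1]], [np.zeros(len(basal), bool)]
    offs = np.asarray(offsets, float)
    for k, (px, py) in enumerate(basal):
        if mode == "all":
            use = offs
        else:
            use = offs[[rng.integers(len(offs))]]
        theta = rng.uniform(0.0, 2.0 * np.pi, size=len(use))
        ox = px + use * np.cos(theta)
        oy = py + use * np.sin(theta)
        cx = np.clip(ox, 0.0, geom.width - eps)
        cy = np.clip(oy, 0.0, geom.height - eps)
        xs.append(cx)
        ys.append(cy)
        clipped.append((cx != ox) | (cy != oy))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    out = pd.DataFrame({"x": x, "y": y, "clipped": np.concatenate(clipped)})
    for name, fld in fields.items():
        v = fld.value_at(x, y).astype(float)
        if noise_sd > 0:
            v = v + noise_sd * rng.standard_normal(len(v))
        out[name] = v
    return out


def generate_phylogeny(n_species: int, seed: int = 0,
                       birth_rate: float = 1.0) -> dendropy.Tree:
    """Simulate an ultrametric Yule (pure-birth) tree with labelled tips.

    Tips are labelled ``s001 .. sNNN`` in lineage-creation order. The tree is
    strictly bifurcating; all root-to-tip path lengths are equal.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)

    # Lineage bookkeeping: (node, birth_time). Waiting time to the next split
    # among k lineages is Exp(k * birth_rate).
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = [(tree.seed_node, 0.0)]
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.edge.length = (node.edge.length or 0.0)
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        # record elapsed time on the splitting node's own edge
        node._split_time = t  # type: ignore[attr-defined]
        node.edge.length = t - born
        active.append((left, t))
        active.append((right, t))
    # let terminal branches run for one more waiting time so they are positive
    t += rng.exponential(1.0 / (n_species * birth_rate))
    width = len(str(n_species))
    for i, (node, born) in enumerate(active):
        node.edge.length = t - born
        label = f"s{i + 1:0{width}d}"
        node.taxon = taxa.new_taxon(label)
    tree.seed_node.edge.length = None
    return tree


def evolve_traits(
    tree: dendropy.Tree,
    bm_sigma: float | dict[str, float],
    root_value: float | dict[str, float] = 0.0,
    seed: int = 0,
    traits: tuple[str, ...] = ("trait",),
    allow_zero_lengths: bool = False,
) -> pd.DataFrame:
    """Brownian-motion trait evolution on a phylogeny.

    Each trait column evolves independently down the tree: a child's value is
    its parent's plus a Normal(0, sigma^2 * branch_length) increment. Returns
    a species x trait frame indexed by tip label.
    """
    if isinstance(bm_sigma, (int, float)):
        bm_sigma = {tr: float(bm_sigma) for tr in traits}
    if isinstance(root_value, (int, float)):
        root_value = {tr: float(root_value) for tr in traits}
    rng = np.random.default_rng(seed)
    values: dict[str, dict[str, float]] = {tr: {} for tr in traits}
    node_state: dict[int, dict[str, float]] = {
        id(tree.seed_node): {tr: root_value[tr] for tr in traits}
    }
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state = node_state[id(node)]
        else:
            bl = node.edge.length
            if bl is None or bl < 0 or (bl == 0 and not allow_zero_lengths):
                raise ValueError(
                    f"non-positive branch length {bl!r} (set "
                    "allow_zero_lengths=True to permit zero)"
                )
            parent = node_state[id(node.parent_node)]
            state = {
                tr: parent[tr] + bm_sigma[tr] * np.sqrt(bl) * rng.standard_normal()
                for tr in traits
            }
            node_state[id(node)] = state
        if node.is_leaf():
            for tr in traits:
                values[tr][node.taxon.label] = state[tr]
    out = pd.DataFrame(values)
    return out.loc[sorted(out.index)]


def geometric_abundances(n_species: int, n_stems: int, ratio: float = 0.93,
                         seed: int = 0) -> pd.Series:
    """Few-common-many-rare abundances from a geometric rank series.

    The expected share of rank-k species is proportional to ratio**k, a
    light-weight stand-in for a log-series community; counts are a
    multinomial draw so the total is exactly ``n_stems``.
    """
    rng = np.random.default_rng(seed)
    p = ratio ** np.arange(n_species)
    p /= p.sum()
    counts = rng.multinomial(n_stems, p)
    width = len(str(n_species))
    labels = [f"s{i + 1:0{width}d}" for i in range(n_species)]
    return pd.Series(counts, index=labels, name="abundance")


def simulate_community(
    geometry: PlotGeometry,
    field: SoilField,
    affinities: pd.Series,
    n_stems: int,
    seed: int = 0,
    abundance_ratio: float = 0.93,
) -> pd.DataFrame:
    """Place stems so each species sorts along the soil field per its affinity.

    Species abundances follow a geometric rank series; each stem of species
    s lands at (x, y) with density proportional to exp(affinity_s *
    field(x, y)). Because the field is piecewise constant on its lattice,
    this is sampled exactly: a cell is drawn from the categorical
    distribution with weight exp(affinity * cell value), then the position
    is uniform within the cell — equivalent in distribution to thinning a
    uniform proposal, but immune to the vanishing acceptance rates of
    extreme affinities. Affinity 0 means spatially uniform placement.
    Returns a stem map frame (x, y, species) with exactly ``n_stems`` rows.
    """
    if n_stems <= 0:
        raise ValueError("n_stems must be positive")
    aff = affinities.astype(float)
    if not np.all(np.isfinite(aff)):
        raise ValueError("affinities must be finite")
    rng = np.random.default_rng(seed)
    counts = geometric_abundances(len(aff), n_stems, abundance_ratio,
                                  seed=rng.integers(2**31))
    counts.index = aff.index  # ranks assigned in the affinity table's order
    ny, nx = field.values.shape
    fvals = field.values.ravel()
    res = field.resolution
    xs, ys, sp = [], [], []
    for species, need in counts.items():
        if need == 0:
            continue
        a = aff[species]
        logw = a * fvals
        w = np.exp(logw - logw.max())
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise RuntimeError(
                f"degenerate placement weights for {species} (affinity={a})"
            )
        cells = rng.choice(ny * nx, size=need, p=w / total)
        cy, cx = np.divmod(cells, nx)
        xs.append(np.minimum((cx + rng.uniform(size=need)) * res,
                             geometry.width * (1 - 1e-12)))
        ys.append(np.minimum((cy + rng.uniform(size=need)) * res,
                             geometry.height * (1 - 1e-12)))
        sp.extend([species] * need)
    return pd.DataFrame({
        "x": np.concatenate(xs),
        "y": np.concatenate(ys),
        "species": sp,
    })


# ---------------------------------------------------------------------------
# Full coupled dataset


#: Loadings of each of the 13 soil variables on the two latent axes
#: (fertility, acidity), mimicking the empirical structure of tropical-plot
#: soil chemistry: most cations move together along a fertility axis, while
#: pH opposes Fe/B/Al along an acidity axis.
_SOIL_MIXING: dict[str, tuple[float, float]] = {
    "Ca": (0.9, 0.0), "Mg": (0.9, 0.0), "K": (0.8, 0.0), "Zn": (0.8, 0.1),
    "Mn": (0.7, -0.1), "Cu": (0.7, 0.1), "N": (0.7, -0.1), "Nmin": (0.5, -0.1),
    "P": (0.5, -0.2), "Fe": (-0.1, 0.8), "B": (0.1, 0.8), "Al": (0.0, 0.4),
    "pH": (0.1, -0.8),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a full synthetic plot dataset.

    Defaults emulate a GTS-like 24-ha plot: 600 x 400 m, 20 m quadrats, a
    30 m basal soil grid with 2/5/15 m offsets, log-series-like abundances,
    soil autocorrelation range of 80 m, and one planted trait-soil coupling:
    species affinity to the latent fertility field is proportional to
    standardised log10 leaf area with strength ``coupling``. ``coupling=0``
    gives a fully uncoupled (null) community.
    """

    width: float = 600.0
    height: float = 400.0
    quadrat_size: float = 20.0
    resolution: float = 10.0
    n_species: int = 40
    n_stems: int = 5000
    gp_range: float = 80.0
    gp_sill: float = 1.0
    gp_nugget: float = 0.0
    noise_sd: float = 0.5
    basal_spacing: float = 30.0
    offsets: tuple[float, ...] = (2.0, 5.0, 15.0)
    sample_mode: str = "all"
    coupling: float = 2.0
    coupled_trait: str = "LA"
    bm_sigma: float = 0.35
    abundance_ratio: float = 0.93
    seed: int = 0

    def geometry(self) -> PlotGeometry:
        return PlotGeometry(self.width, self.height, self.quadrat_size)


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`generate_dataset`; inputs for the pipeline
    plus the latent ground truth used by calibration tests."""

    config: SyntheticConfig
    geometry: PlotGeometry
    fertility: SoilField
    acidity: SoilField
    soil_fields: dict[str, SoilField]
    samples: pd.DataFrame
    tree: dendropy.Tree
    traits: pd.DataFrame          # positive trait values, species x 5
    log_traits: pd.DataFrame      # the underlying Brownian (log10) values
    stems: pd.DataFrame
    affinities: pd.Series = dc_field(default_factory=lambda: pd.Series(dtype=float))


#: Root log10 values giving realistic trait magnitudes
#: (LA ~ 30 cm^2, SLA ~ 150 cm^2/g, SM ~ 0.1 g, WD ~ 0.6 g/cm^3, Hmax ~ 20 m).
_TRAIT_ROOTS = {"LA": 1.5, "SLA": 2.2, "SM": -1.0, "WD": -0.22, "Hmax": 1.3}


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete synthetic plot dataset under ``config``.

    The 13 soil variables are linear mixtures of two latent autocorrelated
    fields (fertility and acidity) plus white noise, so that a correlation
    PCA of their kriged quadrat values recovers the two latent axes. Species
    placement is coupled to the latent fertility field through
    ``config.coupled_trait`` with strength ``config.coupling``.
    """
    geom = config.geometry()
    root = np.random.default_rng(config.seed)
    seeds = root.integers(2**31, size=8)

    fert = generate_soil_field(geom, config.gp_range, config.gp_sill,
                               config.gp_nugget, seed=int(seeds[0]),
                               resolution=config.resolution)
    acid = generate_soil_field(geom, config.gp_range, config.gp_sill,
                               config.gp_nugget, seed=int(seeds[1]),
                               resolution=config.resolution)
    noise_rng = np.random.default_rng(int(seeds[2]))
    soil_fields = {}
    for name in SOIL_VARIABLES:
        wf, wa = _SOIL_MIXING[name]
        vals = (wf * fert.values + wa * acid.values
                + config.noise_sd * noise_rng.standard_normal(fert.values.shape))
        soil_fields[name] = SoilField(geom, config.resolution, vals)

    samples = sample_soil_design(soil_fields, config.basal_spacing,
                                 list(config.offsets), seed=int(seeds[3]),
                                 mode=config.sample_mode)

    tree = generate_phylogeny(config.n_species, seed=int(seeds[4]))
    log_traits = evolve_traits(
        tree, bm_sigma=config.bm_sigma,
        root_value=dict(_TRAIT_ROOTS), seed=int(seeds[5]),
        traits=TRAITS,
    )
    traits = 10.0 ** log_traits

    z = log_traits[config.coupled_trait]
    z = (z - z.mean()) / z.std(ddof=0)
    affinities = config.coupling * z

    stems = simulate_community(geom, fert, affinities, config.n_stems,
                               seed=int(seeds[6]),
                               abundance_ratio=config.abundance_ratio)
    return SyntheticDataset(
        config=config, geometry=geom, fertility=fert, acidity=acid,
        soil_fields=soil_fields, samples=samples, tree=tree, traits=traits,
        log_traits=log_traits, stems=stems, affinities=affinities,
    )
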