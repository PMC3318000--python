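# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer should know about.

## Soil interpolation

Each soil variable is treated as an intrinsically stationary random field
observed at irregular points. The empirical semivariogram is
γ̂(h) = ½·mean[(z_i − z_j)²] over pairs binned by separation (default 15
equal-width bins to half the maximum pairwise distance); empty bins are
flagged, never interpolated over. A parametric model (exponential by
default; spherical and Gaussian available) is fitted by least squares with
√(pair count) weights via bounded `scipy.optimize.least_squares`
(nugget ≥ 0, partial sill ≥ 0, range > 0; initial values from the first bin,
the tail mean and max_dist/3). Non-convergence raises an error carrying the
best-so-far parameters.

Prediction is ordinary kriging in semivariogram form with a Lagrange
multiplier, so weights sum to one by construction (checked to 1e-8). All
samples enter every system (global neighbourhood — n is at most ~1200 here,
and search neighbourhoods introduce artefacts the analysis has no way to
diagnose). Exact duplicate coordinates are averaged before the solve.
Predictions are made at quadrat centres and stand in for quadrat values;
block kriging is deliberately out of scope. No transformation of skewed
variables is applied before kriging by default. Variables sharing a fitted
model share one LU factorisation; with per-variable models the system is
factorised per variable.

The exponential default matches both common practice for soil chemistry and
the synthetic generator's ground truth, which makes the self-consistency
recovery tests meaningful; it is a package default, not a claim about any
particular field study.

## Soil PCA

PCA is computed on the correlation matrix of the kriged quadrat values
(variables standardised over quadrats; eigen-decomposition by `numpy.eigh`),
so Σλ = 13 and percent explained is 100·λ/13. Quadrats with any missing
kriged value receive no scores and drop out downstream. Axis retention uses
the Kaiser rule (λ > 1) by default, with an explicit first-k override; the
downstream test family always uses the first two retained axes, interpreted
as fertility and acidity. Axes are oriented by sign anchors — Ca negative
on PC1 and pH negative on PC2 — flipping loadings and scores together;
orientation never changes eigenvalues or score geometry, and applying a
convention twice is the identity. The initial (pre-convention) sign is fixed
deterministically by making each eigenvector's largest-magnitude entry
positive.

## Aggregation

The abundance matrix N_SQ bins stems half-open (floor(x/20), floor(y/20)),
so a stem at exactly x = 20 m belongs to column 1. Species soil means and
community-weighted trait means are plain weighted means; species missing a
trait are excluded pairwise per trait (from numerator *and* denominator),
which reproduces the per-trait n variation seen in real plot analyses, and
quadrats left with no trait-bearing stems are undefined and excluded. Leaf
area and seed mass are log10-transformed before averaging by default at
both analysis levels (configurable per level).

## Correlation testing

Pearson r over pairwise-complete cases; the p-value is one-tailed *in the
direction of the observed r*: p = P(T_{n−2} > |t|), t = r√((n−2)/(1−r²)),
so r = 0 gives p = 0.5. This directional convention and the FDR family
definition (the 10 trait × axis tests within one plot and one analysis
level) were both validated by back-calculating published correlation tables
to 3 decimal places (see `traitsoil.reference` and the acceptance tests).
Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest.multipletests` and cross-checked against a
by-definition step-up oracle. Display rounding (3 d.p., half away from
zero) is applied only at table emission; all computation uses full
precision.

## Independent contrasts

Felsenstein's pruning algorithm: contrast (x_L − x_R)/√(v_L + v_R) at each
internal node, ancestral value the branch-length-weighted average, parent
edge inflated by v_L·v_R/(v_L + v_R). The engine requires a strictly
bifurcating tree; polytomies are resolved randomly with zero-length internal
branches under a caller-supplied seed. Trees are pruned per trait to the
species with data (path lengths preserved, unary nodes collapsed
additively), so n varies by trait.

Trait contrasts are regressed on soil contrasts through the origin
(contrast signs are arbitrary): slope = Σxy/Σx², r = sign(slope)·√(1 −
RSS/Σy²), one-tailed p on n − 2 df. Diagnostics come from the same
through-origin fit: leverage h_i = x_i²/Σx², externally studentized
residuals from the deletion variance estimate. Contrasts with h > 0.2 or
|t| > 5 are removed and the model refitted once — a single pass, not
iterated. An alternative (interceptful auxiliary fit for diagnostics) is
conceivable but not implemented; the through-origin choice keeps the
diagnostics consistent with the model actually fitted.

## Torus translation

The score lattice is shifted by every (dx, dy) quadrat increment with
wrap-around — exactly ncol·nrow distinct translations, identity included —
and the Pearson correlation with the fixed T_Q lattice recomputed each
time, excluding undefined quadrats pairwise per translation. The observed
rank (ties counted toward the rank, so an identity maximum attains rank n)
gives p = rank/n: small p means a stronger-than-expected negative
correlation, large p a stronger-than-expected positive one. Only
translations are used (no reflections or rotations), keeping the null set
equal to the quadrat count.

The two-tailed FDR display folds each p onto its near tail,
q = min(p, 1 − p), BH-adjusts the q's across the 10-test family, and
reports the adjusted q on the lower tail and 1 − adjusted q on the upper
tail. This folding procedure reproduces every published adjusted cell we
could check (20 of 20 at 3 d.p.), and is the package's documented
convention.

## Synthetic generator

The generator's defaults define the study conditions used by the
calibration and power tests:

* **Plot**: 600 × 400 m, 20 m quadrats (a 30 × 20 lattice, 600 quadrats),
  mirroring a 24-ha subtropical plot.
* **Soil fields**: zero-mean Gaussian random fields with exponential
  covariance C(h) = sill·e^(−h/range), simulated by dense Cholesky on the
  cell-centre lattice with a fixed 1e-10 diagonal jitter (an error is raised
  rather than regularising further). Defaults: range 80 m, sill 1, nugget 0,
  10 m resolution — soil-chemistry variograms in forest plots typically
  show ranges of tens of metres. The Cholesky factor is memoised on the
  covariance parameters so multi-seed studies redraw only the Gaussian
  vector.
* **13 soil variables** are linear mixtures of two independent latent
  fields — "fertility" (Ca, Mg, K, Zn, Mn, Cu, N, Nmin, P loading
  positively) and "acidity" (Fe, B, Al positive; pH negative) — plus white
  noise (sd 0.5), so a correlation PCA of the kriged values recovers the
  two latent axes as PC1/PC2.
* **Sampling design**: 30 m basal grid (boundary inclusive) with offsets of
  2, 5 and 15 m along uniform random compass directions; points falling
  outside the plot are clipped to the boundary and recorded, keeping sample
  counts deterministic. Both all-offsets-per-point and one-offset-per-point
  layouts are supported, since both occur in real plot soil surveys.
* **Phylogeny and traits**: a seeded Yule tree (birth rate 1, tips
  contemporaneous) with Brownian motion on log10 trait scales (σ = 0.35 per
  unit depth; root values giving realistic magnitudes, e.g. LA ≈ 30 cm²,
  WD ≈ 0.6 g/cm³), exponentiated to positive trait values.
* **Community**: geometric rank-abundance series (ratio 0.93 — few common,
  many rare — a light-weight stand-in for a log-series) over 40 species and
  5000 stems. Each stem lands with density ∝ exp(affinity_s · field(x, y)).
  Because the field is piecewise constant on its lattice this is sampled
  *exactly* (categorical draw over cells, uniform within the cell), which
  is equivalent in distribution to thinning a uniform proposal but immune
  to the vanishing acceptance rates that thinning suffers at strong
  affinities.
* **Planted coupling**: species affinity to the latent fertility field is
  2 × the standardised log10 leaf area, so high-LA species occupy fertile
  quadrats and the predicted detection is a *negative* LA × PC1 correlation
  on the nutrient-negative fertility axis.

What the generator does **not** emulate: real species composition,
clustered point patterns beyond soil affinity (no dispersal limitation or
conspecific clumping), topography, intraspecific trait variation,
measurement error in traits, or real soil chemistry ranges. Passing the
calibration and power tests therefore shows the pipeline is correct and
well-calibrated *under its own assumptions* — not that any particular
forest satisfies them.

## Simulation studies and problem sizes

* **Null calibration**: 200 uncoupled plots (nuisance-field community,
  independent score field, both at quadrat resolution; 25 species, 2500
  stems). Observed two-tailed rejection rates at 0.025/0.975 across seeds
  fall at roughly 0.03–0.09 against the nominal 0.05; the mild upward drift
  is expected because the simulated fields are planar rather than
  torus-stationary, so translations are not perfectly exchangeable. The
  accepted band is [0.01, 0.10].
* **Power**: 50 replicates of the full default dataset through the entire
  pipeline (kriging with per-variable variogram fits included); the planted
  pair wins its family with the correct sign at both species and quadrat
  level in 100% of replicates at the default coupling.

These sizes were chosen as the package's standard study conditions; both
studies are recomputed from scratch by `scripts/acceptance.py` and the test
suite.

## Known limitations

* Centre-point kriging rather than block kriging over quadrats.
* No kriging variance, cross-validation model selection, co-kriging or
  anisotropy.
* PIC assumes Brownian evolution; no λ/OU transformations or PGLS.
* The quadrat-level parametric p-values ignore spatial autocorrelation by
  design — the torus translation test is the remedy, and the two should be
  read together.
* Published PIC tables could not be fully back-calculated from their
  printed (r, n) values under any simple df convention; the regression
  fixtures therefore anchor on the arithmetically consistent cells only.
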