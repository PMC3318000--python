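"""Generator behaviour: field covariance, sampling design, tree, traits, community."""
import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from traitsoil import (
    PlotGeometry,
    evolve_traits,
    generate_phylogeny,
    generate_soil_field,
    sample_soil_design,
    simulate_community,
)
from traitsoil.kriging import empirical_variogram


class TestSoilField:
    def test_degenerate_variance_gives_zero_field(self, small_geometry):
        f = generate_soil_field(small_geometry, range_m=50, sill=0, nugget=0, seed=1)
        assert np.all(f.values == 0.0)

    def test_same_seed_identical(self, small_geometry):
        a = generate_soil_field(small_geometry, 50, 1.0, 0.1, seed=7)
        b = generate_soil_field(small_geometry, 50, 1.0, 0.1, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        c = generate_soil_field(small_geometry, 50, 1.0, 0.1, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_empirical_semivariance_matches_exponential_model(self):
        # 50-seed average semivariance at h ~ range should be sill*(1-1/e)
        geom = PlotGeometry(200.0, 200.0, 20.0)
        lags, gammas = None, []
        for seed in range(50):
            f = generate_soil_field(geom, range_m=50, sill=1.0, nugget=0.0,
                                    seed=seed, resolution=10.0)
            ny, nx = f.values.shape
            gx, gy = np.meshgrid((np.arange(nx) + 0.5) * 10, (np.arange(ny) + 0.5) * 10)
            samples = pd.DataFrame(
                {"x": gx.ravel(), "y": gy.ravel(), "v": f.values.ravel()}
            )
            emp = empirical_variogram(samples, "v", n_bins=14, max_dist=140.0)
            gammas.append(emp["gamma"].to_numpy())
            lags = emp["dist"].to_numpy()
        mean_gamma = np.mean(gammas, axis=0)
        at_range = mean_gamma[np.argmin(np.abs(lags - 50.0))]
        expected = 1.0 - np.exp(-1.0)
        assert abs(at_range - expected) < 0.15 * expected

    def test_invalid_parameters_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            generate_soil_field(small_geometry, range_m=0, sill=1)
        with pytest.raises(ValueError):
            generate_soil_field(small_geometry, range_m=10, sill=-1)


class TestSamplingDesign:
    def test_boundary_inclusive_grid_count(self):
        # 50 m grid on a 1000 x 500 m plot: 21 x 11 basal points, 4 samples each
        geom = PlotGeometry(1000.0, 500.0, 20.0)
        field = generate_soil_field(geom, 50, 1.0, seed=0, resolution=20.0)
        s = sample_soil_design(field, basal_spacing=50.0, offsets=[2.0, 8.0, 20.0],
                               seed=0)
        assert len(s) == 21 * 11 * 4
        assert s["x"].between(0, 1000).all() and s["y"].between(0, 500).all()

    def test_one_offset_mode_count(self):
        geom = PlotGeometry(1000.0, 500.0, 20.0)
        field = generate_soil_field(geom, 50, 1.0, seed=0, resolution=20.0)
        s = sample_soil_design(field, 50.0, [2.0, 8.0, 20.0], seed=0, mode="one")
        assert len(s) == 21 * 11 * 2

    def test_empty_offsets_rejected(self, small_geometry):
        field = generate_soil_field(small_geometry, 50, 1.0, seed=0)
        with pytest.raises(ValueError):
            sample_soil_design(field, 50.0, [], seed=0)

    def test_zero_noise_samples_equal_field_values(self, small_geometry):
        field = generate_soil_field(small_geometry, 50, 1.0, seed=3)
        s = sample_soil_design(field, 50.0, [5.0], seed=3, noise_sd=0.0)
        np.testing.assert_allclose(
            s["value"], field.value_at(s["x"].to_numpy(), s["y"].to_numpy())
        )


class TestPhylogeny:
    def test_two_tips_equal_depths(self):
        tree = generate_phylogeny(2, seed=0)
        tips = tree.leaf_nodes()
        assert len(tips) == 2
        depths = [t.distance_from_root() for t in tips]
        assert depths[0] == pytest.approx(depths[1])

    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_bifurcating_identity_and_ultrametric(self, n):
        tree = generate_phylogeny(n, seed=4)
        internal = [nd for nd in tree if not nd.is_leaf()]
        assert len(internal) == n - 1
        assert all(len(nd.child_nodes()) == 2 for nd in internal)
        depths = [t.distance_from_root() for t in tree.leaf_nodes()]
        np.testing.assert_allclose(depths, depths[0])

    def test_same_seed_identical_newick(self):
        a = generate_phylogeny(12, seed=9).as_string(schema="newick")
        b = generate_phylogeny(12, seed=9).as_string(schema="newick")
        assert a == b


class TestBrownianTraits:
    def test_zero_rate_keeps_root_value(self):
        tree = generate_phylogeny(6, seed=1)
        vals = evolve_traits(tree, bm_sigma=0.0, root_value=3.5, seed=0)
        assert (vals["trait"] == 3.5).all()

    def test_tip_variance_matches_brownian_expectation(self):
        tree = generate_phylogeny(8, seed=2)
        sigma = 0.7
        reps = [f"r{i}" for i in range(1000)]
        vals = evolve_traits(tree, bm_sigma=sigma, root_value=0.0, seed=5,
                             traits=tuple(reps))
        tip = tree.leaf_nodes()[0]
        depth = tip.distance_from_root()
        observed = vals.loc[tip.taxon.label].to_numpy().var(ddof=1)
        expected = sigma**2 * depth
        se = expected * np.sqrt(2.0 / (len(reps) - 1))
        assert abs(observed - expected) < 3 * se

    def test_same_seed_identical(self):
        tree = generate_phylogeny(6, seed=1)
        a = evolve_traits(tree, 0.3, 0.0, seed=8)
        b = evolve_traits(tree, 0.3, 0.0, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_branch_length_rejected(self):
        tree = generate_phylogeny(4, seed=0)
        tree.leaf_nodes()[0].edge.length = -0.1
        with pytest.raises(ValueError):
            evolve_traits(tree, 0.3, 0.0, seed=0)


class TestCommunity:
    def _field(self, geom, seed=0):
        return generate_soil_field(geom, 60, 1.0, seed=seed, resolution=20.0)

    def test_stem_count_conserved(self, small_geometry):
        field = self._field(small_geometry)
        aff = pd.Series(0.5, index=[f"s{i:02d}" for i in range(10)])
        stems = simulate_community(small_geometry, field, aff, 1234, seed=0)
        assert len(stems) == 1234
        assert small_geometry.contains(stems["x"], stems["y"]).all()

    def test_zero_affinity_uniform_quadrat_counts(self):
        # chi-square GOF against uniform expected counts; majority of 20 seeds
        geom = PlotGeometry(200.0, 200.0, 20.0)
        field = self._field(geom)
        aff = pd.Series(0.0, index=[f"s{i:02d}" for i in range(5)])
        passed = 0
        for seed in range(20):
            stems = simulate_community(geom, field, aff, 10_000, seed=seed)
            row, col = geom.quadrat_of(stems["x"].to_numpy(), stems["y"].to_numpy())
            counts = np.bincount(row * geom.n_qx + col, minlength=geom.n_quadrats)
            p = sps.chisquare(counts).pvalue
            passed += p > 0.01
        assert passed >= 11

    def test_positive_affinity_tracks_field(self):
        geom = PlotGeometry(200.0, 200.0, 20.0)
        wins = 0
        for seed in range(100):
            field = self._field(geom, seed=seed)
            aff = pd.Series([3.0, 0.0], index=["A", "B"])
            stems = simulate_community(geom, field, aff, 2000, seed=seed)
            a = stems[stems["species"] == "A"]
            row, col = geom.quadrat_of(a["x"].to_numpy(), a["y"].to_numpy())
            counts = np.bincount(row * geom.n_qx + col, minlength=geom.n_quadrats)
            r = np.corrcoef(counts, field.quadrat_means().ravel())[0, 1]
            wins += r > 0
        assert wins >= 95

    def test_affinity_must_be_finite(self, small_geometry):
        field = self._field(small_geometry)
        aff = pd.Series([np.inf, 0.0], index=["A", "B"])
        with pytest.raises(ValueError):
            simulate_community(small_geometry, field, aff, 100, seed=0)
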