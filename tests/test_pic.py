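"""Independent contrasts: pruning, Felsenstein's algorithm, robust origin fit."""
import numpy as np
import pandas as pd
import pytest

from traitsoil import (
    compute_contrasts,
    evolve_traits,
    generate_phylogeny,
    prune_to_data,
    regress_through_origin,
    screen_contrasts,
)


def oracle_contrasts(tree, values):
    """Recursive by-the-formula implementation, independent of the engine."""
    out = []

    def visit(node):
        # returns (value, extra_variance)
        if node.is_leaf():
            return float(values[node.taxon.label]), 0.0
        left, right = node.child_nodes()
        x1, e1 = visit(left)
        x2, e2 = visit(right)
        v1 = left.edge.length + e1
        v2 = right.edge.length + e2
        out.append((x1 - x2) / np.sqrt(v1 + v2))
        anc = (x1 * v2 + x2 * v1) / (v1 + v2)
        return anc, v1 * v2 / (v1 + v2)

    visit(tree.seed_node)
    return np.array(out)


class TestPrune:
    def test_no_missing_species_unchanged(self):
        tree = generate_phylogeny(8, seed=0)
        labels = {t.label for t in tree.taxon_namespace}
        pruned = prune_to_data(tree, labels)
        assert {t.label for t in pruned.taxon_namespace} == labels
        assert pruned.length() == pytest.approx(tree.length())

    def test_cherry_drop_merges_branch_lengths(self):
        tree = generate_phylogeny(3, seed=1)
        tips = {t.label for t in tree.taxon_namespace}
        depth0 = tree.leaf_nodes()[0].distance_from_root()
        drop = sorted(tips)[0]
        pruned = prune_to_data(tree, tips - {drop})
        assert len(pruned.leaf_nodes()) == 2
        for leaf in pruned.leaf_nodes():
            assert leaf.distance_from_root() == pytest.approx(depth0)

    def test_root_to_tip_distances_preserved(self):
        for seed in range(10):
            tree = generate_phylogeny(12, seed=seed)
            depths = {t.taxon.label: t.distance_from_root()
                      for t in tree.leaf_nodes()}
            keep = set(sorted(depths)[:7])
            pruned = prune_to_data(tree, keep)
            for leaf in pruned.leaf_nodes():
                assert leaf.distance_from_root() == \
                    pytest.approx(depths[leaf.taxon.label])

    def test_too_few_shared_species(self):
        tree = generate_phylogeny(5, seed=0)
        with pytest.raises(ValueError):
            prune_to_data(tree, {"nonexistent"})


class TestContrasts:
    def test_two_tip_hand_value(self):
        tree = generate_phylogeny(2, seed=0)
        for leaf in tree.leaf_nodes():
            leaf.edge.length = 1.0
        labels = sorted(t.label for t in tree.taxon_namespace)
        vals = pd.Series({labels[0]: 3.0, labels[1]: 1.0})
        ct = compute_contrasts(tree, vals)
        assert len(ct) == 1
        assert abs(ct.loc[0, "contrast"]) == pytest.approx(2 / np.sqrt(2))

    def test_equal_values_give_zero_contrasts(self):
        tree = generate_phylogeny(9, seed=3)
        labels = [t.label for t in tree.taxon_namespace]
        ct = compute_contrasts(tree, pd.Series(4.2, index=labels))
        np.testing.assert_allclose(ct["contrast"], 0.0, atol=1e-12)

    def test_matches_recursive_oracle_on_random_trees(self):
        for seed in range(100):
            tree = generate_phylogeny(8, seed=seed)
            r = np.random.default_rng(seed + 1000)
            labels = [t.label for t in tree.taxon_namespace]
            vals = pd.Series(r.standard_normal(8), index=labels)
            got = np.sort(np.abs(compute_contrasts(tree, vals)["contrast"]))
            want = np.sort(np.abs(oracle_contrasts(tree, vals)))
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_shift_invariance_and_scaling(self):
        tree = generate_phylogeny(10, seed=4)
        labels = [t.label for t in tree.taxon_namespace]
        vals = pd.Series(np.random.default_rng(0).standard_normal(10),
                         index=labels)
        base = compute_contrasts(tree, vals)["contrast"]
        shifted = compute_contrasts(tree, vals + 7.0)["contrast"]
        scaled = compute_contrasts(tree, vals * 3.0)["contrast"]
        np.testing.assert_allclose(shifted, base, atol=1e-10)
        np.testing.assert_allclose(scaled, 3.0 * base, atol=1e-10)

    def test_contrast_count_identity(self):
        tree = generate_phylogeny(23, seed=5)
        labels = [t.label for t in tree.taxon_namespace]
        vals = pd.Series(np.arange(23.0), index=labels)
        assert len(compute_contrasts(tree, vals)) == 22


class TestThroughOriginRegression:
    def test_exact_line(self):
        x = np.array([1.0, -2.0, 3.0, 0.5])
        reg = regress_through_origin(x, 2 * x)
        assert reg.slope == pytest.approx(2.0)
        assert reg.r == pytest.approx(1.0)

    def test_sign_symmetry(self):
        r = np.random.default_rng(1)
        x = r.standard_normal(30)
        y = 0.5 * x + r.standard_normal(30)
        a = regress_through_origin(x, y)
        b = regress_through_origin(-x, y)
        assert b.slope == pytest.approx(-a.slope)
        assert b.r == pytest.approx(-a.r)
        assert b.p_raw == pytest.approx(a.p_raw)

    def test_zero_soil_contrasts_rejected(self):
        with pytest.raises(ValueError):
            regress_through_origin(np.zeros(5), np.arange(5.0))


class TestScreening:
    def _contrast_frame(self, x, y):
        return pd.DataFrame({
            "node_id": [f"node{i}" for i in range(len(x))],
            "soil": x, "trait": y,
        })

    def test_clean_brownian_data_rarely_screened(self):
        # tree size matches the ~10^2 contrasts of a real plot analysis; the
        # leverage rule (x_i^2 > 0.2 sum x^2) is only rarely tripped by
        # clean Brownian data at that scale
        removals = 0
        for seed in range(100):
            tree = generate_phylogeny(120, seed=seed)
            traits = evolve_traits(tree, bm_sigma=1.0, seed=seed,
                                   traits=("a", "b"))
            ca = compute_contrasts(tree, traits["a"])["contrast"]
            cb = compute_contrasts(tree, traits["b"])["contrast"]
            reg = screen_contrasts(self._contrast_frame(cb.to_numpy(),
                                                        ca.to_numpy()))
            removals += len(reg.removed) > 0
        assert removals <= 5

    def test_planted_outlier_removed_by_residual_rule(self):
        r = np.random.default_rng(2)
        x = r.standard_normal(60)
        y = 1.5 * x + 0.1 * r.standard_normal(60)
        y[13] += 25.0  # gross outlier at moderate leverage
        reg = screen_contrasts(self._contrast_frame(x, y))
        assert ("node13", "residual") in reg.removed
        assert reg.n == 59

    def test_high_leverage_point_removed_by_hat_rule(self):
        x = np.array([1.0, -1.0, 0.5, -0.5, 10.0])  # x4^2 > 0.2 * sum(x^2)
        y = 0.3 * x
        reg = screen_contrasts(self._contrast_frame(x, y + 1e-6))
        assert ("node4", "leverage") in reg.removed

    def test_screening_everything_raises(self):
        x = np.array([10.0, 0.1, 0.1])
        y = np.array([1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            screen_contrasts(self._contrast_frame(x[:1], y[:1] + 100))


class TestContrastDiagnostics:
    def test_standardised_contrasts_uncorrelated_with_sd(self):
        # under Brownian evolution |contrast| should not trend with its sd
        slopes = []
        for seed in range(30):
            tree = generate_phylogeny(60, seed=seed)
            vals = evolve_traits(tree, bm_sigma=1.0, seed=seed + 500)
            ct = compute_contrasts(tree, vals["trait"])
            b = np.polyfit(ct["sd"], np.abs(ct["contrast"]), 1)[0]
            slopes.append(b)
        mean = np.mean(slopes)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean) < 3 * se
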