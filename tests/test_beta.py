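import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverdiv.beta import (
    beta_component_regression,
    beta_summary,
    functional_beta,
    hull_intersection_volume,
    hull_volume,
    monte_carlo_pair_volumes,
    phylogenetic_beta,
    sorensen_components,
    taxonomic_beta,
)
from riverdiv.data import CommunityMatrix, Phylogeny
from riverdiv.errors import ValidationError
from riverdiv.simulate import generate_tree
from riverdiv.traitspace import build_trait_space

from conftest import random_trait_table
from oracles import (
    hull_area_oracle_2d,
    pd_beta_oracle,
    quadratic_fit_oracle,
    sorensen_oracle,
    td_beta_oracle,
)


class TestSorensenComponents:
    def test_direct_substitution(self):
        comp = sorensen_components(5, 3, 2)
        assert comp.beta_sor == pytest.approx(5 / 15)

    def test_partition_hand_checked(self):
        comp = sorensen_components(5, 3, 2)
        assert comp.beta_sim == pytest.approx(2 / 7)
        assert comp.beta_nes == pytest.approx(5 / 15 - 2 / 7)

    def test_identical_and_disjoint(self):
        same = sorensen_components(4, 0, 0)
        assert (same.beta_sor, same.beta_sim, same.beta_nes) == (0.0, 0.0, 0.0)
        disj = sorensen_components(0, 3, 5)
        assert (disj.beta_sor, disj.beta_sim, disj.beta_nes) == (1.0, 1.0, 0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            sorensen_components(0, 0, 0)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            sorensen_components(-1, 1, 1)

    @given(
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=100),
    )
    @settings(max_examples=200, deadline=None)
    def test_additivity_and_bounds(self, a, b, c):
        if 2 * a + b + c <= 0:
            return
        comp = sorensen_components(a, b, c)
        assert comp.beta_sor == pytest.approx(comp.beta_sim + comp.beta_nes, abs=1e-12)
        for v in (comp.beta_sor, comp.beta_sim, comp.beta_nes):
            assert -1e-12 <= v <= 1 + 1e-12


class TestTaxonomicBeta:
    def test_identical_rows_zero(self):
        cm = CommunityMatrix(pd.DataFrame([[1, 2], [3, 4]],
                                          index=["s1", "s2"], columns=["A", "B"]))
        m = taxonomic_beta(cm)
        assert m.sor.loc["s1", "s2"] == 0.0

    def test_pure_nestedness(self):
        cm = CommunityMatrix(pd.DataFrame([[1, 1, 1], [1, 1, 0]],
                                          index=["s1", "s2"], columns=list("ABC")))
        m = taxonomic_beta(cm)
        assert m.sim.loc["s1", "s2"] == 0.0
        assert m.nes.loc["s1", "s2"] == pytest.approx(m.sor.loc["s1", "s2"])

    def test_five_site_toy_matches_set_oracle(self, toy_community):
        m = taxonomic_beta(toy_community)
        pa = toy_community.presence_absence()
        for s1, s2 in itertools.combinations(toy_community.sites, 2):
            set1 = {sp for sp in toy_community.species if pa.loc[s1, sp]}
            set2 = {sp for sp in toy_community.species if pa.loc[s2, sp]}
            sor, sim, nes = td_beta_oracle(set1, set2)
            assert m.sor.loc[s1, s2] == pytest.approx(sor, abs=1e-12)
            assert m.sim.loc[s1, s2] == pytest.approx(sim, abs=1e-12)
            assert m.nes.loc[s1, s2] == pytest.approx(nes, abs=1e-12)

    def test_abundance_scaling_invariant(self, toy_community):
        scaled = CommunityMatrix(toy_community.table * 7)
        assert np.allclose(taxonomic_beta(toy_community).sor.to_numpy(),
                           taxonomic_beta(scaled).sor.to_numpy())

    def test_symmetry_zero_diagonal(self, toy_community):
        m = taxonomic_beta(toy_community)
        for which in ("sor", "sim", "nes"):
            grid = getattr(m, which).to_numpy()
            assert np.allclose(grid, grid.T)
            assert np.allclose(np.diag(grid), 0.0)


class TestPhylogeneticBeta:
    def test_same_species_sets_zero(self, tree_abc):
        cm = CommunityMatrix(pd.DataFrame([[1, 1], [2, 5]],
                                          index=["s1", "s2"], columns=list("AB")))
        m = phylogenetic_beta(cm, tree_abc)
        assert m.sor.loc["s1", "s2"] == 0.0

    def test_star_singletons_fully_distinct(self, star3):
        cm = CommunityMatrix(pd.DataFrame([[1, 0, 0], [0, 1, 0], [0, 0, 1]],
                                          index=["s1", "s2", "s3"], columns=list("ABC")))
        m = phylogenetic_beta(cm, star3, include_root=True)
        assert m.sor.loc["s1", "s2"] == pytest.approx(1.0)
        assert m.sim.loc["s1", "s2"] == pytest.approx(1.0)

    @pytest.mark.parametrize("include_root", [True, False])
    def test_random_tree_matches_branch_set_oracle(self, include_root):
        tree = generate_tree(12, seed=9)
        newick = tree.tree.as_string(schema="newick", suppress_rooting=True)
        rng = np.random.default_rng(10)
        pa = rng.random((4, 12)) < 0.5
        pa[:, 0] = True  # avoid empty sites
        cm = CommunityMatrix(pd.DataFrame(pa.astype(int) + 0,
                                          index=[f"s{i}" for i in range(4)],
                                          columns=tree.tips))
        m = phylogenetic_beta(cm, tree, include_root=include_root)
        for s1, s2 in itertools.combinations(cm.sites, 2):
            tips1 = [sp for sp in cm.species if cm.table.loc[s1, sp] > 0]
            tips2 = [sp for sp in cm.species if cm.table.loc[s2, sp] > 0]
            sor, sim, nes = pd_beta_oracle(newick, tips1, tips2, include_root)
            assert m.sor.loc[s1, s2] == pytest.approx(sor, abs=1e-9)
            assert m.sim.loc[s1, s2] == pytest.approx(sim, abs=1e-9)

    def test_star_unit_branches_reduces_to_td_exhaustive(self):
        species = list("ABCDEF")
        newick = "(" + ",".join(f"{s}:1" for s in species) + ");"
        tree = Phylogeny.from_newick(newick)
        # exhaustive over all pairs of non-empty subsets of <= 6 species
        subsets = [set(c) for r in range(1, 7)
                   for c in itertools.combinations(species, r)]
        rng = np.random.default_rng(0)
        picks = rng.choice(len(subsets), size=(60, 2))
        for i1, i2 in picks:
            set1, set2 = subsets[i1], subsets[i2]
            pool = sorted(set1 | set2)
            rows = pd.DataFrame(
                [[1 if s in set1 else 0 for s in pool],
                 [1 if s in set2 else 0 for s in pool]],
                index=["s1", "s2"], columns=pool)
            cm = CommunityMatrix(rows)
            pdm = phylogenetic_beta(cm, tree, include_root=True)
            tdm = taxonomic_beta(cm)
            assert pdm.sor.loc["s1", "s2"] == pytest.approx(tdm.sor.loc["s1", "s2"])
            assert pdm.sim.loc["s1", "s2"] == pytest.approx(tdm.sim.loc["s1", "s2"])


class TestHullGeometry:
    def test_identical_point_sets(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        assert hull_intersection_volume(pts, pts) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_squares(self):
        sq1 = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        sq2 = sq1 + np.array([5.0, 0.0])
        assert hull_intersection_volume(sq1, sq2) == 0.0

    def test_square_vs_half_square_components(self):
        sq = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        half = np.array([[0, 0], [0.5, 0], [0, 1], [0.5, 1]], float)
        inter = hull_intersection_volume(sq, half)
        a = inter
        b = hull_volume(sq) - inter
        c = hull_volume(half) - inter
        sor, sim, nes = sorensen_oracle(a, b, c)
        assert sor == pytest.approx(1 / 3, abs=1e-9)
        assert sim == pytest.approx(0.0, abs=1e-9)
        assert nes == pytest.approx(1 / 3, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_shapely_2d(self, seed):
        rng = np.random.default_rng(seed)
        p1 = rng.normal(size=(7, 2))
        p2 = rng.normal(size=(7, 2)) + 0.3
        got = hull_intersection_volume(p1, p2)
        _, _, expected = hull_area_oracle_2d(p1, p2)
        assert got == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("dim", [2, 3])
    def test_monte_carlo_agrees_with_exact(self, dim):
        rng = np.random.default_rng(42 + dim)
        p1 = rng.normal(size=(8, dim))
        p2 = rng.normal(size=(8, dim)) + 0.4
        exact = hull_intersection_volume(p1, p2)
        mc = monte_carlo_pair_volumes(p1, p2, n_points=100_000, seed=7)
        p_hat = mc["intersection"] / mc["box_volume"]
        se = mc["box_volume"] * np.sqrt(p_hat * (1 - p_hat) / mc["n_points"])
        assert abs(mc["intersection"] - exact) <= 3 * se + 1e-12


@pytest.fixture(scope="module")
def space_and_community():
    traits = random_trait_table(12, seed=21)
    space = build_trait_space(traits, n_axes=4)
    rng = np.random.default_rng(22)
    pa = rng.random((5, 12)) < 0.6
    pa[0] = True
    pa[1, :] = False
    pa[1, :2] = True  # a 2-species site -> missing FD entries
    for i in range(5):
        if not pa[i].any():
            pa[i, 0] = True
    cm = CommunityMatrix(pd.DataFrame(pa.astype(int), columns=traits.species,
                                      index=[f"s{i}" for i in range(5)]))
    return space, cm


class TestFunctionalBeta:
    def test_missing_and_reduced_flags(self, space_and_community):
        space, cm = space_and_community
        m = functional_beta(cm, space, n_axes_fd=4, seed=1)
        # the 2-species site yields missing entries against everyone
        others = [s for s in cm.sites if s != "s1"]
        assert m.sor.loc["s1", others].isna().all()
        assert (m.flags.loc["s1", others] == "missing").all()
        # additivity wherever defined
        tri = zip(m.sor.to_numpy().ravel(), m.sim.to_numpy().ravel(),
                  m.nes.to_numpy().ravel())
        for sor, sim, nes in tri:
            if not np.isnan(sor):
                assert sor == pytest.approx(sim + nes, abs=1e-12)

    def test_identical_sites_zero(self):
        traits = random_trait_table(8, seed=31)
        space = build_trait_space(traits, n_axes=2)
        cm = CommunityMatrix(pd.DataFrame(np.ones((2, 8), int), columns=traits.species,
                                          index=["s1", "s2"]))
        m = functional_beta(cm, space, n_axes_fd=2, seed=0)
        assert m.sor.loc["s1", "s2"] == pytest.approx(0.0, abs=1e-9)

    def test_axis_budget_checked(self, space_and_community):
        space, cm = space_and_community
        with pytest.raises(ValidationError):
            functional_beta(cm, space, n_axes_fd=9)


class TestSummaryAndRegression:
    def test_constant_matrix_sd_zero(self):
        sites = ["s1", "s2", "s3"]
        grid = pd.DataFrame(0.4, index=sites, columns=sites)
        np.fill_diagonal(grid.values, 0.0)
        from riverdiv.beta import BetaMatrices

        m = BetaMatrices("TD", grid, grid * 0.5, grid * 0.5)
        s = beta_summary(m)
        assert s["sor"]["sd"] == pytest.approx(0.0, abs=1e-12)
        assert s["sor"]["mean"] == pytest.approx(0.4)

    def test_three_site_hand_mean(self, toy_community):
        m = taxonomic_beta(toy_community)
        s = beta_summary(m)
        tri = m.upper_triangle("sor")
        assert s["sor"]["mean"] == pytest.approx(sum(tri) / len(tri))
        assert s["sor"]["n_pairs"] == len(tri)

    def test_all_missing_rejected(self):
        sites = ["s1", "s2"]
        grid = pd.DataFrame(np.nan, index=sites, columns=sites)
        from riverdiv.beta import BetaMatrices

        with pytest.raises(ValidationError):
            beta_summary(BetaMatrices("FD", grid, grid, grid))

    def test_histogram_counts_sum_to_pairs(self, toy_community):
        s = beta_summary(taxonomic_beta(toy_community))
        assert sum(s["sor"]["histogram"]) == s["sor"]["n_pairs"]

    def test_regression_y_equals_x(self):
        sites = [f"s{i}" for i in range(6)]
        rng = np.random.default_rng(5)
        vals = rng.random((6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        grid = pd.DataFrame(vals, index=sites, columns=sites)
        from riverdiv.beta import BetaMatrices

        m = BetaMatrices("TD", grid, grid.copy(), grid * 0.0)
        fits = beta_component_regression(m).set_index(["x", "y"])
        row = fits.loc[("sor", "sim")]
        assert row["r2_adj"] == pytest.approx(1.0)
        assert row["relation_sign"] == 1

    def test_regression_negative_relation(self):
        sites = [f"s{i}" for i in range(6)]
        rng = np.random.default_rng(6)
        vals = rng.random((6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        grid = pd.DataFrame(vals, index=sites, columns=sites)
        ones = pd.DataFrame(1.0, index=sites, columns=sites)
        np.fill_diagonal(ones.values, 0.0)
        from riverdiv.beta import BetaMatrices

        m = BetaMatrices("TD", grid, ones - grid, grid * 0.0)
        fits = beta_component_regression(m).set_index(["x", "y"])
        assert fits.loc[("sor", "sim")]["relation_sign"] == -1

    def test_regression_matches_normal_equations(self, toy_community):
        m = taxonomic_beta(toy_community)
        fits = beta_component_regression(m).set_index(["x", "y"])
        x = m.upper_triangle("sor").to_numpy()
        y = m.upper_triangle("sim").to_numpy()
        coef, r2, r2_adj = quadratic_fit_oracle(x, y)
        row = fits.loc[("sor", "sim")]
        assert np.allclose([row["intercept"], row["linear"], row["quadratic"]],
                           coef, atol=1e-8)
        assert row["r2_adj"] == pytest.approx(r2_adj, abs=1e-10)
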