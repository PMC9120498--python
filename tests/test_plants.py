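"""Crown occlusion geometry, cover combination, and taxonomic/phylogenetic
diversity metrics."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from specdiv import plants, scene
from _oracles import (
    hellinger_distances_loops,
    phylo_covariance_ancestor_sets,
    pse_direct,
    psv_direct,
    visible_cover_exact,
)
from conftest import cover_frame


def tree_df(rows):
    return pd.DataFrame(
        rows, columns=["plot_id", "species", "x_m", "y_m", "crown_diameter_m", "height_m"]
    )


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestVisibleCrownCover:
    def test_coincident_crowns_fully_occlude_the_shorter(self):
        trees = tree_df(
            [
                ("p", "tall", 10.0, 10.0, 4.0, 10.0),
                ("p", "short", 10.0, 10.0, 4.0, 5.0),
            ]
        )
        frac, total = plants.visible_crown_cover(trees, 20.0, resolution=0.1)
        assert frac["short"] == 0.0
        assert frac["tall"] == pytest.approx(np.pi * 4.0 / 400.0, rel=0.02)
        assert total == pytest.approx(frac["tall"])

    def test_single_crown_matches_circle_area(self):
        trees = tree_df([("p", "a", 10.0, 10.0, 2.0, 8.0)])
        frac, _ = plants.visible_crown_cover(trees, 20.0, resolution=0.05)
        assert frac["a"] == pytest.approx(np.pi / 400.0, rel=0.02)

    def test_disjoint_crowns_match_polygon_oracle(self):
        trees = tree_df(
            [
                ("p", "a", 4.0, 4.0, 3.0, 12.0),
                ("p", "b", 14.0, 14.0, 5.0, 6.0),
                ("p", "c", 18.5, 4.0, 4.0, 9.0),  # clipped at the edge
            ]
        )
        frac, _ = plants.visible_crown_cover(trees, 20.0, resolution=0.05)
        exact = visible_cover_exact(trees, 20.0)
        for s in exact:
            assert frac[s] == pytest.approx(exact[s], rel=0.02)

    def test_overlapping_crowns_match_polygon_oracle(self):
        rng = np.random.default_rng(12)
        rows = [
            (
                "p",
                f"s{i % 3}",
                rng.uniform(0, 20),
                rng.uniform(0, 20),
                rng.uniform(2, 6),
                rng.uniform(4, 20),
            )
            for i in range(8)
        ]
        trees = tree_df(rows)
        frac, _ = plants.visible_crown_cover(trees, 20.0, resolution=0.05)
        exact = visible_cover_exact(trees, 20.0)
        for s, val in exact.items():
            assert frac[s] == pytest.approx(val, rel=0.02, abs=5e-4)

    def test_resolution_convergence(self):
        rng = np.random.default_rng(13)
        rows = [
            ("p", f"s{i}", rng.uniform(0, 20), rng.uniform(0, 20),
             rng.uniform(2, 6), rng.uniform(4, 20))
            for i in range(5)
        ]
        trees = tree_df(rows)
        coarse, _ = plants.visible_crown_cover(trees, 20.0, resolution=0.2)
        fine, _ = plants.visible_crown_cover(trees, 20.0, resolution=0.05)
        exact = visible_cover_exact(trees, 20.0)
        err_c = sum(abs(coarse[s] - exact[s]) for s in exact)
        err_f = sum(abs(fine[s] - exact[s]) for s in exact)
        assert err_f <= err_c + 1e-12

    def test_invalid_resolution_rejected(self):
        trees = tree_df([("p", "a", 1.0, 1.0, 2.0, 5.0)])
        with pytest.raises(ValueError):
            plants.visible_crown_cover(trees, 20.0, resolution=0.0)
        with pytest.raises(ValueError):
            plants.visible_crown_cover(trees, 20.0, resolution=1.0)


class TestCombineCover:
    def test_no_crowns_leaves_understory_unchanged(self):
        under = pd.Series({"A": 50.0, "B": 10.0})
        out = plants.combine_cover(pd.Series(dtype=float), under, 0.0)
        assert out["A"] == 50.0 and out["B"] == 10.0

    def test_full_canopy_suppresses_understory(self):
        under = pd.Series({"A": 50.0})
        trees = pd.Series({"T": 1.0})
        out = plants.combine_cover(trees, under, 1.0)
        assert "A" not in out.index or out["A"] == 0.0
        assert out["T"] == 100.0

    def test_partial_canopy_arithmetic(self):
        out = plants.combine_cover(
            pd.Series({"T": 0.4}), pd.Series({"A": 50.0}), 0.4
        )
        assert out["A"] == pytest.approx(30.0)
        assert out.sum() <= 100.0 + 1e-9

    def test_shared_species_accumulates_and_overfull_understory_rescales(self):
        with pytest.warns(UserWarning):
            out = plants.combine_cover(
                pd.Series({"A": 0.2}), pd.Series({"A": 80.0, "B": 120.0}), 0.2
            )
        # understory rescaled to 100 total, then scaled by open fraction 0.8
        assert out["A"] == pytest.approx(20.0 + 0.8 * 40.0)
        assert out["B"] == pytest.approx(0.8 * 60.0)


class TestAlphaMetrics:
    def test_richness_counts_positive_entries(self):
        assert plants.richness([0.0, 0.0]) == 0
        assert plants.richness([10.0, 0.0, 5.0]) == 2
        assert plants.richness(np.array([10.0, 0.0, 5.0]) * 3.7) == 2

    def test_shannon_closed_forms(self):
        assert plants.shannon([42.0]) == 0.0
        assert plants.shannon([5.0, 5.0, 5.0, 5.0]) == pytest.approx(np.log(4))
        assert np.isnan(plants.shannon([0.0, 0.0]))

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            row = rng.random(8) * (rng.random(8) > 0.3)
            if row.sum() == 0:
                continue
            assert plants.shannon(row) <= np.log(max(plants.richness(row), 1)) + 1e-12


class TestPhyloCovariance:
    def test_star_tree_gives_identity(self):
        C = plants.phylo_covariance(newick("(a:1,b:1,c:1,d:1);"))
        assert np.allclose(C.to_numpy(), np.eye(4))

    def test_cherry_shares_half_depth(self):
        C = plants.phylo_covariance(newick("((a:0.5,b:0.5):0.5,c:1);"))
        assert C.loc["a", "b"] == pytest.approx(0.5)
        assert C.loc["a", "c"] == 0.0
        assert np.allclose(np.diag(C), 1.0)

    def test_random_tree_matches_ancestor_set_oracle(self):
        tree = scene.simulate_phylogeny(15, seed=44)
        C = plants.phylo_covariance(tree)
        labels, expected = phylo_covariance_ancestor_sets(tree)
        got = C.loc[labels, labels].to_numpy()
        off = ~np.eye(len(labels), dtype=bool)
        assert np.allclose(got[off], expected[off], atol=1e-10)
        assert np.allclose(np.diag(got), 1.0, atol=1e-9)
        evals = np.linalg.eigvalsh(got)
        assert evals.min() > -1e-10  # positive semidefinite

    def test_missing_species_listed(self):
        tree = newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="zz"):
            plants.phylo_covariance(tree, species=["a", "zz"])


class TestPse:
    def test_star_phylogeny_is_perfectly_even(self):
        C = np.eye(5)
        rng = np.random.default_rng(1)
        for _ in range(10):
            m = rng.uniform(0.1, 50.0, size=5)
            assert plants.pse(m, C) == pytest.approx(1.0, abs=1e-12)

    def test_equal_abundances_reduce_to_psv(self):
        tree = scene.simulate_phylogeny(10, seed=5)
        C = plants.phylo_covariance(tree).to_numpy()
        m = np.full(10, 7.3)
        assert plants.pse(m, C) == pytest.approx(psv_direct(C), rel=1e-12)

    def test_matches_independent_formula_evaluation(self):
        tree = scene.simulate_phylogeny(12, seed=6)
        C = plants.phylo_covariance(tree).to_numpy()
        rng = np.random.default_rng(6)
        for _ in range(10):
            m = rng.uniform(0.0, 30.0, size=12)
            m[rng.random(12) < 0.3] = 0.0
            if (m > 0).sum() < 2:
                continue
            keep = m > 0
            expected = pse_direct(m[keep], C[np.ix_(keep, keep)])
            assert plants.pse(m, C) == pytest.approx(expected, rel=1e-12)

    def test_concentrating_abundance_on_a_clade_reduces_evenness(self):
        # two clades joined at the root: weight sweeps toward one clade
        C = plants.phylo_covariance(
            newick("((a:0.2,b:0.2):0.8,(c:0.2,d:0.2):0.8);")
        ).to_numpy()
        values = []
        for w in (1.0, 3.0, 9.0, 27.0):
            values.append(plants.pse(np.array([w, w, 1.0, 1.0]), C))
        assert all(x > y for x, y in zip(values, values[1:]))
        assert all(0.0 < v <= 1.0 for v in values)

    def test_fewer_than_two_species_is_undefined(self):
        assert np.isnan(plants.pse(np.array([5.0, 0.0]), np.eye(2)))


class TestHellinger:
    def test_relative_abundance_invariance(self):
        cov = cover_frame([[10.0, 30.0], [1.0, 3.0]])
        d = plants.taxonomic_beta_distances(plants.hellinger_transform(cov))
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_monocultures_at_sqrt2(self):
        cov = cover_frame([[50.0, 0.0], [0.0, 80.0]])
        d = plants.taxonomic_beta_distances(plants.hellinger_transform(cov))
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(2.0))

    def test_matches_brute_force_and_bounds(self):
        rng = np.random.default_rng(7)
        cov = cover_frame(rng.uniform(0.0, 40.0, size=(6, 4)))
        got = plants.taxonomic_beta_distances(
            plants.hellinger_transform(cov)
        ).to_numpy()
        expected = hellinger_distances_loops(cov.to_numpy())
        assert np.allclose(got, expected, atol=1e-12)
        assert got.max() <= np.sqrt(2.0) + 1e-12

    def test_zero_rows_excluded_with_warning(self):
        cov = cover_frame([[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
        with pytest.warns(UserWarning):
            t = plants.hellinger_transform(cov)
        assert list(t.index) == ["p0", "p2"]
        assert np.allclose(np.linalg.norm(t.to_numpy(), axis=1), 1.0)


class TestDiversityTable:
    def test_table_combines_metrics_and_averages_replicate_trees(self):
        cov = cover_frame([[10.0, 5.0, 0.0], [4.0, 4.0, 4.0]],
                          species=["sp01", "sp02", "sp03"])
        reps = [scene.simulate_phylogeny(3, seed=s) for s in (1, 2, 3)]
        table = plants.diversity_table(cov, trees=reps)
        assert list(table.columns) == ["richness", "shannon", "pse"]
        assert table.loc["p0", "richness"] == 2
        assert table.loc["p1", "shannon"] == pytest.approx(np.log(3))
        expected = np.mean(
            [plants.pse(cov.loc["p0"], plants.phylo_covariance(t)) for t in reps]
        )
        assert table.loc["p0", "pse"] == pytest.approx(expected)
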