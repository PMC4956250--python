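import math

import numpy as np
import pandas as pd
import pytest

from msatpop import differentiation as diff
from msatpop import synthetic as syn
from msatpop.dataset import GenotypeDataset
from .conftest import make_dataset


class TestTheta:
    def test_identical_large_populations_near_zero(self):
        rng = np.random.default_rng(2)
        draws = rng.choice([100, 102, 104], size=(400, 2))
        pops = {"A": [[(a, b)] for a, b in draws[:200]],
                "B": [[(a, b)] for a, b in draws[200:]]}
        ds = make_dataset(pops)
        assert abs(diff.wc_theta(ds)) < 0.02

    def test_fixed_disjoint_populations_are_one(self):
        ds = make_dataset({
            "A": [[(100, 100)]] * 10,
            "B": [[(108, 108)]] * 10,
        })
        assert diff.wc_theta(ds) == pytest.approx(1.0)

    def test_recovers_island_model_target(self):
        spec = syn.GeneratorSpec(
            n_populations=10, n_individuals=50, n_loci=8, fst=0.2, seed=31
        )
        ds, _ = syn.generate(spec)
        assert diff.wc_theta(ds) == pytest.approx(0.2, abs=0.03)

    def test_invariant_to_size_relabelling(self, island_dataset):
        from .test_diversity import make_relabelled

        ds, _ = island_dataset
        assert diff.wc_theta(make_relabelled(ds)) == pytest.approx(
            diff.wc_theta(ds), abs=1e-12
        )

    def test_bootstrap_ci_brackets_estimate(self, island_dataset):
        ds, _ = island_dataset
        theta, (lo, hi) = diff.theta_bootstrap_ci(ds, n_boot=500, seed=3)
        assert lo <= theta <= hi


class TestPairwiseSignificance:
    def test_split_population_p_centred(self):
        spec = syn.GeneratorSpec(
            n_populations=1, n_individuals=60, n_loci=5, fst=0.0, seed=7
        )
        ds, _ = syn.generate(spec)
        # split one panmictic population arbitrarily in two
        ds.pop_index = np.repeat([0, 1], 30)
        from msatpop.dataset import PopulationInfo

        ds.populations = [PopulationInfo(id="A", n=30), PopulationInfo(id="B", n=30)]
        ps = []
        rng = np.random.default_rng(0)
        for rep in range(20):
            ds.pop_index = rng.permutation(ds.pop_index)
            p = diff.pairwise_fst_significance(ds, n_perm=60, seed=rep)
            ps.append(p.loc["A", "B"])
        assert 0.25 < np.mean(ps) < 0.75

    def test_disjoint_pair_minimal_p(self):
        ds = make_dataset({
            "A": [[(100, 100)]] * 8,
            "B": [[(108, 108)]] * 8,
        })
        p = diff.pairwise_fst_significance(ds, n_perm=99, seed=1)
        assert p.loc["A", "B"] == pytest.approx(1 / 100)


class TestChordDistance:
    def test_identical_profiles_zero(self):
        ds = make_dataset({"A": [[(100, 102)]], "B": [[(102, 100)]]})
        assert diff.chord_distance(ds, "A", "B") == pytest.approx(0.0)

    def test_fixed_different_alleles_single_locus(self):
        ds = make_dataset({"A": [[(100, 100)]] * 3, "B": [[(102, 102)]] * 3})
        # one locus, two alleles: D^2 = 4(1 - 0)/1, D = 2
        assert diff.chord_distance(ds, "A", "B") == pytest.approx(2.0)

    def test_symmetry_and_self_distance(self, island_dataset):
        ds, _ = island_dataset
        d_ab = diff.chord_distance(ds, "P01", "P02")
        d_ba = diff.chord_distance(ds, "P02", "P01")
        assert d_ab == pytest.approx(d_ba)
        assert diff.chord_distance(ds, "P01", "P01") == pytest.approx(0.0)
        assert d_ab >= 0


class TestFitchMargoliash:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree: (A:1, B:2):1 | (C:3, D:2): internal edge 1 -> additive matrix
        dm = pd.DataFrame(
            [
                [0, 3, 5, 4],
                [3, 0, 6, 5],
                [5, 6, 0, 5],
                [4, 5, 5, 0],
            ],
            index=list("ABCD"),
            columns=list("ABCD"),
            dtype=float,
        )
        tree, obj = diff.fitch_margoliash(dm)
        assert obj == pytest.approx(0.0, abs=1e-15)
        bps = diff.tree_bipartitions(tree, list("ABCD"))
        assert frozenset({"A", "B"}) in bps
        # branch lengths reproduce the path distances
        dists = {}
        tips = {t.name: t for t in tree.tips()}
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    d = tips[a].distance(tips[b])
                    assert d == pytest.approx(dm.loc[a, b], abs=1e-9)

    def test_three_taxa_solves_linear_system(self):
        dm = pd.DataFrame(
            [[0, 5, 7], [5, 0, 8], [7, 8, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree, obj = diff.fitch_margoliash(dm)
        assert obj == pytest.approx(0.0, abs=1e-15)
        tips = {t.name: t for t in tree.tips()}
        # x+y=5, x+z=7, y+z=8 -> x=2, y=3, z=5
        lengths = sorted(t.length for t in tree.tips())
        assert lengths == pytest.approx([2.0, 3.0, 5.0])

    def test_degenerate_matrix_yields_star_tree(self):
        dm = pd.DataFrame(np.zeros((4, 4)), index=list("ABCD"), columns=list("ABCD"))
        tree, obj = diff.fitch_margoliash(dm)
        assert obj == 0.0
        assert len(tree.children) == 4


class TestBootstrapTree:
    def test_identical_loci_give_full_support(self):
        spec = syn.GeneratorSpec(
            n_populations=5, n_individuals=20, n_loci=1, fst=0.3, seed=17
        )
        ds, _ = syn.generate(spec)
        ds2 = GenotypeDataset(
            [ds.loci[0], type(ds.loci[0])("L02", 2)],
            ds.populations,
            np.repeat(ds.calls, 2, axis=1),
            ds.pop_index,
        )
        tree, supports = diff.bootstrap_tree(ds2, n_boot=30, seed=1)
        assert supports and all(v == 100.0 for v in supports.values())

    def test_separated_groups_supported(self):
        ds, _ = syn.paper_shaped_fixture(seed=3)
        sub = ds.subset_populations(
            ["P01", "P02", "P03", "P27", "P28", "P30"]
        )
        tree, supports = diff.bootstrap_tree(sub, n_boot=60, seed=2)
        split = frozenset({"P27", "P28", "P30"})
        other = frozenset({"P01", "P02", "P03"})
        key = min(split, other, key=lambda s: (len(s), sorted(s)))
        assert supports.get(key, 0.0) >= 90.0


class TestAmova:
    def test_two_fixed_populations_all_among(self):
        ds = make_dataset({
            "A": [[(100, 100)]] * 10,
            "B": [[(108, 108)]] * 10,
        })
        res = diff.amova(ds, n_perm=50, seed=1)
        assert res.table.loc["among_populations", "pct"] == pytest.approx(100.0)
        assert res.phi["phi_ST"] == pytest.approx(1.0)

    def test_panmictic_near_zero(self):
        spec = syn.GeneratorSpec(
            n_populations=4, n_individuals=30, n_loci=6, fst=0.0, seed=41
        )
        ds, _ = syn.generate(spec)
        res = diff.amova(ds, n_perm=50, seed=2)
        assert abs(res.phi["phi_ST"]) < 0.02
        assert res.p_values["phi_ST"] > 0.05

    def test_components_sum_to_hundred_and_df_consistent(self, paper_fixture):
        ds, _ = paper_fixture
        groups = ds.status_groups()
        res = diff.amova(ds, groups=groups, n_perm=20, seed=3)
        assert res.table["pct"].sum() == pytest.approx(100.0, abs=0.01)
        # df sum over strata = total gene copies - 1
        assert res.table["df"].sum() == pytest.approx(2 * ds.n_individuals - 1)
        res1 = diff.amova(ds, n_perm=20, seed=4)
        assert res1.table["pct"].sum() == pytest.approx(100.0, abs=0.01)
        assert res1.p_values["phi_ST"] <= 0.05


class TestMantelIbd:
    @staticmethod
    def _coords(ids, rng):
        return {p: (float(rng.uniform(40, 48)), float(rng.uniform(13, 29))) for p in ids}

    def test_perfectly_proportional_matrices_r_one(self):
        rng = np.random.default_rng(5)
        ids = [f"P{i}" for i in range(6)]
        coords = self._coords(ids, rng)
        geo = np.zeros((6, 6))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i != j:
                    geo[i, j] = math.log(diff.haversine_km(*coords[a], *coords[b]))
        lin = 0.01 * geo  # FST/(1-FST) proportional to ln km
        fst = lin / (1 + lin)
        np.fill_diagonal(fst, 0.0)
        res = diff.mantel_ibd(pd.DataFrame(fst, index=ids, columns=ids), coords,
                              n_perm=200, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert res.r_squared == pytest.approx(res.r**2)
        assert res.p_value < 0.05

    def test_shuffled_matrices_uncorrelated(self):
        rng = np.random.default_rng(6)
        ids = [f"P{i}" for i in range(8)]
        coords = self._coords(ids, rng)
        rs, ps = [], []
        for rep in range(15):
            f = rng.uniform(0.01, 0.3, size=(8, 8))
            f = (f + f.T) / 2
            np.fill_diagonal(f, 0)
            res = diff.mantel_ibd(
                pd.DataFrame(f, index=ids, columns=ids), coords, n_perm=150, seed=rep
            )
            rs.append(res.r)
            ps.append(res.p_value)
        assert abs(np.mean(rs)) < 0.25
        assert 0.2 < np.mean(ps) < 0.8

    def test_fst_one_raises_with_pair_name(self):
        ids = ["PA", "PB", "PC", "PD"]
        f = np.full((4, 4), 0.1)
        np.fill_diagonal(f, 0)
        f[0, 1] = f[1, 0] = 1.0
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="PA.*PB"):
            diff.mantel_ibd(
                pd.DataFrame(f, index=ids, columns=ids),
                self._coords(ids, rng),
                n_perm=10,
            )
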