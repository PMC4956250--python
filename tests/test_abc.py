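import numpy as np
import pytest

from msatpop import abc
from msatpop import structure as st
from msatpop import synthetic as syn


@pytest.fixture(scope="module")
def small_table():
    return abc.build_reference_table(120, seed=3)  # 600 rows


class TestPriors:
    def test_constraints_hold_over_many_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            s = int(rng.integers(1, 6))
            p = abc.sample_prior(s, rng)
            assert p["NA"] > max(p["N1"], p["N2"], p["N3"])
            assert p["t2"] >= p["t1"]
            if s == 5:
                assert p["t1"] == p["t2"]
            if s == 4:
                assert 0.001 <= p["r"] <= 0.999
            else:
                assert np.isnan(p["r"])
            assert 1e-5 <= p["mu_mean"] <= 1e-3
            assert 0.10 <= p["p_mean"] <= 0.30
            assert 1e-8 <= p["sni_mean"] <= 1e-5

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            abc.sample_prior(6, np.random.default_rng(0))


class TestSimulator:
    def test_negligible_mutation_gives_monomorphic_sample(self):
        params = dict(
            scenario=5, N1=100.0, N2=100.0, N3=100.0, NA=200.0,
            t1=10.0, t2=10.0, r=np.nan,
            mu_mean=1e-12, p_mean=0.2, sni_mean=0.0,
        )
        ds = abc.simulate_dataset(params, seed=1)
        for li in range(ds.n_loci):
            assert len(ds.pooled_allele_counts(li)) == 1

    def test_trifurcation_with_tiny_t_gives_near_zero_fst(self):
        rng = np.random.default_rng(2)
        fsts = []
        for _ in range(10):
            params = dict(
                scenario=5, N1=1000.0, N2=1000.0, N3=1000.0, NA=1000.0,
                t1=1.0, t2=1.0, r=np.nan,
                mu_mean=5e-4, p_mean=0.2, sni_mean=1e-7,
            )
            s = abc.summary_stats(abc.simulate_dataset(params, seed=rng))
            fsts.append(np.mean(s[12:15]))
        assert abs(np.mean(fsts)) < 0.02

    def test_divergence_increases_fst_and_decreases_assignment(self):
        rng = np.random.default_rng(3)
        mean_fst, mean_lij = [], []
        for t in (50.0, 500.0, 5000.0):
            f, l = [], []
            for _ in range(8):
                params = dict(
                    scenario=5, N1=1000.0, N2=1000.0, N3=1000.0, NA=1500.0,
                    t1=t, t2=t, r=np.nan,
                    mu_mean=5e-4, p_mean=0.2, sni_mean=1e-7,
                )
                s = abc.summary_stats(abc.simulate_dataset(params, seed=rng))
                f.append(np.mean(s[12:15]))
                l.append(np.mean(s[18:24]))
            mean_fst.append(np.mean(f))
            mean_lij.append(np.mean(l))
        assert mean_fst[0] < mean_fst[1] < mean_fst[2]
        assert mean_lij[0] > mean_lij[1] > mean_lij[2]

    def test_oracle_tree_height_matches_msprime(self):
        # independent oracle for the structured coalescent: expected sample
        # heterozygosity of a single population under the infinite-sites-free
        # engine is checked against msprime's pairwise coalescence times
        import msprime

        N = 500.0
        n = 20  # gene copies
        rng = np.random.default_rng(8)
        from msatpop.coalescent import simulate_locus

        theta = 0.5
        mu = theta / (4 * N)
        he_own = []
        for _ in range(300):
            vals = simulate_locus([n], [N], [], mu, rng, motif_length=1, root_size=1000)
            _, c = np.unique(vals, return_counts=True)
            p = c / c.sum()
            he_own.append(1 - (p**2).sum())
        # msprime oracle: diploid scaling gives the same 1/(2N) pair rate;
        # overlay the same single-step mutations on its trees
        rng2 = np.random.default_rng(9)
        he_ms = []
        for ts in msprime.sim_ancestry(
            samples=n // 2, population_size=N, ploidy=2,
            num_replicates=300, random_seed=11,
        ):
            tree = ts.first()
            vals = {}
            for node in tree.nodes(order="preorder"):
                parent = tree.parent(node)
                if parent == -1:
                    vals[node] = 0
                    continue
                blen = tree.time(parent) - tree.time(node)
                nmut = rng2.poisson(mu * blen)
                step = (rng2.integers(0, 2, size=nmut) * 2 - 1).sum() if nmut else 0
                vals[node] = vals[parent] + step
            leaf_vals = np.asarray([vals[u] for u in ts.samples()])
            _, c = np.unique(leaf_vals, return_counts=True)
            p = c / c.sum()
            he_ms.append(1 - (p**2).sum())
        se = np.sqrt(np.var(he_own) / 300 + np.var(he_ms) / 300)
        assert abs(np.mean(he_own) - np.mean(he_ms)) < 3 * se + 0.01


class TestSummaryStats:
    def test_das_of_disjoint_fixed_populations_is_one(self):
        params = dict(
            scenario=5, N1=50.0, N2=50.0, N3=50.0, NA=100.0,
            t1=1.0, t2=1.0, r=np.nan, mu_mean=1e-12, p_mean=0.2, sni_mean=0.0,
        )
        ds = abc.simulate_dataset(params, seed=4)
        # force disjoint fixed alleles per population
        ds.calls[ds.individuals_of(0)] = 100
        ds.calls[ds.individuals_of(1)] = 120
        ds.calls[ds.individuals_of(2)] = 140
        s = abc.summary_stats(ds)
        names = abc.summary_stat_names()
        das = s[[names.index(f"DAS_{p}") for p in ("12", "13", "23")]]
        assert np.allclose(das, 1.0)

    def test_identical_populations_low_fst_and_low_das(self):
        rng = np.random.default_rng(5)
        spec = syn.GeneratorSpec(n_populations=3, n_individuals=30, n_loci=8,
                                 fst=0.0, seed=6)
        ds, _ = syn.generate(spec)
        s = abc.summary_stats(ds)
        assert abs(np.mean(s[12:15])) < 0.02

    def test_vector_length_and_order(self):
        assert len(abc.summary_stat_names()) == 24


class TestReferenceTable:
    def test_row_count_exact(self, small_table):
        assert len(small_table) == 5 * 120
        assert sorted(small_table["scenario"].unique()) == [1, 2, 3, 4, 5]

    def test_stats_finite(self, small_table):
        stats = small_table[abc.summary_stat_names()].to_numpy()
        assert np.isfinite(stats).all()

    def test_seeded_reproducibility(self):
        a = abc.build_reference_table(5, seed=9)
        b = abc.build_reference_table(5, seed=9)
        assert np.allclose(
            a[abc.summary_stat_names()].to_numpy(),
            b[abc.summary_stat_names()].to_numpy(),
        )


class TestModelChoice:
    def test_probabilities_sum_to_one(self, small_table):
        rng = np.random.default_rng(11)
        obs = abc.summary_stats(abc.simulate_dataset(abc.sample_prior(5, rng), seed=rng))
        mc = abc.model_choice(small_table, obs, n_closest=100)
        assert mc["posterior_probability"].sum() == pytest.approx(1.0, abs=1e-9)
        assert ((mc["ci_low"] <= mc["ci_high"])).all()

    def test_duplicated_scenarios_split_evenly(self, small_table):
        # relabel: scenarios 1 and 2 replaced by copies of scenario 5's rows
        tab = small_table.copy()
        five = tab[tab["scenario"] == 5]
        clone = five.copy()
        clone["scenario"] = 1
        tab = tab[tab["scenario"].isin([5])]
        import pandas as pd

        tab = pd.concat([tab, clone], ignore_index=True)
        rng = np.random.default_rng(12)
        obs = abc.summary_stats(abc.simulate_dataset(abc.sample_prior(5, rng), seed=rng))
        mc = abc.model_choice(tab, obs, n_closest=200)
        p = mc.set_index("scenario")["posterior_probability"]
        assert p[1] == pytest.approx(p[5], abs=0.12)

    def test_rescaling_invariance(self, small_table):
        rng = np.random.default_rng(13)
        obs = abc.summary_stats(abc.simulate_dataset(abc.sample_prior(3, rng), seed=rng))
        mc1 = abc.model_choice(small_table, obs, n_closest=150)
        scaled = small_table.copy()
        names = abc.summary_stat_names()
        factors = np.linspace(2.0, 11.0, len(names))
        scaled[names] = scaled[names] * factors
        mc2 = abc.model_choice(scaled, obs * factors, n_closest=150)
        assert np.allclose(
            mc1["posterior_probability"], mc2["posterior_probability"], atol=1e-6
        )

    def test_n_closest_bounded(self, small_table):
        with pytest.raises(ValueError):
            abc.model_choice(small_table, np.zeros(24), n_closest=10**6)


class TestEstimateParams:
    def test_observed_equal_to_reference_row_concentrates_weight(self, small_table):
        row = small_table[small_table["scenario"] == 5].iloc[7]
        obs = row[abc.summary_stat_names()].to_numpy(dtype=float)
        post = abc.posterior_sample(small_table, obs, 5, n_closest=50)
        assert post["abc_weight"].iloc[0] == post["abc_weight"].max()
        assert post.iloc[0]["t1"] == pytest.approx(row["t1"])

    def test_quantiles_ordered_and_within_prior(self, small_table):
        rng = np.random.default_rng(15)
        obs = abc.summary_stats(abc.simulate_dataset(abc.sample_prior(5, rng), seed=rng))
        est = abc.estimate_params(small_table, obs, scenario=5, n_closest=120)
        for _, r in est.iterrows():
            lo, hi = abc.PARAM_BOUNDS[r["parameter"]]
            assert lo <= r["q025"] <= r["q05"] <= r["median"] <= r["q95"] <= r["q975"] <= hi


class TestModelCheck:
    def test_tail_probabilities_and_pca_shapes(self, small_table):
        rng = np.random.default_rng(16)
        obs = abc.summary_stats(abc.simulate_dataset(abc.sample_prior(5, rng), seed=rng))
        post = abc.posterior_sample(small_table, obs, 5, n_closest=60)
        prior_stats = small_table[abc.summary_stat_names()].to_numpy()[:300]
        chk = abc.model_check(
            post, obs, n_ppc=40, seed=2, prior_stats=prior_stats
        )
        tails = chk["tails"]
        ok = tails[~tails["constant"]]
        assert ((ok["tail"] >= 0) & (ok["tail"] <= 1)).all()
        assert ((ok["p_two_sided"] >= 0) & (ok["p_two_sided"] <= 1)).all()
        assert chk["pca"]["prior"].shape == (300, 2)
        assert chk["pca"]["observed"].shape == (1, 2)


class TestDefineAbcPopulations:
    def test_threshold_monotonicity_and_exclusion(self):
        spec = syn.GeneratorSpec(
            n_populations=2, n_individuals=40, n_loci=8, fst=0.25, seed=19
        )
        ds, _ = syn.generate(spec)
        run = st.gibbs_run(ds, K=2, burnin=600, reps=2000, seed=4)
        # map each new population to the cluster dominating its source
        mapping = {
            f"Pop{j + 1}": int(run.Q[ds.individuals_of(j)].mean(axis=0).argmax())
            for j in range(2)
        }
        assert mapping["Pop1"] != mapping["Pop2"]
        d0 = abc.define_abc_populations(run, ds, mapping, threshold=0.0)
        d9 = abc.define_abc_populations(run, ds, mapping, threshold=0.9)
        assert d9.n_individuals <= d0.n_individuals == ds.n_individuals
        # excluding a sampling population removes its individuals entirely
        c2 = mapping["Pop2"]
        dx = abc.define_abc_populations(
            run, ds, {"PopX": c2}, threshold=0.0, exclude_populations=["P01"]
        )
        expected = int(
            ((run.Q.argmax(axis=1) == c2) & (ds.pop_index == 1)).sum()
        )
        assert dx.n_individuals == expected

    def test_empty_cluster_raises(self):
        spec = syn.GeneratorSpec(n_populations=2, n_individuals=10, n_loci=4, seed=20)
        ds, _ = syn.generate(spec)
        run = st.gibbs_run(ds, K=2, burnin=200, reps=600, seed=5)
        with pytest.raises(ValueError):
            abc.define_abc_populations(run, ds, {"A": 0}, threshold=1.0)
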