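import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msatpop import diversity as dv
from msatpop import synthetic as syn
from msatpop.dataset import MISSING
from .conftest import make_dataset


class TestPic:
    def test_two_equifrequent_alleles(self):
        ds = make_dataset({"P1": [[(100, 102)], [(102, 100)]]})
        assert dv.pic(ds, 0) == pytest.approx(1 - 0.5 - 0.125)

    def test_monomorphic_is_zero(self):
        ds = make_dataset({"P1": [[(100, 100)], [(100, 100)]]})
        assert dv.pic(ds, 0) == 0.0


class TestHeterozygosity:
    def test_single_heterozygote_unbiased_he_is_one(self):
        ds = make_dataset({"P1": [[(100, 102)]]})
        assert dv.expected_het(ds, "P1", 0) == pytest.approx(1.0)

    def test_monomorphic_he_is_zero(self):
        ds = make_dataset({"P1": [[(100, 100)], [(100, 100)]]})
        assert dv.expected_het(ds, "P1", 0) == 0.0

    def test_observed_het_half(self):
        ds = make_dataset({"P1": [[(100, 100)], [(100, 102)]]})
        assert dv.observed_het(ds, "P1", 0) == pytest.approx(0.5)

    def test_observed_het_all_homozygous(self):
        ds = make_dataset({"P1": [[(100, 100)], [(102, 102)]]})
        assert dv.observed_het(ds, "P1", 0) == 0.0

    def test_size_relabelling_invariance(self, island_dataset):
        ds, _ = island_dataset
        shifted = make_relabelled(ds)
        for li in range(ds.n_loci):
            assert dv.expected_het(ds, 0, li) == pytest.approx(
                dv.expected_het(shifted, 0, li)
            )
            assert dv.pic(ds, li) == pytest.approx(dv.pic(shifted, li))


def make_relabelled(ds):
    from msatpop.dataset import GenotypeDataset

    calls = ds.calls.copy()
    calls[calls != MISSING] = calls[calls != MISSING] * 3 + 7
    return GenotypeDataset(ds.loci, ds.populations, calls, ds.pop_index)


class TestAllelicRichness:
    def test_counts_3_1_at_g2_matches_enumeration(self):
        # oracle: enumerate all C(4,2)=6 subsamples of copies {a,a,a,b}
        copies = ["a", "a", "a", "b"]
        expected = np.mean(
            [len(set(c)) for c in itertools.combinations(copies, 2)]
        )
        ds = make_dataset({"P1": [[(100, 100)], [(100, 102)]]})
        assert dv.allelic_richness(ds, "P1", 0, g=2) == pytest.approx(expected)
        assert expected == pytest.approx(1.5)

    def test_full_sample_recovers_allele_count(self):
        ds = make_dataset({"P1": [[(100, 102)], [(104, 100)]]})
        assert dv.allelic_richness(ds, "P1", 0, g=4) == pytest.approx(3.0)

    def test_monotone_in_g_and_bounded_at_g2(self, island_dataset):
        ds, _ = island_dataset
        vals = [dv.allelic_richness(ds, 0, 0, g) for g in range(2, 20)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert 1.0 <= vals[0] <= 2.0

    def test_g_above_sample_raises(self):
        ds = make_dataset({"P1": [[(100, 102)]]})
        with pytest.raises(ValueError):
            dv.allelic_richness(ds, "P1", 0, g=3)


class TestPrivateAlleles:
    def test_fully_shared_alleles_give_zero(self):
        ds = make_dataset(
            {"P1": [[(100, 102)]], "P2": [[(102, 100)]]}
        )
        assert set(dv.private_alleles(ds).values()) == {0}

    def test_private_allele_counted_once(self):
        ds = make_dataset(
            {"P1": [[(100, 104)]], "P2": [[(102, 100)]]}
        )
        priv = dv.private_alleles(ds)
        assert priv == {"P1": 1, "P2": 1}


class TestFis:
    def test_fully_selfed_population_is_one(self):
        inds = [[(100, 100)]] * 5 + [[(102, 102)]] * 5
        ds = make_dataset({"P1": inds})
        assert dv.fis(ds, "P1") == pytest.approx(1.0)

    def test_hwe_population_near_zero(self):
        rng = np.random.default_rng(1)
        draws = rng.choice([100, 102], size=(10_000, 2), p=[0.5, 0.5])
        ds = make_dataset({"P1": [[(a, b)] for a, b in draws]})
        assert abs(dv.fis(ds, "P1")) < 0.03


class TestHweExact:
    def test_two_allele_enumeration_matches_monte_carlo(self):
        rng = np.random.default_rng(5)
        draws = rng.choice([100, 102], size=(10, 2), p=[0.6, 0.4])
        ds = make_dataset({"P1": [[(a, b)] for a, b in draws]})
        p_exact = dv.hwe_exact(ds, "P1", 0)
        p_mc = dv._hwe_mc(
            ds.calls[:, 0, :], ds.calls[:, 0, :].ravel(), 10, 40_000, 1, "two-sided"
        )
        assert p_mc == pytest.approx(p_exact, abs=0.01)

    def test_all_heterozygote_pair_is_unsurprising(self):
        # two individuals a/b, a/b: conditional table distribution puts the
        # observed (most probable) table's probability mass at P = 1
        ds = make_dataset({"P1": [[(100, 102)], [(100, 102)]]})
        assert dv.hwe_exact(ds, "P1", 0) == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_is_one(self):
        ds = make_dataset({"P1": [[(100, 100)], [(100, 100)]]})
        assert dv.hwe_exact(ds, "P1", 0) == 1.0

    def test_heterozygote_deficit_tail_flags_inbred_data(self):
        inds = [[(100, 100)]] * 12 + [[(102, 102)]] * 12 + [[(100, 102)]] * 1
        ds = make_dataset({"P1": inds})
        p = dv.hwe_exact(ds, "P1", 0, mc_reps=4000, seed=2, alternative="deficit")
        assert p < 0.01


class TestGlobalHwe:
    def test_all_ones_combine_to_one(self):
        assert dv.global_hwe([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_is_identity(self):
        assert dv.global_hwe([0.37]) == pytest.approx(0.37)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        st.integers(0, 5),
    )
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_components(self, ps, idx):
        idx = idx % len(ps)
        lowered = list(ps)
        lowered[idx] = ps[idx] / 2
        assert dv.global_hwe(lowered) <= dv.global_hwe(ps) + 1e-12


class TestSequentialBonferroni:
    def test_both_rejected_when_holm_chain_passes(self):
        flags = dv.sequential_bonferroni([0.001, 0.04], alpha=0.05)
        assert flags.tolist() == [True, True]

    def test_chain_stops_at_first_failure(self):
        flags = dv.sequential_bonferroni([0.03, 0.04], alpha=0.05)
        assert flags.tolist() == [False, False]

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    @settings(max_examples=40, deadline=None)
    def test_holm_flags_subset_of_unadjusted(self, ps):
        holm = dv.sequential_bonferroni(ps, alpha=0.05)
        raw = np.asarray(ps) <= 0.05
        assert not np.any(holm & ~raw)


class TestGroupPermutation:
    def test_identical_groups_not_significant(self):
        inds = [[(100, 102)], [(100, 100)], [(102, 102)]]
        ds = make_dataset({f"P{i}": list(inds) for i in range(1, 5)})
        grouping = {"a": ["P1", "P2"], "b": ["P3", "P4"]}
        _, p = dv.group_permutation_test(
            ds, "He", grouping, n_perm=200, seed=1
        )
        assert p == pytest.approx(1.0)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(3)
        pops = {}
        for i in range(10):  # diverse: 6 alleles
            draws = rng.integers(0, 6, size=(15, 2)) * 2 + 100
            pops[f"H{i}"] = [[(a, b)] for a, b in draws]
        for i in range(10):  # depauperate: 2 skewed alleles
            draws = rng.choice([100, 102], size=(15, 2), p=[0.9, 0.1])
            pops[f"L{i}"] = [[(a, b)] for a, b in draws]
        ds = make_dataset(pops)
        grouping = {
            "high": [f"H{i}" for i in range(10)],
            "low": [f"L{i}" for i in range(10)],
        }
        means, p = dv.group_permutation_test(ds, "He", grouping, n_perm=1000, seed=2)
        assert means["high"] > means["low"]
        assert p <= 0.01

    def test_empty_group_rejected(self, island_dataset):
        ds, _ = island_dataset
        with pytest.raises(ValueError):
            dv.group_permutation_test(ds, "He", {"a": ["P01"], "b": []})


def test_diversity_table_shape(island_dataset):
    ds, _ = island_dataset
    tab = dv.diversity_table(ds, hwe_reps=300, seed=0)
    assert len(tab) == ds.n_populations
    assert {"Nav", "Nar", "Npr", "Ho", "He", "FIS", "P_HWE_global"} <= set(tab.columns)
    assert ((tab["Ho"] >= 0) & (tab["Ho"] <= 1)).all()
    assert ((tab["He"] >= 0) & (tab["He"] <= 1)).all()
    assert tab["FIS"].abs().max() <= 1.0
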