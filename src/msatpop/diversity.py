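"""Within-population diversity statistics and Hardy-Weinberg tests.

Implements the left half of a standard per-population microsatellite summary
table: average allele number (Nav), rarefied allelic richness (Nar), private
alleles (Npr), observed/expected heterozygosity, Weir-Cockerham FIS, exact HWE
tests with sequential-Bonferroni correction, and between-group permutation
tests on population means.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import combine_pvalues
from statsmodels.stats.multitest import multipletests

from .dataset import MISSING, GenotypeDataset

UNDEFINED = float("nan")


# -- single-locus statistics -----------------------------------------------------


def pic(dataset: GenotypeDataset, locus) -> float:
    """Polymorphism information content from pooled allele frequencies.

    Botstein's formula: ``PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``.
    A monomorphic locus has PIC 0.
    """
    counts = dataset.pooled_allele_counts(locus)
    if not counts:
        return UNDEFINED
    p = np.asarray(list(counts.values()), dtype=float)
    p /= p.sum()
    sum_p2 = float(np.sum(p**2))
    sum_p4 = float(np.sum(p**4))
    cross = (sum_p2**2 - sum_p4)  # = sum_{i != j} p_i^2 p_j^2
    return 1.0 - sum_p2 - cross


def expected_het(dataset: GenotypeDataset, population, locus) -> float:
    """Nei's unbiased expected heterozygosity ``(2n/(2n-1)) (1 - sum p^2)``."""
    counts = dataset.allele_counts(population, locus)
    n2 = sum(counts.values())  # gene copies
    if n2 == 0:
        return UNDEFINED
    if n2 == 1:
        return UNDEFINED
    p = np.asarray(list(counts.values()), dtype=float) / n2
    return (n2 / (n2 - 1.0)) * (1.0 - float(np.sum(p**2)))


def observed_het(dataset: GenotypeDataset, population, locus=None):
    """Fraction of typed individuals with two distinct alleles.

    With ``locus=None`` returns the vector over loci (NaN where untyped).
    """
    rows = dataset.individuals_of(population)
    calls = dataset.calls[rows]
    if locus is not None:
        li = dataset.locus_index(locus)
        g = calls[:, li, :]
        typed = g[:, 0] != MISSING
        if not typed.any():
            return UNDEFINED
        return float((g[typed, 0] != g[typed, 1]).mean())
    out = np.full(dataset.n_loci, UNDEFINED)
    for li in range(dataset.n_loci):
        g = calls[:, li, :]
        typed = g[:, 0] != MISSING
        if typed.any():
            out[li] = float((g[typed, 0] != g[typed, 1]).mean())
    return out


def allelic_richness(dataset: GenotypeDataset, population, locus, g: int) -> float:
    """Rarefied allele count for a standardized subsample of ``g`` gene copies.

    Hypergeometric rarefaction: ``Nar = sum_a [1 - C(N - N_a, g)/C(N, g)]``
    where ``N`` is the number of typed gene copies in the cell and ``N_a`` the
    copies of allele ``a``.  ``g`` must not exceed ``N``.
    """
    counts = dataset.allele_counts(population, locus)
    n_total = sum(counts.values())
    if n_total == 0:
        return UNDEFINED
    if g > n_total:
        raise ValueError(f"rarefaction size g={g} exceeds typed copies N={n_total}")
    if g < 1:
        raise ValueError("g must be >= 1")
    total = 0.0
    for c in counts.values():
        total += 1.0 - _hyper_ratio(n_total, c, g)
    return total


def _hyper_ratio(n_total: int, n_a: int, g: int) -> float:
    """``C(N - N_a, g) / C(N, g)`` computed in log space (0 when g > N - N_a)."""
    if g > n_total - n_a:
        return 0.0
    lg = (
        gammaln(n_total - n_a + 1)
        - gammaln(g + 1)
        - gammaln(n_total - n_a - g + 1)
        - (gammaln(n_total + 1) - gammaln(g + 1) - gammaln(n_total - g + 1))
    )
    return float(np.exp(lg))


def min_gene_copies(dataset: GenotypeDataset) -> int:
    """Dataset-wide minimum typed gene copies over population x locus cells.

    The default rarefaction size for allelic richness, mirroring the
    smallest-complete-cell convention of the standard diversity software.
    """
    lo = None
    for k in range(dataset.n_populations):
        for li in range(dataset.n_loci):
            n2 = 2 * dataset.n_typed(k, li)
            if n2 > 0:
                lo = n2 if lo is None else min(lo, n2)
    if lo is None:
        raise ValueError("dataset has no typed cells")
    return lo


def private_alleles(dataset: GenotypeDataset, grouping: str = "population"):
    """Private-allele counts per unit of a partition.

    ``grouping='population'`` counts alleles found in exactly one population;
    ``grouping='status'`` partitions populations into indigenous vs
    cultivated/naturalised and counts alleles exclusive to each group.
    Returns a dict unit -> count.
    """
    if grouping == "population":
        units = {p.id: [k] for k, p in enumerate(dataset.populations)}
    elif grouping == "status":
        sg = dataset.status_groups()
        units = {
            name: [dataset.population_index(pid) for pid in pids]
            for name, pids in sg.items()
        }
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    out = {name: 0 for name in units}
    for li in range(dataset.n_loci):
        presence: dict[int, set[str]] = {}
        for name, ks in units.items():
            for k in ks:
                for a in dataset.allele_counts(k, li):
                    presence.setdefault(a, set()).add(name)
        for a, found_in in presence.items():
            if len(found_in) == 1:
                out[next(iter(found_in))] += 1
    return out


# -- Weir & Cockerham FIS --------------------------------------------------------


def _wc_within_components(dataset: GenotypeDataset, population, locus):
    """Per-allele (b, c) Weir-Cockerham variance components for one sample.

    For a single population the among-population terms vanish and the
    small-``f`` estimator reduces to ``1 - sum(c)/sum(b + c)`` with
    ``b = (n/(n-1)) [p(1-p) - (2n-1)/(4n) hbar]`` and ``c = hbar/2`` per allele.
    """
    li = dataset.locus_index(locus)
    rows = dataset.individuals_of(population)
    g = dataset.calls[rows, li, :]
    typed = g[:, 0] != MISSING
    g = g[typed]
    n = g.shape[0]
    if n < 2:
        return np.zeros(0), np.zeros(0)
    alleles = np.unique(g)
    bs, cs = [], []
    het = g[:, 0] != g[:, 1]
    for a in alleles:
        p = float((g == a).sum()) / (2 * n)
        hbar = float((het & ((g == a).any(axis=1))).sum()) / n
        b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1.0) / (4.0 * n) * hbar)
        c = hbar / 2.0
        bs.append(b)
        cs.append(c)
    return np.asarray(bs), np.asarray(cs)


def fis(dataset: GenotypeDataset, population, locus=None) -> float:
    """Weir & Cockerham (1984) small-``f`` inbreeding coefficient.

    Components are summed over alleles (and over loci for the multilocus
    value) before the ratio is taken.  Returns NaN when no polymorphism.
    """
    loci = range(dataset.n_loci) if locus is None else [dataset.locus_index(locus)]
    b_sum = c_sum = 0.0
    for li in loci:
        b, c = _wc_within_components(dataset, population, li)
        b_sum += float(b.sum())
        c_sum += float(c.sum())
    denom = b_sum + c_sum
    if denom == 0.0:
        return UNDEFINED
    return 1.0 - c_sum / denom


# -- HWE exact tests -------------------------------------------------------------


def _table_logprob_terms(genos: np.ndarray) -> float:
    """Table-dependent part of the log conditional probability of one table.

    ``genos`` is an (n, 2) array of genotype pairs.  Returns
    ``h ln 2 - sum_ab ln(n_ab!)``, which orders tables identically to the full
    conditional probability ``n! prod(c_a)! 2^h / ((2n)! prod(n_ab)!)`` at
    fixed allele counts.
    """
    pairs = np.sort(genos, axis=1)
    h = int((pairs[:, 0] != pairs[:, 1]).sum())
    keys = pairs[:, 0].astype(np.int64) * 100000 + pairs[:, 1]
    _, counts = np.unique(keys, return_counts=True)
    return h * math.log(2.0) - float(gammaln(counts + 1).sum())


def hwe_exact(
    dataset: GenotypeDataset,
    population,
    locus,
    mc_reps: int = 100_000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> float:
    """Exact-test P for Hardy-Weinberg proportions in one population x locus cell.

    The conditional distribution of genotype tables given allele counts is
    explored by Monte-Carlo shuffling of gene copies into diploids; for
    loci with two alleles the table distribution is enumerated exactly.
    ``alternative='deficit'`` gives the one-tailed heterozygote-deficit P
    (probability of a table with no more heterozygotes than observed).
    Monomorphic cells return P = 1.
    """
    li = dataset.locus_index(locus)
    rows = dataset.individuals_of(population)
    g = dataset.calls[rows, li, :]
    g = g[g[:, 0] != MISSING]
    n = g.shape[0]
    if n == 0:
        return UNDEFINED
    copies = g.ravel()
    alleles, counts = np.unique(copies, return_counts=True)
    if len(alleles) < 2:
        return 1.0
    if len(alleles) == 2 and alternative == "two-sided":
        return _hwe_exact_two_alleles(int(counts[0]), n, _het_count(g))
    return _hwe_mc(g, copies, n, mc_reps, seed, alternative)


def _het_count(g: np.ndarray) -> int:
    return int((g[:, 0] != g[:, 1]).sum())


def _hwe_exact_two_alleles(c1: int, n: int, het_obs: int) -> float:
    """Full enumeration for two alleles: tables indexed by heterozygote count."""
    c2 = 2 * n - c1
    hets = np.arange(c1 % 2, min(c1, c2) + 1, 2)
    n11 = (c1 - hets) // 2
    n22 = (c2 - hets) // 2
    logp = (
        hets * math.log(2.0)
        - gammaln(n11 + 1)
        - gammaln(hets + 1)
        - gammaln(n22 + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.searchsorted(hets, het_obs)]
    return float(p[p <= obs + 1e-12].sum())


def _hwe_mc(g, copies, n, mc_reps, seed, alternative) -> float:
    """Vectorized Monte-Carlo shuffling of gene copies into diploids."""
    rng = np.random.default_rng(seed)
    alleles = np.unique(copies)
    k = len(alleles)
    coded = np.searchsorted(alleles, copies)
    g_coded = np.searchsorted(alleles, g)
    extreme = 0
    done = 0
    chunk = max(1, min(mc_reps, 4_000_000 // max(1, 2 * n)))
    if alternative == "deficit":
        obs_stat = _het_count(g)
        while done < mc_reps:
            r = min(chunk, mc_reps - done)
            idx = rng.random((r, 2 * n)).argsort(axis=1)
            perms = coded[idx].reshape(r, n, 2)
            h = (perms[:, :, 0] != perms[:, :, 1]).sum(axis=1)
            extreme += int((h <= obs_stat).sum())
            done += r
        return (extreme + 1) / (mc_reps + 1)
    obs = _table_logprob_terms(g_coded)
    kk = k * k
    chunk = max(1, min(chunk, 2_000_000 // kk))
    while done < mc_reps:
        r = min(chunk, mc_reps - done)
        idx = rng.random((r, 2 * n)).argsort(axis=1)
        perms = coded[idx].reshape(r, n, 2)
        lo = perms.min(axis=2)
        hi = perms.max(axis=2)
        h = (lo != hi).sum(axis=1)
        pair_id = lo.astype(np.int64) * k + hi
        flat = (np.arange(r, dtype=np.int64)[:, None] * kk + pair_id).ravel()
        tables = np.bincount(flat, minlength=r * kk).reshape(r, kk)
        stat = h * math.log(2.0) - gammaln(tables + 1.0).sum(axis=1)
        extreme += int((stat <= obs + 1e-9).sum())
        done += r
    return (extreme + 1) / (mc_reps + 1)


def global_hwe(pvalues) -> float:
    """Fisher's combined probability over loci (chi-square with 2L df)."""
    p = np.asarray([x for x in np.atleast_1d(pvalues) if np.isfinite(x)], dtype=float)
    if p.size == 0:
        return UNDEFINED
    if p.size == 1:
        return float(p[0])
    return float(combine_pvalues(np.clip(p, 1e-300, 1.0), method="fisher").pvalue)


def sequential_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down significance flags for a family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    finite = np.isfinite(p)
    flags = np.zeros(p.shape, dtype=bool)
    if finite.any():
        flags[finite] = multipletests(p[finite], alpha=alpha, method="holm")[0]
    return flags


# -- group comparison ------------------------------------------------------------

_GROUP_STATS = ("Nar", "Ho", "He", "FIS")


def _population_statistic(dataset: GenotypeDataset, population, statistic: str, g: int):
    if statistic == "Nar":
        vals = [
            allelic_richness(dataset, population, li, g)
            for li in range(dataset.n_loci)
        ]
    elif statistic == "Ho":
        vals = list(observed_het(dataset, population))
    elif statistic == "He":
        vals = [expected_het(dataset, population, li) for li in range(dataset.n_loci)]
    elif statistic == "FIS":
        return fis(dataset, population)
    else:
        raise ValueError(f"statistic must be one of {_GROUP_STATS}")
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else UNDEFINED


def group_permutation_test(
    dataset: GenotypeDataset,
    statistic: str,
    grouping: dict[str, list] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    g: int | None = None,
):
    """Permutation test for a difference in mean per-population statistics.

    Populations are shuffled between the two groups; the two-sided P is the
    fraction of permutations (the observed assignment included in both the
    numerator and the denominator) with ``|mean_1 - mean_2|`` at least the
    observed difference.  Returns ``(observed_means, P)``.
    """
    if grouping is None:
        grouping = dataset.status_groups()
    names = list(grouping)
    if len(names) != 2:
        raise ValueError("grouping must define exactly two groups")
    ga, gb = (grouping[nm] for nm in names)
    if not ga or not gb:
        raise ValueError("each group needs at least one population")
    if g is None and statistic == "Nar":
        g = min_gene_copies(dataset)
    vals = {}
    for pid in list(ga) + list(gb):
        vals[pid] = _population_statistic(dataset, pid, statistic, g)
    xa = np.asarray([vals[p] for p in ga])
    xb = np.asarray([vals[p] for p in gb])
    obs = abs(np.nanmean(xa) - np.nanmean(xb))
    pool = np.concatenate([xa, xb])
    na = len(xa)
    rng = np.random.default_rng(seed)
    hits = 1  # observed assignment counts
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        d = abs(np.nanmean(perm[:na]) - np.nanmean(perm[na:]))
        if d >= obs - 1e-12:
            hits += 1
    means = {names[0]: float(np.nanmean(xa)), names[1]: float(np.nanmean(xb))}
    return means, hits / (n_perm + 1)


# -- assembled table -------------------------------------------------------------


def diversity_table(
    dataset: GenotypeDataset,
    g: int | None = None,
    hwe_reps: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-population diversity summary (the left half of the headline table).

    Columns: n, Nav (mean alleles/locus), Nar (rarefied richness at ``g``
    gene copies), Npr (private alleles), Ho, He (unbiased), FIS, HWE global P.
    Multilocus means are unweighted over loci with data.
    """
    if g is None:
        g = min_gene_copies(dataset)
    priv = private_alleles(dataset, "population")
    rows = []
    rng = np.random.default_rng(seed)
    for k, pop in enumerate(dataset.populations):
        nav, nar, he = [], [], []
        plocus = []
        for li in range(dataset.n_loci):
            counts = dataset.allele_counts(k, li)
            if counts:
                nav.append(len(counts))
                nar.append(allelic_richness(dataset, k, li, min(g, sum(counts.values()))))
            h = expected_het(dataset, k, li)
            if np.isfinite(h):
                he.append(h)
            plocus.append(
                hwe_exact(dataset, k, li, mc_reps=hwe_reps, seed=int(rng.integers(2**31)))
            )
        ho = observed_het(dataset, k)
        rows.append(
            {
                "population": pop.id,
                "status": pop.status,
                "n": int((dataset.pop_index == k).sum()),
                "Nav": float(np.mean(nav)) if nav else UNDEFINED,
                "Nar": float(np.mean(nar)) if nar else UNDEFINED,
                "Npr": priv.get(pop.id, 0),
                "Ho": float(np.nanmean(ho)),
                "He": float(np.mean(he)) if he else UNDEFINED,
                "FIS": fis(dataset, k),
                "P_HWE_global": global_hwe(plocus),
            }
        )
    return pd.DataFrame(rows)
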