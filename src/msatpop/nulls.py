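"""Null-allele estimation and corrections.

A microsatellite null allele fails to amplify: visible/null heterozygotes are
scored as homozygotes and null/null genotypes as missing, inflating apparent
homozygosity.  The per-cell (population x locus) null frequency is estimated
by an expectation-maximization mixture over genotype classes assuming
Hardy-Weinberg proportions, with missing data treated as uninformative.
Downstream corrections: expected heterozygosity on the corrected visible
frequencies, and the "excluding null alleles" (ENA) variant of the
Weir-Cockerham FST.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .dataset import MISSING, GenotypeDataset
from .diversity import hwe_exact

UNDEFINED = float("nan")


@dataclass
class NullEstimate:
    population: str
    locus: str
    null_frequency: float
    flagged: bool
    visible_freqs: dict[int, float]  # corrected, sums to 1 - null_frequency
    log_likelihood: float
    n_iter: int
    converged: bool


def em_null_frequency(
    dataset: GenotypeDataset,
    population,
    locus,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> NullEstimate:
    """EM estimate of the null-allele frequency in one population x locus cell.

    Observed homozygotes are a mixture of true homozygotes (probability
    ``p_i^2``) and visible/null heterozygotes (``2 p_i r``); heterozygotes are
    fully observed.  The E-step splits each observed homozygote class between
    the two origins and adds the expected number of unobserved null/null
    individuals (``n r^2/(1-r^2)``), making this the EM for the
    visibility-truncated multinomial; the M-step re-normalizes allele-copy
    counts over the visible alleles plus the null class.  The observed-data
    (conditional) log-likelihood is non-decreasing across iterations
    (asserted in tests).  Missing genotypes carry no information about the
    null class beyond the truncation term: blanks are never counted as null
    homozygotes.
    """
    li = dataset.locus_index(locus)
    rows = dataset.individuals_of(population)
    g = dataset.calls[rows, li, :]
    g = g[g[:, 0] != MISSING]
    n = g.shape[0]
    pop_id = dataset.populations[dataset.population_index(population)].id
    loc_name = dataset.loci[li].name
    if n == 0:
        return NullEstimate(pop_id, loc_name, UNDEFINED, False, {}, UNDEFINED, 0, False)

    alleles = np.unique(g)
    k = len(alleles)
    code = {int(a): i for i, a in enumerate(alleles)}
    hom_mask = g[:, 0] == g[:, 1]
    hom_counts = np.zeros(k)
    for a, b in g[hom_mask]:
        hom_counts[code[int(a)]] += 1
    het_copy_counts = np.zeros(k)
    for a, b in g[~hom_mask]:
        het_copy_counts[code[int(a)]] += 1
        het_copy_counts[code[int(b)]] += 1
    het_pair_logs = []
    for a, b in g[~hom_mask]:
        het_pair_logs.append((code[int(a)], code[int(b)]))

    # initialize from observed copy counts, small null mass
    p = (2 * hom_counts + het_copy_counts).astype(float)
    p /= p.sum()
    r = 0.05
    p = p * (1.0 - r)

    def loglik(p, r):
        # conditional (visibility-truncated) log-likelihood
        ll = -n * np.log(max(1.0 - r**2, 1e-300))
        with np.errstate(divide="ignore"):
            hom_p = p**2 + 2 * p * r
            ll += float(np.where(hom_counts > 0, hom_counts * np.log(np.maximum(hom_p, 1e-300)), 0.0).sum())
        for i, j in het_pair_logs:
            ll += np.log(max(2 * p[i] * p[j], 1e-300))
        return ll

    last = loglik(p, r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: expected null copies hidden inside observed homozygotes,
        # plus the expected unobserved null/null individuals
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(hom_counts > 0, 2 * r / np.maximum(p + 2 * r, 1e-300), 0.0)
        n_hidden = n * r**2 / max(1.0 - r**2, 1e-300)
        null_copies = float((hom_counts * w).sum()) + 2.0 * n_hidden
        vis_copies = 2 * hom_counts - hom_counts * w + het_copy_counts
        total = 2.0 * (n + n_hidden)
        p_new = vis_copies / total
        r_new = null_copies / total
        ll = loglik(p_new, r_new)
        delta = abs(ll - last)
        p, r, last = p_new, r_new, ll
        if delta < tol:
            converged = True
            break

    freqs = {int(a): float(p[code[int(a)]]) for a in alleles}
    return NullEstimate(pop_id, loc_name, float(r), False, freqs, float(last), it, converged)


def flag_null_cells(
    dataset: GenotypeDataset,
    r_min: float = 0.05,
    alpha: float = 0.05,
    hwe_reps: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Nominate population x locus cells likely to carry null alleles.

    A cell is flagged when the EM null frequency is at least ``r_min`` AND the
    one-tailed heterozygote-deficit exact test is significant at ``alpha`` —
    a homozygote-excess screen in the spirit of the standard genotyping-error
    checkers, with the EM frequency as the downstream quantity of interest.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k, pop in enumerate(dataset.populations):
        for li, loc in enumerate(dataset.loci):
            est = em_null_frequency(dataset, k, li)
            if not np.isfinite(est.null_frequency):
                continue
            p_def = hwe_exact(
                dataset, k, li, mc_reps=hwe_reps,
                seed=int(rng.integers(2**31)), alternative="deficit",
            )
            flagged = bool(est.null_frequency >= r_min and p_def < alpha)
            rows.append(
                {
                    "population": pop.id,
                    "locus": loc.name,
                    "null_frequency": est.null_frequency,
                    "P_het_deficit": p_def,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


def he_null(dataset: GenotypeDataset, population, locus=None):
    """Unbiased expected heterozygosity on null-corrected visible frequencies.

    The EM's visible-allele frequencies are renormalized without the null
    class; with a null frequency of zero this equals the ordinary He.
    With ``locus=None`` returns the mean over loci with data.
    """
    loci = range(dataset.n_loci) if locus is None else [dataset.locus_index(locus)]
    vals = []
    for li in loci:
        est = em_null_frequency(dataset, population, li)
        if not est.visible_freqs:
            continue
        q = np.asarray(list(est.visible_freqs.values()))
        s = q.sum()
        if s <= 0:
            continue
        q = q / s
        n2 = 2 * dataset.n_typed(population, li)
        if n2 < 2:
            continue
        vals.append((n2 / (n2 - 1.0)) * (1.0 - float(np.sum(q**2))))
    if locus is not None:
        return vals[0] if vals else UNDEFINED
    return float(np.mean(vals)) if vals else UNDEFINED


def wilcoxon_paired(x, y) -> float:
    """Two-sided Wilcoxon signed-rank P for paired vectors.

    Exact null distribution for up to 20 non-zero pairs, normal approximation
    with continuity correction above; all-zero differences give P = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[np.isfinite(d)]
    nz = np.count_nonzero(d)
    if nz == 0:
        return 1.0
    method = "exact" if nz <= 20 else "approx"
    res = wilcoxon(
        d, alternative="two-sided", zero_method="wilcox", method=method,
        correction=(method == "approx"),
    )
    return float(res.pvalue)


# -- ENA-corrected FST -----------------------------------------------------------


def _ena_locus_components(dataset: GenotypeDataset, pop_ids, locus, estimates):
    """Weir-Cockerham (a, b, c) sums using EM-corrected visible frequencies.

    The EM's corrected visible-allele frequencies are used *unnormalized*
    (they sum to ``1 - r``): the null class is simply excluded from the sums
    over alleles rather than having its mass redistributed.  Renormalizing
    would fold the null allele's own between-population variance into every
    visible allele and inflate theta — the very bias the correction removes.
    The per-allele heterozygote proportions are augmented by the expected
    visible/null heterozygotes scored as homozygotes (``2 p_a r/(1-r^2)``).
    With all null frequencies zero this reproduces the uncorrected
    components exactly.
    """
    li = dataset.locus_index(locus)
    samples = []
    for p in pop_ids:
        rows = dataset.individuals_of(p)
        g = dataset.calls[rows, li, :]
        g = g[g[:, 0] != MISSING]
        if g.shape[0] >= 1:
            key = (dataset.populations[dataset.population_index(p)].id, dataset.loci[li].name)
            samples.append((g, estimates[key]))
    r = len(samples)
    if r < 2:
        return 0.0, 0.0, 0.0
    ns = np.asarray([g.shape[0] for g, _ in samples], dtype=float)
    nbar = ns.mean()
    if nbar <= 1.0:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted(
        set().union(*[set(est.visible_freqs) for _, est in samples])
    )
    a_s = b_s = c_s = 0.0
    for al in alleles:
        p_i = []
        h_i = []
        for g, est in samples:
            q = est.visible_freqs.get(al, 0.0)  # unnormalized: sums to 1 - r
            p_i.append(q)
            het = (g[:, 0] != g[:, 1]) & ((g == al).any(axis=1))
            r0 = est.null_frequency if np.isfinite(est.null_frequency) else 0.0
            hidden = 2.0 * q * r0 / max(1.0 - r0**2, 1e-300)
            h_i.append(min(het.sum() / g.shape[0] + hidden, 1.0))
        p_i = np.asarray(p_i)
        h_i = np.asarray(h_i)
        pbar = (ns * p_i).sum() / (r * nbar)
        s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_s += a
        b_s += b
        c_s += c
    return a_s, b_s, c_s


def fst_ena(
    dataset: GenotypeDataset,
    populations=None,
    pairwise: bool = False,
    n_boot: int = 10_000,
    seed: int | None = None,
):
    """ENA-corrected Weir-Cockerham theta ("excluding null alleles").

    EM-corrected visible frequencies, renormalized without the null class,
    feed the theta variance components.  Global scope returns
    ``(theta_ena, (ci_lo, ci_hi))`` with a percentile bootstrap over loci
    (no CI with fewer than two loci); ``pairwise=True`` returns the corrected
    pairwise matrix.
    """
    pops = (
        [p.id for p in dataset.populations] if populations is None else list(populations)
    )
    estimates = {}
    for pid in pops:
        for li, loc in enumerate(dataset.loci):
            est = em_null_frequency(dataset, pid, li)
            estimates[(est.population, est.locus)] = est

    if pairwise:
        ids = pops
        mat = pd.DataFrame(0.0, index=ids, columns=ids)
        for a, b in itertools.combinations(ids, 2):
            per = [
                _ena_locus_components(dataset, [a, b], li, estimates)
                for li in range(dataset.n_loci)
            ]
            num = sum(x[0] for x in per)
            den = sum(sum(x) for x in per)
            t = num / den if den != 0 else UNDEFINED
            mat.loc[a, b] = mat.loc[b, a] = t
        return mat

    per = [
        _ena_locus_components(dataset, pops, li, estimates)
        for li in range(dataset.n_loci)
    ]
    per_arr = np.asarray(per)
    den = per_arr.sum()
    theta = per_arr[:, 0].sum() / den if den != 0 else UNDEFINED
    if per_arr.shape[0] < 2:
        return theta, (UNDEFINED, UNDEFINED)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, per_arr.shape[0], size=(n_boot, per_arr.shape[0]))
    sums = per_arr[idx].sum(axis=1)
    denom = sums.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        thetas = np.where(denom != 0.0, sums[:, 0] / denom, np.nan)
    lo, hi = np.nanpercentile(thetas, [2.5, 97.5])
    return theta, (float(lo), float(hi))
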