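"""Genetic differentiation: F-statistics, chord-distance trees, AMOVA, IBD.

Weir & Cockerham's theta is the canonical FST estimator throughout; variance
components are summed over alleles and loci before the ratio is taken.
Distance trees use the Cavalli-Sforza & Edwards chord distance and a
Fitch-Margoliash weighted least-squares search (neighbour-joining start,
nearest-neighbour-interchange hill climb, non-negative branch lengths).
AMOVA follows the classical molecular-variance partition on allele-identity
mismatch distances over gene copies.  Isolation by distance is the Mantel
correlation of linearized FST against log great-circle distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .dataset import MISSING, GenotypeDataset

UNDEFINED = float("nan")


# -- Weir & Cockerham theta ------------------------------------------------------


def _wc_locus_components(dataset: GenotypeDataset, pop_ids, locus):
    """Per-allele (a, b, c) components for one locus over the given populations."""
    li = dataset.locus_index(locus)
    samples = []
    for p in pop_ids:
        rows = dataset.individuals_of(p)
        g = dataset.calls[rows, li, :]
        g = g[g[:, 0] != MISSING]
        if g.shape[0] >= 1:
            samples.append(g)
    r = len(samples)
    if r < 2:
        return np.zeros(0), np.zeros(0), np.zeros(0)
    ns = np.asarray([g.shape[0] for g in samples], dtype=float)
    nbar = ns.mean()
    if nbar <= 1.0:
        return np.zeros(0), np.zeros(0), np.zeros(0)
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in samples]))
    n_al = len(alleles)
    # per-population allele frequencies and per-allele heterozygote proportions
    P = np.empty((r, n_al))
    H = np.empty((r, n_al))
    for i, g in enumerate(samples):
        coded = np.searchsorted(alleles, g)
        P[i] = np.bincount(coded.ravel(), minlength=n_al) / (2.0 * g.shape[0])
        het = coded[coded[:, 0] != coded[:, 1]]
        # a heterozygote contributes once to each of its two (distinct) alleles
        H[i] = np.bincount(het.ravel(), minlength=n_al) / g.shape[0]
    pbar = ns @ P / (r * nbar)
    s2 = (ns[:, None] * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = ns @ H / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_theta(
    dataset: GenotypeDataset,
    populations=None,
    per_locus: bool = False,
):
    """Weir & Cockerham (1984) theta over the given populations (all by default).

    Components are summed over alleles and loci before the ratio; a dataset
    with no polymorphism returns NaN.  With ``per_locus=True`` also returns
    the per-locus (a, b, c) sums for bootstrap resampling.
    """
    pops = (
        [p.id for p in dataset.populations] if populations is None else list(populations)
    )
    if len(pops) < 2:
        raise ValueError("theta needs at least two populations")
    per = []
    for li in range(dataset.n_loci):
        a, b, c = _wc_locus_components(dataset, pops, li)
        per.append((float(a.sum()), float(b.sum()), float(c.sum())))
    a_sum = sum(x[0] for x in per)
    abc = sum(sum(x) for x in per)
    theta = a_sum / abc if abc != 0.0 else UNDEFINED
    if per_locus:
        return theta, per
    return theta


def theta_bootstrap_ci(
    dataset: GenotypeDataset,
    populations=None,
    n_boot: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
):
    """Percentile bootstrap CI for theta, resampling loci with replacement."""
    theta, per = wc_theta(dataset, populations, per_locus=True)
    per_arr = np.asarray(per)
    if per_arr.shape[0] < 2:
        return theta, (UNDEFINED, UNDEFINED)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, per_arr.shape[0], size=(n_boot, per_arr.shape[0]))
    sums = per_arr[idx].sum(axis=1)  # (n_boot, 3)
    denom = sums.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        thetas = np.where(denom != 0.0, sums[:, 0] / denom, np.nan)
    lo, hi = np.nanpercentile(thetas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return theta, (float(lo), float(hi))


def pairwise_fst(dataset: GenotypeDataset) -> pd.DataFrame:
    """Symmetric matrix of pairwise Weir-Cockerham theta (diagonal 0)."""
    ids = [p.id for p in dataset.populations]
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        t = wc_theta(dataset, [a, b])
        mat.loc[a, b] = mat.loc[b, a] = t
    return mat


def pairwise_fst_significance(
    dataset: GenotypeDataset, n_perm: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Permutation P-values for pairwise theta > 0.

    Multilocus genotypes are shuffled between the two populations; P is the
    fraction of permutations (observed included) with theta at least the
    observed value.
    """
    rng = np.random.default_rng(seed)
    ids = [p.id for p in dataset.populations]
    out = pd.DataFrame(1.0, index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        sub = dataset.subset_populations([a, b])
        obs = wc_theta(sub)
        n_a = int((sub.pop_index == 0).sum())
        hits = 1
        pi = sub.pop_index.copy()
        for _ in range(n_perm):
            sub.pop_index = rng.permutation(pi)
            t = wc_theta(sub)
            if np.isfinite(t) and t >= obs - 1e-12:
                hits += 1
        sub.pop_index = pi
        out.loc[a, b] = out.loc[b, a] = hits / (n_perm + 1)
    return out


# -- chord distance and trees ----------------------------------------------------


def chord_distance(dataset: GenotypeDataset, pop_a, pop_b) -> float:
    """Cavalli-Sforza & Edwards chord distance between two populations.

    ``D^2 = sum_l 4 (1 - sum_a sqrt(x_la y_la)) / sum_l (K_l - 1)`` with
    ``K_l`` the number of alleles observed at locus ``l`` in the pair;
    ``D = sqrt(D^2)``.  Loci untyped in either population are skipped.
    """
    num = 0.0
    den = 0.0
    shared = 0
    for li in range(dataset.n_loci):
        ca = dataset.allele_counts(pop_a, li)
        cb = dataset.allele_counts(pop_b, li)
        if not ca or not cb:
            continue
        shared += 1
        alleles = sorted(set(ca) | set(cb))
        x = np.asarray([ca.get(al, 0) for al in alleles], dtype=float)
        y = np.asarray([cb.get(al, 0) for al in alleles], dtype=float)
        x /= x.sum()
        y /= y.sum()
        num += 4.0 * (1.0 - float(np.sqrt(x * y).sum()))
        den += max(len(alleles) - 1, 1)
    if shared == 0:
        raise ValueError("populations share no typed loci")
    return math.sqrt(max(num, 0.0) / den)


def chord_distance_matrix(dataset: GenotypeDataset, loci=None) -> pd.DataFrame:
    """All pairwise chord distances (optionally on a resampled locus set)."""
    if loci is not None:
        sub = _resample_loci(dataset, loci)
    else:
        sub = dataset
    ids = [p.id for p in sub.populations]
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        d = chord_distance(sub, a, b)
        mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def _resample_loci(dataset: GenotypeDataset, loci) -> GenotypeDataset:
    loci = list(loci)
    calls = dataset.calls[:, loci, :]
    from .dataset import Locus

    new_loci = [
        Locus(f"{dataset.loci[li].name}.{j}", dataset.loci[li].motif_length)
        for j, li in enumerate(loci)
    ]
    return GenotypeDataset(new_loci, dataset.populations, calls, dataset.pop_index)


# -- Fitch-Margoliash least-squares tree ----------------------------------------


def _tree_edges(tree: TreeNode):
    """Non-root nodes in post-order (each represents the edge to its parent)."""
    return [n for n in tree.postorder() if not n.is_root()]


def _path_matrix(tree: TreeNode, taxa: list[str]):
    """Pairs x edges incidence matrix: which edges lie on each tip-to-tip path."""
    edges = _tree_edges(tree)
    edge_index = {id(n): j for j, n in enumerate(edges)}
    # tip -> set of edges on path to root
    to_root: dict[str, set[int]] = {}
    for tip in tree.tips():
        path = set()
        node = tip
        while not node.is_root():
            path.add(edge_index[id(node)])
            node = node.parent
        to_root[tip.name] = path
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    rows = np.zeros((len(pairs), len(edges)))
    for r, (i, j) in enumerate(pairs):
        sym = to_root[taxa[i]] ^ to_root[taxa[j]]
        rows[r, list(sym)] = 1.0
    return rows, pairs, edges


def _fit_branch_lengths(tree: TreeNode, dm: np.ndarray, taxa: list[str], power: float):
    """Weighted non-negative least squares branch lengths; returns objective.

    Minimizes ``sum (D_ij - d_ij)^2 / D_ij^power`` over non-negative branch
    lengths for the fixed topology.
    """
    A, pairs, edges = _path_matrix(tree, taxa)
    d = np.asarray([dm[i, j] for i, j in pairs])
    w = np.where(d > 0, d ** (-power / 2.0), 1.0)
    coef, _ = nnls(A * w[:, None], d * w)
    for n, ln in zip(edges, coef):
        n.length = float(ln)
    resid = A @ coef - d
    return float(np.sum(resid**2 * np.where(d > 0, d ** (-power), 1.0)))


def _nni_neighbourhoods(tree: TreeNode):
    """Yield trees one NNI move away (around each internal edge).

    For each internal non-root node ``n`` with parent ``p``, swapping one
    child of ``n`` with one sibling of ``n`` enumerates the alternative
    topologies across the edge (n, p).
    """
    for n in list(tree.non_tips(include_self=False)):
        p = n.parent
        if p is None:
            continue
        siblings = [s for s in p.children if s is not n]
        for child in list(n.children):
            for sib in siblings:
                t2 = tree.copy()
                # find corresponding nodes in the copy by traversal order
                n2, child2, sib2 = _find_nodes(tree, t2, [n, child, sib])
                p2 = n2.parent
                p2.remove(sib2)
                n2.remove(child2)
                n2.append(sib2)
                p2.append(child2)
                yield t2


def _find_nodes(src: TreeNode, dst: TreeNode, targets):
    order_src = list(src.postorder())
    order_dst = list(dst.postorder())
    idx = {id(n): i for i, n in enumerate(order_src)}
    return tuple(order_dst[idx[id(t)]] for t in targets)


def fitch_margoliash(
    dm: pd.DataFrame,
    power: float = 2.0,
    n_restarts: int = 0,
    seed: int | None = None,
) -> tuple[TreeNode, float]:
    """Weighted least-squares (Fitch-Margoliash) tree for a distance matrix.

    Starts from neighbour joining, hill-climbs with nearest-neighbour
    interchanges (first-improvement under a fixed taxon order), optionally
    restarts from randomly ordered NJ inputs.  Returns the unrooted tree (as a
    TreeNode with a trifurcating root where possible) and the final objective
    ``sum (D_ij - d_ij)^2 / D_ij^power``.

    A degenerate all-zero matrix yields a star tree with zero branch lengths.
    """
    taxa = list(dm.index)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    mat = dm.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    if np.allclose(mat, 0.0):
        star = TreeNode(name=None, children=[TreeNode(name=t, length=0.0) for t in taxa])
        return star, 0.0

    orders = [list(range(n))]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        orders.append(list(rng.permutation(n)))

    best_tree, best_obj = None, np.inf
    for order in orders:
        sub = mat[np.ix_(order, order)]
        names = [taxa[i] for i in order]
        skbio_dm = DistanceMatrix(sub, ids=names)
        tree = nj(skbio_dm)
        tree = _as_unrooted(tree)
        obj = _fit_branch_lengths(tree, mat, taxa, power)
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbourhoods(tree):
                o2 = _fit_branch_lengths(cand, mat, taxa, power)
                if o2 < obj - 1e-12:
                    tree, obj = cand, o2
                    improved = True
                    break
        if obj < best_obj - 1e-12:
            best_tree, best_obj = tree, obj
    _fit_branch_lengths(best_tree, mat, taxa, power)
    return best_tree, best_obj


def _as_unrooted(tree: TreeNode) -> TreeNode:
    """Ensure a trifurcating root (classic unrooted representation)."""
    tree = tree.copy()
    while len(tree.children) == 2:
        ch = [c for c in tree.children if not c.is_tip()]
        if not ch:
            break
        c = ch[0]
        tree.remove(c)
        for gc in list(c.children):
            c.remove(gc)
            tree.append(gc)
    return tree


def tree_bipartitions(tree: TreeNode, taxa: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, as frozensets of the smaller side."""
    all_taxa = frozenset(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            other = all_taxa - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_tree(
    dataset: GenotypeDataset,
    n_boot: int = 1000,
    seed: int | None = None,
    power: float = 2.0,
    replicate_search: str = "nni",
):
    """Fitch-Margoliash tree with bootstrap supports over loci.

    Loci are resampled with replacement; supports are the percentage of
    replicates whose tree contains each internal bipartition of the best
    tree (majority-rule style support annotation).  Returns
    ``(tree, supports)`` where supports maps bipartition -> percent, and the
    tree's internal nodes carry supports as names.

    ``replicate_search`` controls the per-replicate topology search:
    ``"nni"`` repeats the full least-squares search on every replicate;
    ``"nj"`` scores neighbour-joining topologies only, which is much faster
    for large taxon sets and changes supports little in practice.
    """
    if dataset.n_loci < 2:
        raise ValueError("bootstrap over loci needs at least 2 loci")
    rng = np.random.default_rng(seed)
    taxa = [p.id for p in dataset.populations]
    dm = chord_distance_matrix(dataset)
    tree, _ = fitch_margoliash(dm, power=power)
    target = tree_bipartitions(tree, taxa)
    counts = {bp: 0 for bp in target}
    for _ in range(n_boot):
        loci = rng.integers(0, dataset.n_loci, size=dataset.n_loci)
        dmb = chord_distance_matrix(dataset, loci=loci)
        if replicate_search == "nj":
            tb = _as_unrooted(nj(DistanceMatrix(dmb.to_numpy(), ids=list(dmb.index))))
        else:
            tb, _ = fitch_margoliash(dmb, power=power)
        bps = tree_bipartitions(tb, taxa)
        for bp in target:
            if bp in bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_boot for bp, c in counts.items()}
    all_taxa = frozenset(taxa)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            key = min(side, all_taxa - side, key=lambda s: (len(s), sorted(s)))
            node.name = f"{supports[key]:.0f}"
    return tree, supports


# -- AMOVA -----------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Molecular-variance partition with phi statistics and permutation P-values."""

    table: pd.DataFrame  # rows: strata; cols: df, variance, pct
    phi: dict[str, float]
    p_values: dict[str, float]


def _locus_ss(dataset: GenotypeDataset, li: int, partition: list[np.ndarray]):
    """Per-locus sums of squares over gene copies for a partition of individuals.

    With allele-identity mismatch distances the within-set sum of squared
    distances reduces to ``(n - sum c_a^2 / n)/2`` over the set's gene copies.
    Returns (ss_within_sets, ss_total, copies_per_set, copies_total).
    """

    def ss_of(copies: np.ndarray) -> float:
        if copies.size == 0:
            return 0.0
        _, counts = np.unique(copies, return_counts=True)
        n = copies.size
        return (n - (counts.astype(float) ** 2).sum() / n) / 2.0

    per_set = []
    copies_sets = []
    all_copies = []
    for rows in partition:
        g = dataset.calls[rows, li, :]
        c = g[g != MISSING].ravel()
        per_set.append(ss_of(c))
        copies_sets.append(c.size)
        all_copies.append(c)
    allc = np.concatenate(all_copies) if all_copies else np.zeros(0, dtype=np.int64)
    return per_set, ss_of(allc), copies_sets, allc.size


def _amova_components(dataset: GenotypeDataset, pop_of: np.ndarray, groups=None):
    """Variance components for one- or two-level AMOVA on gene copies."""
    n_pops = int(pop_of.max()) + 1
    pops_rows = [np.flatnonzero(pop_of == k) for k in range(n_pops)]
    ss_wp = 0.0
    ss_total = 0.0
    copies_pop = np.zeros(n_pops)
    for li in range(dataset.n_loci):
        per_set, tot, csets, _ = _locus_ss(dataset, li, pops_rows)
        ss_wp += sum(per_set)
        ss_total += tot
        copies_pop += np.asarray(csets)
    # SS are summed over loci; df and n' coefficients count gene copies once
    # (average typed copies per population across loci)
    copies_pop /= dataset.n_loci
    n_total = copies_pop.sum()

    if groups is None:
        df_ap = n_pops - 1
        df_wp = n_total - n_pops
        ss_ap = ss_total - ss_wp
        ms_ap = ss_ap / df_ap
        ms_wp = ss_wp / df_wp if df_wp > 0 else np.nan
        n_prime = (n_total - (copies_pop**2).sum() / n_total) / (n_pops - 1)
        sigma_w = ms_wp
        sigma_a = (ms_ap - ms_wp) / n_prime
        return {
            "df": {"among_pops": df_ap, "within_pops": df_wp},
            "ss": {"among_pops": ss_ap, "within_pops": ss_wp},
            "sigma": {"among_pops": sigma_a, "within_pops": sigma_w},
        }

    # two-level: groups is array mapping population -> group
    groups = np.asarray(groups)
    n_groups = int(groups.max()) + 1
    group_rows = [
        np.concatenate([pops_rows[k] for k in range(n_pops) if groups[k] == g])
        for g in range(n_groups)
    ]
    ss_wg = 0.0
    for li in range(dataset.n_loci):
        per_set, _, _, _ = _locus_ss(dataset, li, group_rows)
        ss_wg += sum(per_set)
    ss_ag = ss_total - ss_wg
    ss_ap_wg = ss_wg - ss_wp

    copies_group = np.asarray(
        [copies_pop[groups == g].sum() for g in range(n_groups)]
    )
    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n_total - n_pops
    ms_ag = ss_ag / df_ag
    ms_ap = ss_ap_wg / df_ap
    ms_wp = ss_wp / df_wp

    # coefficients (Excoffier et al. 1992 notation n, n', n'')
    sum_sq_pop_over_group = sum(
        (copies_pop[groups == g] ** 2).sum() / copies_group[g]
        for g in range(n_groups)
    )
    n_coef = (n_total - sum_sq_pop_over_group) / df_ap
    n_p = (sum_sq_pop_over_group - (copies_pop**2).sum() / n_total) / df_ag
    n_pp = (n_total - (copies_group**2).sum() / n_total) / df_ag

    sigma_w = ms_wp
    sigma_b = (ms_ap - sigma_w) / n_coef
    sigma_a = (ms_ag - sigma_w - n_p * sigma_b) / n_pp
    return {
        "df": {"among_groups": df_ag, "among_pops_within_groups": df_ap, "within_pops": df_wp},
        "ss": {"among_groups": ss_ag, "among_pops_within_groups": ss_ap_wg, "within_pops": ss_wp},
        "sigma": {
            "among_groups": sigma_a,
            "among_pops_within_groups": sigma_b,
            "within_pops": sigma_w,
        },
    }


def amova(
    dataset: GenotypeDataset,
    groups: dict[str, list] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA on allele-identity mismatch distances over gene copies.

    One-level (among/within populations, phi_ST) by default; passing
    ``groups`` (group name -> population ids) adds the among-group stratum
    (phi_CT, phi_SC).  Permutation schemes: individuals among populations for
    phi_ST; individuals among populations within groups for phi_SC; whole
    populations among groups for phi_CT.
    """
    rng = np.random.default_rng(seed)
    pop_of = dataset.pop_index

    if groups is None:
        comp = _amova_components(dataset, pop_of)
        sa, sw = comp["sigma"]["among_pops"], comp["sigma"]["within_pops"]
        total = sa + sw
        phi_st = sa / total if total != 0 else UNDEFINED
        hits = 1
        for _ in range(n_perm):
            perm = rng.permutation(pop_of)
            c = _amova_components(dataset, perm)
            s2 = c["sigma"]["among_pops"] + c["sigma"]["within_pops"]
            p = c["sigma"]["among_pops"] / s2 if s2 != 0 else -np.inf
            if p >= phi_st - 1e-12:
                hits += 1
        table = pd.DataFrame(
            {
                "df": [comp["df"]["among_pops"], comp["df"]["within_pops"]],
                "variance": [sa, sw],
                "pct": [100 * sa / total, 100 * sw / total],
            },
            index=["among_populations", "within_populations"],
        )
        return AmovaResult(table, {"phi_ST": phi_st}, {"phi_ST": hits / (n_perm + 1)})

    group_names = list(groups)
    gmap = np.zeros(dataset.n_populations, dtype=np.int64)
    for g, name in enumerate(group_names):
        for pid in groups[name]:
            gmap[dataset.population_index(pid)] = g
    comp = _amova_components(dataset, pop_of, gmap)
    sa = comp["sigma"]["among_groups"]
    sb = comp["sigma"]["among_pops_within_groups"]
    sw = comp["sigma"]["within_pops"]
    total = sa + sb + sw
    phi = {
        "phi_CT": sa / total,
        "phi_SC": sb / (sb + sw),
        "phi_ST": (sa + sb) / total,
    }

    def stats_of(pop_perm, group_perm):
        c = _amova_components(dataset, pop_perm, group_perm)
        s_a, s_b, s_w = (
            c["sigma"]["among_groups"],
            c["sigma"]["among_pops_within_groups"],
            c["sigma"]["within_pops"],
        )
        t = s_a + s_b + s_w
        return s_a / t, s_b / (s_b + s_w), (s_a + s_b) / t

    hits = {"phi_CT": 1, "phi_SC": 1, "phi_ST": 1}
    group_of_ind = gmap[pop_of]
    for _ in range(n_perm):
        # phi_ST: individuals among populations (whole dataset)
        perm = rng.permutation(pop_of)
        _, _, st = stats_of(perm, gmap)
        if st >= phi["phi_ST"] - 1e-12:
            hits["phi_ST"] += 1
        # phi_SC: individuals among populations within their group
        perm2 = pop_of.copy()
        for g in range(len(group_names)):
            rows = np.flatnonzero(group_of_ind == g)
            perm2[rows] = rng.permutation(pop_of[rows])
        _, sc, _ = stats_of(perm2, gmap)
        if sc >= phi["phi_SC"] - 1e-12:
            hits["phi_SC"] += 1
        # phi_CT: whole populations among groups
        gperm = rng.permutation(gmap)
        ct, _, _ = stats_of(pop_of, gperm)
        if ct >= phi["phi_CT"] - 1e-12:
            hits["phi_CT"] += 1

    table = pd.DataFrame(
        {
            "df": [
                comp["df"]["among_groups"],
                comp["df"]["among_pops_within_groups"],
                comp["df"]["within_pops"],
            ],
            "variance": [sa, sb, sw],
            "pct": [100 * sa / total, 100 * sb / total, 100 * sw / total],
        },
        index=[
            "among_groups",
            "among_populations_within_groups",
            "within_populations",
        ],
    )
    pvals = {k: hits[k] / (n_perm + 1) for k in hits}
    return AmovaResult(table, phi, pvals)


# -- isolation by distance -------------------------------------------------------

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance on a spherical Earth (km)."""
    la1, lo1, la2, lo2 = map(math.radians, (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = math.sin(dlat / 2) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class IbdResult:
    r: float
    r_squared: float
    p_value: float
    genetic: pd.DataFrame
    geographic: pd.DataFrame


def mantel_ibd(
    fst: pd.DataFrame,
    coordinates: dict[str, tuple[float, float]],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> IbdResult:
    """Mantel test of linearized FST against log geographic distance.

    Genetic matrix: ``FST/(1-FST)``; geographic: ``ln`` of great-circle km.
    ``r`` is the Pearson correlation of off-diagonal entries; P is the
    fraction of row/column permutations with ``r`` at least the observed
    (one-sided, observed included).  An FST of 1 makes the transform
    infinite and raises, naming the pair.
    """
    ids = list(fst.index)
    f = fst.to_numpy(dtype=float)
    ones = np.argwhere((f >= 1.0) & ~np.eye(len(ids), dtype=bool))
    if ones.size:
        i, j = ones[0]
        raise ValueError(f"FST = 1 between {ids[i]} and {ids[j]}: transform infinite")
    gen = f / (1.0 - f)
    geo = np.zeros_like(gen)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                km = haversine_km(*coordinates[a], *coordinates[b])
                if km <= 0:
                    raise ValueError(f"zero geographic distance between {a} and {b}")
                geo[i, j] = geo[j, i] = math.log(km)

    iu = np.triu_indices(len(ids), 1)
    x = gen[iu]
    rng = np.random.default_rng(seed)

    def corr(perm):
        y = geo[np.ix_(perm, perm)][iu]
        xm, ym = x - x.mean(), y - y.mean()
        return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))

    ident = np.arange(len(ids))
    r_obs = corr(ident)
    hits = 1
    for _ in range(n_perm):
        if corr(rng.permutation(ident)) >= r_obs - 1e-12:
            hits += 1
    return IbdResult(
        r=r_obs,
        r_squared=r_obs**2,
        p_value=hits / (n_perm + 1),
        genetic=pd.DataFrame(gen, index=ids, columns=ids),
        geographic=pd.DataFrame(geo, index=ids, columns=ids),
    )
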