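"""Approximate Bayesian computation for three-population demographic history.

Five candidate scenarios relate three sampled populations (serial splits in
either direction, two independent derivations, admixture, and simultaneous
trifurcation) with uniform priors on effective sizes and event times and a
generalized stepwise mutation (GSM) model with rare single-nucleotide indels
(SNI).  A reference table of coalescent simulations is summarized by 24
statistics; scenario choice retains the simulations closest to the observed
vector and fits a multinomial logistic regression of the scenario indicator
on the summary deviations, and parameter posteriors use local-linear
(Epanechnikov-weighted) regression adjustment on logit-transformed
parameters.  Model checking simulates from the posterior and reports
tail-area probabilities per statistic plus a PCA of prior/posterior
predictive clouds.
"""

from __future__ import annotations

import itertools
import numpy as np
import pandas as pd

from .coalescent import Event, GsmModel, simulate_locus
from .dataset import MISSING, GenotypeDataset, Locus, PopulationInfo

# -- priors ----------------------------------------------------------------------

PRIOR_N = (10.0, 10_000.0)
PRIOR_T = (1.0, 100_000.0)
PRIOR_R = (0.001, 0.999)
PRIOR_MU = (1e-5, 1e-3)
PRIOR_P = (0.10, 0.30)
PRIOR_SNI_LOG10 = (-8.0, -5.0)

SCENARIO_IDS = (1, 2, 3, 4, 5)

PARAM_BOUNDS = {
    "N1": PRIOR_N,
    "N2": PRIOR_N,
    "N3": PRIOR_N,
    "NA": PRIOR_N,
    "t1": PRIOR_T,
    "t2": PRIOR_T,
    "r": PRIOR_R,
    "mu_mean": PRIOR_MU,
    "p_mean": PRIOR_P,
    "sni_mean": (10.0 ** PRIOR_SNI_LOG10[0], 10.0 ** PRIOR_SNI_LOG10[1]),
}


def sample_prior(scenario: int, rng: np.random.Generator) -> dict:
    """One draw from the joint prior of a scenario, constraints enforced.

    ``NA > max(N1, N2, N3)`` and ``t2 > t1`` are imposed by re-sampling;
    scenario 5 has a single divergence time (``t1 = t2 = t``); scenario 4
    has the admixture rate ``r``.
    """
    if scenario not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario {scenario}")
    while True:
        n1, n2, n3 = rng.uniform(*PRIOR_N, size=3)
        na = rng.uniform(*PRIOR_N)
        if na > max(n1, n2, n3):
            break
    if scenario == 5:
        t1 = t2 = rng.uniform(*PRIOR_T)
    else:
        while True:
            t1, t2 = rng.uniform(*PRIOR_T, size=2)
            if t2 > t1:
                break
    r = rng.uniform(*PRIOR_R) if scenario == 4 else np.nan
    mu_mean = rng.uniform(*PRIOR_MU)
    p_mean = rng.uniform(*PRIOR_P)
    sni_mean = 10.0 ** rng.uniform(*PRIOR_SNI_LOG10)
    return {
        "scenario": scenario,
        "N1": n1,
        "N2": n2,
        "N3": n3,
        "NA": na,
        "t1": t1,
        "t2": t2,
        "r": r,
        "mu_mean": mu_mean,
        "p_mean": p_mean,
        "sni_mean": sni_mean,
    }


def scenario_events(params: dict) -> list[Event]:
    """Backward-in-time event list for a parameter draw.

    Populations are indexed 0, 1, 2; after the final merge the receiving
    population takes the ancestral size ``NA``.  Intermediate receiving
    populations keep their own size until they merge (sizes change only at
    the listed events).
    """
    s = params["scenario"]
    t1, t2, na = params["t1"], params["t2"], params["NA"]
    if s == 1:  # Pop1 <- Pop2 <- Pop3
        return [
            Event(t=t1, kind="merge", a=0, b=1),
            Event(t=t2, kind="merge", a=1, b=2),
            Event(t=t2, kind="resize", a=2, size=na),
        ]
    if s == 2:  # Pop3 <- Pop2 <- Pop1
        return [
            Event(t=t1, kind="merge", a=2, b=1),
            Event(t=t2, kind="merge", a=1, b=0),
            Event(t=t2, kind="resize", a=0, size=na),
        ]
    if s == 3:  # Pop1 and Pop3 independently derived from Pop2
        return [
            Event(t=t1, kind="merge", a=0, b=1),
            Event(t=t2, kind="merge", a=2, b=1),
            Event(t=t2, kind="resize", a=1, size=na),
        ]
    if s == 4:  # Pop2 founded by admixture of Pop1 and Pop3
        return [
            Event(t=t1, kind="admix", a=1, b=0, c=2, rate=params["r"]),
            Event(t=t2, kind="merge", a=2, b=0),
            Event(t=t2, kind="resize", a=0, size=na),
        ]
    # scenario 5: simultaneous trifurcation at t1 (= t2)
    return [
        Event(t=t1, kind="merge", a=1, b=0),
        Event(t=t1, kind="merge", a=2, b=0),
        Event(t=t1, kind="resize", a=0, size=na),
    ]


def draw_locus_rates(params: dict, n_loci: int, rng: np.random.Generator):
    """Per-locus mutation parameters around the sampled means.

    Locus mutation rates are Gamma(shape 2) around the mean; the geometric
    parameter varies uniformly within +-0.05 of its mean (clamped); SNI rates
    are Gamma(shape 2) around their mean.
    """
    mu = rng.gamma(2.0, params["mu_mean"] / 2.0, size=n_loci)
    p = np.clip(
        rng.uniform(params["p_mean"] - 0.05, params["p_mean"] + 0.05, size=n_loci),
        0.01,
        0.95,
    )
    sni = rng.gamma(2.0, params["sni_mean"] / 2.0, size=n_loci)
    return mu, p, sni


def simulate_dataset(
    params: dict,
    sample_sizes=(25, 25, 25),
    n_loci: int = 8,
    seed: int | np.random.Generator = 0,
    motif_length: int = 2,
) -> GenotypeDataset:
    """Coalescent simulation of one three-population microsatellite dataset."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = scenario_events(params)
    pop_sizes = [params["N1"], params["N2"], params["N3"]]
    mu, p, sni = draw_locus_rates(params, n_loci, rng)
    n_ind = [int(s) for s in sample_sizes]
    copies = [2 * s for s in n_ind]
    total = sum(n_ind)
    calls = np.empty((total, n_loci, 2), dtype=np.int64)
    for li in range(n_loci):
        vals = simulate_locus(
            copies,
            pop_sizes,
            events,
            mu[li],
            rng,
            step_model=GsmModel(float(p[li])),
            sni_rate=float(sni[li]),
            motif_length=motif_length,
            root_size=200,
        )
        calls[:, li, :] = vals.reshape(total, 2)
    loci = [Locus(f"L{li + 1:02d}", motif_length) for li in range(n_loci)]
    pops = [PopulationInfo(id=f"Pop{j + 1}", n=n_ind[j]) for j in range(3)]
    pop_index = np.repeat(np.arange(3), n_ind)
    return GenotypeDataset(loci, pops, calls, pop_index)


# -- summary statistics ----------------------------------------------------------


def summary_stat_names(n_pops: int = 3) -> list[str]:
    names = [f"Na_{i + 1}" for i in range(n_pops)]
    names += [f"He_{i + 1}" for i in range(n_pops)]
    pairs = list(itertools.combinations(range(n_pops), 2))
    names += [f"Na_{a + 1}{b + 1}" for a, b in pairs]
    names += [f"He_{a + 1}{b + 1}" for a, b in pairs]
    names += [f"FST_{a + 1}{b + 1}" for a, b in pairs]
    names += [f"DAS_{a + 1}{b + 1}" for a, b in pairs]
    names += [f"L_{a + 1}{b + 1}" for a, b in itertools.permutations(range(n_pops), 2)]
    return names


def _unbiased_he(counts: np.ndarray) -> float:
    n = counts.sum()
    if n < 2:
        return 0.0
    p = counts / n
    return (n / (n - 1.0)) * (1.0 - float((p**2).sum()))


def _pop_locus_counts(calls: np.ndarray):
    copies = calls[calls != MISSING].ravel()
    if copies.size == 0:
        return np.zeros(0)
    _, c = np.unique(copies, return_counts=True)
    return c.astype(float)


def _shared_allele_distance(ga: np.ndarray, gb: np.ndarray) -> float:
    """1 - mean proportion of alleles shared between cross-population pairs."""
    a1, a2 = ga[:, None, :, 0], ga[:, None, :, 1]
    b1, b2 = gb[None, :, :, 0], gb[None, :, :, 1]
    hom_a = a1 == a2
    m_hom = (b1 == a1).astype(np.int64) + (b2 == a1).astype(np.int64)
    s1 = ((a1 == b1) | (a1 == b2)).astype(np.int64)
    s2 = ((a2 == b1) | (a2 == b2)).astype(np.int64)
    m = np.where(hom_a, m_hom, s1 + s2)
    valid = (ga[:, None, :, 0] != MISSING) & (gb[None, :, :, 0] != MISSING)
    ps = np.where(valid, m / 2.0, np.nan)
    with np.errstate(invalid="ignore"):
        per_pair = np.nanmean(ps, axis=2)
    return float(1.0 - np.nanmean(per_pair))


def _assignment_loglik(ga: np.ndarray, ref_counts) -> float:
    """Mean log-likelihood of pop-A genotypes under pop-B allele frequencies.

    Frequencies are smoothed with a uniform Dirichlet prior (1/k pseudo-count
    per allele over the k alleles seen in either population) so unseen
    alleles keep finite likelihood.
    """
    total = 0.0
    n_ind = ga.shape[0]
    for li, (alleles, freqs) in enumerate(ref_counts):
        g = ga[:, li, :]
        typed = g[:, 0] != MISSING
        if not typed.any():
            continue
        pos = np.searchsorted(alleles, g[typed])
        fa = freqs[np.clip(pos, 0, len(alleles) - 1)]
        pa, pb = fa[:, 0], fa[:, 1]
        het = g[typed, 0] != g[typed, 1]
        total += float(np.log(np.where(het, 2.0 * pa * pb, pa * pb)).sum())
    return total / n_ind


def summary_stats(dataset: GenotypeDataset) -> np.ndarray:
    """The 24-statistic summary vector for a three-population dataset.

    Per population: mean allele number, mean unbiased expected
    heterozygosity.  Per pair: the same two on the pooled pair, pairwise
    Weir-Cockerham theta, shared-allele distance; plus directional mean
    individual assignment log-likelihoods (reference frequencies smoothed
    with a uniform Dirichlet prior over the alleles of the pair).

    Alleles are coded once per locus; allele counts, heterozygote counts and
    the theta variance components are all derived from that single pass.
    """
    n_pops = dataset.n_populations
    if n_pops < 2:
        raise ValueError("summary statistics need at least two populations")
    L = dataset.n_loci
    rows = [dataset.individuals_of(k) for k in range(n_pops)]
    if any(len(r) == 0 for r in rows):
        raise ValueError("empty population")
    pairs = list(itertools.combinations(range(n_pops), 2))
    perms = list(itertools.permutations(range(n_pops), 2))

    # per-locus, per-pop: allele counts C[k] (K_l,), het-involvement counts
    counts_per_locus = []  # list of (K_l, counts (n_pops,K), hets (n_pops,K), n_ind (n_pops,))
    for li in range(L):
        col = dataset.calls[:, li, :]
        alleles = np.unique(col[col != MISSING])
        K = len(alleles)
        C = np.zeros((n_pops, K))
        Hc = np.zeros((n_pops, K))
        n_typed = np.zeros(n_pops)
        for k in range(n_pops):
            g = col[rows[k]]
            g = g[g[:, 0] != MISSING]
            n_typed[k] = g.shape[0]
            if g.shape[0] == 0:
                continue
            coded = np.searchsorted(alleles, g)
            C[k] = np.bincount(coded.ravel(), minlength=K)
            het = coded[coded[:, 0] != coded[:, 1]]
            Hc[k] = np.bincount(het.ravel(), minlength=K)
        counts_per_locus.append((alleles, C, Hc, n_typed))

    def he_from_counts(c):
        n = c.sum()
        if n < 2:
            return 0.0
        p = c / n
        return (n / (n - 1.0)) * (1.0 - float((p**2).sum()))

    out = []
    for k in range(n_pops):  # Na per pop
        out.append(float(np.mean([(C[k] > 0).sum() for _, C, _, _ in counts_per_locus])))
    for k in range(n_pops):  # He per pop
        out.append(float(np.mean([he_from_counts(C[k]) for _, C, _, _ in counts_per_locus])))
    for a, b in pairs:  # pooled Na
        out.append(
            float(np.mean([((C[a] + C[b]) > 0).sum() for _, C, _, _ in counts_per_locus]))
        )
    for a, b in pairs:  # pooled He
        out.append(
            float(np.mean([he_from_counts(C[a] + C[b]) for _, C, _, _ in counts_per_locus]))
        )
    # pairwise Weir-Cockerham theta from the shared counts
    for a, b in pairs:
        num = den = 0.0
        for _, C, Hc, n_typed in counts_per_locus:
            ns = np.asarray([n_typed[a], n_typed[b]])
            if (ns < 1).any() or ns.sum() < 3:
                continue
            P = np.vstack([C[a], C[b]]) / (2.0 * ns[:, None])
            H = np.vstack([Hc[a], Hc[b]]) / ns[:, None]
            aa, bb, cc = _theta_components(P, H, ns)
            num += aa
            den += aa + bb + cc
        out.append(num / den if den != 0 else 0.0)
    for a, b in pairs:  # DAS
        out.append(
            _shared_allele_distance(dataset.calls[rows[a]], dataset.calls[rows[b]])
        )
    for a, b in perms:  # assignment log-likelihoods
        tables = []
        for alleles, C, _, n_typed in counts_per_locus:
            present = (C[a] + C[b]) > 0
            k_pair = max(int(present.sum()), 1)
            nb = C[b].sum()
            freqs = (C[b] + 1.0 / k_pair) / (nb + 1.0)
            tables.append((alleles, freqs))
        out.append(_assignment_loglik(dataset.calls[rows[a]], tables))
    return np.asarray(out)


def _theta_components(P, H, ns):
    """Weir-Cockerham (a, b, c) sums for r=2 samples from frequency/het arrays."""
    r = 2
    nbar = ns.mean()
    if nbar <= 1.0:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
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
    return float(a.sum()), float(b.sum()), float(c.sum())


# -- reference table -------------------------------------------------------------


def build_reference_table(
    n_per_scenario: int,
    sample_sizes=(25, 25, 25),
    n_loci: int = 8,
    seed: int = 0,
    scenarios=SCENARIO_IDS,
) -> pd.DataFrame:
    """Simulate the ABC reference table: one row per (scenario, prior draw).

    Row count is exactly ``len(scenarios) * n_per_scenario``.  Columns:
    scenario id, the parameter draw, and the 24 summary statistics.
    """
    rng = np.random.default_rng(seed)
    names = summary_stat_names()
    records = []
    for s in scenarios:
        for _ in range(n_per_scenario):
            params = sample_prior(s, rng)
            ds = simulate_dataset(params, sample_sizes, n_loci, rng)
            stats = summary_stats(ds)
            rec = dict(params)
            rec.update({nm: v for nm, v in zip(names, stats)})
            records.append(rec)
    return pd.DataFrame(records)


def _standardize(table_stats: np.ndarray, obs: np.ndarray):
    sd = table_stats.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (table_stats - obs) / sd, sd


def _closest(table: pd.DataFrame, observed: np.ndarray, n_closest: int):
    names = summary_stat_names()
    stats = table[names].to_numpy(dtype=float)
    dev, sd = _standardize(stats, observed)
    d = np.sqrt((dev**2).sum(axis=1))
    idx = np.argsort(d, kind="stable")[:n_closest]
    return idx, dev, d


# -- model choice ----------------------------------------------------------------


def model_choice(
    table: pd.DataFrame,
    observed: np.ndarray,
    n_closest: int = 10_000,
) -> pd.DataFrame:
    """Scenario posterior probabilities with 95% CI by logistic regression.

    Summary statistics are standardized by their reference-table standard
    deviations; the ``n_closest`` simulations by Euclidean distance are
    retained; a multinomial logistic regression of the scenario indicator on
    the standardized deviations is evaluated at the observed point (deviation
    zero), with a delta-method CI from the asymptotic covariance.  Falls back
    to rejection proportions (with binomial CI) if the regression is
    degenerate.  Scenario probabilities sum to one.
    """
    if n_closest > len(table):
        raise ValueError("n_closest exceeds the reference table size")
    idx, dev, d = _closest(table, observed, n_closest)
    scen = table["scenario"].to_numpy()[idx]
    X = dev[idx]
    present = np.unique(scen)
    all_scen = np.unique(table["scenario"].to_numpy())

    pp, ci = None, None
    if len(present) > 1:
        try:
            pp, ci = _logistic_pp(X, scen, present)
        except Exception:
            pp = None
    if pp is None:
        # rejection fallback
        pp = {int(s): float((scen == s).mean()) for s in present}
        ci = {}
        n = len(scen)
        for s, p in pp.items():
            se = np.sqrt(max(p * (1 - p) / n, 0.0))
            ci[s] = (max(p - 1.96 * se, 0.0), min(p + 1.96 * se, 1.0))

    rows = []
    for s in all_scen:
        p = pp.get(int(s), 0.0)
        lo, hi = ci.get(int(s), (0.0, 0.0))
        rows.append(
            {"scenario": int(s), "posterior_probability": p, "ci_low": lo, "ci_high": hi}
        )
    out = pd.DataFrame(rows)
    out["posterior_probability"] = out["posterior_probability"].fillna(0.0)
    total = out["posterior_probability"].sum()
    if total > 0:
        out["posterior_probability"] /= total
    else:
        out["posterior_probability"] = 1.0 / len(out)
    return out


def _logistic_pp(X, scen, present, n_components: int = 12):
    """Multinomial logistic PP at the observed point with delta-method CI.

    The standardized deviations are decorrelated by a PCA fitted on the
    retained set (the 24 raw statistics are strongly collinear and make the
    unregularized logistic ill-conditioned); the regression runs on the
    leading components and is evaluated at the observed point's projection.
    """
    import statsmodels.api as sm
    from sklearn.decomposition import PCA

    code = {int(s): j for j, s in enumerate(present)}
    y = np.asarray([code[int(s)] for s in scen])
    n_comp = int(min(n_components, X.shape[1], X.shape[0] - 1))
    pca = PCA(n_components=n_comp, svd_solver="full")
    Z = pca.fit_transform(X)
    scale = Z.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    Z = Z / scale
    z_obs = (pca.transform(np.zeros((1, X.shape[1])))[0]) / scale

    Xc = sm.add_constant(Z, has_constant="add")
    fit = sm.MNLogit(y, Xc).fit(disp=0, maxiter=200, method="newton")
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError("MNLogit did not converge")
    kp = Xc.shape[1]
    S = len(present)
    params = np.asarray(fit.params).reshape(kp, S - 1)
    x_t = np.concatenate([[1.0], z_obs])
    logits = np.concatenate([[0.0], x_t @ params])
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    if not np.isfinite(p).all():
        raise RuntimeError("degenerate logistic fit")

    # delta method: gradient of softmax wrt the flattened parameter vector
    cov = np.asarray(fit.cov_params())  # ((S-1)*kp, (S-1)*kp), per-equation blocks
    J = np.zeros((S, (S - 1) * kp))
    for j in range(S):
        for m in range(S - 1):
            grad_logit = p[j] * ((1.0 if j == m + 1 else 0.0) - p[m + 1])
            J[j, m * kp : (m + 1) * kp] = grad_logit * x_t
    var = np.clip(np.diag(J @ cov @ J.T), 0.0, None)
    se = np.sqrt(var)
    pp = {int(s): float(p[j]) for j, s in enumerate(present)}
    ci = {
        int(s): (float(max(p[j] - 1.96 * se[j], 0.0)), float(min(p[j] + 1.96 * se[j], 1.0)))
        for j, s in enumerate(present)
    }
    return pp, ci


# -- parameter estimation --------------------------------------------------------


def _to_unbounded(y: np.ndarray, lo: float, hi: float) -> np.ndarray:
    z = np.clip((y - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return np.log(z / (1 - z))


def _from_unbounded(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) / (1.0 + np.exp(-z))


def _weighted_quantile(values, weights, qs):
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights)[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return np.interp(qs, cw, v)


def estimate_params(
    table: pd.DataFrame,
    observed: np.ndarray,
    scenario: int,
    n_closest: int = 1_000,
    parameters=("N1", "N2", "N3", "NA", "t1", "t2"),
) -> pd.DataFrame:
    """Posterior quantiles for the selected scenario's parameters.

    Local-linear regression adjustment: retained draws are weighted by an
    Epanechnikov kernel on their distance; each parameter is logit-
    transformed to the real line (its prior is bounded), regressed on the
    standardized summary deviations, and the regression-detrended draws are
    back-transformed.  Reported: median, 90% and 95% intervals.  A singular
    regression falls back to the unadjusted rejection posterior.
    """
    sub = table[table["scenario"] == scenario].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"scenario {scenario} absent from the table")
    n_closest = min(n_closest, len(sub))
    idx, dev, d = _closest(sub, observed, n_closest)
    dmax = d[idx].max()
    u = d[idx] / dmax if dmax > 0 else np.zeros(len(idx))
    w = 0.75 * (1.0 - u**2)
    w = np.maximum(w, 1e-12)
    X = dev[idx]
    rows = []
    for name in parameters:
        if name == "r" and not np.isfinite(sub[name].to_numpy()).any():
            continue
        lo, hi = PARAM_BOUNDS[name]
        y = _to_unbounded(sub[name].to_numpy()[idx], lo, hi)
        Xd = np.column_stack([np.ones(len(idx)), X])
        Ws = np.sqrt(w)
        try:
            beta, *_ = np.linalg.lstsq(Xd * Ws[:, None], y * Ws, rcond=None)
            adjusted = y - X @ beta[1:]
        except np.linalg.LinAlgError:
            adjusted = y
        vals = _from_unbounded(adjusted, lo, hi)
        q = _weighted_quantile(vals, w, [0.025, 0.05, 0.5, 0.95, 0.975])
        rows.append(
            {
                "parameter": name,
                "median": q[2],
                "q05": q[1],
                "q95": q[3],
                "q025": q[0],
                "q975": q[4],
            }
        )
    return pd.DataFrame(rows)


def posterior_sample(
    table: pd.DataFrame,
    observed: np.ndarray,
    scenario: int,
    n_closest: int = 1_000,
) -> pd.DataFrame:
    """Retained parameter draws (rejection posterior) with kernel weights."""
    sub = table[table["scenario"] == scenario].reset_index(drop=True)
    n_closest = min(n_closest, len(sub))
    idx, dev, d = _closest(sub, observed, n_closest)
    out = sub.iloc[idx].copy()
    dmax = d[idx].max()
    u = d[idx] / dmax if dmax > 0 else np.zeros(len(idx))
    out["abc_weight"] = np.maximum(0.75 * (1.0 - u**2), 1e-12)
    return out


# -- model checking --------------------------------------------------------------


def model_check(
    posterior: pd.DataFrame,
    observed: np.ndarray,
    n_ppc: int = 500,
    sample_sizes=(25, 25, 25),
    n_loci: int = 8,
    seed: int = 0,
    prior_stats: np.ndarray | None = None,
) -> dict:
    """Posterior-predictive check of the selected scenario.

    Parameter vectors are resampled from the weighted posterior, datasets
    simulated and summarized; per statistic the tail probability
    ``P(t_sim < t_obs)`` (midpoint tie handling) and the two-sided
    ``2 min(tail, 1-tail)`` are reported.  Statistics constant across
    simulations are flagged and excluded.  If ``prior_stats`` is given a
    PCA is fitted on the prior-predictive cloud and prior, posterior and
    observed points are projected.
    """
    rng = np.random.default_rng(seed)
    names = summary_stat_names()
    w = posterior["abc_weight"].to_numpy()
    w = w / w.sum()
    picks = rng.choice(len(posterior), size=n_ppc, p=w)
    sims = np.empty((n_ppc, len(names)))
    for i, j in enumerate(picks):
        params = posterior.iloc[int(j)].to_dict()
        ds = simulate_dataset(params, sample_sizes, n_loci, rng)
        sims[i] = summary_stats(ds)
    rows = []
    for s, nm in enumerate(names):
        col = sims[:, s]
        if np.allclose(col, col[0]):
            rows.append({"statistic": nm, "tail": np.nan, "p_two_sided": np.nan, "constant": True})
            continue
        tail = ((col < observed[s]).sum() + 0.5 * (col == observed[s]).sum()) / n_ppc
        rows.append(
            {
                "statistic": nm,
                "tail": tail,
                "p_two_sided": 2.0 * min(tail, 1.0 - tail),
                "constant": False,
            }
        )
    result = {"tails": pd.DataFrame(rows), "ppc_stats": sims}
    if prior_stats is not None:
        from sklearn.decomposition import PCA

        sd = prior_stats.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        mu = prior_stats.mean(axis=0)
        pca = PCA(n_components=2)
        prior_xy = pca.fit_transform((prior_stats - mu) / sd)
        result["pca"] = {
            "prior": prior_xy,
            "posterior": pca.transform((sims - mu) / sd),
            "observed": pca.transform(((observed - mu) / sd)[None, :]),
            "explained_variance_ratio": pca.explained_variance_ratio_,
        }
    return result


# -- observed-data assembly ------------------------------------------------------


def define_abc_populations(
    run,
    dataset: GenotypeDataset,
    clusters: dict[str, int],
    threshold: float = 0.90,
    exclude_populations=(),
) -> GenotypeDataset:
    """Assemble the three ABC populations from admixture-clustering output.

    ``clusters`` maps new population names (order preserved) to cluster
    indices of ``run.Q``; only individuals whose membership in the mapped
    cluster exceeds ``threshold`` are kept, and individuals from excluded
    sampling populations are dropped entirely.  Raising the threshold can
    only shrink the populations; an empty population raises.
    """
    excluded = {dataset.population_index(p) for p in exclude_populations}
    keep_rows = []
    new_index = []
    names = list(clusters)
    argmax = run.Q.argmax(axis=1)
    for j, name in enumerate(names):
        k = clusters[name]
        members = np.flatnonzero(
            (argmax == k)
            & (run.Q[:, k] >= threshold)
            & ~np.isin(dataset.pop_index, list(excluded) if excluded else [])
        )
        if members.size == 0:
            raise ValueError(f"cluster {k} has no members above Q > {threshold}")
        keep_rows.append(members)
        new_index.extend([j] * members.size)
    rows = np.concatenate(keep_rows)
    pops = [PopulationInfo(id=nm, n=int((np.asarray(new_index) == j).sum())) for j, nm in enumerate(names)]
    return GenotypeDataset(
        dataset.loci, pops, dataset.calls[rows].copy(), np.asarray(new_index)
    )
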