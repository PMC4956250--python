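"""Bayesian admixture clustering with correlated allele frequencies.

A Gibbs sampler over the classical admixture model: each allele copy has a
latent cluster of origin Z, each individual a membership vector Q ~
Dirichlet(alpha, ..., alpha), and each cluster draws its allele frequencies
at every locus from a Dirichlet centred on ancestral frequencies with
cluster-specific drift F_k (the F-model: concentration
``p_ancestral (1-F_k)/F_k``).  alpha and the F_k are updated by Metropolis
steps; the model log-evidence for each K is estimated from the
log-likelihood trace as ``mean - var/2``, and the number of clusters is
chosen by the second-order rate of change of that estimate across K
(the Evanno delta-K statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dataset import MISSING, GenotypeDataset


@dataclass
class StructureRun:
    """One MCMC run at a fixed number of clusters K."""

    K: int
    Q: np.ndarray  # (N, K) posterior mean memberships
    cluster_freqs: list[np.ndarray]  # per locus (K, A_l) posterior means
    allele_codes: list[np.ndarray]  # per locus allele sizes for the A_l columns
    alpha_trace: np.ndarray
    F_trace: np.ndarray  # (sweeps, K)
    ln_likelihood_trace: np.ndarray
    ln_prob_data: float  # lnP(X|K) = mean(lnL) - var(lnL)/2
    seed: int


def _code_dataset(dataset: GenotypeDataset):
    """Map allele sizes to dense per-locus codes; -1 for missing."""
    coded = np.full(dataset.calls.shape, -1, dtype=np.int64)
    codes = []
    for li in range(dataset.n_loci):
        col = dataset.calls[:, li, :]
        alleles = np.unique(col[col != MISSING])
        codes.append(alleles)
        for j, a in enumerate(alleles):
            coded[:, li, :][col == a] = j
    return coded, codes


def _dirichlet_logpdf(x, alpha):
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * np.log(np.maximum(x, 1e-300))).sum()
    )


def gibbs_run(
    dataset: GenotypeDataset,
    K: int,
    burnin: int = 5_000,
    reps: int = 20_000,
    seed: int = 0,
    thin: int = 10,
    lambda_anc: float = 1.0,
    alpha_prior_max: float = 10.0,
    f_prior_mean: float = 0.01,
    f_prior_sd: float = 0.05,
) -> StructureRun:
    """Run the admixture-model Gibbs sampler at a fixed K.

    Defaults are desk-scale (5k burn-in, 20k sweeps); the published run plan
    (200k burn-in, 1M sweeps) is reachable through the same arguments.
    Missing genotypes are skipped in the origin updates, never imputed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > dataset.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    coded, codes = _code_dataset(dataset)
    N, L, _ = coded.shape
    A = [len(c) for c in codes]
    valid = coded >= 0  # (N, L, 2)
    x_safe = np.where(valid, coded, 0)

    # state
    Q = rng.dirichlet(np.ones(K), size=N)
    P = [rng.dirichlet(np.ones(A[li]), size=K) for li in range(L)]
    p_anc = [np.full(A[li], 1.0 / A[li]) for li in range(L)]
    alpha = 1.0
    F = np.full(K, 0.01)

    f_shape = (f_prior_mean / f_prior_sd) ** 2
    f_scale = f_prior_sd**2 / f_prior_mean

    total = burnin + reps
    q_accum = np.zeros((N, K))
    p_accum = [np.zeros((K, A[li])) for li in range(L)]
    n_accum = 0
    lnl_trace = []
    alpha_trace = []
    f_trace = []

    locus_idx = np.arange(L)[None, :, None]

    for sweep in range(total):
        # --- Z | Q, P ---
        # gather P[k, l, x] into (N, L, 2, K)
        G = np.empty((N, L, 2, K))
        for li in range(L):
            G[:, li, :, :] = P[li][:, x_safe[:, li, :]].transpose(1, 2, 0)
        W = G * Q[:, None, None, :]
        Wsum = W.sum(axis=3)
        lnl = float(np.log(np.maximum(Wsum[valid], 1e-300)).sum())
        probs = W / np.maximum(Wsum[..., None], 1e-300)
        u = rng.random((N, L, 2, 1))
        Z = (probs.cumsum(axis=3) < u).sum(axis=3)
        Z = np.minimum(Z, K - 1)

        # --- Q | Z ---
        zk = np.where(valid, Z, -1)
        n_ik = np.zeros((N, K))
        for k in range(K):
            n_ik[:, k] = (zk == k).sum(axis=(1, 2))
        Q = rng.gamma(alpha + n_ik)
        Q /= Q.sum(axis=1, keepdims=True)
        Q = np.maximum(Q, 1e-12)
        Q /= Q.sum(axis=1, keepdims=True)

        # --- P | Z, p_anc, F ---
        for li in range(L):
            counts = np.zeros((K, A[li]))
            for c in range(2):
                v = valid[:, li, c]
                np.add.at(counts, (Z[v, li, c], coded[v, li, c]), 1.0)
            prior = p_anc[li][None, :] * ((1.0 - F) / F)[:, None]
            draw = rng.gamma(np.maximum(prior + counts, 1e-6))
            draw /= draw.sum(axis=1, keepdims=True)
            P[li] = np.maximum(draw, 1e-12)
            P[li] /= P[li].sum(axis=1, keepdims=True)

        # --- p_anc | P, F (Metropolis, Dirichlet proposal) ---
        for li in range(L):
            cur = p_anc[li]
            conc = 200.0
            prop = rng.dirichlet(np.maximum(cur * conc, 1e-3))
            prop = np.maximum(prop, 1e-9)
            prop /= prop.sum()

            def log_target(pa):
                lt = _dirichlet_logpdf(pa, np.full(A[li], lambda_anc))
                for k in range(K):
                    lt += _dirichlet_logpdf(P[li][k], pa * (1.0 - F[k]) / F[k])
                return lt

            log_acc = (
                log_target(prop)
                - log_target(cur)
                + _dirichlet_logpdf(cur, np.maximum(prop * conc, 1e-3))
                - _dirichlet_logpdf(prop, np.maximum(cur * conc, 1e-3))
            )
            if np.log(rng.random()) < log_acc:
                p_anc[li] = prop

        # --- F | P, p_anc (Metropolis, per cluster) ---
        for k in range(K):
            cur = F[k]
            prop = cur + rng.normal(0.0, 0.03)
            if not 0.001 < prop < 0.999:
                continue

            def log_f(fv):
                lt = (f_shape - 1.0) * np.log(fv) - fv / f_scale  # Gamma prior
                for li in range(L):
                    lt += _dirichlet_logpdf(P[li][k], p_anc[li] * (1.0 - fv) / fv)
                return lt

            if np.log(rng.random()) < log_f(prop) - log_f(cur):
                F[k] = prop

        # --- alpha (Metropolis, uniform prior) ---
        if K > 1:
            prop = alpha + rng.normal(0.0, 0.05)
            if 0.001 < prop < alpha_prior_max:
                lcur = N * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1.0) * np.log(Q).sum()
                lprop = N * (gammaln(K * prop) - K * gammaln(prop)) + (prop - 1.0) * np.log(Q).sum()
                if np.log(rng.random()) < lprop - lcur:
                    alpha = prop

        if sweep >= burnin:
            lnl_trace.append(lnl)
            if (sweep - burnin) % thin == 0:
                alpha_trace.append(alpha)
                f_trace.append(F.copy())
                q_accum += Q
                for li in range(L):
                    p_accum[li] += P[li]
                n_accum += 1

    lnl_trace = np.asarray(lnl_trace)
    ln_prob = float(lnl_trace.mean() - lnl_trace.var(ddof=1) / 2.0)
    return StructureRun(
        K=K,
        Q=q_accum / max(n_accum, 1),
        cluster_freqs=[p / max(n_accum, 1) for p in p_accum],
        allele_codes=codes,
        alpha_trace=np.asarray(alpha_trace),
        F_trace=np.asarray(f_trace),
        ln_likelihood_trace=lnl_trace,
        ln_prob_data=ln_prob,
        seed=seed,
    )


def run_k_range(
    dataset: GenotypeDataset,
    k_values,
    runs_per_k: int = 3,
    burnin: int = 2_000,
    reps: int = 6_000,
    seed: int = 0,
) -> dict[int, list[StructureRun]]:
    """Replicate runs over a range of K (the published plan: 10 runs, K 1-11)."""
    out: dict[int, list[StructureRun]] = {}
    base = np.random.default_rng(seed)
    for K in k_values:
        out[K] = [
            gibbs_run(dataset, K, burnin=burnin, reps=reps, seed=int(base.integers(2**31)))
            for _ in range(runs_per_k)
        ]
    return out


def evanno_delta_k(runs_by_k: dict[int, list[StructureRun]]) -> pd.DataFrame:
    """Evanno's delta-K over replicate runs grouped by K.

    ``deltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))``,
    defined for interior K with at least two runs; sd of zero leaves the
    entry undefined (NaN).
    """
    ks = sorted(runs_by_k)
    if len(ks) < 3:
        raise ValueError("delta-K needs at least three consecutive K values")
    stats = {
        k: (
            float(np.mean([r.ln_prob_data for r in runs_by_k[k]])),
            float(np.std([r.ln_prob_data for r in runs_by_k[k]], ddof=1))
            if len(runs_by_k[k]) > 1
            else float("nan"),
        )
        for k in ks
    }
    rows = []
    for k in ks:
        mean_l, sd_l = stats[k]
        dk = float("nan")
        if k - 1 in stats and k + 1 in stats and sd_l and np.isfinite(sd_l) and sd_l > 0:
            dk = abs(stats[k + 1][0] - 2.0 * mean_l + stats[k - 1][0]) / sd_l
        rows.append({"K": k, "mean_lnP": mean_l, "sd_lnP": sd_l, "delta_K": dk})
    return pd.DataFrame(rows)


def best_run(runs: list[StructureRun]) -> StructureRun:
    """The run with the highest estimated lnP(X|K)."""
    return max(runs, key=lambda r: r.ln_prob_data)


def membership_summary(
    runs: list[StructureRun], dataset: GenotypeDataset
) -> pd.DataFrame:
    """Population-averaged memberships from the best-likelihood run at one K.

    No cross-run label alignment is attempted: summaries follow the single
    best run, so label switching across runs is immaterial.
    """
    run = best_run(runs)
    rows = []
    for k, pop in enumerate(dataset.populations):
        idx = dataset.individuals_of(k)
        qbar = run.Q[idx].mean(axis=0)
        rows.append({"population": pop.id, **{f"Q{j + 1}": q for j, q in enumerate(qbar)}})
    return pd.DataFrame(rows)


def assign_clusters(run: StructureRun, threshold: float = 0.9) -> np.ndarray:
    """Hard assignment per individual: argmax cluster if its Q exceeds the
    threshold, else -1 (unassigned)."""
    top = run.Q.argmax(axis=1)
    ok = run.Q.max(axis=1) > threshold
    return np.where(ok, top, -1)
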