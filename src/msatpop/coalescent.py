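"""Backward-in-time coalescent engine with stepwise microsatellite mutation.

A single engine serves three consumers: the mutation-drift-equilibrium
reference distributions of the bottleneck tests, the demographic-scenario
simulator of the ABC stage, and the bottlenecked-population generator of the
synthetic-data module.

Time runs backwards in generations.  Within each population, pairs of
lineages coalesce at rate ``C(j,2)/(2N)`` per generation (diploid population
of effective size ``N`` holding ``2N`` gene copies).  Demographic events —
population merges, admixture splits, size changes — are applied at fixed
times.  Mutations are laid on branches as a Poisson process and move alleles
on the repeat-unit lattice with geometrically distributed step sizes; rare
single-nucleotide indels (SNI) move fragment sizes off-lattice by +-1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

# -- mutation step samplers ------------------------------------------------------


def geometric_multistep_mean(variance: float) -> float:
    """Mean of a geometric step-size distribution with the given variance.

    For a geometric distribution on {1,2,...} with mean ``m`` the variance is
    ``m(m-1)``; solving ``m(m-1) = v`` gives ``m = (1+sqrt(1+4v))/2``.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    return 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * variance))


@dataclass(frozen=True)
class TpmModel:
    """Two-phase mutation model: single steps mixed with geometric multisteps.

    ``p_multistep`` is the probability that a mutation changes the allele by
    more than one repeat unit; multistep magnitudes are geometric with
    variance ``multistep_variance`` (defaults follow the empirical
    recommendation of 22% multistep changes with variance 11.92).
    """

    p_multistep: float = 0.22
    multistep_variance: float = 11.92

    def __post_init__(self):
        if not 0.0 <= self.p_multistep <= 1.0:
            raise ValueError("p_multistep must be in [0, 1]")
        if self.multistep_variance <= 0:
            raise ValueError("multistep_variance must be positive")

    def sample_steps(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` signed mutation steps in repeat units."""
        if n == 0:
            return np.zeros(0, dtype=np.int64)
        mag = np.ones(n, dtype=np.int64)
        multi = rng.random(n) < self.p_multistep
        k = int(multi.sum())
        if k:
            m = geometric_multistep_mean(self.multistep_variance)
            mag[multi] = rng.geometric(1.0 / m, size=k)
        sign = rng.integers(0, 2, size=n) * 2 - 1
        return mag * sign


@dataclass(frozen=True)
class GsmModel:
    """Generalized stepwise mutation: geometric step sizes with parameter ``p_geom``.

    Step magnitude ``k`` has probability ``(1-p_geom) * p_geom**(k-1)``;
    ``p_geom = 0`` recovers the strict single-step model (SMM).
    """

    p_geom: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p_geom < 1.0:
            raise ValueError("p_geom must be in [0, 1)")

    def sample_steps(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n == 0:
            return np.zeros(0, dtype=np.int64)
        mag = rng.geometric(1.0 - self.p_geom, size=n)
        sign = rng.integers(0, 2, size=n) * 2 - 1
        return mag * sign


# -- demographic events ----------------------------------------------------------


@dataclass(frozen=True)
class Event:
    """A demographic event at backward time ``t`` (generations).

    kind:
      - ``merge``: lineages of population ``a`` move into population ``b``.
      - ``admix``: lineages of population ``a`` move to ``b`` with probability
        ``rate`` and to ``c`` otherwise (backward view of an admixture founding).
      - ``resize``: population ``a`` takes effective size ``size``.
    """

    t: float
    kind: str
    a: int
    b: int = -1
    c: int = -1
    rate: float = 0.0
    size: float = 0.0


def simulate_locus(
    sample_sizes: Sequence[int],
    pop_sizes: Sequence[float],
    events: Sequence[Event],
    mu: float,
    rng: np.random.Generator,
    step_model: TpmModel | GsmModel | None = None,
    sni_rate: float = 0.0,
    motif_length: int = 2,
    root_size: int = 200,
) -> np.ndarray:
    """Simulate one microsatellite locus; returns allele sizes (bp) per gene copy.

    ``sample_sizes`` counts gene copies sampled per population (2 x diploid
    individuals).  The returned array is ordered population by population.
    The caller pairs consecutive copies into diploid individuals.
    """
    step_model = step_model or GsmModel(0.0)
    n_pops = len(sample_sizes)
    total = int(sum(sample_sizes))
    if total < 1:
        raise ValueError("need at least one sampled gene copy")

    # Tree arrays: nodes 0..total-1 are leaves; internals appended in coalescence
    # order.  parent/time fixed as events happen.
    max_nodes = 2 * total - 1
    parent = np.full(max_nodes, -1, dtype=np.int64)
    node_time = np.zeros(max_nodes, dtype=np.float64)

    # active lineages per population (python lists; swap-pop removal)
    active: list[list[int]] = []
    node = 0
    for k, s in enumerate(sample_sizes):
        active.append(list(range(node, node + int(s))))
        node += int(s)
    next_node = total

    sizes = np.asarray(pop_sizes, dtype=np.float64).copy()
    evs = sorted(events, key=lambda e: e.t)
    ev_i = 0
    t = 0.0

    # Populations evolve independently between demographic events, so each
    # epoch is handled per population with a batch of exponential waits.
    while True:
        t_end = evs[ev_i].t if ev_i < len(evs) else np.inf
        for k in range(n_pops):
            lin = active[k]
            j = len(lin)
            if j < 2:
                continue
            scale = 2.0 * sizes[k]
            jj = np.arange(j, 1, -1, dtype=np.float64)
            times = t + np.cumsum(rng.exponential(scale / (jj * (jj - 1) / 2.0)))
            u = rng.random(2 * (j - 1))
            m = len(lin)
            for step in range(j - 1):
                if times[step] >= t_end:
                    break
                i = int(u[2 * step] * m)
                a = lin[i]
                lin[i] = lin[-1]
                lin.pop()
                m -= 1
                i = int(u[2 * step + 1] * m)
                b = lin[i]
                p = next_node
                next_node += 1
                parent[a] = p
                parent[b] = p
                node_time[p] = times[step]
                lin[i] = p
        if ev_i >= len(evs):
            if sum(len(a) for a in active) > 1:
                raise RuntimeError(
                    "lineages cannot reach a common ancestor: isolated populations"
                )
            break
        ev = evs[ev_i]
        t = ev.t
        ev_i += 1
        if ev.kind == "merge":
            active[ev.b].extend(active[ev.a])
            active[ev.a] = []
        elif ev.kind == "admix":
            movers = active[ev.a]
            active[ev.a] = []
            for ln in movers:
                if rng.random() < ev.rate:
                    active[ev.b].append(ln)
                else:
                    active[ev.c].append(ln)
        elif ev.kind == "resize":
            sizes[ev.a] = ev.size
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")

    root = next_node - 1
    n_nodes = next_node

    # mutations on branches
    blen = node_time[parent[:n_nodes]] - node_time[:n_nodes]
    blen[root] = 0.0
    n_mut = rng.poisson(mu * blen)
    steps = step_model.sample_steps(int(n_mut.sum()), rng)
    branch_step = np.zeros(n_nodes, dtype=np.int64)
    np.add.at(branch_step, np.repeat(np.arange(n_nodes), n_mut), steps)

    units = np.zeros(n_nodes, dtype=np.int64)
    # nodes were created in increasing time order; parents always have larger
    # index than children, so a reverse sweep accumulates root-to-leaf.
    for v in range(n_nodes - 2, -1, -1):
        units[v] = units[parent[v]] + branch_step[v]

    values = root_size + motif_length * units[:total]

    if sni_rate > 0.0:
        n_sni = rng.poisson(sni_rate * blen)
        sni_steps = rng.integers(0, 2, size=int(n_sni.sum())) * 2 - 1
        branch_sni = np.zeros(n_nodes, dtype=np.int64)
        np.add.at(branch_sni, np.repeat(np.arange(n_nodes), n_sni), sni_steps)
        off = np.zeros(n_nodes, dtype=np.int64)
        for v in range(n_nodes - 2, -1, -1):
            off[v] = off[parent[v]] + branch_sni[v]
        values = values + off[:total]

    return np.maximum(values, 1)  # fragment sizes stay positive


def simulate_single_population(
    n_copies: int,
    theta: float,
    rng: np.random.Generator,
    step_model: TpmModel | GsmModel | None = None,
    size_history: Sequence[tuple[float, float]] = (),
    n_ref: float = 1000.0,
) -> np.ndarray:
    """One-population locus in repeat units, parameterized by ``theta = 4*N*mu``.

    ``size_history`` lists (time_in_generations, relative_size) changes looking
    backwards; sizes are relative to the present-day reference ``n_ref``.
    Returns lattice coordinates (repeat units) per sampled gene copy.
    """
    mu = theta / (4.0 * n_ref)
    events = [Event(t=t, kind="resize", a=0, size=s * n_ref) for t, s in size_history]
    vals = simulate_locus(
        [n_copies], [n_ref], events, mu, rng, step_model=step_model, motif_length=1,
        root_size=10**6,
    )
    return vals - 10**6
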