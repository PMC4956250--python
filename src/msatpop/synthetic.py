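"""Synthetic genotype generators with known truth, for calibration and tests.

Every stage of the pipeline is testable without external downloads: the
generators here produce multi-population diploid microsatellite datasets with
controlled differentiation (island model with a target FST), optional null
alleles, optional recent bottlenecks (via the coalescent engine), and a
30-population fixture shaped like the real study (sample sizes, statuses and
coordinates from the published sampling table, genotypes synthetic).

Each generator returns the dataset together with a *truth* record (the
parameters actually used) so parameter-recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import coalescent
from .dataset import (
    MISSING,
    GenotypeDataset,
    Locus,
    PopulationInfo,
    population_info_from_table,
)


@dataclass
class GeneratorSpec:
    """Parameters of the island-model genotype generator.

    ``fst`` is the target differentiation: population allele frequencies are
    drawn from a Dirichlet centred on a common ancestral frequency vector with
    concentration ``(1 - fst)/fst``, whose expected Weir-Cockerham theta is
    ``fst``.  ``null_freq`` injects a per-locus null allele with that
    ancestral frequency; the null drifts across populations like any other
    allele.  In the visible dataset null/null genotypes become missing and
    visible/null genotypes appear homozygous; the truth sidecar keeps the
    unmasked genotypes (null coded as allele size 999) and the realized
    per-population null frequencies.
    """

    n_populations: int = 4
    n_individuals: int = 25
    n_loci: int = 8
    n_alleles: int = 10
    motif_length: int = 2
    fst: float = 0.1
    null_freq: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("fst", "null_freq", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")


def _draw_pop_freqs(ancestral: np.ndarray, fst: float, rng) -> np.ndarray:
    if fst <= 0.0:
        return ancestral.copy()
    conc = (1.0 - fst) / fst
    return rng.dirichlet(np.maximum(ancestral * conc, 1e-9))


def generate(spec: GeneratorSpec):
    """Island-model dataset plus truth sidecar.

    Returns ``(dataset, truth)`` where ``truth`` records the ancestral and
    per-population allele frequencies, the target FST and the injected null
    frequency per locus.
    """
    rng = np.random.default_rng(spec.seed)
    n_pops, n_ind, n_loci = spec.n_populations, spec.n_individuals, spec.n_loci
    loci = [Locus(f"L{li + 1:02d}", spec.motif_length) for li in range(n_loci)]
    pops = [PopulationInfo(id=f"P{k + 1:02d}", n=n_ind) for k in range(n_pops)]

    NULL_CODE = 999  # unmasked truth codes the null as this allele size
    has_null = spec.null_freq > 0.0
    sizes_per_locus = []
    anc_freqs = []
    pop_freqs = []  # [locus][pop] -> vector over visible alleles (+ null last)
    for li in range(n_loci):
        base = int(rng.integers(80, 180))
        sizes = base + spec.motif_length * np.arange(spec.n_alleles)
        sizes_per_locus.append(sizes)
        anc = rng.dirichlet(np.full(spec.n_alleles, 1.0))
        if has_null:
            anc = np.append(anc * (1.0 - spec.null_freq), spec.null_freq)
        anc_freqs.append(anc)
        pop_freqs.append([_draw_pop_freqs(anc, spec.fst, rng) for _ in range(n_pops)])

    true_calls = np.empty((n_pops * n_ind, n_loci, 2), dtype=np.int64)
    pop_index = np.repeat(np.arange(n_pops), n_ind)
    null_realized = np.zeros((n_pops, n_loci))
    for li in range(n_loci):
        sizes = sizes_per_locus[li]
        values = np.append(sizes, NULL_CODE) if has_null else sizes
        for k in range(n_pops):
            f = pop_freqs[li][k]
            draws = rng.choice(values, size=(n_ind, 2), p=f)
            true_calls[k * n_ind : (k + 1) * n_ind, li, :] = draws
            if has_null:
                null_realized[k, li] = (draws == NULL_CODE).mean()

    calls = true_calls.copy()
    if has_null:
        both_null = (calls == NULL_CODE).all(axis=2)
        one_null = (calls == NULL_CODE).any(axis=2) & ~both_null
        for li in range(n_loci):
            b, o = both_null[:, li], one_null[:, li]
            calls[b, li, :] = MISSING
            if o.any():
                vis = np.where(calls[o, li, :] == NULL_CODE, 0, calls[o, li, :]).sum(axis=1)
                calls[o, li, :] = vis[:, None]  # apparent homozygote
    if spec.missing_rate > 0.0:
        drop = rng.random((n_pops * n_ind, n_loci)) < spec.missing_rate
        calls[drop, :] = MISSING

    # guarantee at least one typed call per individual (re-type locus 0 from
    # the visible frequencies)
    untyped = (calls[:, :, 0] == MISSING).all(axis=1)
    for i in np.flatnonzero(untyped):
        k = pop_index[i]
        f = pop_freqs[0][k][: spec.n_alleles]
        f = f / f.sum()
        calls[i, 0, :] = rng.choice(sizes_per_locus[0], size=2, p=f)
        true_calls[i, 0, :] = calls[i, 0, :]

    ds = GenotypeDataset(loci, pops, calls, pop_index)
    truth = {
        "fst": spec.fst,
        "null_freq": spec.null_freq,
        "null_realized": null_realized,
        "true_calls": true_calls,
        "ancestral_freqs": anc_freqs,
        "pop_freqs": pop_freqs,
        "allele_sizes": sizes_per_locus,
        "seed": spec.seed,
    }
    return ds, truth


# -- coalescent-backed single populations ---------------------------------------


def equilibrium_population(
    n_individuals: int,
    n_loci: int,
    theta: float,
    model=None,
    seed: int = 0,
    motif_length: int = 2,
) -> GenotypeDataset:
    """A single population at mutation-drift equilibrium (coalescent sample)."""
    return _coalescent_population(
        n_individuals, n_loci, theta, model, seed, motif_length, size_history=()
    )


def bottlenecked_population(
    n_individuals: int,
    n_loci: int,
    theta_pre: float,
    severity: float = 0.05,
    time_generations: float = 10.0,
    model=None,
    seed: int = 0,
    motif_length: int = 2,
) -> GenotypeDataset:
    """A population whose size crashed to ``severity`` x ancestral, recently.

    Looking backwards: present-day size ``severity * N_pre`` until
    ``time_generations`` ago, ancestral size ``N_pre`` (with ``theta_pre =
    4 N_pre mu``) before that.  Defaults emulate a severe (95%) crash ten
    generations ago.
    """
    if not 0.0 < severity <= 1.0:
        raise ValueError("severity must be in (0, 1]")
    # engine sizes are relative to the ancestral N; the present size is scaled
    history = [(time_generations, 1.0)]
    return _coalescent_population(
        n_individuals,
        n_loci,
        theta_pre,
        model,
        seed,
        motif_length,
        size_history=history,
        present_relative_size=severity,
    )


def _coalescent_population(
    n_individuals,
    n_loci,
    theta,
    model,
    seed,
    motif_length,
    size_history,
    present_relative_size: float = 1.0,
) -> GenotypeDataset:
    rng = np.random.default_rng(seed)
    model = model or coalescent.GsmModel(0.0)
    n_ref = 1000.0
    mu = theta / (4.0 * n_ref)
    calls = np.empty((n_individuals, n_loci, 2), dtype=np.int64)
    for li in range(n_loci):
        events = [
            coalescent.Event(t=t, kind="resize", a=0, size=s * n_ref)
            for t, s in size_history
        ]
        vals = coalescent.simulate_locus(
            [2 * n_individuals],
            [present_relative_size * n_ref],
            events,
            mu,
            rng,
            step_model=model,
            motif_length=1,  # engine works on the unit lattice; bp applied below
            root_size=10**6,
        )
        units = vals - 10**6
        sizes = 100 + (units - units.min()) * motif_length
        calls[:, li, :] = sizes.reshape(n_individuals, 2)
    loci = [Locus(f"L{li + 1:02d}", motif_length) for li in range(n_loci)]
    pops = [PopulationInfo(id="P01", n=n_individuals)]
    return GenotypeDataset(loci, pops, calls, np.zeros(n_individuals, dtype=np.int64))


# -- study-shaped fixture --------------------------------------------------------

_WILD_GROUPS = {
    "A1": ["P01", "P02", "P03", "P04", "P05", "P06", "P07", "P15"],
    "A2": ["P08", "P09", "P10", "P11", "P12", "P13", "P14", "P16", "P17", "P18", "P26"],
    "A3": ["P19", "P20", "P21", "P22"],
}
_CULTIVATED = ["P23", "P24", "P25", "P27", "P28", "P29", "P30"]

_LOCUS_NAMES = [
    "SoUZ001",
    "SoUZ002",
    "SoUZ003",
    "SoUZ007",
    "SoUZ011",
    "SoUZ013",
    "SoUZ014",
    "SoUZ019",
]


def load_population_metadata() -> list[PopulationInfo]:
    """The 30 published sampling sites (id, locality, n, coordinates, status)."""
    with resources.files("msatpop.data").joinpath("populations.csv").open() as fh:
        df = pd.read_csv(fh)
    return population_info_from_table(df)


def paper_shaped_fixture(seed: int = 0, n_alleles: int = 18):
    """A 30-population dataset shaped like the published study.

    Population ids, sample sizes, coordinates and statuses follow the
    published sampling table; genotypes are synthetic.  Wild populations form
    three geographically coherent gene pools (moderate hierarchical
    differentiation, diversity highest in the central pool); the seven
    cultivated/naturalised populations descend from the northwestern pool
    through a strong founder bottleneck, giving them reduced allelic richness
    and no private alleles in expectation.

    Returns ``(dataset, truth)``; truth records group membership and the
    drift levels used.
    """
    rng = np.random.default_rng(seed)
    infos = load_population_metadata()
    loci = [Locus(nm, 2) for nm in _LOCUS_NAMES]

    group_fst = 0.10  # wild pools vs ancestral
    within_fst = 0.06  # populations within a pool
    cult_founder_fst = 0.35  # founder drift of the cultivated gene pool
    cult_within_fst = 0.08

    group_of = {}
    for gname, pids in _WILD_GROUPS.items():
        for pid in pids:
            group_of[pid] = gname
    for pid in _CULTIVATED:
        group_of[pid] = "CULT"

    calls_rows = []
    pop_index = []
    n_pops = len(infos)
    per_pop_freqs: list[dict[str, np.ndarray]] = [dict() for _ in range(n_pops)]
    sizes_per_locus = []

    for li, loc in enumerate(loci):
        base = int(rng.integers(90, 200))
        sizes = base + loc.motif_length * np.arange(n_alleles)
        sizes_per_locus.append(sizes)
        # smooth unimodal ancestral spectrum: common alleles contiguous in the
        # middle of the lattice, rare ones at the edges (stepwise-mutation
        # shape), so wild populations keep realistic M-ratios while founder
        # drift still empties interior positions in the cultivated pool
        centre = rng.uniform(n_alleles * 0.3, n_alleles * 0.7)
        width = rng.uniform(2.0, 4.5)
        shape = np.exp(-0.5 * ((np.arange(n_alleles) - centre) / width) ** 2)
        anc = rng.dirichlet(40.0 * shape / shape.sum())
        pool = {
            g: _draw_pop_freqs(anc, group_fst, rng) for g in _WILD_GROUPS
        }
        pool["CULT"] = _draw_pop_freqs(pool["A1"], cult_founder_fst, rng)
        for k, info in enumerate(infos):
            g = group_of[info.id]
            w = cult_within_fst if g == "CULT" else within_fst
            per_pop_freqs[k][loc.name] = _draw_pop_freqs(pool[g], w, rng)

    for k, info in enumerate(infos):
        n_ind = info.n
        block = np.empty((n_ind, len(loci), 2), dtype=np.int64)
        for li, loc in enumerate(loci):
            f = per_pop_freqs[k][loc.name]
            block[:, li, :] = rng.choice(
                sizes_per_locus[li], size=(n_ind, 2), p=f
            )
        calls_rows.append(block)
        pop_index.extend([k] * n_ind)

    ds = GenotypeDataset(
        loci, infos, np.concatenate(calls_rows, axis=0), np.asarray(pop_index)
    )
    truth = {
        "groups": group_of,
        "group_fst": group_fst,
        "within_fst": within_fst,
        "cult_founder_fst": cult_founder_fst,
        "seed": seed,
    }
    return ds, truth
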