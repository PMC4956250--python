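"""End-to-end orchestration of the microsatellite analysis pipeline.

Each stage reads the genotype dataset and writes documented file artifacts
(CSV / JSON / newick) into the output directory, so stages can be re-run
independently and the whole bundle is reproducible from the configuration
and seeds alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import abc as abc_mod
from . import bottleneck as bn
from . import differentiation as diff
from . import diversity as dv
from . import nulls
from . import structure as st
from .dataset import GenotypeDataset, write_genepop


@dataclass
class PipelineConfig:
    """Stage toggles, per-stage scale parameters and seeds."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    stages: tuple = (
        "diversity",
        "nulls",
        "fst",
        "tree",
        "amova",
        "structure",
        "ibd",
        "bottleneck",
        "abc",
    )
    hwe_reps: int = 2_000
    fst_boot: int = 1_000
    tree_boot: int = 100
    tree_search: str = "nj"
    amova_perm: int = 200
    mantel_perm: int = 2_000
    structure_k: tuple = (1, 2, 3, 4, 5)
    structure_runs: int = 2
    structure_burnin: int = 1_000
    structure_reps: int = 3_000
    bottleneck_sims: int = 300
    abc_sims_per_scenario: int = 500
    abc_n_closest: int = 100
    abc_sample_sizes: tuple = (25, 25, 25)


def run_pipeline(dataset: GenotypeDataset, config: PipelineConfig | None = None) -> dict:
    """Run the configured stages; returns a dict of result objects.

    Artifacts are written under ``config.out_dir``; the configuration and
    per-stage timings land in ``pipeline_log.json``.  A stage failure halts
    the pipeline with the stage name, keeping artifacts already written.
    """
    config = config or PipelineConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {}
    log = {"seed": config.seed, "stages": {}}

    (out / "dataset.genepop").write_text(write_genepop(dataset))

    def stage(name):
        return name in config.stages

    try:
        if stage("diversity"):
            t0 = time.time()
            tab = dv.diversity_table(
                dataset, hwe_reps=config.hwe_reps, seed=int(rng.integers(2**31))
            )
            tab.to_csv(out / "diversity_table.csv", index=False)
            results["diversity"] = tab
            log["stages"]["diversity"] = round(time.time() - t0, 2)

        if stage("nulls"):
            t0 = time.time()
            flags = nulls.flag_null_cells(
                dataset, hwe_reps=config.hwe_reps, seed=int(rng.integers(2**31))
            )
            flags.to_csv(out / "null_alleles.csv", index=False)
            results["nulls"] = flags
            log["stages"]["nulls"] = round(time.time() - t0, 2)

        if stage("fst"):
            t0 = time.time()
            theta, ci = diff.theta_bootstrap_ci(
                dataset, n_boot=config.fst_boot, seed=int(rng.integers(2**31))
            )
            theta_ena, ci_ena = nulls.fst_ena(
                dataset, n_boot=config.fst_boot, seed=int(rng.integers(2**31))
            )
            pw = diff.pairwise_fst(dataset)
            pw.to_csv(out / "pairwise_fst.csv")
            results["fst"] = {
                "global_theta": theta,
                "ci": ci,
                "global_theta_ena": theta_ena,
                "ci_ena": ci_ena,
                "pairwise": pw,
            }
            (out / "global_fst.json").write_text(
                json.dumps(
                    {
                        "theta": theta,
                        "ci": list(ci),
                        "theta_ena": theta_ena,
                        "ci_ena": list(ci_ena),
                    },
                    indent=1,
                )
            )
            log["stages"]["fst"] = round(time.time() - t0, 2)

        if stage("tree"):
            t0 = time.time()
            tree, supports = diff.bootstrap_tree(
                dataset,
                n_boot=config.tree_boot,
                seed=int(rng.integers(2**31)),
                replicate_search=config.tree_search,
            )
            (out / "chord_tree.nwk").write_text(str(tree))
            results["tree"] = (tree, supports)
            log["stages"]["tree"] = round(time.time() - t0, 2)

        if stage("amova"):
            t0 = time.time()
            groups = dataset.status_groups()
            res_one = diff.amova(
                dataset, n_perm=config.amova_perm, seed=int(rng.integers(2**31))
            )
            res_two = (
                diff.amova(
                    dataset,
                    groups=groups,
                    n_perm=config.amova_perm,
                    seed=int(rng.integers(2**31)),
                )
                if all(groups.values())
                else None
            )
            res_one.table.to_csv(out / "amova_onelevel.csv")
            if res_two is not None:
                res_two.table.to_csv(out / "amova_twolevel.csv")
            results["amova"] = {"one_level": res_one, "two_level": res_two}
            log["stages"]["amova"] = round(time.time() - t0, 2)

        if stage("structure"):
            t0 = time.time()
            runs = st.run_k_range(
                dataset,
                config.structure_k,
                runs_per_k=config.structure_runs,
                burnin=config.structure_burnin,
                reps=config.structure_reps,
                seed=int(rng.integers(2**31)),
            )
            ksel = st.evanno_delta_k(runs)
            ksel.to_csv(out / "delta_k.csv", index=False)
            interior = ksel.dropna(subset=["delta_K"])
            best_k = (
                int(interior.loc[interior["delta_K"].idxmax(), "K"])
                if len(interior)
                else config.structure_k[0]
            )
            qsum = st.membership_summary(runs[best_k], dataset)
            qsum.to_csv(out / f"memberships_K{best_k}.csv", index=False)
            results["structure"] = {"runs": runs, "delta_k": ksel, "best_k": best_k}
            log["stages"]["structure"] = round(time.time() - t0, 2)

        if stage("ibd"):
            t0 = time.time()
            pw = results.get("fst", {}).get("pairwise")
            if pw is None:
                pw = diff.pairwise_fst(dataset)
            coords = {
                p.id: (p.latitude, p.longitude) for p in dataset.populations
            }
            ibd = diff.mantel_ibd(
                pw, coords, n_perm=config.mantel_perm, seed=int(rng.integers(2**31))
            )
            results["ibd"] = ibd
            (out / "ibd.json").write_text(
                json.dumps(
                    {"r": ibd.r, "r_squared": ibd.r_squared, "p": ibd.p_value}, indent=1
                )
            )
            log["stages"]["ibd"] = round(time.time() - t0, 2)

        if stage("bottleneck"):
            t0 = time.time()
            tab = bn.bottleneck_table(
                dataset, n_sims=config.bottleneck_sims, seed=int(rng.integers(2**31))
            )
            tab.to_csv(out / "bottleneck.csv", index=False)
            results["bottleneck"] = tab
            log["stages"]["bottleneck"] = round(time.time() - t0, 2)

        if stage("abc"):
            t0 = time.time()
            table = abc_mod.build_reference_table(
                config.abc_sims_per_scenario,
                sample_sizes=config.abc_sample_sizes,
                seed=int(rng.integers(2**31)),
            )
            # observed statistics from three status-coherent population groups
            obs_ds = _observed_three_populations(dataset, config.abc_sample_sizes)
            obs = abc_mod.summary_stats(obs_ds)
            mc = abc_mod.model_choice(table, obs, n_closest=config.abc_n_closest)
            mc.to_csv(out / "abc_model_choice.csv", index=False)
            best = int(mc.loc[mc["posterior_probability"].idxmax(), "scenario"])
            est = abc_mod.estimate_params(
                table, obs, scenario=best, n_closest=config.abc_n_closest
            )
            est.to_csv(out / "abc_parameters.csv", index=False)
            results["abc"] = {"model_choice": mc, "best_scenario": best, "params": est}
            log["stages"]["abc"] = round(time.time() - t0, 2)
    except Exception as exc:
        (out / "pipeline_log.json").write_text(json.dumps(log, indent=1))
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    (out / "pipeline_log.json").write_text(json.dumps(log, indent=1))
    return results


def _observed_three_populations(dataset: GenotypeDataset, sample_sizes):
    """Collapse the dataset into three populations for the demographic stage.

    Indigenous populations are split into a northern and a southern half by
    latitude and the cultivated/naturalised populations form the third unit;
    a latitude-free dataset falls back to the first three populations.  Each
    unit is subsampled to the configured sizes.
    """
    import numpy as np

    groups = dataset.status_groups()
    ind = groups["indigenous"]
    cn = groups["cultivated_naturalised"]
    if len(ind) >= 2 and cn:
        lat = {p.id: p.latitude for p in dataset.populations}
        ind_sorted = sorted(ind, key=lambda pid: -lat[pid])
        half = len(ind_sorted) // 2
        units = [ind_sorted[:half], ind_sorted[half:], cn]
    else:
        ids = [p.id for p in dataset.populations]
        if len(ids) < 3:
            raise ValueError("need at least three populations for the ABC stage")
        units = [[ids[0]], [ids[1]], [ids[2]]]
    from .dataset import GenotypeDataset as GD, PopulationInfo

    rng = np.random.default_rng(0)
    rows = []
    new_index = []
    for j, unit in enumerate(units):
        members = np.concatenate([dataset.individuals_of(p) for p in unit])
        take = min(len(members), sample_sizes[j])
        members = rng.choice(members, size=take, replace=False)
        rows.append(members)
        new_index.extend([j] * take)
    pops = [
        PopulationInfo(id=f"Pop{j + 1}", n=int((np.asarray(new_index) == j).sum()))
        for j in range(3)
    ]
    rows_arr = np.concatenate(rows)
    return GD(dataset.loci, pops, dataset.calls[rows_arr].copy(), np.asarray(new_index))
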