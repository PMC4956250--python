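"""Genetic-bottleneck screening of every population.

Heterozygosity-excess Wilcoxon test under the two-phase mutation model
(22% multistep changes, variance 11.92) and the Garza-Williamson M-ratio
against the critical value Mc = 0.68, per population.
"""

from pathlib import Path

from msatpop import bottleneck as bn
from msatpop.dataset import read_genotype_table
from msatpop.synthetic import load_population_metadata

SEED = 5

out = Path("results/bottleneck")
out.mkdir(parents=True, exist_ok=True)
ds = read_genotype_table("results/data/genotypes.csv", metadata=load_population_metadata())

cache = bn.HeqCache(n_sims=400, seed=SEED)
tab = bn.bottleneck_table(ds, cache=cache)
tab["status"] = [p.status for p in ds.populations]
tab.to_csv(out / "bottleneck.csv", index=False)

sig = tab[tab["P_bottleneck"] < 0.05]
low_m = tab[tab["below_Mc"]]
print(tab.round(3).to_string(index=False))
print(f"\nheterozygosity-excess significant (P < 0.05): "
      f"{list(sig['population'])}")
print(f"M-ratio below Mc = {bn.M_CRITICAL}: {list(low_m['population'])}")
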