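#!/usr/bin/env python
"""Community structure: Bray-Curtis NMDS, PERMANOVA, dispersions, envfit.

Tests how site and plant type structure the root fungal communities:
sequential (adonis-style) PERMANOVA with 999 permutations, NMDS with
Kruskal stress, homogeneity of plant-type dispersions, and soil vectors
fitted onto the ordination.
"""

from pathlib import Path

import pandas as pd

from milletmyco.diversity import rarefy
from milletmyco.ordination import betadisper, bray_curtis, envfit, nmds, permanova
from milletmyco.simulate import SimConfig, generate_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table, metadata, *_ = generate_dataset(SimConfig(seed=SEED))
    rt = rarefy(table, 25_556, seed=SEED + 1)
    meta = metadata.select_samples(rt.sample_ids)
    dist = bray_curtis(rt)

    ord_ = nmds(dist, n_restarts=20, seed=SEED + 2)
    ord_.scores.to_csv(OUT / "nmds_scores.tsv", sep="\t")
    print(f"NMDS stress = {ord_.stress:.3f} (converged: {ord_.converged})")

    res = permanova(dist, meta, n_perm=999, seed=SEED + 3)
    res.table.round(5).to_csv(OUT / "permanova.tsv", sep="\t")
    print("PERMANOVA (sequential SS, 999 permutations):")
    print(res.table.round(4).to_string())

    bd = betadisper(dist, meta.frame["plant_type"], n_perm=999, seed=SEED + 4)
    print(f"betadisper (plant type): F = {bd.F:.3f}, p = {bd.p:.3f}")

    env = envfit(ord_, meta, n_perm=999, seed=SEED + 5)
    env.round(5).to_csv(OUT / "envfit.tsv", sep="\t")
    sig = env[env["p"] < 0.05]
    print(f"envfit: {len(sig)}/{len(env)} soil variables significant at p<0.05:")
    print(sig.round(3).to_string())


if __name__ == "__main__":
    main()
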