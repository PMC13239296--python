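#!/usr/bin/env python
"""Population structure: pairwise Weir-Cockerham FST and PCoA.

FST for every cohort pair on each locus subset (999 bootstrap replicates
over loci, BH-corrected one-tailed p), and classical-scaling PCoA on
bitwise genetic distances.
"""

import json
import pathlib

import pandas as pd

from kelppopgen import (
    bitwise_distance,
    fst_table,
    pairwise_fst,
    pcoa,
    read_genotypes,
)

OUT = pathlib.Path("results/analysis")


def main() -> None:
    gm = read_genotypes(str(OUT / "genotypes_filtered.csv"))
    part = json.loads((OUT / "locus_partition.json").read_text())
    keys = gm.individuals[["population", "cohort"]].astype(str).agg("/".join, axis=1)
    grouping = {k: (keys == k).to_numpy() for k in sorted(keys.unique())}

    subsets = {"all": None}
    subsets.update({k: gm.loci_index(part[k]) for k in
                    ("neutral", "provenance", "hatchery") if part[k]})
    rows = []
    for label, idx in subsets.items():
        rows.extend(pairwise_fst(gm, grouping, idx, n_boot=999, seed=11,
                                 subset_label=label))
    table = fst_table(rows)
    table.to_csv(OUT / "fst.csv", index=False)
    show = table[table.subset == "all"]
    print("pairwise FST (all loci):")
    print(show.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    coords = pcoa(bitwise_distance(gm), n_axes=4)
    pd.DataFrame(coords.coordinates,
                 columns=[f"axis{i+1}" for i in range(coords.coordinates.shape[1])]
                 ).assign(individual_id=gm.individual_ids).to_csv(
        OUT / "pcoa_coordinates.csv", index=False)
    print("PCoA % variance (first axes):",
          [round(v, 1) for v in coords.pct_variance[:4]])


if __name__ == "__main__":
    main()
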