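#!/usr/bin/env python
"""Effective population size per cohort (LD method, neutral loci).

Burrows composite r² with the Waples sample-size-corrected expectation,
MAF cutoff 0 (the panel is already MAF-filtered), jackknife-over-individuals CIs, and the
percent of donors effectively contributing to each F1 cohort.
"""

import json
import math
import pathlib

import pandas as pd

from kelppopgen import donor_contribution_pct, ld_ne, read_genotypes

OUT = pathlib.Path("results/analysis")
N_DONORS = {"warm": 100, "cool": 100}


def main() -> None:
    gm = read_genotypes(str(OUT / "genotypes_filtered.csv"))
    part = json.loads((OUT / "locus_partition.json").read_text())
    neutral = gm.loci_index(part["neutral"])
    keys = gm.individuals[["population", "cohort"]].astype(str).agg("/".join, axis=1)
    rows = []
    for label in sorted(keys.unique()):
        mask = (keys == label).to_numpy()
        est = ld_ne(gm, mask, neutral, maf_cutoff=0.0, ci_method="jackknife")
        pop, cohort = label.split("/")
        contrib = (donor_contribution_pct(est, N_DONORS[pop])
                   if cohort == "hatchery" and math.isfinite(est.ne) else float("nan"))
        rows.append({"group": label, "Ne": round(est.ne, 1),
                     "ci_low": round(est.ci_low, 1), "ci_high": round(est.ci_high, 1),
                     "overall_r2": round(est.overall_r2, 4),
                     "expected_r2": round(est.expected_r2, 4),
                     "n": int(mask.sum()),
                     "donors": N_DONORS[pop] if cohort == "hatchery" else None,
                     "contribution_pct": round(contrib, 1)})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "ne_estimates.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
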