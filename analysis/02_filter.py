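#!/usr/bin/env python
"""Sequential SNP/individual quality filtering of the synthetic panel.

The panel emulates the already-MAF-filtered study dataset, so the MAF
stage is disabled here (its behaviour is exercised in the unit suite);
depth, reproducibility, secondary, missingness and monomorphic stages run
as in the study protocol. Writes the filtered panel and the stage log.
"""

import pathlib

from kelppopgen import FilterConfig, apply_filters, read_genotypes, write_genotypes

DATA = pathlib.Path("data/synthetic")
OUT = pathlib.Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm = read_genotypes(str(DATA / "genotypes.csv"))
    filtered, log = apply_filters(gm, FilterConfig(maf_exclude_at_or_below=0.0,
                                                   rng_seed=11))
    write_genotypes(filtered, str(OUT / "genotypes_filtered.csv"))
    log.to_frame().to_csv(OUT / "filter_log.csv", index=False)
    for rec in log.stages:
        print(f"{rec['stage']}: loci {rec['loci_before']} -> {rec['loci_after']}, "
              f"individuals {rec['individuals_before']} -> {rec['individuals_after']}")
    print(f"final: {filtered.n_individuals} individuals x {filtered.n_loci} loci")


if __name__ == "__main__":
    main()
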