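"""Published summary statistics of the *Ecklonia radiata* hatchery experiment.

The underlying genotype data (DArTseq; 49,220 initial SNPs filtered to
1601 loci x 301 individuals) are deposited at Dryad
(https://doi.org/10.5061/dryad.2v6wwq049). This module carries the
published per-cohort diversity panel and locus counts as *inputs* for
arithmetic summaries (outlier percentages, relative declines between wild
and hatchery cohorts); nothing here is an output of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Locus counts after filtering and outlier partitioning.
N_LOCI_TOTAL = 1601
N_LOCI_NEUTRAL = 1559
N_LOCI_PROVENANCE = 27
N_LOCI_HATCHERY = 15

#: Sample sizes per cohort in the deposited dataset.
SAMPLE_SIZES = {
    ("warm", "wild"): 98,
    ("cool", "wild"): 101,
    ("warm", "hatchery"): 62,
    ("cool", "hatchery"): 36,
}

#: Donors used per provenance for the mass spawn.
N_DONORS = {"warm": 100, "cool": 100}


def published_diversity_table() -> pd.DataFrame:
    """The published per-cohort diversity panel (PL/AR/PA/Ho/He/FIS)."""
    with resources.files("kelppopgen.data").joinpath(
        "published_diversity.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def outlier_percentages() -> dict[str, float]:
    """Percent of all retained SNPs associated with each predictor."""
    return {
        "provenance": 100.0 * N_LOCI_PROVENANCE / N_LOCI_TOTAL,
        "hatchery": 100.0 * N_LOCI_HATCHERY / N_LOCI_TOTAL,
    }


def _overall(table: pd.DataFrame, subset: str) -> pd.DataFrame:
    rows = table[(table["subset"] == subset) & (table["age_months"] == "all")]
    return rows.set_index(["population", "cohort"])


def neutral_ho_decline_pct(table: pd.DataFrame | None = None) -> float:
    """Mean percent decline in neutral Ho from wild donors to F1 cohorts.

    Averaged over the warm and cool population pairs.
    """
    table = table if table is not None else published_diversity_table()
    rows = _overall(table, "neutral")
    declines = []
    for pop in ("warm", "cool"):
        wild = rows.loc[(pop, "wild"), "Ho"]
        hatch = rows.loc[(pop, "hatchery"), "Ho"]
        declines.append(100.0 * (wild - hatch) / wild)
    return float(sum(declines) / len(declines))


def neutral_pl_decline_pct(population: str, table: pd.DataFrame | None = None) -> float:
    """Percent decline in neutral PL from wild donors to the F1 cohort."""
    table = table if table is not None else published_diversity_table()
    rows = _overall(table, "neutral")
    wild = rows.loc[(population, "wild"), "PL_pct"]
    hatch = rows.loc[(population, "hatchery"), "PL_pct"]
    return float(100.0 * (wild - hatch) / wild)
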