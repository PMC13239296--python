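"""Per-group diversity panel: Ho, He, uHe, PL, rarefied AR, PA and FIS.

All statistics operate on alternate-allele dosages with pairwise-complete
handling of missing calls (a missing call simply drops that individual from
that locus). FIS follows the hierfstat/Nei ratio-of-means convention,
1 - mean(Ho) / mean(uHe) over polymorphic loci, with a bootstrap over loci
for its confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import (
    MISSING,
    GenotypeMatrix,
    _resolve_group,
    _resolve_loci,
    allele_frequencies,
)


class PerLocusStat(NamedTuple):
    per_locus: np.ndarray
    mean: float


def _calls_for(gm: GenotypeMatrix, group, loci) -> np.ndarray:
    rows = _resolve_group(gm, group)
    cols = _resolve_loci(gm, loci)
    return gm.calls[np.ix_(rows, cols)]


def observed_heterozygosity(gm: GenotypeMatrix, group=None, loci=None) -> PerLocusStat:
    """Fraction of non-missing individuals that are heterozygous, per locus.

    The mean is taken over loci with at least one valid call.
    """
    calls = _calls_for(gm, group, loci)
    valid = calls != MISSING
    n_valid = valid.sum(axis=0)
    if not (n_valid > 0).any():
        raise ValueError("no locus has a valid call in this group")
    with np.errstate(invalid="ignore"):
        ho = np.where(n_valid > 0, (calls == 1).sum(axis=0) / n_valid, np.nan)
    return PerLocusStat(ho, float(np.nanmean(ho)))


def expected_heterozygosity(
    gm: GenotypeMatrix, group=None, loci=None, unbiased: bool = False
) -> PerLocusStat:
    """Hardy-Weinberg expected heterozygosity 2p(1-p) per locus.

    With ``unbiased`` the Nei small-sample correction 2n/(2n-1) is applied,
    n being the number of valid individuals at that locus.
    """
    p, n_valid = allele_frequencies(gm, group, loci)
    if not (n_valid > 0).any():
        raise ValueError("no locus has a valid call in this group")
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        with np.errstate(divide="ignore", invalid="ignore"):
            he = np.where(n_valid > 0, he * 2 * n_valid / (2 * n_valid - 1), np.nan)
    return PerLocusStat(he, float(np.nanmean(he)))


def polymorphic_loci_pct(gm: GenotypeMatrix, group=None, loci=None) -> float:
    """Percentage of loci at which both alleles are observed in the group.

    Denominator: loci in the subset with at least one valid call.
    """
    p, n_valid = allele_frequencies(gm, group, loci)
    informative = n_valid > 0
    if not informative.any():
        raise ValueError("no locus has a valid call in this group")
    poly = (p > 0) & (p < 1) & informative
    return 100.0 * poly.sum() / informative.sum()


def rarefied_allelic_richness(
    gm: GenotypeMatrix,
    groups: Mapping[str, np.ndarray],
    loci=None,
    g: int | None = None,
) -> pd.Series:
    """Rarefied allelic richness per group at a common gene-copy depth ``g``.

    Per locus the expected allele count in a without-replacement draw of
    ``g`` gene copies is ``sum_a [1 - C(N - N_a, g) / C(N, g)]`` where ``N``
    is the number of valid copies and ``N_a`` the copies of allele ``a``.
    ``g`` defaults to the smallest valid gene-copy count over all
    (group, locus) cells so every group is rarefied to the same depth; loci
    with fewer than ``g`` copies in any group are dropped from the mean.
    """
    if g is not None and g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    freqs = {name: allele_frequencies(gm, idx, loci) for name, idx in groups.items()}
    copies = np.vstack([2 * af.n_valid for af in freqs.values()])
    if g is None:
        positive = copies[copies > 0]
        if positive.size == 0:
            raise ValueError("no valid gene copies in any group")
        g = int(positive.min())
        g = max(g, 2)
    usable = (copies >= g).all(axis=0)
    if not usable.any():
        raise ValueError(f"rarefaction size g={g} exceeds every locus's copy count")
    out = {}
    for name, af in freqs.items():
        n_copies = 2 * af.n_valid[usable]
        alt = np.rint(af.p[usable] * n_copies).astype(int)
        counts = np.stack([n_copies - alt, alt])  # ref, alt copies
        ar = np.zeros(counts.shape[1])
        for allele_counts in counts:
            ar += 1.0 - _hypergeom_absent(allele_counts, n_copies, g)
        out[name] = float(ar.mean())
    return pd.Series(out, name="AR")


def _hypergeom_absent(n_allele: np.ndarray, n_total: np.ndarray, g: int) -> np.ndarray:
    """P(allele absent from a without-replacement draw of g copies).

    C(N - Na, g) / C(N, g), evaluated in log space; 0 where N - Na < g.
    """
    rest = n_total - n_allele
    with np.errstate(invalid="ignore"):
        logp = (
            gammaln(rest + 1)
            - gammaln(rest - g + 1)
            + gammaln(n_total - g + 1)
            - gammaln(n_total + 1)
        )
    return np.where(rest >= g, np.exp(logp), 0.0)


def private_alleles_pct(
    gm: GenotypeMatrix, groups: Mapping[str, np.ndarray], loci=None
) -> pd.Series:
    """Percentage of subset loci with an allele private to each group.

    An allele is private to a group when it is observed there and in no
    other group; the denominator is the number of loci in the subset.
    """
    if len(groups) < 2:
        raise ValueError("private alleles require at least two groups")
    presence = {}
    n_loci = None
    for name, idx in groups.items():
        p, n_valid = allele_frequencies(gm, idx, loci)
        seen_ref = (p < 1) & (n_valid > 0)
        seen_alt = (p > 0) & (n_valid > 0)
        presence[name] = np.stack([seen_ref, seen_alt])
        n_loci = p.size
    out = {}
    names = list(groups)
    for name in names:
        others = np.zeros_like(presence[name], dtype=bool)
        for other in names:
            if other != name:
                others |= presence[other]
        private = presence[name] & ~others
        out[name] = 100.0 * private.any(axis=0).sum() / n_loci
    return pd.Series(out, name="PA")


class FisEstimate(NamedTuple):
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    significant: bool


def fis(
    gm: GenotypeMatrix,
    group=None,
    loci=None,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int | None = None,
) -> FisEstimate:
    """Within-group inbreeding coefficient with a bootstrap-over-loci CI.

    FIS = 1 - mean(Ho_l) / mean(uHe_l) over polymorphic loci (ratio of
    means). The CI is the percentile interval of the statistic over
    ``n_boot`` resamples of loci with replacement; the estimate is flagged
    significant when the interval excludes zero.
    """
    ho = observed_heterozygosity(gm, group, loci).per_locus
    uhe = expected_heterozygosity(gm, group, loci, unbiased=True).per_locus
    poly = np.nan_to_num(uhe) > 0
    if poly.sum() < 2:
        raise ValueError("FIS undefined: fewer than two polymorphic loci in group")
    ho, uhe = ho[poly], uhe[poly]
    point = 1.0 - ho.mean() / uhe.mean()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ho.size, size=(n_boot, ho.size))
    boots = 1.0 - ho[idx].mean(axis=1) / uhe[idx].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return FisEstimate(float(point), float(lo), float(hi), n_boot,
                       bool(lo > 0 or hi < 0))


@dataclass
class DiversityConfig:
    n_boot_fis: int = 1000
    ci: float = 0.95
    rarefaction_g: int | None = None
    seed: int = 0


def diversity_report(
    gm: GenotypeMatrix,
    grouping: str | Sequence[str] = ("population", "cohort"),
    partition: Mapping[str, Sequence[str]] | None = None,
    config: DiversityConfig | None = None,
    stratify_ages: bool = True,
) -> pd.DataFrame:
    """Full diversity panel: one row per group x locus subset (x age stratum).

    ``partition`` maps subset labels (e.g. neutral / provenance / hatchery)
    to locus-ID lists; ``None`` computes a single "all" subset. PA and AR
    compare the groups defined by ``grouping`` within each subset. Hatchery
    groups are additionally stratified by age in months when available.
    """
    config = config or DiversityConfig()
    if isinstance(grouping, str):
        grouping = [grouping]
    subsets: dict[str, np.ndarray] = (
        {"all": np.arange(gm.n_loci)}
        if partition is None
        else {k: gm.loci_index(v) for k, v in partition.items()}
    )
    keys = gm.individuals[list(grouping)].astype(str).agg("/".join, axis=1)
    groups = {k: (keys == k).to_numpy() for k in keys.unique()}

    rows = []
    for subset_name, cols in subsets.items():
        if len(cols) == 0:
            for gname in groups:
                rows.append({"group": gname, "subset": subset_name, "age_months": "all",
                             "n": int(groups[gname].sum()), "empty": True})
            continue
        ar = rarefied_allelic_richness(gm, groups, cols, g=config.rarefaction_g)
        pa = private_alleles_pct(gm, groups, cols)
        for gname, mask in groups.items():
            strata: list[tuple[str, np.ndarray]] = [("all", mask)]
            if stratify_ages and "age_months" in gm.individuals.columns:
                ages = gm.individuals["age_months"]
                for age in sorted(ages[mask].dropna().unique()):
                    sub = mask & (ages == age).fillna(False).to_numpy(dtype=bool)
                    if sub.sum() > 1 and sub.sum() < mask.sum():
                        strata.append((str(int(age)), sub))
            for age_label, sub in strata:
                row = {
                    "group": gname,
                    "subset": subset_name,
                    "age_months": age_label,
                    "n": int(sub.sum()),
                    "empty": False,
                }
                try:
                    row["Ho"] = observed_heterozygosity(gm, sub, cols).mean
                    row["He"] = expected_heterozygosity(gm, sub, cols).mean
                    row["uHe"] = expected_heterozygosity(gm, sub, cols, unbiased=True).mean
                    row["PL_pct"] = polymorphic_loci_pct(gm, sub, cols)
                    f = fis(gm, sub, cols, n_boot=config.n_boot_fis,
                            ci=config.ci, seed=config.seed)
                    row.update(FIS=f.point, FIS_ci_low=f.ci_low,
                               FIS_ci_high=f.ci_high, FIS_significant=f.significant)
                except ValueError:
                    row["empty"] = True
                if age_label == "all":
                    row["AR"] = ar[gname]
                    row["PA_pct"] = pa[gname]
                rows.append(row)
    return pd.DataFrame(rows)
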