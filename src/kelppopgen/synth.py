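"""Synthetic DArTseq-like genotype data with the structure the analysis assumes.

Two wild populations are generated under the Balding-Nichols model (Beta
population frequencies around an ancestral frequency, parameterised by a
target Wright's F), with unequal diversity imposed by shrinking the
ancestral minor-allele-frequency range of one population. Hatchery F1
cohorts are bred from the wild donors with Dirichlet-skewed parental
contributions, elevated selfing and post-hoc allele-frequency shifts at a
small set of designated "hatchery-selected" loci. DArT-style metadata
(read depth, reproducibility, fragment IDs) and missingness are injected
throughout, so every downstream stage of the pipeline is testable without
any data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, concatenate_individuals


@dataclass
class SyntheticConfig:
    """Wild-population generator settings (defaults emulate the study system)."""

    n_pops: int = 2
    n_ind_per_pop: Sequence[int] = (100, 100)
    n_loci: int = 1600
    fst_target: float = 0.08
    maf_lo: float = 0.0005
    maf_hi: float = 0.018
    he_scale: Sequence[float] = (1.0, 1.0)  # per-population ancestral MAF shrink
    missing_rate: float = 0.183
    depth_mean: float = 6.79
    depth_sd: float = 1.0
    reproducibility_min_gen: float = 0.96
    populations: Sequence[str] = ("warm", "cool")
    #: effective size imposed on each wild pool by propagating it this many
    #: generations at constant size before sampling; 0 disables (loci then
    #: carry no background LD and wild LD-Ne estimates diverge)
    wild_ne: int = 500
    ld_generations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        for name in ("missing_rate", "maf_lo", "maf_hi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.n_ind_per_pop) != self.n_pops or len(self.he_scale) != self.n_pops:
            raise ValueError("per-population settings must match n_pops")


@dataclass
class HatcheryConfig:
    """Hatchery F1 breeding settings.

    ``contribution_concentration`` is the symmetric Dirichlet concentration
    of per-donor reproductive weights: small values give few donors most of
    the offspring (strong reproductive skew), large values approach equal
    contributions. ``selected_loci`` lists (locus index, allele-frequency
    shift) pairs emulating hatchery selection.
    """

    n_offspring: int = 50
    contribution_concentration: float = 1.0
    selfing_rate: float = 0.0
    selected_loci: Sequence[tuple[int, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must lie in [0, 1]")
        if self.contribution_concentration <= 0:
            raise ValueError("contribution_concentration must be positive")


def _locus_metadata(n_loci: int, cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    depth = np.clip(rng.normal(cfg.depth_mean, cfg.depth_sd, n_loci), 5.0, 12.0)
    rep = rng.uniform(cfg.reproducibility_min_gen, 1.0, n_loci)
    ids = [f"L{i:05d}" for i in range(n_loci)]
    return pd.DataFrame(
        {"locus_id": ids, "clone_id": ids, "read_depth": depth, "reproducibility": rep}
    )


def _inject_missing(calls: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        calls = calls.copy()
        calls[rng.random(calls.shape) < rate] = MISSING
    return calls


def population_frequencies(
    cfg: SyntheticConfig, rng: np.random.Generator, n_loci: int | None = None
) -> np.ndarray:
    """Balding-Nichols per-population alternate-allele frequencies.

    Ancestral p ~ Uniform(maf_lo, maf_hi) per locus (scaled per population
    by he_scale); population frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = fst_target, or exactly the ancestral frequency when F = 0.
    """
    n_loci = cfg.n_loci if n_loci is None else n_loci
    p_anc = rng.uniform(cfg.maf_lo, cfg.maf_hi, n_loci)
    freqs = np.empty((cfg.n_pops, n_loci))
    f = cfg.fst_target
    for k in range(cfg.n_pops):
        pk = np.clip(p_anc * cfg.he_scale[k], 1e-6, 1 - 1e-6)
        if f == 0:
            freqs[k] = pk
        else:
            ratio = (1.0 - f) / f
            freqs[k] = rng.beta(pk * ratio, (1.0 - pk) * ratio)
    return freqs


def genotypes_from_frequencies(
    freqs: np.ndarray, n_ind: int, rng: np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg dosages: binomial(2, p) per individual per locus."""
    return rng.binomial(2, np.broadcast_to(freqs, (n_ind, freqs.size))).astype(np.int8)


def generate_wild_populations(
    cfg: SyntheticConfig | None = None,
    frequencies: np.ndarray | None = None,
    ascertain_pooled_maf_min: float | None = None,
    keep_loci: np.ndarray | None = None,
    candidate_factor: int = 6,
) -> GenotypeMatrix:
    """Two (or more) wild populations under the Balding-Nichols model.

    ``frequencies`` overrides the model draw (used by the full-study
    scenario to plant provenance-divergent loci). With
    ``ascertain_pooled_maf_min`` the generator emulates SNP discovery:
    ``candidate_factor`` x n_loci candidate loci are generated (through the
    shared burn-in pedigree, so selection does not disturb LD) and the
    panel keeps only loci whose pooled observed MAF exceeds the threshold,
    mirroring a marker panel that is polymorphic by construction.
    ``keep_loci`` indexes candidate columns retained unconditionally; the
    returned locus table records each locus's candidate column in
    ``candidate_index``.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    ascertain = ascertain_pooled_maf_min is not None
    n_cand = cfg.n_loci * (candidate_factor if ascertain else 1)
    if frequencies is None:
        freqs = population_frequencies(cfg, rng, n_cand)
    else:
        freqs = np.asarray(frequencies, dtype=float)
        n_cand = freqs.shape[1]
    blocks, meta = [], []
    for k, (n_ind, pop) in enumerate(zip(cfg.n_ind_per_pop, cfg.populations)):
        if cfg.ld_generations > 0:
            # breed the pool at constant size wild_ne for a few generations so
            # sampled genotypes carry background LD consistent with that Ne
            from .simulate import assign_sexes, mate_randomly

            pool = genotypes_from_frequencies(freqs[k], cfg.wild_ne, rng)
            for _ in range(cfg.ld_generations):
                d, s = assign_sexes(pool.shape[0], rng)
                pool = mate_randomly(pool[d], pool[s], cfg.wild_ne, rng)
            calls = pool[rng.choice(cfg.wild_ne, n_ind, replace=False)]
        else:
            calls = genotypes_from_frequencies(freqs[k], n_ind, rng)
        calls = _inject_missing(calls, cfg.missing_rate, rng)
        blocks.append(calls)
        meta.append(
            pd.DataFrame(
                {
                    "individual_id": [f"{pop}_wild_{i:03d}" for i in range(n_ind)],
                    "population": pop,
                    "cohort": "wild",
                    "age_months": pd.array([pd.NA] * n_ind, dtype="Int64"),
                }
            )
        )
    calls = np.vstack(blocks)

    if ascertain:
        valid = calls != MISSING
        n_valid = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(valid, calls, 0).sum(axis=0) / (2 * n_valid)
        maf = np.minimum(p, 1 - p)
        passing = np.nan_to_num(maf) > ascertain_pooled_maf_min
        keep_loci = (
            np.asarray(keep_loci, dtype=int) if keep_loci is not None
            else np.empty(0, dtype=int)
        )
        background = np.setdiff1d(np.flatnonzero(passing), keep_loci)
        n_background = cfg.n_loci - keep_loci.size
        if background.size < n_background:
            raise ValueError(
                f"only {background.size + keep_loci.size} candidate loci pass "
                f"pooled MAF > {ascertain_pooled_maf_min}; raise candidate_factor"
            )
        selected = np.sort(
            np.concatenate([keep_loci, background[:n_background]])
        )
        calls = calls[:, selected]
    else:
        selected = np.arange(n_cand)

    loci = _locus_metadata(calls.shape[1], cfg, rng)
    loci["candidate_index"] = selected
    return GenotypeMatrix(calls, pd.concat(meta, ignore_index=True), loci)


def generate_hatchery_cohort(
    donors: GenotypeMatrix,
    hcfg: HatcheryConfig,
    missing_rate: float = 0.0,
    label: str | None = None,
) -> GenotypeMatrix:
    """Mass-spawned F1 cohort from a donor pool.

    Per offspring a dam and a sire are drawn with Dirichlet-weighted
    probabilities (the same individual serves as both with probability
    ``selfing_rate``), alleles transmit Mendelian-fashion per unlinked
    locus, and designated selected loci are then resampled from shifted
    frequencies. Offspring are labelled cohort="hatchery" with ages
    assigned round-robin over 5, 7, 9 months.
    """
    if donors.n_individuals < 2:
        raise ValueError("need >= 2 donors to breed a cohort")
    rng = np.random.default_rng(hcfg.seed)
    pool = donors.calls.astype(float)
    miss = pool == MISSING
    if miss.any():  # impute from donor pool frequencies
        valid = ~miss
        p = np.where(valid, pool, 0).sum(0) / np.maximum(2 * valid.sum(0), 1)
        fill = rng.binomial(2, np.broadcast_to(p, pool.shape))
        pool[miss] = fill[miss]
    pool = pool.astype(np.int8)

    weights = rng.dirichlet(
        np.full(donors.n_individuals, hcfg.contribution_concentration)
    )
    n = hcfg.n_offspring
    dam = rng.choice(donors.n_individuals, size=n, p=weights)
    sire = rng.choice(donors.n_individuals, size=n, p=weights)
    selfed = rng.random(n) < hcfg.selfing_rate
    sire[selfed] = dam[selfed]
    gametes_d = rng.binomial(1, pool[dam] / 2.0)
    gametes_s = rng.binomial(1, pool[sire] / 2.0)
    calls = (gametes_d + gametes_s).astype(np.int8)

    for locus, delta in hcfg.selected_loci:
        p0 = calls[:, locus].mean() / 2.0
        p_shift = float(np.clip(p0 + delta, 0.0, 1.0))
        calls[:, locus] = rng.binomial(2, p_shift, size=n).astype(np.int8)

    calls = _inject_missing(calls, missing_rate, rng)
    pop = donors.individuals["population"].iloc[0]
    label = label or str(pop)
    ages = np.array([5, 7, 9], dtype=int)[np.arange(n) % 3]
    donor_ids = donors.individual_ids
    individuals = pd.DataFrame(
        {
            "individual_id": [f"{label}_hatchery_{i:03d}" for i in range(n)],
            "population": pop,
            "cohort": "hatchery",
            "age_months": pd.array(ages, dtype="Int64"),
            "dam_id": donor_ids[dam],
            "sire_id": donor_ids[sire],
        }
    )
    return GenotypeMatrix(calls, individuals, donors.loci)


@dataclass
class StudyBundle:
    """Synthetic full-study dataset: four cohorts plus ground truth."""

    genotypes: GenotypeMatrix  # all cohorts stacked, shared loci
    manifest: dict

    def cohort(self, population: str, cohort: str) -> GenotypeMatrix:
        return self.genotypes.take_individuals(
            self.genotypes.select_individuals(population=population, cohort=cohort)
        )


def _scenario_frequencies(
    rng: np.random.Generator,
    n_loci: int,
    freq_scale: float,
    divergence_mix: float,
    he_scale: Sequence[float],
    common_fraction: float = 0.12,
    common_fst: float = 0.20,
    common_maf: tuple[float, float] = (0.02, 0.10),
) -> np.ndarray:
    """Two-class frequency model for the full-study panel.

    A small *common* class (ancestral MAF uniform on ``common_maf``,
    Balding-Nichols divergence at ``common_fst``) carries most of the
    between-population variance and therefore dominates the ratio-of-sums
    theta, while the *rare* bulk -- frequency ``scale * ((1-d) u + d e_pop)``
    with ``u`` shared and ``e_pop`` private standard-exponential components
    -- sets mean heterozygosity and within-population polymorphism. A
    single-class model cannot meet the study panel's joint conditions
    (every locus polymorphic, He ~0.017/0.006, theta ~0.08): that much
    relative frequency variance at that little diversity forces widespread
    in-sample monomorphism.
    """
    n_common = int(round(common_fraction * n_loci))
    is_common = np.zeros(n_loci, dtype=bool)
    is_common[rng.choice(n_loci, n_common, replace=False)] = True

    u = rng.exponential(1.0, n_loci)
    p_anc = rng.uniform(*common_maf, n_loci)
    ratio = (1.0 - common_fst) / common_fst
    freqs = np.empty((len(he_scale), n_loci))
    for k, scale_k in enumerate(he_scale):
        e = rng.exponential(1.0, n_loci)
        rare = freq_scale * scale_k * (
            (1.0 - divergence_mix) * u + divergence_mix * e
        )
        pk = np.clip(p_anc * scale_k, 1e-6, 1 - 1e-6)
        common = rng.beta(pk * ratio, (1.0 - pk) * ratio)
        freqs[k] = np.clip(np.where(is_common, common, rare), 0.0, 0.5)
    return freqs, is_common


# Scenario constants: two differentiated wild populations with contrasting
# diversity (He ratio ~2-3x, multi-locus theta ~0.08), F1 cohorts of 62
# (warm, strong skew) and 36 (cool, moderate skew), 27 provenance-divergent
# and 15 hatchery-selected loci.
SCENARIO = {
    "n_wild": (100, 100),
    "n_hatchery": {"warm": 62, "cool": 36},
    "fst_target": 0.075,  # used by the generic BN generator path
    "he_scale": (0.36, 1.0),  # warm shrunk -> lower diversity
    "freq_scale": 0.0013,  # cool-population mean rare-class allele frequency
    "divergence_mix": 0.35,  # private-component weight of the rare class
    "common_fraction": 0.06,  # share of the panel in the common divergent class
    "common_fst": 0.16,  # Balding-Nichols F of the common class
    "n_provenance_loci": 27,
    "n_hatchery_loci": 15,
    "provenance_delta": 0.15,
    "hatchery_delta": 0.30,
    "concentration": {"warm": 0.12, "cool": 0.55},
    "selfing": {"warm": 0.15, "cool": 0.05},
    "ld_generations": 6,
    "wild_ne": 500,  # latent wild pool size during the LD burn-in
    "candidate_factor": 8,  # candidate loci drawn per panel locus
    # SNP-discovery ascertainment: every panel locus is observed polymorphic
    # in the pooled wild sample (matching an all-polymorphic final panel)
    "ascertain_maf_min": 0.0,
}


def scenario_full_study(seed: int = 0) -> StudyBundle:
    """One call yields a dataset shaped like the hatchery study.

    Warm and cool wild pools (n = 100 each) with contrasting diversity and
    divergence at 27 designated provenance loci; hatchery F1 cohorts of 62
    (warm) and 36 (cool) bred with skewed contributions, selfing, and
    shifted frequencies at 15 designated hatchery-selected loci.
    """
    sc = SCENARIO
    rng = np.random.default_rng(seed)
    cfg = SyntheticConfig(
        n_ind_per_pop=sc["n_wild"],
        fst_target=sc["fst_target"],
        he_scale=sc["he_scale"],
        ld_generations=sc["ld_generations"],
        wild_ne=sc["wild_ne"],
        seed=int(rng.integers(2**31)),
    )
    n_cand = cfg.n_loci * sc["candidate_factor"]
    freqs, is_common = _scenario_frequencies(
        np.random.default_rng(cfg.seed), n_cand,
        sc["freq_scale"], sc["divergence_mix"], sc["he_scale"],
        common_fraction=sc["common_fraction"] * 2,  # excess candidates per class
        common_fst=sc["common_fst"],
    )

    # plant provenance-divergent candidate loci: common in one population,
    # rare in the other
    prov_cand = np.sort(rng.choice(n_cand, sc["n_provenance_loci"], replace=False))
    base = rng.uniform(0.02, 0.10, prov_cand.size)
    high_pop = rng.integers(0, 2, prov_cand.size)  # which population carries it
    for j, locus in enumerate(prov_cand):
        freqs[:, locus] = base[j]
        freqs[high_pop[j], locus] = base[j] + sc["provenance_delta"]
    is_common[prov_cand] = False  # panel quotas count planted loci separately

    candidates = generate_wild_populations(cfg, frequencies=freqs)

    # panel ascertainment: keep the planted loci plus per-class quotas of
    # loci observed polymorphic in the pooled wild sample
    from .genotypes import minor_allele_frequency

    maf = minor_allele_frequency(candidates)
    observed = np.nan_to_num(maf) > 0
    n_common_panel = int(round(sc["common_fraction"] * cfg.n_loci))
    n_rare_panel = cfg.n_loci - n_common_panel - prov_cand.size
    pool_common = np.flatnonzero(observed & is_common)
    pool_rare = np.setdiff1d(
        np.flatnonzero(observed & ~is_common), prov_cand
    )
    if pool_common.size < n_common_panel or pool_rare.size < n_rare_panel:
        raise ValueError("too few polymorphic candidate loci; raise n_cand")
    selected = np.sort(np.concatenate([
        prov_cand,
        pool_common[:n_common_panel],
        pool_rare[:n_rare_panel],
    ]))
    wild = candidates.take_loci(selected)
    prov_idx = np.flatnonzero(np.isin(selected, prov_cand))
    # designate hatchery-selected loci among the background panel
    background = np.setdiff1d(np.arange(wild.n_loci), prov_idx)
    hatch_idx = np.sort(rng.choice(background, sc["n_hatchery_loci"], replace=False))

    cohorts = [wild]
    for pop in ("warm", "cool"):
        donors = wild.take_individuals(wild.select_individuals(population=pop))
        hcfg = HatcheryConfig(
            n_offspring=sc["n_hatchery"][pop],
            contribution_concentration=sc["concentration"][pop],
            selfing_rate=sc["selfing"][pop],
            selected_loci=[(int(l), sc["hatchery_delta"]) for l in hatch_idx],
            seed=int(rng.integers(2**31)),
        )
        cohorts.append(
            generate_hatchery_cohort(donors, hcfg, missing_rate=cfg.missing_rate)
        )
    genotypes = concatenate_individuals(cohorts)
    manifest = {
        "seed": seed,
        "fst_target": sc["fst_target"],
        "he_scale": list(sc["he_scale"]),
        "provenance_loci": [wild.locus_ids[i] for i in prov_idx],
        "hatchery_loci": [wild.locus_ids[i] for i in hatch_idx],
        "n_per_cohort": {
            "warm/wild": sc["n_wild"][0],
            "cool/wild": sc["n_wild"][1],
            "warm/hatchery": sc["n_hatchery"]["warm"],
            "cool/hatchery": sc["n_hatchery"]["cool"],
        },
        "concentration": sc["concentration"],
        "selfing": sc["selfing"],
    }
    return StudyBundle(genotypes=genotypes, manifest=manifest)
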