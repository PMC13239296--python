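"""Forward-in-time simulation of restored kelp populations.

Donors sampled from a wild pool found a closed population that random-mates
under a 1:1 sex ratio (diploid, unlinked biallelic loci, Mendelian
transmission, no mutation / selection / migration). A donor-number sweep
with bootstrap replication summarises expected heterozygosity (2pq) and the
percentage of polymorphic loci at generation checkpoints, quantifying how
many donors are needed to retain diversity over restored generations.
The simulator is validated against the closed-form drift decay
He_t = He_0 * (1 - 1/(2 Ne))^t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, allele_frequencies


DEFAULT_DONOR_COUNTS = (2, 4, 6, 8, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)


@dataclass
class SimulationConfig:
    donor_counts: Sequence[int] = DEFAULT_DONOR_COUNTS
    n_offspring: int = 500
    generations: int = 100
    checkpoints: Sequence[int] = (1, 3, 10, 100)
    n_boot: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.donor_counts) < 2:
            raise ValueError("donor counts must be >= 2")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if any(c < 1 or c > self.generations for c in self.checkpoints):
            raise ValueError("checkpoints must lie within [1, generations]")


@dataclass
class SimulationResult:
    """Mean +/- SE of He and PL per (donor count, checkpoint) over bootstraps."""

    table: pd.DataFrame  # donor_count, checkpoint, metric, mean, se, n_boot
    trajectories: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# elementary operations (complete dosage arrays)
# ---------------------------------------------------------------------------


def assign_sexes(n_parents: int, rng: np.random.Generator):
    """Seeded shuffle-and-split into (dam indices, sire indices).

    Odd counts put the extra individual on the dam side.
    """
    if n_parents < 2:
        raise ValueError("need >= 2 parents to assign sexes")
    order = rng.permutation(n_parents)
    n_dams = (n_parents + 1) // 2
    return order[:n_dams], order[n_dams:]


def _gametes(parent_dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One allele per locus per row: P(alt) = dosage / 2."""
    return rng.binomial(1, parent_dosages / 2.0).astype(np.int8)


def mate_randomly(
    dams: np.ndarray, sires: np.ndarray, n_offspring: int, rng: np.random.Generator
) -> np.ndarray:
    """Random-mating offspring dosages from complete parental dosage arrays.

    Each offspring draws a dam and a sire uniformly and independently and
    receives one Mendelian allele from each per (unlinked) locus.
    """
    if len(dams) == 0 or len(sires) == 0:
        raise ValueError("both dams and sires must be non-empty")
    di = rng.integers(0, len(dams), size=n_offspring)
    si = rng.integers(0, len(sires), size=n_offspring)
    return _gametes(dams[di], rng) + _gametes(sires[si], rng)


def impute_missing(calls: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace MISSING donor calls by draws from the pool allele frequency.

    Transmission needs complete genotypes; each missing call becomes a
    binomial(2, p) dosage at that locus's pooled alternate-allele frequency.
    """
    calls = np.asarray(calls, dtype=np.int8).copy()
    miss = calls == MISSING
    if not miss.any():
        return calls
    valid = ~miss
    n_valid = valid.sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0)
    p = np.where(n_valid > 0, alt / np.maximum(2 * n_valid, 1), 0.0)
    fill = rng.binomial(2, np.broadcast_to(p, calls.shape)).astype(np.int8)
    calls[miss] = fill[miss]
    return calls


def _he_pl(dosages: np.ndarray) -> tuple[float, float]:
    """Mean 2pq over loci and percent polymorphic loci of a population."""
    p = dosages.mean(axis=0) / 2.0
    he = float(np.mean(2.0 * p * (1.0 - p)))
    pl = float(100.0 * np.mean((p > 0) & (p < 1)))
    return he, pl


def simulate_generations(
    donors: np.ndarray,
    n_offspring: int,
    generations: int,
    checkpoints: Iterable[int],
    rng: np.random.Generator,
    keep_genotypes: bool = False,
) -> dict[int, dict]:
    """Propagate a closed population and summarise it at checkpoints.

    Generation 1 random-mates the donors; every later generation
    random-mates the previous generation's ``n_offspring`` individuals with
    sexes reassigned each generation. Returns {generation: {"he", "pl"
    [, "dosages"]}}.
    """
    checkpoints = sorted(set(checkpoints))
    if checkpoints and checkpoints[-1] > generations:
        raise ValueError("checkpoint beyond the simulated horizon")
    current = np.asarray(donors, dtype=np.int8)
    out: dict[int, dict] = {}
    last = max(checkpoints) if checkpoints else generations
    for gen in range(1, last + 1):
        dam_idx, sire_idx = assign_sexes(current.shape[0], rng)
        current = mate_randomly(current[dam_idx], current[sire_idx], n_offspring, rng)
        if gen in checkpoints:
            he, pl = _he_pl(current)
            record = {"he": he, "pl": pl}
            if keep_genotypes:
                record["dosages"] = current.copy()
            out[gen] = record
    return out


# ---------------------------------------------------------------------------
# donor sweep
# ---------------------------------------------------------------------------


def donor_sweep(
    wild: GenotypeMatrix | np.ndarray,
    cfg: SimulationConfig | None = None,
    keep_trajectories: bool = False,
) -> SimulationResult:
    """Sweep donor counts with bootstrap replication over donor draws.

    Per donor count and bootstrap replicate, donors are drawn without
    replacement from the wild pool (missing calls imputed from pool
    frequencies), the closed population is propagated, and He / PL recorded
    at each checkpoint. RNG streams are split hierarchically
    (sweep -> donor count -> bootstrap) so adding donor counts leaves other
    cells unchanged.
    """
    cfg = cfg or SimulationConfig()
    if isinstance(wild, GenotypeMatrix):
        pool = wild.calls
    else:
        pool = np.asarray(wild, dtype=np.int8)
    if max(cfg.donor_counts) > pool.shape[0]:
        raise ValueError(
            f"largest donor count {max(cfg.donor_counts)} exceeds pool size {pool.shape[0]}"
        )
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    raw = [] if keep_trajectories else None
    for donor_ss, n_donors in zip(root.spawn(len(cfg.donor_counts)), cfg.donor_counts):
        per_boot: dict[int, dict[str, list[float]]] = {
            cp: {"he": [], "pl": []} for cp in cfg.checkpoints
        }
        for boot_ss in donor_ss.spawn(cfg.n_boot):
            rng = np.random.default_rng(boot_ss)
            chosen = rng.choice(pool.shape[0], size=n_donors, replace=False)
            donors = impute_missing(pool[chosen], rng)
            summaries = simulate_generations(
                donors, cfg.n_offspring, cfg.generations, cfg.checkpoints, rng
            )
            for cp, rec in summaries.items():
                per_boot[cp]["he"].append(rec["he"])
                per_boot[cp]["pl"].append(rec["pl"])
                if raw is not None:
                    raw.append(
                        {"donor_count": n_donors, "checkpoint": cp,
                         "he": rec["he"], "pl": rec["pl"]}
                    )
        for cp in cfg.checkpoints:
            for metric in ("he", "pl"):
                vals = np.asarray(per_boot[cp][metric])
                rows.append(
                    {
                        "donor_count": n_donors,
                        "checkpoint": cp,
                        "metric": "He" if metric == "he" else "PL",
                        "mean": float(vals.mean()),
                        "se": float(vals.std(ddof=1) / np.sqrt(vals.size))
                        if vals.size > 1
                        else 0.0,
                        "n_boot": int(vals.size),
                    }
                )
    return SimulationResult(
        table=pd.DataFrame(rows),
        trajectories=pd.DataFrame(raw) if raw is not None else None,
    )


def expected_he_decay(he0: float, n_dams: int, n_sires: int, t: int) -> float:
    """Closed-form neutral drift decay of expected heterozygosity.

    Ne = 4 Nd Ns / (Nd + Ns) for separate sexes; returns
    he0 * (1 - 1/(2 Ne))^t.
    """
    if n_dams < 1 or n_sires < 1:
        raise ValueError("need at least one parent of each sex")
    ne = 4.0 * n_dams * n_sires / (n_dams + n_sires)
    return float(he0 * (1.0 - 1.0 / (2.0 * ne)) ** t)
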