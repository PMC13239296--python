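"""Population structure and outlier detection.

Weir & Cockerham (1984) theta with a bootstrap over loci and
Benjamini-Hochberg correction across pairs, principal coordinates analysis
on bitwise (allele-sharing) distances, redundancy-analysis outlier scans
against binary predictors, and partitioning of loci into neutral /
provenance-associated / hatchery-associated subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING, GenotypeMatrix, _resolve_group, _resolve_loci


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


class WcComponents(NamedTuple):
    """Per-locus variance components: a (among populations), b (among
    individuals within populations), c (within individuals)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta(self) -> float:
        """Multi-locus ratio-of-sums estimate sum(a) / sum(a+b+c)."""
        denom = np.nansum(self.a + self.b + self.c)
        if denom == 0:
            return np.nan
        return float(np.nansum(self.a) / denom)


def wc_theta(gm: GenotypeMatrix, group_a, group_b, loci=None) -> WcComponents:
    """Weir & Cockerham (1984) variance components for two groups.

    Components are computed per locus from genotype counts (two alleles,
    r = 2 populations); loci where either group has fewer than two valid
    individuals are dropped (NaN components). Negative multi-locus theta
    is reported as computed.
    """
    cols = _resolve_loci(gm, loci)
    stats = []
    for group in (group_a, group_b):
        rows = _resolve_group(gm, group)
        calls = gm.calls[np.ix_(rows, cols)]
        valid = calls != MISSING
        n = valid.sum(axis=0).astype(float)  # individuals
        alt = np.where(valid, calls, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
            h = np.where(n > 0, np.where(valid, calls == 1, False).sum(axis=0) / n, np.nan)
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        raise ValueError("a group has < 2 valid individuals at every locus")

    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    return WcComponents(a, b, c)


@dataclass
class FstResult:
    pair: tuple[str, str]
    theta: float
    n_boot: int
    ci_low: float
    ci_high: float
    p_value: float
    p_adjusted: float = np.nan
    subset: str = "all"


def pairwise_fst(
    gm: GenotypeMatrix,
    grouping: str | Mapping[str, np.ndarray] = "population",
    loci=None,
    n_boot: int = 999,
    ci: float = 0.95,
    seed: int | None = None,
    subset_label: str = "all",
) -> list[FstResult]:
    """Pairwise multi-locus theta with bootstrap CIs and BH-adjusted p.

    The bootstrap resamples loci with replacement and recomputes the
    ratio-of-sums theta; p = (1 + #{theta_boot <= 0}) / (n_boot + 1) is a
    one-tailed test of differentiation; Benjamini-Hochberg adjustment runs
    across all pairs computed in this call.
    """
    if isinstance(grouping, str):
        keys = gm.individuals[grouping].astype(str)
        groups = {k: (keys == k).to_numpy() for k in sorted(keys.unique())}
    else:
        groups = dict(grouping)
    names = list(groups)
    if len(names) < 2:
        raise ValueError("pairwise FST requires >= 2 groups")
    rng = np.random.default_rng(seed)
    results = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            comp = wc_theta(gm, groups[names[i]], groups[names[j]], loci)
            usable = ~np.isnan(comp.a)
            av, tv = comp.a[usable], (comp.a + comp.b + comp.c)[usable]
            idx = rng.integers(0, av.size, size=(n_boot, av.size))
            with np.errstate(invalid="ignore", divide="ignore"):
                boots = av[idx].sum(axis=1) / tv[idx].sum(axis=1)
            alpha = (1.0 - ci) / 2.0
            lo, hi = np.nanquantile(boots, [alpha, 1.0 - alpha])
            p = (1.0 + np.sum(boots <= 0.0)) / (n_boot + 1.0)
            results.append(
                FstResult((names[i], names[j]), comp.theta, n_boot,
                          float(lo), float(hi), float(p), subset=subset_label)
            )
    _, p_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    for res, adj in zip(results, p_adj):
        res.p_adjusted = float(adj)
    return results


def fst_table(results: Sequence[FstResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_a": [r.pair[0] for r in results],
            "group_b": [r.pair[1] for r in results],
            "subset": [r.subset for r in results],
            "theta": [r.theta for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p_value for r in results],
            "p_adj": [r.p_adjusted for r in results],
        }
    )


# ---------------------------------------------------------------------------
# bitwise distance + PCoA
# ---------------------------------------------------------------------------


def bitwise_distance(gm: GenotypeMatrix, loci=None) -> np.ndarray:
    """Mean per-locus absolute dosage difference / 2 over shared loci.

    Range [0, 1]; 0 for identical genotypes, 1 for opposite homozygotes at
    every shared locus. Pairs sharing no loci are NaN; an individual with
    no valid calls at all raises.
    """
    cols = _resolve_loci(gm, loci)
    calls = gm.calls[:, cols].astype(float)
    valid = calls != MISSING
    no_calls = ~valid.any(axis=1)
    if no_calls.any():
        bad = gm.individual_ids[no_calls]
        raise ValueError(f"individuals with no valid calls: {list(bad[:5])}")
    if gm.n_individuals < 2:
        raise ValueError("bitwise distance requires >= 2 individuals")
    x = np.where(valid, calls, 0.0)
    v = valid.astype(float)
    # sum over shared loci of |xi - xj| decomposes over dosage categories
    n_shared = v @ v.T
    dist = np.zeros_like(n_shared)
    for di in (0, 1, 2):
        for dj in (0, 1, 2):
            if di >= dj:
                continue
            a = ((calls == di) & valid).astype(float)
            b = ((calls == dj) & valid).astype(float)
            dist += abs(di - dj) * (a @ b.T + b @ a.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = dist / (2.0 * n_shared)
    out[n_shared == 0] = np.nan
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class PcoaResult:
    coordinates: np.ndarray  # individuals x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, decreasing (negatives included)
    pct_variance: np.ndarray  # % of positive-eigenvalue variance per retained axis


def pcoa(distance: np.ndarray, n_axes: int | None = None) -> PcoaResult:
    """Classical scaling (Gower 1966): double-centre -D^2/2, eigendecompose.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); axes with
    negative eigenvalues are reported in ``eigenvalues`` but dropped from
    the coordinates. Axis signs are arbitrary.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > 1e-12 * max(eigval.max(), 1.0)
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    total = eigval[positive].sum()
    pct = 100.0 * eigval[positive][: coords.shape[1]] / total if total > 0 else np.zeros(coords.shape[1])
    return PcoaResult(coords, eigval, pct)


# ---------------------------------------------------------------------------
# RDA outlier scan
# ---------------------------------------------------------------------------


@dataclass
class RdaResult:
    predictor: str
    locus_ids: np.ndarray
    loadings: np.ndarray
    z_scores: np.ndarray
    outlier: np.ndarray
    sd_threshold: float
    variance_explained: float  # proportion of genotypic variance


def rda_scan(
    gm: GenotypeMatrix,
    predictor: str | np.ndarray,
    loci=None,
    sd_threshold: float = 3.0,
    scale: bool = False,
    group=None,
) -> RdaResult:
    """Redundancy-analysis outlier scan against one binary predictor.

    Missing calls are imputed with the per-locus mean dosage (imputation is
    confined to this ordination and never leaks into diversity statistics),
    genotype columns are centred (optionally standardised with ``scale``),
    each locus is regressed on the dummy-coded predictor, and the
    constrained axis is taken from the singular decomposition of the
    fitted-value matrix. Loadings are locus scores on that axis; loci with
    |z| > ``sd_threshold`` (z over loci) are flagged as outliers.
    """
    rows = _resolve_group(gm, group)
    cols = _resolve_loci(gm, loci)
    if isinstance(predictor, str):
        name = predictor
        values = gm.individuals[predictor].to_numpy()[rows]
    else:
        name = "predictor"
        values = np.asarray(predictor)[rows]
    levels = pd.unique(values)
    if len(levels) != 2:
        raise ValueError(f"predictor must be binary with both levels present, got {levels}")
    dummy = (values == levels[1]).astype(float)

    calls = gm.calls[np.ix_(rows, cols)].astype(float)
    calls[calls == MISSING] = np.nan
    col_mean = np.nanmean(calls, axis=0)
    inds = np.where(np.isnan(calls))
    calls[inds] = np.take(col_mean, inds[1])
    x = calls - calls.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd

    d = dummy - dummy.mean()
    denom = (d**2).sum()
    beta = (d @ x) / denom  # per-locus slope on the predictor
    fitted = np.outer(d, beta)
    # rank-1 constrained space: locus scores from the SVD of fitted values
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    loadings = s[0] * vt[0]
    # orient axis consistently (largest-|loading| locus positive)
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
    z = (loadings - loadings.mean()) / loadings.std(ddof=1)
    total_var = (x**2).sum()
    var_explained = float((fitted**2).sum() / total_var) if total_var > 0 else 0.0
    return RdaResult(
        predictor=name,
        locus_ids=gm.locus_ids[cols],
        loadings=loadings,
        z_scores=z,
        outlier=np.abs(z) > sd_threshold,
        sd_threshold=sd_threshold,
        variance_explained=var_explained,
    )


@dataclass
class LocusPartition:
    neutral: list[str]
    provenance: list[str]
    hatchery: list[str]
    overlap: list[str] = field(default_factory=list)

    def sizes(self) -> dict[str, int]:
        return {
            "neutral": len(self.neutral),
            "provenance": len(self.provenance),
            "hatchery": len(self.hatchery),
            "overlap": len(self.overlap),
        }

    def as_mapping(self) -> dict[str, list[str]]:
        return {
            "neutral": self.neutral,
            "provenance": self.provenance,
            "hatchery": self.hatchery,
        }


def partition_loci(rda_provenance: RdaResult, rda_hatchery: RdaResult) -> LocusPartition:
    """Split loci into neutral / provenance / hatchery sets from two scans.

    Neutral is the complement of the union of the two outlier sets; a locus
    flagged by both scans appears in both sets and in ``overlap``.
    """
    if not np.array_equal(rda_provenance.locus_ids, rda_hatchery.locus_ids):
        raise ValueError("RDA results cover different loci")
    ids = rda_provenance.locus_ids
    prov = set(ids[rda_provenance.outlier])
    hatch = set(ids[rda_hatchery.outlier])
    keep_order = list(ids)
    return LocusPartition(
        neutral=[l for l in keep_order if l not in prov | hatch],
        provenance=[l for l in keep_order if l in prov],
        hatchery=[l for l in keep_order if l in hatch],
        overlap=[l for l in keep_order if l in prov & hatch],
    )
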