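"""Effective population size from multilocus genotypes.

Two single-sample estimators: the linkage-disequilibrium method (Burrows
composite r-squared between unlinked locus pairs, with the Waples (2006)
sample-size-corrected expectation and bias-adjusted inversion to Ne) and a
molecular-coancestry method in the spirit of Nomura (2008), where the
effective number of breeders is the reciprocal of twice the mean corrected
coancestry within the cohort.

LD is the default; the random-mating correction is used throughout since
the species mass-spawns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix, _resolve_group, _resolve_loci, \
    minor_allele_frequency


@dataclass
class NeEstimate:
    method: str  # "LD" or "coancestry"
    ne: float  # may be math.inf
    ci_low: float
    ci_high: float
    overall_r2: float = np.nan
    expected_r2: float = np.nan
    harmonic_s: float = np.nan
    n_pairs: int = 0
    maf_cutoff: float = 0.0
    warning: str | None = None


# ---------------------------------------------------------------------------
# Burrows composite r^2
# ---------------------------------------------------------------------------


def burrows_r2(gm: GenotypeMatrix, group=None, loci=None, maf_cutoff: float = 0.0):
    """Pairwise composite LD r^2 between loci from dosage correlations.

    For every locus pair, the Burrows composite disequilibrium is the
    covariance of dosages over individuals non-missing at both loci, and
    r^2 is the squared Pearson correlation of the dosage vectors. Returns
    (r2 matrix, pairwise sample-size matrix) over the loci passing
    ``maf_cutoff``; pairs with < 2 shared individuals or a zero-variance
    locus are NaN.
    """
    rows = _resolve_group(gm, group)
    cols = _resolve_loci(gm, loci)
    maf = minor_allele_frequency(gm, rows, cols)
    usable = np.nan_to_num(maf) > maf_cutoff
    if usable.sum() < 2:
        raise ValueError("fewer than 2 loci pass the MAF cutoff")
    cols = cols[usable]
    calls = gm.calls[np.ix_(rows, cols)].astype(float)
    valid = (calls != MISSING).astype(float)
    x = np.where(valid > 0, calls, 0.0)

    n = valid.T @ valid  # pairwise-complete sample sizes
    sx = x.T @ valid
    sxy = x.T @ x
    sxx_row = (x**2).T @ valid
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var_row = sxx_row / n - (sx / n) ** 2  # var of locus i over pair-complete ind.
        denom = var_row * var_row.T
        # (S/(S-1))^2 matches the Burrows-composite scaling the Waples
        # sampling expectations were calibrated against
        r2 = np.where(denom > 0, (n / (n - 1.0)) ** 2 * cov**2 / denom, np.nan)
    r2[n < 2] = np.nan
    np.fill_diagonal(r2, np.nan)
    return r2, n, cols


def expected_r2_sample(s: float) -> float:
    """Waples (2006) expectation of r^2 from sampling S diploids alone."""
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def _ne_from_r2prime(r2p: float, s: float) -> tuple[float, str | None]:
    """Invert drift r^2 to Ne with Waples' bias-adjusted coefficients."""
    if r2p <= 0:
        return math.inf, None
    if s >= 30:
        k1, k2 = 1.0 / 3.0, 2.76
    else:
        k1, k2 = 0.308, 2.08
    disc = k1**2 - k2 * r2p
    if disc < 0:
        return math.inf, "negative discriminant"
    return (k1 + math.sqrt(disc)) / (2.0 * r2p), None


def ld_ne(
    gm: GenotypeMatrix,
    group=None,
    loci=None,
    maf_cutoff: float = 0.0,
    ci_method: str = "parametric",
    ci: float = 0.95,
    seed: int | None = None,
) -> NeEstimate:
    """LD effective population size (Waples 2006 / NeEstimator conventions).

    Overall r^2 is the pair-sample-size-weighted mean over locus pairs;
    the sampling expectation E[r^2 | S] uses the harmonic mean S over
    pairs; Ne inverts r^2' = r^2 - E[r^2|S]. Non-positive r^2' means no
    drift signal and Ne = +inf. Confidence intervals: ``parametric``
    (chi-square on an n_pairs-equivalent df) or ``jackknife`` (delete-one-
    locus, normal interval on overall r^2).
    """
    r2, n, used_cols = burrows_r2(gm, group, loci, maf_cutoff)
    iu = np.triu_indices_from(r2, k=1)
    r2v, nv = r2[iu], n[iu]
    ok = ~np.isnan(r2v)
    r2v, nv = r2v[ok], nv[ok]
    if r2v.size == 0:
        raise ValueError("no usable locus pairs")
    w = nv
    overall = float(np.average(r2v, weights=w))
    s_harm = float(r2v.size / np.sum(1.0 / nv))
    e_r2 = expected_r2_sample(s_harm)
    ne, warning = _ne_from_r2prime(overall - e_r2, s_harm)

    n_pairs = int(r2v.size)
    if ci_method == "parametric":
        df = n_pairs
        lo_r2 = df * overall / stats.chi2.ppf(1 - (1 - ci) / 2, df)
        hi_r2 = df * overall / stats.chi2.ppf((1 - ci) / 2, df)
    elif ci_method == "jackknife":
        lo_r2, hi_r2 = _jackknife_r2_interval(gm, rows_cols=(group, used_cols), ci=ci)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    # low r^2 -> high Ne, so the interval flips on inversion
    ne_hi, _ = _ne_from_r2prime(lo_r2 - e_r2, s_harm)
    ne_lo, _ = _ne_from_r2prime(hi_r2 - e_r2, s_harm)
    return NeEstimate(
        method="LD",
        ne=ne,
        ci_low=min(ne_lo, ne),
        ci_high=max(ne_hi, ne),
        overall_r2=overall,
        expected_r2=e_r2,
        harmonic_s=s_harm,
        n_pairs=n_pairs,
        maf_cutoff=maf_cutoff,
        warning=warning,
    )


def _jackknife_r2_interval(gm: GenotypeMatrix, rows_cols, ci: float):
    """Delete-one-individual jackknife interval for the overall r^2.

    Individuals, not loci, dominate the sampling noise of the mean pairwise
    r^2 (all pairs share the same individuals), so the resampling unit is
    the individual.
    """
    group, cols = rows_cols
    rows = _resolve_group(gm, group)
    leave = []
    for drop in range(rows.size):
        sub = np.delete(rows, drop)
        try:
            r2, n, _ = burrows_r2(gm, sub, cols, maf_cutoff=0.0)
        except ValueError:
            continue
        iu = np.triu_indices_from(r2, k=1)
        r2v, nv = r2[iu], n[iu]
        ok = ~np.isnan(r2v)
        if ok.any():
            leave.append(float(np.average(r2v[ok], weights=nv[ok])))
    leave = np.asarray(leave)
    m = leave.mean()
    se = math.sqrt((len(leave) - 1) / len(leave) * np.sum((leave - m) ** 2))
    zcrit = stats.norm.ppf(1 - (1 - ci) / 2)
    r2_full, n_full, _ = burrows_r2(gm, rows, cols, maf_cutoff=0.0)
    iu = np.triu_indices_from(r2_full, k=1)
    r2v, nv = r2_full[iu], n_full[iu]
    ok = ~np.isnan(r2v)
    overall = float(np.average(r2v[ok], weights=nv[ok]))
    return overall - zcrit * se, overall + zcrit * se


# ---------------------------------------------------------------------------
# molecular coancestry
# ---------------------------------------------------------------------------


def coancestry_ne(
    gm: GenotypeMatrix, group=None, loci=None, reference=None, ci: float = 0.95
) -> NeEstimate:
    """Effective number of breeders from within-cohort molecular coancestry.

    Per pair of individuals, per-locus allele-sharing similarity
    s = (1/4)(I_ac + I_ad + I_bc + I_bd) is corrected by its expectation
    for unrelated individuals at reference allele frequencies and combined
    over loci as a ratio of sums; Neb = 1 / (2 * mean pairwise coancestry).
    A non-positive mean coancestry gives Neb = +inf. CI: delete-one-
    individual jackknife.

    ``reference`` supplies the baseline allele frequencies: a per-locus
    frequency array, or a group of individuals (e.g. the genotyped donor
    pool, the natural parental reference for a hatchery cohort). With the
    default (the group itself) mean coancestry is self-centred near zero,
    so the estimate reflects only *excess* relatedness over the cohort
    average and is conservative (large) for uniformly related cohorts.
    """
    rows = _resolve_group(gm, group)
    cols = _resolve_loci(gm, loci)
    if rows.size < 2:
        raise ValueError("coancestry Ne requires >= 2 individuals")
    calls = gm.calls[np.ix_(rows, cols)].astype(float)
    valid = calls != MISSING
    if reference is None or not isinstance(reference, np.ndarray) or (
        np.asarray(reference).dtype != float
    ):
        ref_rows = rows if reference is None else _resolve_group(gm, reference)
        ref_calls = gm.calls[np.ix_(ref_rows, cols)]
        ref_valid = ref_calls != MISSING
        n_valid = ref_valid.sum(axis=0)
        alt = np.where(ref_valid, ref_calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_valid > 0, alt / (2 * n_valid), np.nan)
    else:
        p = np.asarray(reference, dtype=float)[_resolve_loci(gm, loci)] if (
            len(np.asarray(reference)) == gm.n_loci
        ) else np.asarray(reference, dtype=float)
    poly = np.nan_to_num(p) * (1 - np.nan_to_num(p)) > 0
    if not poly.any():
        raise ValueError("coancestry Ne undefined on monomorphic-only data")
    calls, valid, p = calls[:, poly], valid[:, poly], p[poly]

    # pairwise mean allele-sharing: s_xy(l) = (x/2)(y/2) + (1-x/2)(1-y/2)
    half = np.where(valid, calls / 2.0, 0.0)
    v = valid.astype(float)
    s_alt = half @ half.T
    s_ref = (v - half) @ (v - half).T
    shared = v @ v.T
    # expectation for unrelated pairs, summed over the loci each pair shares
    e_locus = p**2 + (1 - p) ** 2
    e_pair = v @ (v * e_locus).T
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (s_alt + s_ref - e_pair) / (shared - e_pair)
    iu = np.triu_indices_from(f, k=1)
    fv = f[iu]
    fv = fv[np.isfinite(fv)]
    if fv.size == 0:
        raise ValueError("no pair shares a polymorphic locus")
    fbar = float(fv.mean())

    def _ne(fb: float) -> float:
        return math.inf if fb <= 0 else 1.0 / (2.0 * fb)

    # jackknife over individuals on mean coancestry
    n_ind = f.shape[0]
    mask = ~np.eye(n_ind, dtype=bool) & np.isfinite(f)
    tot = np.nansum(np.where(mask, f, 0.0)) / 2.0
    cnt = mask.sum() / 2
    row_sum = np.nansum(np.where(mask, f, 0.0), axis=1)
    row_cnt = mask.sum(axis=1)
    leave = (tot - row_sum) / np.maximum(cnt - row_cnt, 1)
    m = leave.mean()
    se = math.sqrt((n_ind - 1) / n_ind * np.sum((leave - m) ** 2))
    zcrit = stats.norm.ppf(1 - (1 - ci) / 2)
    lo_f, hi_f = fbar - zcrit * se, fbar + zcrit * se
    return NeEstimate(
        method="coancestry",
        ne=_ne(fbar),
        ci_low=min(_ne(hi_f), _ne(fbar)),
        ci_high=max(_ne(lo_f), _ne(fbar)),
        n_pairs=int(cnt),
    )


def donor_contribution_pct(ne: NeEstimate | float, n_donors: int) -> float:
    """Percent of donors effectively contributing: 100 * Ne / donors, <= 100."""
    value = ne.ne if isinstance(ne, NeEstimate) else float(ne)
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    if math.isinf(value):
        raise ValueError("contribution undefined for infinite Ne")
    return min(100.0, 100.0 * value / n_donors)
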