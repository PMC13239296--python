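"""Genotype data model, file I/O and allele-frequency utilities.

Genotypes are biallelic SNP calls coded as alternate-allele dosage
(0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate).
Missing calls are the sentinel :data:`MISSING` (-1), kept distinct from the
dosage codes so that allele arithmetic can never silently include them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call (never a valid dosage).
MISSING: int = -1

VALID_CODES = frozenset({0, 1, 2, MISSING})

#: Closed vocabularies for individual metadata.
POPULATIONS = ("warm", "cool")
COHORTS = ("wild", "hatchery", "simulated")

INDIVIDUAL_COLUMNS = ["individual_id", "population", "cohort", "age_months"]
LOCUS_COLUMNS = ["locus_id", "clone_id", "read_depth", "reproducibility"]


class GenotypeFormatError(ValueError):
    """Raised when an input file cannot be parsed as genotypes."""


class AlleleFrequencies(NamedTuple):
    """Per-locus alternate-allele frequency and the number of valid calls.

    ``p`` is NaN at loci with zero non-missing calls in the group.
    """

    p: np.ndarray
    n_valid: np.ndarray


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of biallelic SNP dosages with metadata.

    Parameters
    ----------
    calls
        ``(n_individuals, n_loci)`` integer array with entries in
        {0, 1, 2, MISSING}.
    individuals
        DataFrame with at least ``individual_id`` (unique), ``population``,
        ``cohort`` and ``age_months`` columns; one row per matrix row.
    loci
        DataFrame with at least ``locus_id`` (unique), ``clone_id``,
        ``read_depth`` and ``reproducibility`` columns; one row per column.
    """

    calls: np.ndarray
    individuals: pd.DataFrame
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        self.individuals = self.individuals.reset_index(drop=True)
        self.loci = self.loci.reset_index(drop=True)
        n_ind, n_loc = self.calls.shape
        if len(self.individuals) != n_ind:
            raise ValueError(
                f"calls has {n_ind} rows but individuals table has {len(self.individuals)}"
            )
        if len(self.loci) != n_loc:
            raise ValueError(
                f"calls has {n_loc} columns but loci table has {len(self.loci)}"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"calls contains invalid codes: {np.unique(self.calls[bad])}")
        if self.individuals["individual_id"].duplicated().any():
            raise ValueError("individual IDs are not unique")
        if self.loci["locus_id"].duplicated().any():
            raise ValueError("locus IDs are not unique")
        pops = set(self.individuals["population"].dropna().unique())
        if not pops <= set(POPULATIONS):
            raise ValueError(f"unknown population labels: {pops - set(POPULATIONS)}")
        cohorts = set(self.individuals["cohort"].dropna().unique())
        if not cohorts <= set(COHORTS):
            raise ValueError(f"unknown cohort labels: {cohorts - set(COHORTS)}")

    # -- basic properties -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def individual_ids(self) -> np.ndarray:
        return self.individuals["individual_id"].to_numpy()

    @property
    def locus_ids(self) -> np.ndarray:
        return self.loci["locus_id"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    # -- subsetting --------------------------------------------------------

    def take_individuals(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[index, :],
            self.individuals.iloc[index],
            self.loci,
        )

    def take_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.individuals,
            self.loci.iloc[index],
        )

    def select_individuals(self, **where) -> np.ndarray:
        """Boolean mask of individuals matching all keyword equality filters.

        Example: ``gm.select_individuals(population="cool", cohort="wild")``.
        """
        mask = np.ones(self.n_individuals, dtype=bool)
        for col, val in where.items():
            mask &= (self.individuals[col] == val).to_numpy()
        return mask

    def loci_index(self, locus_ids: Iterable[str]) -> np.ndarray:
        pos = pd.Index(self.loci["locus_id"])
        idx = pos.get_indexer(list(locus_ids))
        if (idx < 0).any():
            missing = [l for l, i in zip(locus_ids, idx) if i < 0]
            raise KeyError(f"unknown locus IDs: {missing[:5]}")
        return idx


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def _resolve_group(gm: GenotypeMatrix, group) -> np.ndarray:
    """Normalise a group spec (mask, indices or None = all) to row indices."""
    if group is None:
        return np.arange(gm.n_individuals)
    group = np.asarray(group)
    if group.dtype == bool:
        group = np.flatnonzero(group)
    if group.size == 0:
        raise ValueError("group of individuals is empty")
    return group


def _resolve_loci(gm: GenotypeMatrix, loci) -> np.ndarray:
    if loci is None:
        return np.arange(gm.n_loci)
    loci = np.asarray(loci)
    if loci.dtype == bool:
        loci = np.flatnonzero(loci)
    return loci


def allele_frequencies(gm: GenotypeMatrix, group=None, loci=None) -> AlleleFrequencies:
    """Alternate-allele frequency per locus within a group of individuals.

    frequency = (alternate allele count) / (2 x non-missing individuals);
    loci where every call is missing get frequency NaN (undefined).
    """
    rows = _resolve_group(gm, group)
    cols = _resolve_loci(gm, loci)
    calls = gm.calls[np.ix_(rows, cols)]
    valid = calls != MISSING
    n_valid = valid.sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_valid > 0, alt / (2.0 * n_valid), np.nan)
    return AlleleFrequencies(p=p, n_valid=n_valid)


def minor_allele_frequency(gm: GenotypeMatrix, group=None, loci=None) -> np.ndarray:
    """Per-locus minor allele frequency, min(p, 1-p); NaN where undefined."""
    p, _ = allele_frequencies(gm, group, loci)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# genotype-csv I/O
# ---------------------------------------------------------------------------

_NA = "NA"


def write_genotypes(gm: GenotypeMatrix, path: str, format: str = "genotype-csv") -> None:
    """Write a GenotypeMatrix to ``path``.

    genotype-csv layout: header row of metadata column names followed by
    locus IDs; one row per individual; missing calls written as ``NA``.
    A sidecar ``<path basename>.loci.csv`` carries the locus metadata.
    """
    if format != "genotype-csv":
        raise ValueError(f"unsupported output format: {format!r}")
    body = pd.DataFrame(
        gm.calls.astype(object), columns=gm.loci["locus_id"].tolist()
    )
    body = body.mask(gm.calls == MISSING, _NA)
    meta_cols = [c for c in INDIVIDUAL_COLUMNS if c in gm.individuals.columns]
    extra = [c for c in gm.individuals.columns if c not in meta_cols]
    out = pd.concat(
        [gm.individuals[meta_cols + extra].reset_index(drop=True), body], axis=1
    )
    out.to_csv(path, index=False)
    gm.loci.to_csv(locus_metadata_path(path), index=False)


def locus_metadata_path(genotype_path: str) -> str:
    root, _ = os.path.splitext(genotype_path)
    return root + ".loci.csv"


def read_genotypes(
    path: str, format: str = "genotype-csv", locus_metadata: str | None = None
) -> GenotypeMatrix:
    """Read genotypes from ``path`` in ``genotype-csv`` or ``vcf`` format.

    Unparseable genotype entries become MISSING. For VCF, only biallelic
    SNP records are accepted and GT fields 0/0, 0/1, 1/1, ./. map to
    dosages 0, 1, 2, MISSING.
    """
    if format == "genotype-csv":
        return _read_genotype_csv(path, locus_metadata)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unsupported input format: {format!r}")


def _read_genotype_csv(path: str, locus_metadata: str | None) -> GenotypeMatrix:
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeFormatError(f"cannot parse {path}: {exc}") from exc
    if "individual_id" not in table.columns:
        raise GenotypeFormatError(
            f"{path}: header line lacks required column 'individual_id' "
            f"(got {list(table.columns)[:4]}...)"
        )
    meta_cols = [c for c in INDIVIDUAL_COLUMNS if c in table.columns]
    extra_meta = [
        c for c in ("tank", "rock", "dam_id", "sire_id") if c in table.columns
    ]
    locus_cols = [c for c in table.columns if c not in meta_cols + extra_meta]
    individuals = table[meta_cols + extra_meta].copy()
    if "age_months" in individuals.columns:
        individuals["age_months"] = pd.to_numeric(
            individuals["age_months"].replace({_NA: None, "": None}), errors="coerce"
        ).astype("Int64")
    raw = table[locus_cols].to_numpy(dtype=object)
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    for code in (0, 1, 2):
        calls[raw == str(code)] = code
    if locus_metadata is None:
        candidate = locus_metadata_path(path)
        locus_metadata = candidate if os.path.exists(candidate) else None
    if locus_metadata is not None:
        loci = pd.read_csv(locus_metadata)
        if list(loci["locus_id"].astype(str)) != [str(c) for c in locus_cols]:
            loci = loci.set_index("locus_id").loc[locus_cols].reset_index()
    else:
        loci = pd.DataFrame(
            {
                "locus_id": locus_cols,
                "clone_id": locus_cols,
                "read_depth": np.nan,
                "reproducibility": np.nan,
            }
        )
    return GenotypeMatrix(calls, individuals, loci)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    locus_ids: list[str] = []
    ref: list[str] = []
    alt: list[str] = []
    columns: list[np.ndarray] = []
    for record in vcf:
        if len(record.ALT) != 1:
            raise GenotypeFormatError(
                f"{path}: record {record.ID or record.CHROM + ':' + str(record.POS)} "
                f"is not biallelic (ALT={record.ALT})"
            )
        locus_ids.append(record.ID or f"{record.CHROM}:{record.POS}")
        ref.append(record.REF)
        alt.append(record.ALT[0])
        types = record.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        col = np.full(len(sample_ids), MISSING, dtype=np.int8)
        col[types == 0] = 0
        col[types == 1] = 1
        col[types == 3] = 2
        columns.append(col)
    calls = (
        np.stack(columns, axis=1) if columns else np.empty((len(sample_ids), 0), np.int8)
    )
    individuals = pd.DataFrame(
        {
            "individual_id": sample_ids,
            "population": pd.NA,
            "cohort": pd.NA,
            "age_months": pd.array([pd.NA] * len(sample_ids), dtype="Int64"),
        }
    )
    loci = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "clone_id": locus_ids,
            "read_depth": np.nan,
            "reproducibility": np.nan,
            "ref_allele": ref,
            "alt_allele": alt,
        }
    )
    return GenotypeMatrix(calls, individuals, loci)


def concatenate_individuals(matrices: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack cohorts that share an identical locus table."""
    if not matrices:
        raise ValueError("no matrices to concatenate")
    first = matrices[0]
    for gm in matrices[1:]:
        if not np.array_equal(gm.locus_ids, first.locus_ids):
            raise ValueError("matrices do not share the same loci")
    calls = np.vstack([gm.calls for gm in matrices])
    individuals = pd.concat(
        [gm.individuals for gm in matrices], ignore_index=True
    )
    return GenotypeMatrix(calls, individuals, first.loci)
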