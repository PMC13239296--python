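"""End-to-end orchestration: filter -> outliers -> diversity -> structure ->
effective size -> breeding simulation, with machine-readable outputs.

A single :class:`PipelineConfig` (optionally loaded from YAML) binds the
study's analysis parameters as defaults; a global seed determines every
stochastic stage (secondary removal, bootstraps, simulations). All outputs
are plain CSV plus a JSON provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import DiversityConfig, diversity_report
from .effective_size import donor_contribution_pct, ld_ne
from .filtering import FilterConfig, apply_filters
from .genotypes import GenotypeMatrix, read_genotypes
from .simulate import SimulationConfig, donor_sweep
from .structure import (
    bitwise_distance,
    fst_table,
    pairwise_fst,
    partition_loci,
    pcoa,
    rda_scan,
)

log = logging.getLogger("kelppopgen")


@dataclass
class PipelineConfig:
    genotype_path: str = ""
    locus_metadata_path: str | None = None
    input_format: str = "genotype-csv"
    output_dir: str = "results"
    seed: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)
    rda_sd_threshold: float = 3.0
    fst_n_boot: int = 999
    fis_n_boot: int = 1000
    ne_maf_cutoff: float = 0.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    run_simulation: bool = True
    n_donors: dict = field(default_factory=lambda: {"warm": 100, "cool": 100})

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "filters" in kwargs:
            kwargs["filters"] = FilterConfig(**kwargs["filters"])
        if "simulation" in kwargs:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig, gm: GenotypeMatrix | None = None) -> dict:
    """Execute every stage in order; returns a result bundle dict.

    ``gm`` may be passed directly (e.g. a synthetic bundle) instead of
    reading ``cfg.genotype_path``. Completed-stage outputs are written as
    they are produced, so a failing stage leaves earlier results on disk
    together with an error report.
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    manifest: dict = {
        "tool": "kelppopgen",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    results: dict = {"manifest": manifest}
    stage = "load"
    try:
        if gm is None:
            if not os.path.exists(cfg.genotype_path):
                raise FileNotFoundError(f"genotype file not found: {cfg.genotype_path}")
            gm = read_genotypes(cfg.genotype_path, cfg.input_format,
                                cfg.locus_metadata_path)
        log.info("loaded %d individuals x %d loci", gm.n_individuals, gm.n_loci)
        manifest["stages"]["load"] = {"individuals": gm.n_individuals, "loci": gm.n_loci}

        stage = "filter"
        cfg.filters.rng_seed = cfg.seed
        filtered, flog = apply_filters(gm, cfg.filters)
        flog.to_frame().to_csv(os.path.join(cfg.output_dir, "filter_log.csv"), index=False)
        manifest["stages"]["filter"] = flog.stages
        results["filtered"] = filtered
        log.info("filtered to %d individuals x %d loci", filtered.n_individuals,
                 filtered.n_loci)

        stage = "outliers"
        hatchery_pred = filtered.individuals["cohort"].to_numpy()
        rda_prov = rda_scan(filtered, "population", sd_threshold=cfg.rda_sd_threshold)
        rda_hatch = rda_scan(filtered, hatchery_pred, sd_threshold=cfg.rda_sd_threshold)
        rda_hatch.predictor = "hatchery"
        for res in (rda_prov, rda_hatch):
            pd.DataFrame(
                {"locus_id": res.locus_ids, "loading": res.loadings,
                 "z": res.z_scores, "outlier": res.outlier}
            ).to_csv(os.path.join(cfg.output_dir, f"rda_{res.predictor}.csv"), index=False)
        partition = partition_loci(rda_prov, rda_hatch)
        with open(os.path.join(cfg.output_dir, "locus_partition.json"), "w") as fh:
            json.dump({**partition.as_mapping(), "overlap": partition.overlap}, fh)
        manifest["stages"]["outliers"] = partition.sizes()
        results["partition"] = partition
        results["rda"] = {"provenance": rda_prov, "hatchery": rda_hatch}

        stage = "diversity"
        subsets = {"all": list(filtered.locus_ids), **partition.as_mapping()}
        report = diversity_report(
            filtered,
            partition={k: v for k, v in subsets.items() if v},
            config=DiversityConfig(n_boot_fis=cfg.fis_n_boot, seed=cfg.seed),
        )
        report.to_csv(os.path.join(cfg.output_dir, "diversity_report.csv"), index=False)
        manifest["stages"]["diversity"] = {"rows": len(report)}
        results["diversity"] = report

        stage = "fst"
        keys = filtered.individuals[["population", "cohort"]].astype(str).agg(
            "/".join, axis=1
        )
        grouping = {k: (keys == k).to_numpy() for k in sorted(keys.unique())}
        fst_rows = []
        for label, ids in subsets.items():
            if not ids:
                continue
            fst_rows.extend(
                pairwise_fst(filtered, grouping, filtered.loci_index(ids),
                             n_boot=cfg.fst_n_boot, seed=cfg.seed, subset_label=label)
            )
        fst = fst_table(fst_rows)
        fst.to_csv(os.path.join(cfg.output_dir, "fst.csv"), index=False)
        manifest["stages"]["fst"] = {"pairs": len(fst)}
        results["fst"] = fst

        stage = "pcoa"
        dist = bitwise_distance(filtered)
        coords = pcoa(dist, n_axes=4)
        pd.DataFrame(
            coords.coordinates,
            columns=[f"axis{i + 1}" for i in range(coords.coordinates.shape[1])],
        ).assign(individual_id=filtered.individual_ids).to_csv(
            os.path.join(cfg.output_dir, "pcoa_coordinates.csv"), index=False
        )
        manifest["stages"]["pcoa"] = {
            "pct_variance": [round(v, 3) for v in coords.pct_variance[:4].tolist()]
        }
        results["pcoa"] = coords

        stage = "ne"
        neutral_idx = (
            filtered.loci_index(partition.neutral) if partition.neutral else None
        )
        ne_rows = []
        for label, mask in grouping.items():
            try:
                est = ld_ne(filtered, mask, neutral_idx,
                            maf_cutoff=cfg.ne_maf_cutoff, seed=cfg.seed)
            except ValueError as exc:
                log.warning("Ne estimation failed for %s: %s", label, exc)
                continue
            pop, cohort = label.split("/")
            donors = cfg.n_donors.get(pop)
            contrib = (
                donor_contribution_pct(est, donors)
                if cohort == "hatchery" and donors and np.isfinite(est.ne)
                else np.nan
            )
            ne_rows.append(
                {"group": label, "method": est.method, "Ne": est.ne,
                 "ci_low": est.ci_low, "ci_high": est.ci_high,
                 "overall_r2": est.overall_r2, "expected_r2": est.expected_r2,
                 "n": int(mask.sum()), "donors": donors if cohort == "hatchery" else np.nan,
                 "contribution_pct": contrib}
            )
        ne_df = pd.DataFrame(ne_rows)
        ne_df.to_csv(os.path.join(cfg.output_dir, "ne_estimates.csv"), index=False)
        manifest["stages"]["ne"] = {"groups": len(ne_df)}
        results["ne"] = ne_df

        if cfg.run_simulation:
            stage = "simulate"
            wild = filtered.take_individuals(filtered.select_individuals(cohort="wild"))
            if partition.neutral:
                wild = wild.take_loci(wild.loci_index(partition.neutral))
            sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
            sweep = donor_sweep(wild, sim_cfg)
            sweep.table.to_csv(os.path.join(cfg.output_dir, "simulation_sweep.csv"),
                               index=False)
            manifest["stages"]["simulate"] = {"rows": len(sweep.table)}
            results["simulation"] = sweep
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise PipelineError(stage, exc) from exc

    with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
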