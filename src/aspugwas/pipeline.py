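"""End-to-end orchestration: simulate -> QC -> assoc -> meta -> aSPU -> refine.

Mirrors the analysis order of a combined-phenotype GWAS: per-subgroup
univariate association with covariate adjustment, inverse-variance-weighted
meta-analysis per trait, the adaptive SPU combined-phenotype test, iterative
conditional analysis to enumerate independent signals, and generalization
testing of previously reported regions.  Every stage writes a plain
tab-delimited artifact, and the run log (JSON) records the seed, a config
hash and per-stage record counts, which together suffice to reproduce the
run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import aspu as aspu_mod
from . import io as io_mod
from . import meta as meta_mod
from . import refine as refine_mod
from .simdata import PhenotypeTable, SimConfig, VariantPanel, generate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters for one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    traits: Sequence[str] | None = None  # default: all simulated traits
    covariates: Sequence[str] | None = None
    genome_wide_alpha: float = refine_mod.GENOME_WIDE_ALPHA
    generalization_alpha: float = field(default_factory=refine_mod.generalization_threshold)
    min_imputation_quality: float = 0.4
    min_effective_heterozygosity: float = 35.0
    min_subgroup_n: int = 1000
    aspu: aspu_mod.AspuConfig = field(default_factory=aspu_mod.AspuConfig)
    known_regions_path: str | None = None
    run_conditional: bool = True

    def validate(self) -> None:
        if self.genome_wide_alpha <= 0 or self.generalization_alpha <= 0:
            raise ValueError("significance thresholds must be positive")
        self.sim.validate()

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _subgroup_inclusion(panels, phenos, min_n):
    keep_p, keep_t = [], []
    for panel, pheno in zip(panels, phenos):
        if panel.n_samples >= min_n:
            keep_p.append(panel)
            keep_t.append(pheno)
        else:
            logger.warning("subgroup %s (n=%d) below minimum n=%d; excluded",
                           panel.subgroup_id, panel.n_samples, min_n)
    return keep_p, keep_t


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    panels: Sequence[VariantPanel] | None = None,
    phenos: Sequence[PhenotypeTable] | None = None,
) -> dict:
    """Run every stage, writing artifacts under ``out_dir``.

    When ``panels``/``phenos`` are omitted they are simulated from
    ``config.sim``.  Returns the run log dictionary (also written as
    ``run_log.json``).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "seed": int(config.sim.seed),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **counts}

        return done

    # --- simulate -----------------------------------------------------------
    done = stage("simulate")
    if panels is None or phenos is None:
        panels, phenos = generate_dataset(config.sim)
    write_dataset(panels, phenos, out_dir / "dataset", config.sim)
    done(subgroups=len(panels), variants=panels[0].n_variants,
         samples=int(sum(p.n_samples for p in panels)))

    panels, phenos = _subgroup_inclusion(panels, phenos, config.min_subgroup_n)
    traits = list(config.traits) if config.traits else list(phenos[0].trait_names)
    covariates = (
        list(config.covariates) if config.covariates is not None else phenos[0].covariate_names
    )

    # --- phenotype QC (pooled 4-SD rule) ------------------------------------
    done = stage("phenotype_qc")
    pooled = assoc_mod.pooled_trait_stats(phenos, traits)
    cleaned, n_excl = [], 0
    for pheno in phenos:
        cl, exlog = assoc_mod.qc_phenotypes(pheno, traits, pooled_stats=pooled)
        cleaned.append(cl)
        n_excl += len(exlog)
    phenos = cleaned
    done(excluded_values=n_excl)

    # --- variant filter ------------------------------------------------------
    done = stage("variant_filter")
    filtered_panels = []
    n_dropped = 0
    reports = []
    for panel in panels:
        rep = assoc_mod.filter_variants(
            panel,
            min_quality=config.min_imputation_quality,
            min_effhet=config.min_effective_heterozygosity,
        )
        rep.insert(0, "subgroup", panel.subgroup_id)
        reports.append(rep)
        keep = rep["retained"].to_numpy()
        n_dropped += int((~keep).sum())
        filtered_panels.append(
            VariantPanel(
                subgroup_id=panel.subgroup_id,
                variant_meta=panel.variant_meta[keep].reset_index(drop=True),
                dosages=panel.dosages[:, keep],
                sample_ids=panel.sample_ids,
            )
        )
    pd.concat(reports, ignore_index=True).to_csv(
        out_dir / "variant_filter.tsv", sep="\t", index=False, float_format="%.6g"
    )
    panels = filtered_panels
    done(dropped=n_dropped)

    # --- univariate association + meta --------------------------------------
    done = stage("assoc_meta")
    meta_tables: dict[str, pd.DataFrame] = {}
    lambdas = {}
    for trait in traits:
        per_study = [
            assoc_mod.run_univariate(panel, pheno, trait, covariates)
            for panel, pheno in zip(panels, phenos)
        ]
        stacked = pd.concat(per_study, ignore_index=True)
        io_mod.write_summary(stacked, out_dir / f"assoc_{trait}.tsv")
        mt = meta_mod.ivw_meta(stacked, harmonize=False)
        io_mod.write_summary(mt, out_dir / f"meta_{trait}.tsv")
        meta_tables[trait] = mt
        zs = mt["Zscore"].to_numpy(dtype=float)
        zs = zs[np.isfinite(zs)]
        if zs.size:
            lambdas[trait] = meta_mod.genomic_lambda(zs, trait=trait).lambda_gc
    with open(out_dir / "genomic_lambda.json", "w") as fh:
        json.dump(lambdas, fh, indent=1)
    done(records=int(sum(len(t) for t in meta_tables.values())))

    # --- partial correlations (largest subgroup, covariate-adjusted) --------
    biggest = max(range(len(phenos)), key=lambda i: panels[i].n_samples)
    pcorr = assoc_mod.partial_correlations(phenos[biggest], traits, covariates)
    pcorr.to_csv(out_dir / "trait_partial_correlations.tsv", sep="\t", float_format="%.4f")

    # --- combined-phenotype aSPU --------------------------------------------
    done = stage("aspu")
    zpanel = aspu_mod.zpanel_from_meta(meta_tables)
    sigma = aspu_mod.estimate_null_corr(zpanel)
    results = aspu_mod.staged_aspu(zpanel, sigma, config.aspu)
    io_mod.write_summary(results, out_dir / "aspu_results.tsv")
    pd.DataFrame(sigma.sigma, index=traits, columns=traits).to_csv(
        out_dir / "null_z_correlation.tsv", sep="\t", float_format="%.4f"
    )
    done(variants=len(results), sigma_snps=sigma.n_snps_used)

    # --- conditional signals + loci -----------------------------------------
    signals, loci = [], []
    if config.run_conditional:
        done = stage("conditional")
        signals, _ = refine_mod.conditional_iteration(
            panels, phenos, traits, covariates,
            alpha=config.genome_wide_alpha, aspu_config=config.aspu,
        )
        loci = refine_mod.define_loci(signals)
        refine_mod.signals_to_frame(signals, loci).to_csv(
            out_dir / "signals.tsv", sep="\t", index=False, float_format="%.6g"
        )
        done(signals=len(signals), loci=len(loci))

    # --- generalization ------------------------------------------------------
    if config.known_regions_path:
        done = stage("generalization")
        regions = io_mod.read_known_regions(config.known_regions_path)
        gen = refine_mod.generalize_regions(
            results, regions, threshold=config.generalization_alpha
        )
        gen.to_csv(out_dir / "generalization.tsv", sep="\t", index=False, float_format="%.6g")
        done(regions=len(gen), generalized=int(gen["generalizes"].fillna(False).sum()))

    log["n_signals"] = len(signals)
    log["n_loci"] = len(loci)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return log
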