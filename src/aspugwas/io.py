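"""Readers and writers for the pipeline's tab-delimited interchange formats.

Formats (all plain text, tab-delimited, 1-based coordinates):

* dosage file — one row per variant: variant_id, chromosome, position,
  coded_allele, other_allele, CAF, imputation_quality, then one dosage
  column per sample (header carries the sample ids).
* phenotype file — header row; sample_id then trait and covariate columns.
* summary-statistics file (METAL-style) — the columns listed in
  :data:`aspugwas.assoc.SUMMARY_COLUMNS`, plus QStat/QDf/QPval/NStudies for
  meta output.
* known-regions file — chromosome, position, variant_id, trait, source.
* VCF — optional import path; the per-genotype dosage field (default
  ``DS``) maps to [0, 2] dosages and an INFO key (default ``R2``) to
  imputation quality, with hard-call fallback when the dosage field is
  absent.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import PhenotypeTable, VariantPanel

logger = logging.getLogger(__name__)

_DOSAGE_META_COLS = [
    "variant_id", "chromosome", "position", "coded_allele", "other_allele",
    "CAF", "imputation_quality",
]

FLOAT_FORMAT = "%.6g"


def write_dosage(panel: VariantPanel, path: str | Path) -> None:
    meta = panel.variant_meta
    with open(path, "w") as fh:
        fh.write("\t".join(_DOSAGE_META_COLS + list(panel.sample_ids)) + "\n")
        for j in range(panel.n_variants):
            row = meta.iloc[j]
            fields = [
                str(row["variant_id"]), str(row["chromosome"]), str(int(row["position"])),
                str(row["coded_allele"]), str(row["other_allele"]),
                f"{row['CAF']:.6f}", f"{row['imputation_quality']:.6f}",
            ]
            fields += [f"{d:.6f}" for d in panel.dosages[:, j]]
            fh.write("\t".join(fields) + "\n")


def read_dosage(path: str | Path, subgroup_id: str | None = None) -> VariantPanel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in _DOSAGE_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: dosage file missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in _DOSAGE_META_COLS]
    meta = df[_DOSAGE_META_COLS].copy()
    meta["position"] = meta["position"].astype(int)
    dosages = df[sample_ids].to_numpy(dtype=float).T  # samples x variants
    if dosages.size and (dosages.min() < -1e-9 or dosages.max() > 2 + 1e-9):
        raise ValueError(f"{path}: dosages outside [0, 2]")
    if subgroup_id is None:
        subgroup_id = path.stem.replace("dosage_", "")
    return VariantPanel(
        subgroup_id=subgroup_id,
        variant_meta=meta.reset_index(drop=True),
        dosages=dosages,
        sample_ids=sample_ids,
    )


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_phenotypes(
    path: str | Path,
    trait_names: list[str] | None = None,
    covariate_names: list[str] | None = None,
    subgroup_id: str | None = None,
) -> PhenotypeTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: phenotype file lacks a sample_id column")
    other = [c for c in df.columns if c != "sample_id"]
    if trait_names is None and covariate_names is None:
        # Convention: covariates are SEX/AGE/PC*; the rest are traits.
        covariate_names = [c for c in other if c in ("SEX", "AGE") or c.startswith("PC")]
        trait_names = [c for c in other if c not in covariate_names]
    elif trait_names is None:
        trait_names = [c for c in other if c not in (covariate_names or [])]
    elif covariate_names is None:
        covariate_names = [c for c in other if c not in trait_names]
    if subgroup_id is None:
        subgroup_id = path.stem.replace("pheno_", "")
    return PhenotypeTable(
        subgroup_id=subgroup_id,
        data=df,
        trait_names=list(trait_names),
        covariate_names=list(covariate_names),
    )


def write_summary(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    if "MarkerName" not in df.columns:
        raise ValueError(f"{path}: not a summary-statistics file (no MarkerName)")
    return df


def read_known_regions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    needed = {"chromosome", "position", "variant_id"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: known-regions file missing columns {sorted(missing)}")
    df["position"] = df["position"].astype(int)
    return df


def read_vcf(
    path: str | Path,
    dosage_field: str = "DS",
    quality_key: str = "R2",
    subgroup_id: str = "VCF",
) -> VariantPanel:
    """Import a VCF with per-genotype dosages into a VariantPanel.

    Uses cyvcf2 when available.  Records lacking the dosage FORMAT field fall
    back to hard-call dosages from GT (flagged via a warning); a missing
    INFO quality key defaults to 1.0.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("VCF import requires the cyvcf2 package (pip install aspugwas[vcf])") from exc

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    meta_rows, dosage_cols = [], []
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) != 1:
            logger.warning("skipping non-biallelic record at %s:%d", rec.CHROM, rec.POS)
            continue
        try:
            raw = rec.format(dosage_field)
        except KeyError:
            raw = None
        if raw is not None:
            ds = np.asarray(raw, dtype=float).reshape(-1)
        else:
            gt = np.asarray(rec.genotypes, dtype=object)[:, :2].astype(int)
            ds = np.clip(gt, 0, None).sum(axis=1).astype(float)
            logger.warning(
                "record %s:%d lacks FORMAT/%s; using hard-call dosages",
                rec.CHROM, rec.POS, dosage_field,
            )
        ds = np.clip(ds, 0.0, 2.0)
        qual = rec.INFO.get(quality_key)
        meta_rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chromosome": str(rec.CHROM),
                "position": int(rec.POS),
                "coded_allele": rec.ALT[0],
                "other_allele": rec.REF,
                "CAF": float(ds.mean() / 2.0),
                "imputation_quality": float(qual) if qual is not None else 1.0,
            }
        )
        dosage_cols.append(ds)
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(sample_ids), 0))
    )
    return VariantPanel(
        subgroup_id=subgroup_id,
        variant_meta=pd.DataFrame(
            meta_rows, columns=_DOSAGE_META_COLS
        ),
        dosages=dosages,
        sample_ids=sample_ids,
    )
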