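"""Phenotype QC, variant filtering, and univariate additive-model association.

Per-variant association uses ordinary least squares of the trait on the
coded-allele dosage plus covariates, vectorized across variants through the
Frisch-Waugh-Lovell decomposition: trait and dosages are residualized on the
covariate design, after which each variant's slope, standard error and Wald
z follow from simple-regression formulas with the correct residual degrees
of freedom.  p-values come from the normal approximation by default (the
convention of standard GWAS software at these sample sizes); Student's t is
available via ``use_t=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import PhenotypeTable, VariantPanel

logger = logging.getLogger(__name__)

#: Lower bound applied to every reported p-value so that downstream log-space
#: work never sees an exact zero.
P_FLOOR = 1e-300

SUMMARY_COLUMNS = [
    "MarkerName",
    "Chromosome",
    "Position",
    "Allele1",
    "Allele2",
    "Freq1",
    "ImpQuality",
    "Effect",
    "StdErr",
    "Zscore",
    "Pvalue",
    "N",
    "Trait",
    "Subgroup",
]


def qc_phenotypes(
    table: PhenotypeTable,
    traits: Sequence[str] | None = None,
    *,
    pooled_stats: dict[str, tuple[float, float]] | None = None,
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Set trait values beyond 4 SD of the study-population mean to missing.

    ``pooled_stats`` maps trait -> (mean, sd) computed over the pooled study
    population (see :func:`pooled_trait_stats`); when omitted, the statistics
    of ``table`` itself are used.  Returns the cleaned table and an exclusion
    log with one row per removed value.
    """
    traits = list(traits) if traits is not None else table.trait_names
    data = table.data.copy()
    log_rows = []
    for trait in traits:
        vals = data[trait].to_numpy(dtype=float)
        if pooled_stats is not None:
            mean, sd = pooled_stats[trait]
        else:
            mean, sd = np.nanmean(vals), np.nanstd(vals, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("trait %s has zero variance; no outlier exclusion", trait)
            continue
        bad = np.abs(vals - mean) > 4.0 * sd
        bad &= ~np.isnan(vals)
        for i in np.flatnonzero(bad):
            log_rows.append(
                {
                    "sample_id": data["sample_id"].iloc[i],
                    "trait": trait,
                    "value": vals[i],
                    "mean": mean,
                    "sd": sd,
                }
            )
        vals[bad] = np.nan
        data[trait] = vals
    cleaned = PhenotypeTable(
        subgroup_id=table.subgroup_id,
        data=data,
        trait_names=table.trait_names,
        covariate_names=table.covariate_names,
    )
    return cleaned, pd.DataFrame(log_rows, columns=["sample_id", "trait", "value", "mean", "sd"])


def pooled_trait_stats(
    tables: Sequence[PhenotypeTable], traits: Sequence[str]
) -> dict[str, tuple[float, float]]:
    """Mean and SD of each trait over all subgroups pooled together."""
    out = {}
    for trait in traits:
        vals = np.concatenate([t.data[trait].to_numpy(dtype=float) for t in tables])
        out[trait] = (float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1)))
    return out


def effective_heterozygosity(caf: np.ndarray, n: int, quality: np.ndarray) -> np.ndarray:
    """2 * CAF * (1 - CAF) * N * imputation quality."""
    caf = np.asarray(caf, dtype=float)
    return 2.0 * caf * (1.0 - caf) * float(n) * np.asarray(quality, dtype=float)


def filter_variants(
    panel: VariantPanel,
    n: int | None = None,
    min_quality: float = 0.4,
    min_effhet: float = 35.0,
) -> pd.DataFrame:
    """Imputation-quality and effective-heterozygosity inclusion filter.

    A variant is retained iff quality >= ``min_quality`` and effective
    heterozygosity >= ``min_effhet`` (both boundaries inclusive: the
    exclusion rules are "quality < 0.4" and "effective heterozygosity < 35").
    The report gives the first failing rule per excluded variant.
    """
    if n is None:
        n = panel.n_samples
    meta = panel.variant_meta
    effhet = effective_heterozygosity(meta["CAF"].to_numpy(), n, meta["imputation_quality"].to_numpy())
    qual = meta["imputation_quality"].to_numpy(dtype=float)
    retained = (qual >= min_quality) & (effhet >= min_effhet)
    reason = np.where(
        qual < min_quality,
        "low_imputation_quality",
        np.where(effhet < min_effhet, "low_effective_heterozygosity", "retained"),
    )
    return pd.DataFrame(
        {
            "variant_id": meta["variant_id"].to_numpy(),
            "effective_heterozygosity": effhet,
            "imputation_quality": qual,
            "retained": retained,
            "reason": reason,
        }
    )


def _residualize(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of y (n or n x m) on X via least squares; returns (resid, rank)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef, rank


def run_univariate(
    panel: VariantPanel,
    phenos: PhenotypeTable,
    trait: str,
    covariates: Sequence[str] | None = None,
    *,
    extra_dosage_covariates: np.ndarray | None = None,
    variant_mask: np.ndarray | None = None,
    use_t: bool = False,
) -> pd.DataFrame:
    """OLS association of one trait with every variant in the panel.

    Complete-case analysis: rows with a missing trait or covariate value are
    dropped for this trait only.  ``extra_dosage_covariates`` (n x L) appends
    conditioning dosages (e.g. lead-SNP dosages) to the covariate design;
    zero-variance or collinear columns are dropped with a warning.  Variants
    with zero dosage variance among complete cases yield a record with
    missing beta/se and p = 1, flagged in the ``Flag`` column.
    """
    covariates = list(covariates) if covariates is not None else phenos.covariate_names
    df = phenos.data
    y_all = df[trait].to_numpy(dtype=float)
    C = df[covariates].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    if extra_dosage_covariates is not None:
        extra = np.atleast_2d(np.asarray(extra_dosage_covariates, dtype=float))
        if extra.shape[0] != len(df):
            extra = extra.T
        C = np.hstack([C, extra])
    keep = ~np.isnan(y_all)
    if C.shape[1]:
        keep &= ~np.isnan(C).any(axis=1)
    y = y_all[keep]
    Xc = C[keep]
    n = int(keep.sum())
    if n < Xc.shape[1] + 3:
        raise ValueError(f"too few complete cases ({n}) for trait {trait}")

    # Drop constant / collinear conditioning columns before building the design.
    if Xc.shape[1]:
        sds = Xc.std(axis=0)
        const = sds == 0
        if const.any():
            logger.warning("dropping %d constant covariate column(s)", int(const.sum()))
            Xc = Xc[:, ~const]
    X = np.hstack([np.ones((n, 1)), Xc])
    rank = np.linalg.matrix_rank(X)
    while rank < X.shape[1]:
        # remove the last column contributing no rank (conditioning dosages
        # collinear with earlier covariates)
        for j in range(X.shape[1] - 1, 0, -1):
            Xtry = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xtry) == rank:
                logger.warning("dropping collinear design column %d", j)
                X = Xtry
                break
        else:
            raise ValueError("rank-deficient covariate matrix: could not repair")
        rank = np.linalg.matrix_rank(X)

    G = panel.dosages[keep]
    meta = panel.variant_meta
    m = panel.n_variants
    if variant_mask is None:
        variant_mask = np.ones(m, dtype=bool)

    ry, _ = _residualize(y, X)
    rG, _ = _residualize(G, X)
    sxx = np.einsum("ij,ij->j", rG, rG)
    sxy = ry @ rG
    syy = float(ry @ ry)
    dof = n - X.shape[1] - 1

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(sigma2 / sxx)
        z = beta / se

    zero_var = (sxx <= 1e-12) | ~np.isfinite(beta)
    if use_t:
        p = 2.0 * stats.t.sf(np.abs(z), dof)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, P_FLOOR, 1.0)
    beta = np.where(zero_var, np.nan, beta)
    se = np.where(zero_var, np.nan, se)
    z = np.where(zero_var, np.nan, z)
    p = np.where(zero_var, 1.0, p)

    caf = G.mean(axis=0) / 2.0
    out = pd.DataFrame(
        {
            "MarkerName": meta["variant_id"].to_numpy(),
            "Chromosome": meta["chromosome"].to_numpy(),
            "Position": meta["position"].to_numpy(),
            "Allele1": meta["coded_allele"].to_numpy(),
            "Allele2": meta["other_allele"].to_numpy(),
            "Freq1": caf,
            "ImpQuality": meta["imputation_quality"].to_numpy(),
            "Effect": beta,
            "StdErr": se,
            "Zscore": z,
            "Pvalue": p,
            "N": n,
            "Trait": trait,
            "Subgroup": panel.subgroup_id,
            "Flag": np.where(zero_var, "zero_dosage_variance", ""),
        }
    )
    return out[variant_mask].reset_index(drop=True)


def partial_correlations(
    phenos: PhenotypeTable,
    traits: Sequence[str] | None = None,
    covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted pairwise trait correlations (complete cases).

    Each trait is residualized on the covariate design (with intercept); the
    returned K x K matrix is the Pearson correlation of those residuals.
    """
    traits = list(traits) if traits is not None else phenos.trait_names
    covariates = list(covariates) if covariates is not None else phenos.covariate_names
    df = phenos.data[traits + covariates].dropna()
    K = len(traits)
    if len(df) < K + len(covariates) + 2:
        raise ValueError("insufficient complete cases for partial correlations")
    Y = df[traits].to_numpy(dtype=float)
    X = np.hstack([np.ones((len(df), 1)), df[covariates].to_numpy(dtype=float)]) if covariates else np.ones((len(df), 1))
    R, _ = _residualize(Y, X)
    corr = np.corrcoef(R, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=traits, columns=traits)
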