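"""Fixed-effect inverse-variance-weighted meta-analysis and calibration.

Implements the standard IVW combination used by METAL-style GWAS
meta-analysis: per-study weights w_i = 1/se_i^2, pooled effect
sum(w_i b_i)/sum(w_i), pooled SE 1/sqrt(sum w_i), Cochran's Q for effect
heterogeneity, plus the genomic inflation factor lambda for calibration
diagnostics.  Allele coding is harmonized to the first contributing study
before combining; strand-ambiguous A/T and C/G variants with coded-allele
frequency in [0.4, 0.6] are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import P_FLOOR

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_alleles(group: pd.DataFrame) -> pd.DataFrame | None:
    """Align every study's coding to the first study's allele pair.

    A coded/other swap negates the effect and maps CAF to 1-CAF; a strand
    flip (complement alleles) is applied silently.  Returns ``None`` when a
    study's alleles cannot be reconciled, or when the variant is a
    strand-ambiguous palindrome with CAF in [0.4, 0.6] (unresolvable).
    """
    ref_a1 = str(group["Allele1"].iloc[0]).upper()
    ref_a2 = str(group["Allele2"].iloc[0]).upper()
    rows = []
    for _, row in group.iterrows():
        a1, a2 = str(row["Allele1"]).upper(), str(row["Allele2"]).upper()
        if _is_ambiguous(a1, a2) and 0.4 <= float(row["Freq1"]) <= 0.6:
            logger.warning(
                "dropping strand-ambiguous variant %s (CAF %.2f)",
                row["MarkerName"], row["Freq1"],
            )
            return None
        flip = {"a1": _COMPLEMENT.get(a1, "?"), "a2": _COMPLEMENT.get(a2, "?")}
        if (a1, a2) == (ref_a1, ref_a2):
            rows.append(row)
        elif (a2, a1) == (ref_a1, ref_a2):
            row = row.copy()
            row["Allele1"], row["Allele2"] = ref_a1, ref_a2
            row["Effect"] = -row["Effect"]
            row["Zscore"] = -row["Zscore"]
            row["Freq1"] = 1.0 - row["Freq1"]
            rows.append(row)
        elif (flip["a1"], flip["a2"]) == (ref_a1, ref_a2):
            row = row.copy()
            row["Allele1"], row["Allele2"] = ref_a1, ref_a2
            rows.append(row)
        elif (flip["a2"], flip["a1"]) == (ref_a1, ref_a2):
            row = row.copy()
            row["Allele1"], row["Allele2"] = ref_a1, ref_a2
            row["Effect"] = -row["Effect"]
            row["Zscore"] = -row["Zscore"]
            row["Freq1"] = 1.0 - row["Freq1"]
            rows.append(row)
        else:
            logger.warning(
                "allele mismatch for %s: %s/%s vs %s/%s; variant dropped",
                row["MarkerName"], a1, a2, ref_a1, ref_a2,
            )
            return None
    return pd.DataFrame(rows)


def ivw_meta(records: pd.DataFrame, harmonize: bool = True) -> pd.DataFrame:
    """Fixed-effect IVW meta-analysis of per-study summary statistics.

    ``records`` stacks association rows (one per study) in the summary
    format of :mod:`aspugwas.assoc`; rows are grouped by (MarkerName, Trait).
    Studies with missing beta or SE (e.g. monomorphic in that subgroup) do
    not contribute; a variant with no contributing study at all yields a row
    with missing effect and p = NaN so downstream stages can flag it.
    """
    if harmonize:
        pieces = []
        for _, group in records.groupby(["MarkerName", "Trait"], sort=False):
            g = harmonize_alleles(group) if len(group) > 1 else group
            if g is not None:
                pieces.append(g)
        if not pieces:
            return pd.DataFrame(columns=list(records.columns) + ["QStat", "QDf", "QPval", "NStudies"])
        records = pd.concat(pieces, ignore_index=True)

    df = records.copy()
    ok = df["Effect"].notna() & df["StdErr"].notna() & (df["StdErr"] > 0)
    w = np.where(ok, 1.0 / df["StdErr"].to_numpy(dtype=float) ** 2, 0.0)
    df["_w"] = w
    df["_wb"] = np.where(ok, w * df["Effect"].to_numpy(dtype=float), 0.0)
    df["_n"] = np.where(ok, df["N"].to_numpy(dtype=float), 0.0)
    df["_nf"] = np.where(ok, df["_n"] * df["Freq1"].to_numpy(dtype=float), 0.0)
    df["_k"] = ok.astype(int)

    keys = ["MarkerName", "Trait"]
    grouped = df.groupby(keys, sort=False)
    agg = grouped.agg(
        Chromosome=("Chromosome", "first"),
        Position=("Position", "first"),
        Allele1=("Allele1", "first"),
        Allele2=("Allele2", "first"),
        _w=("_w", "sum"),
        _wb=("_wb", "sum"),
        _n=("_n", "sum"),
        _nf=("_nf", "sum"),
        NStudies=("_k", "sum"),
    ).reset_index()

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = agg["_wb"] / agg["_w"]
        se = 1.0 / np.sqrt(agg["_w"])
        freq = agg["_nf"] / agg["_n"]
    # Cochran's Q needs the per-study deviations from the pooled effect.
    df = df.merge(agg[keys].assign(_beta=beta.to_numpy()), on=keys, how="left")
    df["_qterm"] = df["_w"] * (df["Effect"].fillna(0.0) - df["_beta"]) ** 2 * (df["_w"] > 0)
    q = df.groupby(keys, sort=False)["_qterm"].sum().reset_index(drop=True)

    none = agg["NStudies"] == 0
    beta = np.where(none, np.nan, beta)
    se = np.where(none, np.nan, se)
    z = beta / se
    with np.errstate(invalid="ignore"):
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)
    p = np.where(none, np.nan, p)
    q_df = np.maximum(agg["NStudies"].to_numpy() - 1, 0)
    q_stat = np.where(none, np.nan, q.to_numpy(dtype=float))
    q_p = np.where(q_df > 0, stats.chi2.sf(np.nan_to_num(q_stat), np.maximum(q_df, 1)), 1.0)
    q_p = np.where(none, np.nan, q_p)

    return pd.DataFrame(
        {
            "MarkerName": agg["MarkerName"],
            "Chromosome": agg["Chromosome"],
            "Position": agg["Position"],
            "Allele1": agg["Allele1"],
            "Allele2": agg["Allele2"],
            "Freq1": np.where(none, np.nan, freq),
            "Effect": beta,
            "StdErr": se,
            "Zscore": z,
            "Pvalue": p,
            "N": agg["_n"].astype(int),
            "Trait": agg["Trait"],
            "QStat": q_stat,
            "QDf": q_df,
            "QPval": q_p,
            "NStudies": agg["NStudies"],
        }
    )


@dataclass
class GenomicControl:
    """Genomic inflation factor and QQ-plot coordinates for one trait."""

    trait: str
    lambda_gc: float
    qq_points: pd.DataFrame  # columns: expected, observed (-log10 p, ascending)


def genomic_lambda(
    values: Sequence[float] | np.ndarray,
    kind: str = "z",
    trait: str = "",
) -> GenomicControl:
    """Genomic inflation factor: median chi-square over the null chi2_1 median.

    ``kind='z'`` interprets the input as z-scores (chi-square = z^2);
    ``kind='p'`` converts two-sided p-values back to chi-square quantiles.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("genomic_lambda needs at least one finite value")
    if vals.size < 100:
        logger.warning("genomic_lambda on only %d values; unstable estimate", vals.size)
    if kind == "z":
        chi2 = vals**2
        p = 2.0 * stats.norm.sf(np.abs(vals))
    elif kind == "p":
        p = vals
        chi2 = stats.chi2.isf(np.clip(p, P_FLOOR, 1.0), 1)
    else:
        raise ValueError("kind must be 'z' or 'p'")
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    p_sorted = np.sort(np.clip(p, P_FLOOR, 1.0))
    M = p_sorted.size
    expected = -np.log10((np.arange(1, M + 1) - 0.5) / M)
    observed = -np.log10(p_sorted)
    qq = pd.DataFrame({"expected": expected[::-1], "observed": observed[::-1]})
    return GenomicControl(trait=trait, lambda_gc=lam, qq_points=qq)
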