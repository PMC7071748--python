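"""Conditionally independent signals, locus bookkeeping, and generalization.

A genome-wide scan of a combined-phenotype statistic typically shows broad
peaks in which many variants tag the same underlying signal through linkage
disequilibrium.  The procedure here enumerates independent signals by
iterative conditioning on individual-level dosages: the top variant per
10-Mb window per chromosome seeds the lead set, every trait's regression is
re-fit with the lead dosages as extra covariates (leads on the same
chromosome as the tested variant), meta-analysis and aSPU are re-run on the
conditioned results, and any variant still exceeding the significance
threshold becomes the next lead — until none remains.  Signals within
500 kb of each other merge (transitively) into loci, and previously
reported regions are checked for generalization at a region-count
Bonferroni threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import aspu as aspu_mod
from . import meta as meta_mod
from .simdata import PhenotypeTable, VariantPanel

logger = logging.getLogger(__name__)

#: Genome-wide significance for the combined-phenotype analysis: Bonferroni
#: for ten million independent tests.
GENOME_WIDE_ALPHA = 0.05 / 1e7  # = 5e-9

#: Generalization threshold: Bonferroni over the 466 one-megabase regions
#: with previously reported signals for any of the traits.
N_KNOWN_REGIONS = 466


def generalization_threshold(n_regions: int = N_KNOWN_REGIONS) -> float:
    """0.05 / n_regions rounded to three significant figures (1.07e-4)."""
    raw = 0.05 / n_regions
    return float(f"{raw:.2e}")


@dataclass
class Signal:
    """A conditionally independent association signal."""

    lead_variant: str
    chromosome: str
    position: int
    conditioning_round: int
    p_aspu_at_discovery: float
    conditioned_on: list[str] = field(default_factory=list)
    monomorphic_subgroups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.conditioning_round == 0) != (len(self.conditioned_on) == 0):
            raise ValueError("round 0 signals must have empty conditioned_on and vice versa")


@dataclass
class Locus:
    """A +/- 500 kb physical window around a lead, holding >= 1 signals."""

    locus_id: str
    chromosome: str
    signals: list[Signal]

    @property
    def window(self) -> tuple[int, int]:
        lead = self.signals[0]
        return (lead.position - 500_000, lead.position + 500_000)


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance dosage: LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _rank_results(df: pd.DataFrame) -> pd.DataFrame:
    """Order by significance: p ascending, then (for Monte-Carlo p-floor
    ties) z-vector magnitude descending, then position ascending."""
    if "ZNorm2" in df.columns:
        df = df.assign(_neg_mag=-df["ZNorm2"].fillna(0.0))
        out = df.sort_values(["Paspu", "_neg_mag", "Position"], kind="mergesort")
        return out.drop(columns="_neg_mag")
    return df.sort_values(["Paspu", "Position"], kind="mergesort")


def select_window_leads(
    results: pd.DataFrame,
    alpha: float = GENOME_WIDE_ALPHA,
    window_mb: float = 10.0,
) -> list[Signal]:
    """Top significant variant within fixed 10-Mb tiles per chromosome.

    Windows tile each chromosome anchored at position 1.  Within a tile the
    variant with the smallest p_aspu below ``alpha`` wins; p ties (which at
    finite Monte-Carlo resolution happen at the attainable floor) break to
    the larger z-score magnitude, then to the smaller position.
    """
    width = int(window_mb * 1e6)
    sig = results[results["Paspu"] < alpha]
    leads: list[Signal] = []
    if sig.empty:
        return leads
    sig = sig.assign(_win=((sig["Position"].astype(int) - 1) // width))
    for (_, _), grp in sig.groupby(["Chromosome", "_win"], sort=True):
        top = _rank_results(grp).iloc[0]
        leads.append(
            Signal(
                lead_variant=str(top["MarkerName"]),
                chromosome=str(top["Chromosome"]),
                position=int(top["Position"]),
                conditioning_round=0,
                p_aspu_at_discovery=float(top["Paspu"]),
            )
        )
    leads.sort(key=lambda s: (s.chromosome, s.position))
    return leads


def _monomorphic_subgroups(panels: Sequence[VariantPanel], variant_id: str) -> list[str]:
    """Subgroups where the variant carries no information (constant or absent)."""
    out = []
    for panel in panels:
        try:
            d = panel.dosage_of(variant_id)
        except KeyError:
            out.append(panel.subgroup_id)
            continue
        if d.std() == 0:
            out.append(panel.subgroup_id)
    return out


def run_combined_scan(
    panels: Sequence[VariantPanel],
    phenos: Sequence[PhenotypeTable],
    traits: Sequence[str],
    covariates: Sequence[str] | None = None,
    lead_dosage_ids: Sequence[str] = (),
    aspu_config: aspu_mod.AspuConfig | None = None,
    sigma: aspu_mod.NullCorr | None = None,
) -> tuple[pd.DataFrame, aspu_mod.NullCorr]:
    """One pass of univariate -> meta -> aSPU, optionally conditioned.

    ``lead_dosage_ids`` name variants whose dosages enter every regression as
    extra covariates (only leads sharing the tested chromosome are used; the
    synthetic panels are single-matrix, so all leads on that panel apply).
    Sigma is re-estimated from the scan's own z-panel unless supplied.
    """
    meta_tables: dict[str, pd.DataFrame] = {}
    for trait in traits:
        per_study = []
        for panel, pheno in zip(panels, phenos):
            by_chrom = {}
            chroms = panel.variant_meta["chromosome"].unique()
            for chrom in chroms:
                mask = (panel.variant_meta["chromosome"] == chrom).to_numpy()
                extra = None
                if lead_dosage_ids:
                    lead_meta = panel.variant_meta[
                        panel.variant_meta["variant_id"].isin(lead_dosage_ids)
                        & (panel.variant_meta["chromosome"] == chrom)
                    ]
                    if len(lead_meta):
                        extra = panel.dosages[:, lead_meta.index.to_numpy()]
                by_chrom[chrom] = assoc_mod.run_univariate(
                    panel,
                    pheno,
                    trait,
                    covariates,
                    extra_dosage_covariates=extra,
                    variant_mask=mask,
                )
            per_study.append(pd.concat(by_chrom.values(), ignore_index=True))
        stacked = pd.concat(per_study, ignore_index=True)
        meta_tables[trait] = meta_mod.ivw_meta(stacked, harmonize=False)
    zpanel = aspu_mod.zpanel_from_meta(meta_tables)
    if sigma is None:
        sigma = aspu_mod.estimate_null_corr(zpanel)
    results = aspu_mod.staged_aspu(zpanel, sigma, aspu_config)
    return results, sigma


def conditional_iteration(
    panels: Sequence[VariantPanel],
    phenos: Sequence[PhenotypeTable],
    traits: Sequence[str],
    covariates: Sequence[str] | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
    aspu_config: aspu_mod.AspuConfig | None = None,
    max_rounds: int = 25,
) -> tuple[list[Signal], pd.DataFrame]:
    """Enumerate conditionally independent combined-phenotype signals.

    Round 0 scans unconditioned and seeds the lead set with the top variant
    per 10-Mb window.  Each later round conditions every regression on all
    current leads (same chromosome), re-runs meta + aSPU, and promotes the
    most significant remaining variant if it stays below ``alpha``; the
    iteration stops when none does.  Returns the signals and the final
    (conditioned) scan results.
    """
    results, _ = run_combined_scan(panels, phenos, traits, covariates, aspu_config=aspu_config)
    signals = select_window_leads(results, alpha=alpha)
    for s in signals:
        s.monomorphic_subgroups = _monomorphic_subgroups(panels, s.lead_variant)
    if not signals:
        return [], results

    for rnd in range(1, max_rounds + 1):
        lead_ids = [s.lead_variant for s in signals]
        results, _ = run_combined_scan(
            panels, phenos, traits, covariates,
            lead_dosage_ids=lead_ids, aspu_config=aspu_config,
        )
        remaining = results[~results["MarkerName"].isin(lead_ids)]
        remaining = remaining[remaining["Paspu"] < alpha]
        if remaining.empty:
            break
        top = _rank_results(remaining).iloc[0]
        conditioned_on = [
            s.lead_variant for s in signals if s.chromosome == str(top["Chromosome"])
        ]
        signals.append(
            Signal(
                lead_variant=str(top["MarkerName"]),
                chromosome=str(top["Chromosome"]),
                position=int(top["Position"]),
                conditioning_round=rnd,
                p_aspu_at_discovery=float(top["Paspu"]),
                conditioned_on=conditioned_on,
                monomorphic_subgroups=_monomorphic_subgroups(panels, str(top["MarkerName"])),
            )
        )
    else:
        logger.warning("conditional iteration hit max_rounds=%d", max_rounds)
    return signals, results


def define_loci(signals: Sequence[Signal], merge_kb: float = 500.0) -> list[Locus]:
    """Group signals into +/- 500 kb loci with transitive merging.

    Signals within ``merge_kb`` of an existing locus lead join that locus;
    chains (A-B close, B-C close, A-C apart) merge into one locus.  With
    signals sorted by position per chromosome this is single-linkage
    clustering with a 500-kb gap threshold.  Within a locus, signals are
    ordered by discovery p-value then position; locus ids are assigned in
    (chromosome, first-lead position) order.
    """
    width = int(merge_kb * 1000)
    by_chrom: dict[str, list[Signal]] = {}
    for s in signals:
        by_chrom.setdefault(s.chromosome, []).append(s)
    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        ss = sorted(by_chrom[chrom], key=lambda s: s.position)
        cluster: list[Signal] = []
        for s in ss:
            if cluster and s.position - cluster[-1].position > width:
                loci.append(Locus("", chrom, cluster))
                cluster = []
            cluster.append(s)
        if cluster:
            loci.append(Locus("", chrom, cluster))
    for i, locus in enumerate(loci):
        locus.signals.sort(key=lambda s: (s.p_aspu_at_discovery, s.position))
        locus.locus_id = f"locus_{i + 1}"
    return loci


def generalization_test(
    p: float,
    threshold: float | None = None,
    in_known_region: bool = True,
) -> bool | None:
    """Does a previously reported region generalize at the Bonferroni bound?

    Returns ``None`` (not evaluated) when the variant is not within 500 kb
    of any previously reported variant, else ``p < threshold``.
    """
    if not in_known_region:
        return None
    if threshold is None:
        threshold = generalization_threshold()
    return bool(p < threshold)


def generalize_regions(
    results: pd.DataFrame,
    known_regions: pd.DataFrame,
    p_column: str = "Paspu",
    threshold: float | None = None,
    window_kb: float = 500.0,
) -> pd.DataFrame:
    """Evaluate generalization for every previously reported region.

    ``known_regions`` has columns chromosome, position, variant_id (the
    reported index variants).  For each region, the smallest ``p_column``
    value among scan variants within ``window_kb`` of the reported position
    is compared to the threshold.
    """
    if threshold is None:
        threshold = generalization_threshold()
    width = int(window_kb * 1000)
    rows = []
    for _, reg in known_regions.iterrows():
        near = results[
            (results["Chromosome"].astype(str) == str(reg["chromosome"]))
            & (np.abs(results["Position"].astype(int) - int(reg["position"])) <= width)
        ]
        if near.empty:
            rows.append(
                {
                    "region_variant": reg["variant_id"],
                    "chromosome": reg["chromosome"],
                    "position": reg["position"],
                    "best_p": np.nan,
                    "best_variant": "",
                    "generalizes": None,
                }
            )
            continue
        best = near.sort_values([p_column, "Position"], kind="mergesort").iloc[0]
        rows.append(
            {
                "region_variant": reg["variant_id"],
                "chromosome": reg["chromosome"],
                "position": reg["position"],
                "best_p": float(best[p_column]),
                "best_variant": best["MarkerName"],
                "generalizes": bool(best[p_column] < threshold),
            }
        )
    return pd.DataFrame(rows)


def signals_to_frame(signals: Sequence[Signal], loci: Sequence[Locus] | None = None) -> pd.DataFrame:
    """Tabular signal report (one row per signal, tab-friendly columns)."""
    locus_of = {}
    if loci:
        for locus in loci:
            for s in locus.signals:
                locus_of[s.lead_variant] = locus.locus_id
    rows = [
        {
            "lead_variant": s.lead_variant,
            "chromosome": s.chromosome,
            "position": s.position,
            "conditioning_round": s.conditioning_round,
            "p_aspu_at_discovery": s.p_aspu_at_discovery,
            "conditioned_on": ",".join(s.conditioned_on),
            "ancestry_specific": bool(s.monomorphic_subgroups),
            "monomorphic_subgroups": ",".join(s.monomorphic_subgroups),
            "locus_id": locus_of.get(s.lead_variant, ""),
        }
        for s in signals
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lead_variant", "chromosome", "position", "conditioning_round",
            "p_aspu_at_discovery", "conditioned_on", "ancestry_specific",
            "monomorphic_subgroups", "locus_id",
        ],
    )
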