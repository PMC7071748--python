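"""Synthetic multi-subgroup genotype/phenotype data with known ground truth.

The generator emulates the design of a multi-ethnic cohort GWAS of correlated
quantitative blood traits: several analytic subgroups genotyped separately,
subgroup-specific allele frequencies (including variants monomorphic in some
subgroups), local linkage disequilibrium, imputation-quality attenuation of
dosages, linear covariate effects, and multivariate-normal trait residuals
with a specified correlation structure.

Genotypes are drawn under Hardy-Weinberg equilibrium by sampling two haploid
alleles per sample from a Gaussian copula: latent normals follow an AR(1)
autocorrelation ``ld_rho`` within blocks of ``ld_block_size`` adjacent
variants and are independent across blocks, so adjacent-variant LD (r^2) is
tunable while distant variants stay uncorrelated.  Imputation uncertainty is
emulated as deterministic shrinkage of each dosage toward its expectation
2*CAF in proportion to (1 - quality); this preserves allele-frequency
estimates while attenuating per-variant information, which is what the
effective-heterozygosity filter downstream responds to.

All traits are simulated on the standardized scale (residual variance 1);
planted genetic effects are per coded-allele-copy effects on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_TRAITS",
    "default_trait_corr",
    "CausalEffect",
    "SimConfig",
    "VariantPanel",
    "PhenotypeTable",
    "generate_genotypes",
    "generate_phenotypes",
    "generate_dataset",
    "write_dataset",
]

#: Trait names used when seven traits are simulated: the three primary red
#: blood cell indices (hematocrit, hemoglobin, RBC count) and four derived
#: ones (mean corpuscular hemoglobin/…concentration, mean corpuscular volume,
#: RBC distribution width).
DEFAULT_TRAITS = ("HCT", "HGB", "MCH", "MCHC", "MCV", "RBCC", "RDW")

# Residual (covariate-adjusted) correlation among the seven traits.  Anchored
# at the strongly coupled HCT-HGB pair (0.94), the essentially independent
# HCT-MCHC pair (-0.02) and HGB-RBCC (0.68); remaining entries follow the
# physiological coupling of the derived indices and were projected to the
# nearest positive-definite correlation matrix.
_CORR7 = np.array(
    [
        [1.00, 0.94, 0.26, -0.02, 0.41, 0.61, -0.10],
        [0.94, 1.00, 0.35, 0.27, 0.36, 0.68, -0.19],
        [0.26, 0.35, 1.00, 0.55, 0.86, -0.40, -0.30],
        [-0.02, 0.27, 0.55, 1.00, 0.11, 0.01, -0.35],
        [0.41, 0.36, 0.86, 0.11, 1.00, -0.38, -0.25],
        [0.61, 0.68, -0.40, 0.01, -0.38, 1.00, 0.10],
        [-0.10, -0.19, -0.30, -0.35, -0.25, 0.10, 1.00],
    ]
)


def default_trait_corr(n_traits: int = 7) -> np.ndarray:
    """Default residual trait correlation matrix (identity unless K = 7)."""
    if n_traits == 7:
        return _CORR7.copy()
    return np.eye(n_traits)


@dataclass(frozen=True)
class CausalEffect:
    """A planted per-allele effect of one variant on one trait."""

    variant: int
    trait: int
    beta: float


@dataclass
class SimConfig:
    """Configuration of one synthetic multi-subgroup dataset.

    Parameters
    ----------
    n_samples_per_subgroup
        Sample size of each analytic subgroup; its length defines the number
        of subgroups.
    n_variants, n_traits
        Panel dimensions.  Seven traits by default.
    trait_corr
        K x K residual correlation matrix (symmetric, unit diagonal, PSD).
    allele_freq_ranges
        Per-subgroup (min, max) coded-allele-frequency range from which each
        variant's subgroup frequency is drawn uniformly.
    ld_block_size, ld_rho
        AR(1) copula parameters: correlation ``ld_rho`` between latent
        variables of adjacent variants within blocks of ``ld_block_size``.
    causal_effects
        Planted (variant, trait, beta) effects, shared across subgroups.
    n_covariates, covariate_effects
        Number of nuisance covariates (the first is a binary sex-like
        indicator, the rest continuous age/site/PC-like scores) and their
        common linear effect on every trait.
    imputation_quality_range
        Per-variant imputation quality drawn uniformly from this range.
    monomorphic_fraction
        Per-subgroup fraction of variants forced to frequency 0 (dosage
        constant 0), emulating ancestry-specific variants.
    monomorphic_variants
        Optional explicit {subgroup index: [variant indices]} assignment; it
        overrides ``monomorphic_fraction`` for the listed subgroups.
    chromosome, position_start, position_spacing
        Physical coordinates (1-based): variant ``m`` sits at
        ``position_start + m * position_spacing``.
    """

    n_samples_per_subgroup: Sequence[int] = (2000,)
    n_variants: int = 200
    n_traits: int = 7
    trait_corr: np.ndarray | None = None
    allele_freq_ranges: Sequence[tuple[float, float]] | None = None
    ld_block_size: int = 10
    ld_rho: float = 0.0
    causal_effects: Sequence[CausalEffect | tuple] = ()
    n_covariates: int = 4
    covariate_effects: Sequence[float] | None = None
    imputation_quality_range: tuple[float, float] = (0.7, 1.0)
    monomorphic_fraction: Sequence[float] | None = None
    monomorphic_variants: dict[int, Sequence[int]] | None = None
    chromosome: str = "1"
    position_start: int = 1_000_000
    position_spacing: int = 5_000
    seed: int = 0
    trait_names: Sequence[str] = field(default_factory=tuple)

    @property
    def n_subgroups(self) -> int:
        return len(self.n_samples_per_subgroup)

    def __post_init__(self) -> None:
        if self.trait_corr is None:
            self.trait_corr = default_trait_corr(self.n_traits)
        self.trait_corr = np.asarray(self.trait_corr, dtype=float)
        if self.allele_freq_ranges is None:
            self.allele_freq_ranges = [(0.05, 0.5)] * self.n_subgroups
        if self.monomorphic_fraction is None:
            self.monomorphic_fraction = [0.0] * self.n_subgroups
        if self.covariate_effects is None:
            self.covariate_effects = [0.1] * self.n_covariates
        self.causal_effects = [
            e if isinstance(e, CausalEffect) else CausalEffect(*e)
            for e in self.causal_effects
        ]
        if not self.trait_names:
            if self.n_traits == 7:
                self.trait_names = DEFAULT_TRAITS
            else:
                self.trait_names = tuple(f"T{k + 1}" for k in range(self.n_traits))
        self.validate()

    def validate(self) -> None:
        R = self.trait_corr
        if R.shape != (self.n_traits, self.n_traits):
            raise ValueError("trait_corr shape does not match n_traits")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("trait_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("trait_corr must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValueError("trait_corr is not positive semi-definite")
        if len(self.allele_freq_ranges) != self.n_subgroups:
            raise ValueError("allele_freq_ranges must have one entry per subgroup")
        for lo, hi in self.allele_freq_ranges:
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError(f"allele frequency range ({lo}, {hi}) outside (0, 1)")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.imputation_quality_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("imputation_quality_range outside (0, 1]")
        for f in self.monomorphic_fraction:
            if not (0.0 <= f <= 1.0):
                raise ValueError("monomorphic_fraction outside [0, 1]")
        for e in self.causal_effects:
            if not (0 <= e.variant < self.n_variants):
                raise ValueError(f"causal variant index {e.variant} out of range")
            if not (0 <= e.trait < self.n_traits):
                raise ValueError(f"causal trait index {e.trait} out of range")

    def covariate_names(self) -> list[str]:
        names = []
        for j in range(self.n_covariates):
            if j == 0:
                names.append("SEX")
            elif j == 1:
                names.append("AGE")
            else:
                names.append(f"PC{j - 1}")
        return names


@dataclass
class VariantPanel:
    """Per-variant metadata plus a samples x variants dosage matrix."""

    subgroup_id: str
    variant_meta: pd.DataFrame  # variant_id, chromosome, position, alleles, CAF, quality
    dosages: np.ndarray  # (n_samples, n_variants), values in [0, 2]
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def dosage_of(self, variant_id: str) -> np.ndarray:
        idx = self.variant_meta.index[self.variant_meta["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in panel {self.subgroup_id}")
        return self.dosages[:, idx[0]]


@dataclass
class PhenotypeTable:
    """One row per sample: trait values plus covariates."""

    subgroup_id: str
    data: pd.DataFrame  # sample_id, <traits...>, <covariates...>
    trait_names: list[str]
    covariate_names: list[str]


def _subgroup_rng(config: SimConfig, subgroup: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(subgroup), int(stream)])
    )


def _subgroup_frequencies(config: SimConfig, subgroup: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant coded-allele frequencies and the monomorphic mask."""
    rng = _subgroup_rng(config, subgroup, 0)
    lo, hi = config.allele_freq_ranges[subgroup]
    freqs = rng.uniform(lo, hi, size=config.n_variants)
    mono = np.zeros(config.n_variants, dtype=bool)
    if config.monomorphic_variants is not None and subgroup in config.monomorphic_variants:
        mono[np.asarray(list(config.monomorphic_variants[subgroup]), dtype=int)] = True
    else:
        frac = config.monomorphic_fraction[subgroup]
        if frac > 0:
            n_mono = int(round(frac * config.n_variants))
            mono[rng.choice(config.n_variants, size=n_mono, replace=False)] = True
    freqs[mono] = 0.0
    return freqs, mono


def _ar1_latents(rng: np.random.Generator, n: int, m: int, rho: float, block: int) -> np.ndarray:
    """n x m latent standard normals, AR(1) within blocks of ``block`` columns."""
    z = rng.standard_normal((n, m))
    if rho == 0.0 or block <= 1:
        return z
    x = np.empty_like(z)
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(m):
        if j % block == 0:
            x[:, j] = z[:, j]
        else:
            x[:, j] = rho * x[:, j - 1] + scale * z[:, j]
    return x


def generate_genotypes(config: SimConfig, subgroup: int = 0) -> VariantPanel:
    """Simulate a dosage panel for one analytic subgroup.

    Two haploid allele vectors are drawn per sample by thresholding AR(1)
    latent normals at the quantile of each variant's subgroup frequency
    (Hardy-Weinberg by construction); the hard genotype is then shrunk toward
    2*CAF in proportion to (1 - imputation quality).
    """
    config.validate()
    n = int(config.n_samples_per_subgroup[subgroup])
    m = config.n_variants
    freqs, mono = _subgroup_frequencies(config, subgroup)
    rng = _subgroup_rng(config, subgroup, 1)

    # Monomorphic columns would need a -inf threshold; give them any finite
    # one and overwrite the dosage with 0 afterwards.
    thresh = stats.norm.ppf(np.where(mono, 0.5, np.clip(freqs, 1e-12, 1 - 1e-12)))
    hap1 = _ar1_latents(rng, n, m, config.ld_rho, config.ld_block_size) < thresh
    hap2 = _ar1_latents(rng, n, m, config.ld_rho, config.ld_block_size) < thresh
    dosages = (hap1.astype(float) + hap2.astype(float))
    dosages[:, mono] = 0.0

    qual = _subgroup_rng(config, subgroup, 2).uniform(
        config.imputation_quality_range[0], config.imputation_quality_range[1], size=m
    )
    expected = 2.0 * freqs
    dosages = expected + qual * (dosages - expected)

    positions = config.position_start + np.arange(m) * config.position_spacing
    meta = pd.DataFrame(
        {
            "variant_id": [f"var{j + 1}" for j in range(m)],
            "chromosome": config.chromosome,
            "position": positions,
            "coded_allele": "A",
            "other_allele": "G",
            "CAF": freqs,
            "imputation_quality": qual,
        }
    )
    sample_ids = [f"S{subgroup}_{i + 1}" for i in range(n)]
    return VariantPanel(
        subgroup_id=f"SG{subgroup + 1}",
        variant_meta=meta,
        dosages=dosages,
        sample_ids=sample_ids,
    )


def generate_phenotypes(panel: VariantPanel, config: SimConfig, subgroup: int = 0) -> PhenotypeTable:
    """Simulate trait and covariate values for the samples of ``panel``.

    Each trait is the sum of planted genetic effects on centered dosages,
    linear covariate effects, and a multivariate-normal residual with
    correlation ``config.trait_corr`` and unit variances.
    """
    n = panel.n_samples
    if n != config.n_samples_per_subgroup[subgroup]:
        raise ValueError("panel sample count does not match config subgroup size")
    if panel.n_variants != config.n_variants:
        raise ValueError("panel variant count does not match config")
    K = config.n_traits
    rng = _subgroup_rng(config, subgroup, 3)

    X = rng.standard_normal((n, config.n_covariates))
    if config.n_covariates >= 1:
        X[:, 0] = rng.integers(0, 2, size=n).astype(float)

    genetic = np.zeros((n, K))
    for e in config.causal_effects:
        d = panel.dosages[:, e.variant]
        genetic[:, e.trait] += e.beta * (d - d.mean())

    L = np.linalg.cholesky(config.trait_corr + 1e-10 * np.eye(K))
    resid = rng.standard_normal((n, K)) @ L.T
    covar_part = X @ np.asarray(config.covariate_effects, dtype=float)
    traits = genetic + covar_part[:, None] + resid

    data = pd.DataFrame({"sample_id": panel.sample_ids})
    for k, name in enumerate(config.trait_names):
        data[name] = traits[:, k]
    for j, name in enumerate(config.covariate_names()):
        data[name] = X[:, j]
    return PhenotypeTable(
        subgroup_id=panel.subgroup_id,
        data=data,
        trait_names=list(config.trait_names),
        covariate_names=config.covariate_names(),
    )


def generate_dataset(config: SimConfig) -> tuple[list[VariantPanel], list[PhenotypeTable]]:
    """All subgroups' panels and phenotype tables for one configuration."""
    panels, phenos = [], []
    for s in range(config.n_subgroups):
        panel = generate_genotypes(config, s)
        panels.append(panel)
        phenos.append(generate_phenotypes(panel, config, s))
    return panels, phenos


def write_dataset(
    panels: Sequence[VariantPanel],
    phenotypes: Sequence[PhenotypeTable],
    out_dir: str | Path,
    config: SimConfig | None = None,
) -> list[Path]:
    """Write dosage, phenotype and ground-truth manifest files.

    One dosage file and one phenotype file per subgroup, tab-delimited, plus
    a YAML manifest echoing the seed and the planted causal effects.
    """
    from . import io as io_mod  # deferred: io imports this module's types

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for panel, pheno in zip(panels, phenotypes):
        dp = out_dir / f"dosage_{panel.subgroup_id}.tsv"
        pp = out_dir / f"pheno_{panel.subgroup_id}.tsv"
        io_mod.write_dosage(panel, dp)
        io_mod.write_phenotypes(pheno, pp)
        written += [dp, pp]
    if config is not None:
        import yaml

        manifest = {
            "seed": int(config.seed),
            "n_subgroups": config.n_subgroups,
            "n_samples_per_subgroup": [int(x) for x in config.n_samples_per_subgroup],
            "n_variants": int(config.n_variants),
            "n_traits": int(config.n_traits),
            "ld_block_size": int(config.ld_block_size),
            "ld_rho": float(config.ld_rho),
            "causal_effects": [
                {
                    "variant_id": f"var{e.variant + 1}",
                    "trait": str(config.trait_names[e.trait]),
                    "beta": float(e.beta),
                }
                for e in config.causal_effects
            ],
        }
        mp = out_dir / "manifest.yaml"
        with open(mp, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        written.append(mp)
    return written
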