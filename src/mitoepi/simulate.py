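"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: diploid nuclear
SNPs in Hardy-Weinberg equilibrium with optional AR(1)-latent LD and
embedded full-sib pairs, homoplasmic (haploid 0/1) mitochondrial variants
shared maternally within sib pairs, and BMI built from covariates, additive
mito and nuclear effects, a mito x nuclear product term, a kinship-correlated
polygenic term and (optionally genotype-class-scaled) residual noise:

    bmi = b0 + sum_c beta_c * covariate_c + beta_mito * g_m + beta_nuc * g_n
          + beta_inter * g_m * g_n + u + eps,
    u ~ N(0, sigma_poly^2 * K_true),   eps_i ~ N(0, sigma_e^2 * m(g_n_i)^2)

with K_true the pedigree relatedness (sib-pair blocks) and m(.) the
per-genotype residual-SD multiplier (1 everywhere unless a variance effect
is configured). Fixed seed => bit-reproducible cohort.

Default cohort scale (n = 1000 samples, 500 nuclear SNPs, 30 haploid
mitochondrial variants) mirrors a small clinical GWAS cohort with a
mitochondrial array panel of a few dozen variants surviving frequency
filtering. Default covariate distributions follow such a cohort: age
~ N(28.5, 5) years, sex ~ Bernoulli(0.5), glucose ~ N(100, 15) mg/dL,
baseline BMI 24 kg/m^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from mitoepi.io import (
    GenotypeMatrix,
    PhenotypeTable,
    VariantInfo,
    write_vcf,
)
import pandas as pd


@dataclass
class SimulationConfig:
    """Parameters of the generative model. See module docstring for the model."""

    n_samples: int = 1000
    n_nuclear_snps: int = 500
    n_mito_snps: int = 30
    #: per-SNP MAFs; a scalar broadcasts, None draws Uniform(0.05, 0.5) / (0.05, 0.3)
    nuclear_mafs: float | Sequence[float] | None = None
    mito_mafs: float | Sequence[float] | None = None
    ld_block_size: int = 1
    ld_rho: float = 0.0
    n_sib_pairs: int = 0
    # covariate model
    age_mean: float = 28.5
    age_sd: float = 5.0
    sex_p: float = 0.5
    glucose_mean: float = 100.0
    glucose_sd: float = 15.0
    # fixed effects
    beta0: float = 24.0
    beta_covariates: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.05, "sex": 1.0}
    )
    beta_mito: float = 0.0
    beta_nuc: float = 0.0
    #: interaction effect per designated causal (mito, nuclear) pair
    beta_inter: float = 0.0
    causal_mito: str | None = None
    causal_nuc: str | None = None
    #: extra causal pairs as (mito_id, nuc_id, beta_inter)
    extra_causal_pairs: Sequence[tuple[str, str, float]] = ()
    # variance structure
    sigma_poly: float = 0.0
    sigma_e: float = 1.0
    #: residual-SD multiplier per genotype class {0,1,2} of variance_variant
    variance_effect: Mapping[int, float] | None = None
    variance_variant: str | None = None
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if 2 * self.n_sib_pairs > self.n_samples:
            raise ValueError("2*n_sib_pairs exceeds n_samples")
        for name in ("sigma_poly", "sigma_e", "age_sd", "glucose_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        for mafs in (self.nuclear_mafs, self.mito_mafs):
            if mafs is None:
                continue
            arr = np.atleast_1d(np.asarray(mafs, dtype=float))
            if np.any(arr <= 0.0) or np.any(arr > 0.5):
                raise ValueError("MAFs must lie in (0, 0.5]")

    def resolved_mafs(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        def expand(mafs, n, lo, hi):
            if mafs is None:
                return rng.uniform(lo, hi, size=n)
            arr = np.atleast_1d(np.asarray(mafs, dtype=float))
            if arr.size == 1:
                return np.full(n, arr[0])
            if arr.size != n:
                raise ValueError("MAF list length does not match SNP count")
            return arr.copy()

        return (
            expand(self.nuclear_mafs, self.n_nuclear_snps, 0.05, 0.5),
            expand(self.mito_mafs, self.n_mito_snps, 0.05, 0.3),
        )


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict

    def __post_init__(self) -> None:
        vids = set(self.genotypes.variant_ids)
        sids = set(self.genotypes.sample_ids)
        for pair in self.truth.get("causal_pairs", []):
            for vid in (pair["mito"], pair["nuc"]):
                if vid is not None and vid not in vids:
                    raise ValueError(f"truth references unknown variant {vid}")
        for a, b in self.truth.get("sib_pairs", []):
            if a not in sids or b not in sids:
                raise ValueError("truth references unknown sample id")


def _nuclear_variant_ids(cfg: SimulationConfig) -> list[VariantInfo]:
    return [
        VariantInfo(f"nuc{j:05d}", "1", 10_000 * (j + 1), "A", "G")
        for j in range(cfg.n_nuclear_snps)
    ]


def _mito_variant_ids(cfg: SimulationConfig) -> list[VariantInfo]:
    return [
        VariantInfo(f"mt{j:03d}", "chrMT", 100 * (j + 1), "A", "G")
        for j in range(cfg.n_mito_snps)
    ]


def _haplotypes(
    rng: np.random.Generator, n_hap: int, mafs: np.ndarray, block: int, rho: float
) -> np.ndarray:
    """n_hap x m 0/1 haplotypes; alleles from thresholded AR(1) latent Gaussians.

    Marginals are exactly Bernoulli(maf); within a block adjacent latents have
    correlation rho, inducing tunable LD without haplotype panels.
    """
    m = mafs.size
    z = rng.standard_normal((n_hap, m))
    if rho > 0.0 and block > 1:
        innov = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            if j % block:  # stays inside the current block
                z[:, j] = rho * z[:, j - 1] + innov * z[:, j]
    thresh = stats.norm.ppf(mafs)
    return (z < thresh[None, :]).astype(np.int8)


def simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw the genotype matrix: HWE diploid nuclear SNPs (optionally in LD,
    with embedded full-sib pairs) plus haploid mitochondrial variants.

    Sib pairs occupy the last ``2*n_sib_pairs`` rows; each sib inherits one
    allele per SNP from each simulated parent (transmissions independent
    across SNPs) and the pair shares the maternal mitochondrial genotype.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    nuc_mafs, mito_mafs = cfg.resolved_mafs(rng)
    n, npairs = cfg.n_samples, cfg.n_sib_pairs
    n_unrel = n - 2 * npairs
    m = cfg.n_nuclear_snps

    hap = _haplotypes(rng, 2 * n_unrel, nuc_mafs, cfg.ld_block_size, cfg.ld_rho)
    geno_unrel = hap[0::2] + hap[1::2]

    sib_rows = []
    mito_unrel = (rng.random((n_unrel, cfg.n_mito_snps)) < mito_mafs[None, :]).astype(
        np.int8
    )
    mito_sibs = []
    for _ in range(npairs):
        parents = _haplotypes(rng, 4, nuc_mafs, cfg.ld_block_size, cfg.ld_rho)
        mother, father = parents[:2], parents[2:]
        for _sib in range(2):
            pick_m = rng.integers(0, 2, size=m)
            pick_f = rng.integers(0, 2, size=m)
            child = mother[pick_m, np.arange(m)] + father[pick_f, np.arange(m)]
            sib_rows.append(child)
        mt = (rng.random(cfg.n_mito_snps) < mito_mafs).astype(np.int8)
        mito_sibs.extend([mt, mt.copy()])  # maternal inheritance

    nuclear = (
        np.vstack([geno_unrel] + [np.asarray(sib_rows)])
        if sib_rows
        else geno_unrel
    )
    mito = np.vstack([mito_unrel] + mito_sibs) if mito_sibs else mito_unrel

    sample_ids = [f"S{i:05d}" for i in range(n)]
    variants = _nuclear_variant_ids(cfg) + _mito_variant_ids(cfg)
    dosages = np.hstack([nuclear, mito]).astype(float)
    return GenotypeMatrix(sample_ids, variants, dosages)


def _true_kinship_blocks(cfg: SimulationConfig) -> np.ndarray:
    """Pedigree relatedness matrix (GRM scale): identity + 0.5 sib off-diagonals."""
    n = cfg.n_samples
    K = np.eye(n)
    start = n - 2 * cfg.n_sib_pairs
    for k in range(cfg.n_sib_pairs):
        i, j = start + 2 * k, start + 2 * k + 1
        K[i, j] = K[j, i] = 0.5
    return K


def simulate_phenotype(
    g: GenotypeMatrix, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> PhenotypeTable:
    """Generate covariates and BMI for the samples of ``g`` under the model
    in the module docstring."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = g.n_samples
    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n)
    sex = (rng.random(n) < cfg.sex_p).astype(float)
    glucose = rng.normal(cfg.glucose_mean, cfg.glucose_sd, size=n)
    cov = {"age": age, "sex": sex, "glucose": glucose}

    y = np.full(n, cfg.beta0, dtype=float)
    for name, beta in cfg.beta_covariates.items():
        if name not in cov:
            raise ValueError(f"unknown covariate {name!r} in beta_covariates")
        y += beta * cov[name]

    vids = set(g.variant_ids)
    for vid in (cfg.causal_mito, cfg.causal_nuc, cfg.variance_variant):
        if vid is not None and vid not in vids:
            raise ValueError(f"causal variant {vid!r} not in genotype matrix")

    g_m = g.dosage_of(cfg.causal_mito) if cfg.causal_mito else np.zeros(n)
    g_n = g.dosage_of(cfg.causal_nuc) if cfg.causal_nuc else np.zeros(n)
    y += cfg.beta_mito * g_m + cfg.beta_nuc * g_n + cfg.beta_inter * g_m * g_n
    for mito_id, nuc_id, beta in cfg.extra_causal_pairs:
        if mito_id not in vids or nuc_id not in vids:
            raise ValueError(f"causal pair ({mito_id}, {nuc_id}) not in matrix")
        y += beta * g.dosage_of(mito_id) * g.dosage_of(nuc_id)

    if cfg.sigma_poly > 0:
        K = _true_kinship_blocks(cfg)
        y += cfg.sigma_poly * np.linalg.cholesky(K) @ rng.standard_normal(n)

    sd = np.full(n, cfg.sigma_e, dtype=float)
    if cfg.variance_effect is not None:
        if cfg.variance_variant is None:
            raise ValueError("variance_effect requires variance_variant")
        classes = g.dosage_of(cfg.variance_variant)
        mult = np.ones(n)
        for cls, mfac in cfg.variance_effect.items():
            mult[classes == cls] = mfac
        sd *= mult
    y += sd * rng.standard_normal(n)

    df = pd.DataFrame(
        {"sample_id": g.sample_ids, "bmi": y, "age": age, "sex": sex, "glucose": glucose}
    )
    return PhenotypeTable(df)


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Full cohort draw (genotypes, phenotypes, truth record) from one seed."""
    rng = np.random.default_rng(cfg.seed)
    g = simulate_genotypes(cfg, rng)
    p = simulate_phenotype(g, cfg, rng)
    start = cfg.n_samples - 2 * cfg.n_sib_pairs
    sib_pairs = [
        (g.sample_ids[start + 2 * k], g.sample_ids[start + 2 * k + 1])
        for k in range(cfg.n_sib_pairs)
    ]
    pairs = []
    if cfg.causal_mito or cfg.causal_nuc:
        pairs.append(
            {
                "mito": cfg.causal_mito,
                "nuc": cfg.causal_nuc,
                "beta_mito": cfg.beta_mito,
                "beta_nuc": cfg.beta_nuc,
                "beta_inter": cfg.beta_inter,
            }
        )
    for mito_id, nuc_id, beta in cfg.extra_causal_pairs:
        pairs.append(
            {"mito": mito_id, "nuc": nuc_id, "beta_mito": 0.0, "beta_nuc": 0.0,
             "beta_inter": beta}
        )
    truth = {
        "seed": cfg.seed,
        "causal_pairs": pairs,
        "sib_pairs": sib_pairs,
        "sigma_poly": cfg.sigma_poly,
        "sigma_e": cfg.sigma_e,
        "variance_effect": dict(cfg.variance_effect) if cfg.variance_effect else None,
        "variance_variant": cfg.variance_variant,
    }
    return SyntheticCohort(g, p, truth)


def export_cohort(cohort: SyntheticCohort, outdir: str | Path, overwrite: bool = False) -> dict:
    """Write genotypes.vcf, phenotypes.tsv and truth.json; returns the paths.

    Re-reading the files through :mod:`mitoepi.io` reproduces the cohort;
    with a fixed config the VCF is byte-identical across runs.
    """
    outdir = Path(outdir)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.json",
    }
    if outdir.exists() and not overwrite:
        clashes = [p for p in paths.values() if p.exists()]
        if clashes:
            raise FileExistsError(
                f"{clashes[0]} exists; pass overwrite=True to replace"
            )
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(cohort.genotypes, paths["vcf"])
    cohort.phenotypes.data.to_csv(paths["phenotypes"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
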