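"""End-to-end orchestration: QC -> GRM -> mitoGWAS -> dispersion screen ->
interaction scan, with plain-file stage outputs, a manifest and a synthetic
demo cohort.

Stage results are files, not an in-memory monolith, so any stage can be
inspected or re-consumed; the manifest records versions, the seed, a config
hash and each stage's inputs/outputs (and asserts the stage graph is
acyclic: no stage consumes a file it also writes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import yaml

import mitoepi
from mitoepi import assoc as assoc_mod
from mitoepi import epistasis as epi_mod
from mitoepi import kinship as kin_mod
from mitoepi import qc as qc_mod
from mitoepi import screen as screen_mod
from mitoepi.io import (
    GenotypeMatrix,
    align_cohort,
    read_phenotypes,
    read_vcf,
    write_results_table,
)
from mitoepi.simulate import SimulationConfig, export_cohort, simulate_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """All thresholds and paths for one pipeline run.

    Either ``simulate`` (inline cohort generation) or both ``vcf`` and
    ``phenotypes`` must be given. Threshold defaults follow array-GWAS
    practice: sample call rate 0.95 (0.99 on the mitochondrial subset),
    HWE P < 1e-5, kinship 0.0442, MAF 0.05.
    """

    outdir: str = "mitoepi_run"
    vcf: str | None = None
    phenotypes: str | None = None
    simulate: SimulationConfig | None = None
    covariates: tuple[str, ...] = ("age", "sex")
    sample_call_rate: float = qc_mod.SAMPLE_CALL_RATE
    mito_sample_call_rate: float = qc_mod.MITO_SAMPLE_CALL_RATE
    variant_call_rate: float = 0.95
    hwe_pval: float = qc_mod.HWE_PVAL_THRESHOLD
    kinship_threshold: float = qc_mod.KINSHIP_THRESHOLD
    min_maf: float = 0.05
    het_sd_window: float = 3.0
    pca_components: int = 2
    pca_sd_window: float = 3.0
    mito_variant: str | None = None  # screen/epistasis target; default: top hit
    screen_perm: int = 200
    screen_alpha: float = 0.05
    min_class_size: int = 10
    grm_in_epistasis: bool = False
    seed: int | None = 17

    def __post_init__(self) -> None:
        if self.simulate is None and (self.vcf is None or self.phenotypes is None):
            raise ConfigError("need simulate: or both vcf: and phenotypes:")
        for name in ("sample_call_rate", "mito_sample_call_rate", "variant_call_rate"):
            if not 0 < getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")
        if not 0 <= self.min_maf < 0.5:
            raise ConfigError("min_maf must be in [0, 0.5)")
        if not 0 < self.screen_alpha < 1:
            raise ConfigError("screen_alpha must be in (0, 1)")
        if self.seed is None:
            raise ConfigError("seed is required (stochastic stages present)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        sim = raw.pop("simulate", None)
        if sim is not None:
            ve = sim.get("variance_effect")
            if isinstance(ve, dict):
                sim["variance_effect"] = {int(k): float(v) for k, v in ve.items()}
            ecp = sim.get("extra_causal_pairs")
            if ecp is not None:
                sim["extra_causal_pairs"] = [tuple(x) for x in ecp]
            try:
                sim = SimulationConfig(**sim)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"simulate: {exc}") from exc
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        try:
            return cls(simulate=sim, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["extra_causal_pairs"] = [list(t) for t in self.simulate.extra_causal_pairs]
            d["simulate"] = sim
        d["covariates"] = list(self.covariates)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_cohort(cfg: PipelineConfig, outdir: Path, manifest: list[dict]):
    if cfg.simulate is not None:
        cohort = simulate_cohort(cfg.simulate)
        paths = export_cohort(cohort, outdir / "input", overwrite=True)
        manifest.append(
            {"stage": "simulate", "inputs": [], "outputs": sorted(paths.values())}
        )
        return cohort.genotypes, cohort.phenotypes
    g = read_vcf(cfg.vcf)
    p = read_phenotypes(cfg.phenotypes)
    manifest.append(
        {"stage": "load", "inputs": [cfg.vcf, cfg.phenotypes], "outputs": []}
    )
    return g, p


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage, writing qc_report.json, grm.tsv, assoc.tsv,
    screen.tsv, inter.tsv, summary.md and manifest.json under ``outdir``.

    Deterministic for a fixed (config, seed). A stage failure propagates
    after partial outputs are preserved on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    g, p = _load_cohort(cfg, outdir, manifest)
    g, p = align_cohort(g, p)
    counts = {"input": {"samples": g.n_samples, "variants": g.n_variants}}

    # --- QC cascade: call rate -> duplicates -> heterozygosity -> HWE ->
    # kinship -> PCA outliers, then the MAF filter feeding the scans
    report = qc_mod.QcReport()
    g1, rep = qc_mod.filter_call_rate(g, cfg.sample_call_rate, cfg.variant_call_rate)
    report = report.merged(rep)
    mito_part = g1.subset_variants(g1.haploid)
    if mito_part.n_variants:
        mito_cr = mito_part.sample_call_rate()
        bad = mito_cr < cfg.mito_sample_call_rate
        kept = g1.subset_samples(~bad)
        stage = qc_mod.QcStage(
            "mito_sample_call_rate",
            {g1.sample_ids[i]: f"chrMT call rate {mito_cr[i]:.4f} "
             f"< {cfg.mito_sample_call_rate}" for i in np.flatnonzero(bad)},
            {}, g1.n_samples, kept.n_samples, g1.n_variants, g1.n_variants,
        )
        report.add(stage)
        g1 = kept
    g1, rep = qc_mod.deduplicate_samples(g1, [])
    report = report.merged(rep)
    het_rep = qc_mod.heterozygosity_outliers(g1, cfg.het_sd_window)
    het_flagged = set(het_rep.removed_samples)
    report = report.merged(het_rep)
    if het_flagged:
        g1 = g1.subset_samples(np.array([s not in het_flagged for s in g1.sample_ids]))
    g1, rep = qc_mod.hwe_filter(g1, cfg.hwe_pval)
    report = report.merged(rep)
    king = kin_mod.king_kinship(g1)
    cr_map = dict(zip(g1.sample_ids, g1.sample_call_rate()))
    to_remove = kin_mod.prune_related(king, cfg.kinship_threshold, cr_map)
    g2 = g1.subset_samples(np.array([s not in set(to_remove) for s in g1.sample_ids]))
    stage = qc_mod.QcStage(
        "kinship_prune",
        {s: f"kinship > {cfg.kinship_threshold}" for s in to_remove}, {},
        g1.n_samples, g2.n_samples, g1.n_variants, g1.n_variants,
    )
    report.add(stage)
    pca_rep = qc_mod.pca_outliers(g2, cfg.pca_components, cfg.pca_sd_window)
    pca_flagged = set(pca_rep.removed_samples)
    report = report.merged(pca_rep)
    if pca_flagged:
        g2 = g2.subset_samples(np.array([s not in pca_flagged for s in g2.sample_ids]))
    g3, rep = qc_mod.maf_filter(g2, cfg.min_maf)
    report = report.merged(rep)
    report.to_json(outdir / "qc_report.json")
    manifest.append({"stage": "qc", "inputs": [], "outputs": [str(outdir / "qc_report.json")]})
    g3, p3 = align_cohort(g3, p)
    counts["post_qc"] = {"samples": g3.n_samples, "variants": g3.n_variants}
    logger.info(
        "%d individuals with %d variants passed QC", g3.n_samples, g3.n_variants
    )

    # --- GRM
    kin = kin_mod.grm_from_genotypes(g3)
    kin_mod.write_grm(kin, outdir / "grm.tsv")
    manifest.append({"stage": "grm", "inputs": [], "outputs": [str(outdir / "grm.tsv")]})

    # --- mitoGWAS
    nm = assoc_mod.fit_null_model(p3, list(cfg.covariates), grm=kin.grm)
    scan = assoc_mod.mito_scan(nm, g3, cfg.min_maf)
    write_results_table(scan, outdir / "assoc.tsv", kind=assoc_mod.AssocResult)
    manifest.append({"stage": "assoc", "inputs": [str(outdir / "grm.tsv")],
                     "outputs": [str(outdir / "assoc.tsv")]})

    # --- dispersion screen on the top (or configured) mitochondrial variant
    mito_id = cfg.mito_variant
    if mito_id is None:
        testable = [r for r in scan if np.isfinite(r.pval)]
        if not testable:
            raise DataError("no testable mitochondrial variant for the screen")
        mito_id = testable[0].variant_id
    mito_dos = g3.dosage_of(mito_id)
    nuclear = g3.subset_variants(~g3.haploid)
    screen_results = screen_mod.screen_genome(
        p3, list(cfg.covariates), mito_dos, nuclear,
        min_class_size=cfg.min_class_size, n_perm=cfg.screen_perm,
        perm_alpha=cfg.screen_alpha, seed=cfg.seed, mito_variant_id=mito_id,
    )
    write_results_table(screen_results, outdir / "screen.tsv",
                        kind=screen_mod.ScreenResult)
    manifest.append({"stage": "screen", "inputs": [str(outdir / "assoc.tsv")],
                     "outputs": [str(outdir / "screen.tsv")]})

    # --- interaction scan over the keep set
    candidates = [r.nuc_variant_id for r in screen_results if r.keep]
    inter = epi_mod.interaction_scan(
        p3, list(cfg.covariates), mito_dos, nuclear, candidates,
        grm=kin.grm if cfg.grm_in_epistasis else None, mito_variant_id=mito_id,
    )
    write_results_table(inter, outdir / "inter.tsv", kind=epi_mod.InteractionResult)
    manifest.append({"stage": "epistasis", "inputs": [str(outdir / "screen.tsv")],
                     "outputs": [str(outdir / "inter.tsv")]})

    _check_acyclic(manifest)
    summary = _summary_text(cfg, counts, scan, screen_results, inter, mito_id)
    (outdir / "summary.md").write_text(summary)
    (outdir / "manifest.json").write_text(json.dumps({
        "versions": {"mitoepi": mitoepi.__version__, "numpy": np.__version__},
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": manifest,
        "counts": counts,
    }, indent=2, sort_keys=True) + "\n")
    return outdir


def _check_acyclic(manifest: list[dict]) -> None:
    for st in manifest:
        overlap = set(st["inputs"]) & set(st["outputs"])
        if overlap:
            raise RuntimeError(f"stage {st['stage']} reads and writes {overlap}")


def _summary_text(cfg, counts, scan, screen_results, inter, mito_id) -> str:
    lines = ["# mitoepi run summary", ""]
    lines.append(f"- samples in: {counts['input']['samples']}, "
                 f"post-QC: {counts['post_qc']['samples']}")
    lines.append(f"- variants in: {counts['input']['variants']}, "
                 f"post-QC: {counts['post_qc']['variants']}")
    if scan:
        top = scan[0]
        lines.append(
            f"- top mitochondrial association: {top.variant_id} "
            f"(beta = {top.beta:.4g}, SE = {top.se:.4g}, p = {top.pval:.3g})"
        )
    kept = [r for r in screen_results if r.keep]
    lines.append(
        f"- dispersion screen vs {mito_id}: kept {len(kept)} of "
        f"{len(screen_results)} nuclear variants"
    )
    if inter:
        t = inter[0]
        lines.append(
            f"- top interaction: {t.mito_variant_id} x {t.nuc_variant_id} "
            f"(inter_eff = {t.inter_eff:.4g}, inter_pval = {t.inter_pval:.3g})"
        )
    else:
        lines.append("- no interaction candidates survived the screen")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Demo
# ---------------------------------------------------------------------------

def make_demo(seed: int = 17, outdir: str | Path = "mitoepi_demo") -> PipelineConfig:
    """Self-contained worked example: n = 600, 300 nuclear SNPs (5 true
    interactors at beta_inter = 1.5), 20 mitochondrial variants (one causal,
    beta = -0.7, MAF 0.2). Writes the cohort files plus a YAML config and
    returns the config."""
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    n_nuc, n_mito = 300, 20
    nuc_mafs = rng.uniform(0.05, 0.5, size=n_nuc)
    mito_mafs = rng.uniform(0.05, 0.3, size=n_mito)
    interactors = [f"nuc{j:05d}" for j in (10, 60, 110, 160, 210)]
    for j in (10, 60, 110, 160, 210):
        nuc_mafs[j] = 0.3
    mito_mafs[0] = 0.2
    sim = SimulationConfig(
        n_samples=600, n_nuclear_snps=n_nuc, n_mito_snps=n_mito,
        nuclear_mafs=nuc_mafs.round(4).tolist(), mito_mafs=mito_mafs.round(4).tolist(),
        n_sib_pairs=5,
        beta_mito=-0.7, causal_mito="mt000",
        extra_causal_pairs=tuple(("mt000", v, 1.5) for v in interactors),
        sigma_poly=0.5, sigma_e=1.5, seed=seed,
    )
    # 300 SNPs put the KING noise floor (SD ~ 0.05) above the third-degree
    # cutoff, so the demo prunes duplicates only and lets the GRM random
    # effect absorb sib-pair correlation
    cfg = PipelineConfig(
        outdir=str(outdir), simulate=sim, mito_variant="mt000", seed=seed,
        kinship_threshold=0.354,
    )
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    return cfg
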