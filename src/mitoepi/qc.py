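"""Cohort quality control.

The cascade mirrors standard array-GWAS practice: sample/variant call-rate
filters, duplicate resolution, heterozygosity outliers, an exact
Hardy-Weinberg test, kinship pruning (see :mod:`mitoepi.kinship`) and a PCA
outlier flag standing in for reference-panel ancestry assignment. Defaults:
sample call rate 0.95 (0.99 for the mitochondrial subset), HWE P < 1e-5,
kinship 0.0442, outlier windows 3 SD.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats
from scipy.special import gammaln

from mitoepi.io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: kinship above this marks third-degree relatives or closer
KINSHIP_THRESHOLD = 0.0442
HWE_PVAL_THRESHOLD = 1e-5
SAMPLE_CALL_RATE = 0.95
MITO_SAMPLE_CALL_RATE = 0.99


@dataclass
class QcStage:
    """One step of the QC cascade with its removals and before/after counts."""

    name: str
    removed_samples: dict[str, str] = field(default_factory=dict)
    removed_variants: dict[str, str] = field(default_factory=dict)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_variants_before: int = 0
    n_variants_after: int = 0

    def validate(self) -> None:
        if self.n_samples_before - len(self.removed_samples) != self.n_samples_after:
            raise ValueError(f"stage {self.name}: inconsistent sample counts")
        if self.n_variants_before - len(self.removed_variants) != self.n_variants_after:
            raise ValueError(f"stage {self.name}: inconsistent variant counts")


@dataclass
class QcReport:
    stages: list[QcStage] = field(default_factory=list)

    def add(self, stage: QcStage) -> None:
        stage.validate()
        self.stages.append(stage)
        logger.info(
            "QC %s: -%d samples, -%d variants (%d samples, %d variants remain)",
            stage.name, len(stage.removed_samples), len(stage.removed_variants),
            stage.n_samples_after, stage.n_variants_after,
        )

    def merged(self, other: "QcReport") -> "QcReport":
        return QcReport(self.stages + other.stages)

    @property
    def removed_samples(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for st in self.stages:
            out.update(st.removed_samples)
        return out

    @property
    def removed_variants(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for st in self.stages:
            out.update(st.removed_variants)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = [
            {
                "name": st.name,
                "removed_samples": st.removed_samples,
                "removed_variants": st.removed_variants,
                "n_samples": [st.n_samples_before, st.n_samples_after],
                "n_variants": [st.n_variants_before, st.n_variants_after],
            }
            for st in self.stages
        ]
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _stage(name: str, g_before: GenotypeMatrix, g_after: GenotypeMatrix,
           removed_samples: dict[str, str] | None = None,
           removed_variants: dict[str, str] | None = None) -> QcStage:
    return QcStage(
        name,
        removed_samples or {},
        removed_variants or {},
        g_before.n_samples, g_after.n_samples,
        g_before.n_variants, g_after.n_variants,
    )


# ---------------------------------------------------------------------------
# Call rate and duplicates
# ---------------------------------------------------------------------------

def filter_call_rate(
    g: GenotypeMatrix,
    sample_threshold: float = SAMPLE_CALL_RATE,
    variant_threshold: float = 0.95,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples with call rate below ``sample_threshold`` (strict), then
    variants below ``variant_threshold``."""
    for t in (sample_threshold, variant_threshold):
        if not 0.0 < t <= 1.0:
            raise ValueError("call-rate thresholds must lie in (0, 1]")
    report = QcReport()
    cr = g.sample_call_rate()
    bad = cr < sample_threshold
    kept = g.subset_samples(~bad)
    if kept.n_samples == 0:
        raise ValueError("call-rate filter removed every sample")
    removed = {
        g.sample_ids[i]: f"sample call rate {cr[i]:.4f} < {sample_threshold}"
        for i in np.flatnonzero(bad)
    }
    report.add(_stage("sample_call_rate", g, kept, removed_samples=removed))

    vcr = kept.variant_call_rate()
    badv = vcr < variant_threshold
    kept2 = kept.subset_variants(~badv)
    removedv = {
        kept.variant_ids[j]: f"variant call rate {vcr[j]:.4f} < {variant_threshold}"
        for j in np.flatnonzero(badv)
    }
    report.add(_stage("variant_call_rate", kept, kept2, removed_variants=removedv))
    return kept2, report


def deduplicate_samples(
    g: GenotypeMatrix, duplicate_pairs: Iterable[tuple[str, str]]
) -> tuple[GenotypeMatrix, QcReport]:
    """Resolve duplicate samples, keeping one representative per duplicate
    group (transitive closure of the pairs): highest call rate wins, ties go
    to the lexicographically smaller id."""
    ids = g.sample_ids
    idx = {s: i for i, s in enumerate(ids)}
    parent = {s: s for s in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in duplicate_pairs:
        if a not in idx or b not in idx:
            raise KeyError(f"duplicate pair ({a}, {b}) references unknown sample")
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    groups: dict[str, list[str]] = {}
    for s in ids:
        groups.setdefault(find(s), []).append(s)
    cr = g.sample_call_rate()
    removed: dict[str, str] = {}
    for members in groups.values():
        if len(members) < 2:
            continue
        best = min(members, key=lambda s: (-cr[idx[s]], s))
        for s in members:
            if s != best:
                removed[s] = f"duplicate of {best} with call rate <= {cr[idx[best]]:.4f}"
    keep_mask = np.array([s not in removed for s in ids])
    kept = g.subset_samples(keep_mask)
    report = QcReport()
    report.add(_stage("deduplicate", g, kept, removed_samples=removed))
    return kept, report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HweResult:
    pval: float
    monomorphic: bool = False
    method: str = "exact"

    def __float__(self) -> float:
        return self.pval


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> HweResult:
    """Exact conditional Hardy-Weinberg test (plain exact, not mid-p).

    Sums, over heterozygote counts compatible with the observed allele
    counts, the probabilities of configurations no more probable than the
    observed one. Monomorphic tables return p = 1 with a flag; totals above
    5000 use a chi-square approximation, flagged in ``method``.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return HweResult(1.0, monomorphic=True)
    if n > 5000:
        p = 2 * n_A / (2.0 * n) * n_a / (2.0 * n)
        expected = np.array([
            n * (n_A / (2.0 * n)) ** 2, n * p, n * (n_a / (2.0 * n)) ** 2,
        ])
        observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        return HweResult(float(stats.chi2.sf(chi2, df=1)), method="chi2")

    rare = min(n_A, n_a)
    h_min = rare % 2
    hs = np.arange(h_min, rare + 1, 2)
    # log P(h) up to a constant: -lgamma terms + h*log(2)
    logp = (
        hs * math.log(2.0)
        - gammaln((n_A - hs) / 2 + 1)
        - gammaln(hs + 1)
        - gammaln((n_a - hs) / 2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hs == n_Aa]
    if p_obs.size == 0:
        raise ValueError("heterozygote count incompatible with allele counts")
    pval = float(probs[probs <= p_obs[0] * (1 + 1e-12)].sum())
    return HweResult(min(1.0, pval))


def hwe_filter(
    g: GenotypeMatrix, pval_threshold: float = HWE_PVAL_THRESHOLD
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove diploid variants deviating from HWE at ``pval_threshold``.

    Haploid (mitochondrial) variants are exempt.
    """
    removed: dict[str, str] = {}
    keep = np.ones(g.n_variants, dtype=bool)
    for j in range(g.n_variants):
        if g.haploid[j]:
            continue
        d = g.dosages[:, j]
        d = d[~np.isnan(d)]
        if d.size == 0:
            continue
        res = hwe_test(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
        if res.pval < pval_threshold:
            keep[j] = False
            removed[g.variant_ids[j]] = f"HWE p {res.pval:.3g} < {pval_threshold}"
    kept = g.subset_variants(keep)
    report = QcReport()
    report.add(_stage("hwe", g, kept, removed_variants=removed))
    return kept, report


# ---------------------------------------------------------------------------
# Sample-level outlier flags
# ---------------------------------------------------------------------------

def heterozygosity_outliers(g: GenotypeMatrix, sd_window: float = 3.0) -> QcReport:
    """Flag samples whose autosomal heterozygosity rate lies beyond
    mean +/- ``sd_window`` SD. Flag-only: the report lists them as removed
    candidates, the matrix is untouched."""
    dip = g.subset_variants(~g.haploid)
    if dip.n_variants < 10:
        raise ValueError("heterozygosity check needs >= 10 diploid variants")
    het = (dip.dosages == 1).sum(axis=1)
    called = (~np.isnan(dip.dosages)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        rate = np.where(called > 0, het / called, np.nan)
    mu, sd = float(np.nanmean(rate)), float(np.nanstd(rate))
    flagged: dict[str, str] = {}
    if np.isfinite(sd_window) and sd > 0:
        out = np.abs(rate - mu) > sd_window * sd
        flagged = {
            g.sample_ids[i]: f"heterozygosity {rate[i]:.4f} outside "
            f"{mu:.4f}+/-{sd_window}x{sd:.4f}"
            for i in np.flatnonzero(out & np.isfinite(rate))
        }
    report = QcReport()
    report.add(QcStage(
        "heterozygosity", flagged, {},
        g.n_samples, g.n_samples - len(flagged), g.n_variants, g.n_variants,
    ))
    return report


def pca_outliers(
    g: GenotypeMatrix, n_components: int = 2, sd_window: float = 3.0
) -> QcReport:
    """Flag samples beyond ``sd_window`` SD on any of the leading PCs of the
    MAF-standardized diploid genotype matrix (mean-imputed missing).

    A light-weight stand-in for reference-panel population assignment:
    ancestry outliers separate on the top PCs. ``n_components = 0`` is a
    no-op. Constant variants are excluded with a log entry.
    """
    report = QcReport()
    if n_components == 0:
        report.add(QcStage("pca_outliers", {}, {}, g.n_samples, g.n_samples,
                           g.n_variants, g.n_variants))
        return report
    dip = g.subset_variants(~g.haploid)
    if dip.n_variants < n_components:
        raise ValueError("need at least n_components diploid variants")
    Z, n_const = _standardized_diploid(dip)
    if n_const:
        logger.info("pca_outliers: %d constant variant(s) excluded", n_const)
    k = min(n_components, Z.shape[1])
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    mu = scores.mean(axis=0)
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    out = np.abs(scores - mu) > sd_window * sd
    flagged = {
        g.sample_ids[i]: "PC outlier on component(s) "
        + ",".join(str(c + 1) for c in np.flatnonzero(out[i]))
        for i in np.flatnonzero(out.any(axis=1))
    }
    report.add(QcStage(
        "pca_outliers", flagged, {},
        g.n_samples, g.n_samples - len(flagged), g.n_variants, g.n_variants,
    ))
    return report


def _standardized_diploid(dip: GenotypeMatrix) -> tuple[np.ndarray, int]:
    """Center diploid dosages at 2p, scale by sqrt(2p(1-p)), zero-impute
    missing; drop monomorphic columns. Returns (Z, n_dropped)."""
    d = dip.dosages
    obs = ~np.isnan(d)
    p = np.nansum(d, axis=0) / (2.0 * obs.sum(axis=0))
    poly = (p > 0) & (p < 1)
    d = d[:, poly]
    p = p[poly]
    Z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    Z[np.isnan(Z)] = 0.0
    return Z, int((~poly).sum())


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def maf_filter(
    g: GenotypeMatrix, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove variants with minor-allele frequency below ``min_maf``
    (boundary inclusive: maf == min_maf is kept).

    MAF is computed on non-missing calls; haploid variants use the allele
    frequency directly (no division by 2). All-missing variants are removed
    with reason "no calls".
    """
    if not 0.0 <= min_maf < 0.5:
        raise ValueError("min_maf must lie in [0, 0.5)")
    maf = g.maf()
    removed: dict[str, str] = {}
    keep = np.ones(g.n_variants, dtype=bool)
    for j in range(g.n_variants):
        if np.isnan(maf[j]):
            keep[j] = False
            removed[g.variant_ids[j]] = "no calls"
        elif maf[j] < min_maf:
            keep[j] = False
            removed[g.variant_ids[j]] = f"maf {maf[j]:.4g} < {min_maf}"
    kept = g.subset_variants(keep)
    report = QcReport()
    report.add(_stage("maf_filter", g, kept, removed_variants=removed))
    return kept, report
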