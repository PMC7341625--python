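"""Mito x nuclear interaction tests with effect decomposition, gene-set
restriction/over-representation, and the expression-level interaction GLM.

For a mitochondrial dosage g_m (haploid 0/1) and a nuclear dosage g_n
(diploid 0/1/2) two nested models are fitted:

    S:  bmi ~ covariates + g_m + g_n
    I:  bmi ~ covariates + g_m + g_n + g_m * g_n

The decomposition reports the nuclear effect in both models (its shift
between S and I is the hallmark of interaction-driven confounding), the
mitochondrial main effect and the interaction coefficient from model I,
each with a two-sided Wald p, plus a 2-df joint test of (nuclear,
interaction) referred to the exact F distribution (identical to the
nested-model sum-of-squares F comparison under least squares). The product
term uses raw dosages (no centering by default), so the interaction effect
is in phenotype units per (mito allele x nuclear alt-allele count) and
rescaling a dosage by c rescales it by 1/c.

With a GRM the fits are generalized least squares under the null variance
ratio (see :mod:`mitoepi.assoc`); the default is plain least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mitoepi.assoc import NullModelFit, _bh_fdr, _lstsq_rss, fit_null_model
from mitoepi.io import GenotypeMatrix, PhenotypeTable, VariantInfo

logger = logging.getLogger(__name__)


@dataclass
class InteractionResult:
    """Single-model and joint-model effects for one variant pair."""

    mito_variant_id: str
    nuc_variant_id: str
    nuc_eff_single: float = float("nan")
    nuc_pval_single: float = float("nan")
    nuc_eff_joint: float = float("nan")
    nuc_pval_joint: float = float("nan")
    mito_eff_joint: float = float("nan")
    mito_pval_joint: float = float("nan")
    inter_eff: float = float("nan")
    inter_se: float = float("nan")
    inter_pval: float = float("nan")
    joint_pval: float = float("nan")
    n: int = 0
    note: str = ""
    fdr_bh: float = float("nan")  # extension column over inter_pval

    def sort_key(self) -> tuple:
        return (self.mito_variant_id, self.nuc_variant_id)


@dataclass
class GeneSetEnrichment:
    set_name: str
    n_hits_in_set: int
    n_hits: int
    n_set: int
    n_universe: int
    odds_ratio: float
    pval: float

    def __post_init__(self) -> None:
        if not (self.n_hits_in_set <= min(self.n_hits, self.n_set) <= self.n_universe):
            raise ValueError("inconsistent enrichment counts")


def _wald(beta: np.ndarray, cov: np.ndarray, idx: int) -> tuple[float, float, float]:
    se = float(np.sqrt(cov[idx, idx]))
    if se == 0 or not np.isfinite(se):
        return float(beta[idx]), float("nan"), float("nan")
    z = beta[idx] / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)))
    return float(beta[idx]), se, p


def test_interaction(
    p: PhenotypeTable,
    covariates: Sequence[str],
    mito_dosage: np.ndarray,
    nuc_dosage: np.ndarray,
    grm: np.ndarray | None = None,
    nm: NullModelFit | None = None,
    mito_variant_id: str = "mito",
    nuc_variant_id: str = "nuc",
    center: bool = False,
) -> InteractionResult:
    """Fit models S and I for one pair and report the decomposition.

    Untestable configurations (constant dosage, constant product term, e.g.
    no carriers of both minor alleles) return a flagged result, not an
    exception. ``center=True`` mean-centers both dosages before forming the
    product (off by default: the raw-product coding matches how interaction
    effect sizes are usually reported, and is coding-dependent).
    """
    out = InteractionResult(mito_variant_id, nuc_variant_id)
    y_all = p.bmi
    X_all = np.column_stack([np.ones(len(y_all)), p.covariates(covariates)])
    m = np.asarray(mito_dosage, dtype=float)
    g = np.asarray(nuc_dosage, dtype=float)
    ok = (
        np.isfinite(y_all) & np.all(np.isfinite(X_all), axis=1)
        & np.isfinite(m) & np.isfinite(g)
    )
    y, X, m, g = y_all[ok], X_all[ok], m[ok], g[ok]
    out.n = int(ok.sum())
    if out.n == 0 or np.all(m == m[0]) or np.all(g == g[0]):
        out.note = "untestable: constant dosage among complete cases"
        return out
    mc, gc = (m - m.mean(), g - g.mean()) if center else (m, g)
    prod = mc * gc
    if np.all(prod == prod[0]):
        out.note = "untestable: constant product term"
        return out

    if grm is not None and nm is None:
        nm = fit_null_model(p, covariates, grm=grm)

    if nm is not None and nm.grm is not None:
        # whitening operates on full-length columns; scatter the (possibly
        # centered) complete-case dosages back into unmasked vectors
        def full(vals: np.ndarray) -> np.ndarray:
            col = np.zeros(len(y_all))
            col[ok] = vals
            return col

        mask = None if ok.all() else ok
        base = np.column_stack([X_all, full(mc), full(gc)])
        A_S = nm.whiten(base, mask)
        A_I = nm.whiten(np.column_stack([base, full(prod)]), mask)
        b = nm.whiten(y_all, mask)[:, 0]
    else:
        A_S = np.column_stack([X, mc, gc])
        A_I = np.column_stack([X, mc, gc, prod])
        b = y

    k_cov = X.shape[1]
    i_mito, i_nuc, i_int = k_cov, k_cov + 1, k_cov + 2

    def fit(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient design")
        beta, rss = _lstsq_rss(A, b)
        dof = A.shape[0] - A.shape[1]
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(A.T @ A)
        return beta, cov, rss, dof

    try:
        beta_S, cov_S, _, _ = fit(A_S)
        beta_I, cov_I, rss_I, dof_I = fit(A_I)
    except np.linalg.LinAlgError:
        out.note = "untestable: collinear design"
        return out

    out.nuc_eff_single, _, out.nuc_pval_single = _wald(beta_S, cov_S, i_nuc)
    out.nuc_eff_joint, _, out.nuc_pval_joint = _wald(beta_I, cov_I, i_nuc)
    out.mito_eff_joint, _, out.mito_pval_joint = _wald(beta_I, cov_I, i_mito)
    out.inter_eff, out.inter_se, out.inter_pval = _wald(beta_I, cov_I, i_int)

    # 2-df joint Wald on (nuclear, interaction), exact F reference: equals
    # the RSS comparison of model I against covariates + mito
    sub = [i_nuc, i_int]
    bsub = beta_I[sub]
    csub = cov_I[np.ix_(sub, sub)]
    try:
        W = float(bsub @ np.linalg.solve(csub, bsub))
        out.joint_pval = float(stats.f.sf(W / 2.0, 2, dof_I))
    except np.linalg.LinAlgError:
        pass
    return out


test_interaction.__test__ = False  # keep pytest from collecting the API name


def interaction_scan(
    p: PhenotypeTable,
    covariates: Sequence[str],
    mito_dosage: np.ndarray,
    g_nuclear: GenotypeMatrix,
    candidate_ids: Sequence[str],
    grm: np.ndarray | None = None,
    mito_variant_id: str = "mito",
) -> list[InteractionResult]:
    """Interaction test per candidate nuclear variant (typically the
    dispersion screen's keep set or a gene-set restriction).

    Duplicate candidates are deduplicated with a warning; p-values are
    unadjusted, with a BH-FDR extension column; sorted by inter_pval."""
    seen: list[str] = []
    for c in candidate_ids:
        if c in seen:
            logger.warning("duplicate candidate %s dropped", c)
        else:
            seen.append(c)
    if not seen:
        logger.warning("interaction_scan: empty candidate list")
        return []
    nm = fit_null_model(p, covariates, grm=grm) if grm is not None else None
    results = []
    for vid in seen:
        res = test_interaction(
            p, covariates, mito_dosage, g_nuclear.dosage_of(vid),
            grm=grm, nm=nm, mito_variant_id=mito_variant_id, nuc_variant_id=vid,
        )
        results.append(res)
    fdr = _bh_fdr(np.array([r.inter_pval for r in results]))
    for r, q in zip(results, fdr):
        r.fdr_bh = float(q)
    results.sort(key=lambda r: (np.isnan(r.inter_pval), r.inter_pval, r.nuc_variant_id))
    return results


# ---------------------------------------------------------------------------
# Gene-set utilities
# ---------------------------------------------------------------------------

def restrict_to_gene_set(
    variants: Sequence[VariantInfo],
    gene_intervals: pd.DataFrame,
    gene_list: Sequence[str],
) -> list[VariantInfo]:
    """Keep variants falling in an interval of a listed gene, annotating the
    gene name. Intervals are half-open (start <= pos < end) per BED input;
    overlapping intervals of the same gene are merged. Unknown gene names in
    the list are warned about and ignored."""
    known = set(gene_intervals["gene"])
    unknown = [gname for gname in gene_list if gname not in known]
    if unknown:
        logger.warning("gene list names not in intervals, ignored: %s", unknown)
    wanted = [gname for gname in gene_list if gname in known]
    merged: list[tuple[str, int, int, str]] = []
    for gname in wanted:
        sub = gene_intervals[gene_intervals["gene"] == gname].sort_values(
            ["chrom", "start"]
        )
        for chrom, grp in sub.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for _, row in grp.iterrows():
                if cur_s is None:
                    cur_s, cur_e = row["start"], row["end"]
                elif row["start"] <= cur_e:
                    cur_e = max(cur_e, row["end"])
                else:
                    merged.append((chrom, cur_s, cur_e, gname))
                    cur_s, cur_e = row["start"], row["end"]
            if cur_s is not None:
                merged.append((chrom, cur_s, cur_e, gname))
    out: list[VariantInfo] = []
    for v in variants:
        for chrom, start, end, gname in merged:
            if v.chrom == chrom and start <= v.pos < end:
                out.append(replace(v, gene=gname))
                break
    return out


def gene_set_overrepresentation(
    hit_genes: Sequence[str],
    set_genes: Sequence[str],
    universe_genes: Sequence[str],
    set_name: str = "gene_set",
) -> GeneSetEnrichment:
    """One-sided (greater) Fisher exact test of hit genes against a gene set
    within a universe. A generic over-representation test for interaction
    hits against e.g. a mitochondrial-function gene inventory."""
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    hits = set(hit_genes)
    if not hits <= universe:
        raise ValueError("hit genes must be a subset of the universe")
    gset = set(set_genes) & universe
    a = len(hits & gset)
    b_ = len(hits - gset)
    c = len(gset - hits)
    d = len(universe) - a - b_ - c
    odds, pval = stats.fisher_exact([[a, b_], [c, d]], alternative="greater")
    if b_ * c == 0 and a * d == 0:
        odds = 0.0 if a == 0 else float("inf")
    return GeneSetEnrichment(
        set_name, a, len(hits), len(gset), len(universe), float(odds), float(pval)
    )


def expression_interaction_glm(
    p: PhenotypeTable,
    expr_nuc: np.ndarray,
    expr_mito: np.ndarray,
    covariates: Sequence[str] = ("age", "sex"),
    nuc_label: str = "expr_nuc",
    mito_label: str = "expr_mito",
) -> InteractionResult:
    """Expression-level analogue: OLS of bmi ~ age + sex + expr_nuc +
    expr_mito + expr_nuc * expr_mito, reported in the interaction schema.

    Mirrors the external-validation design where transcript abundances of a
    mitochondrial and a nuclear gene replace genotype dosages; effects are
    per expression unit, hence tiny for count-scale inputs.
    """
    en = np.asarray(expr_nuc, dtype=float)
    em = np.asarray(expr_mito, dtype=float)
    for name, v in ((nuc_label, en), (mito_label, em)):
        if np.all(v == v[0]):
            raise ValueError(f"{name} is constant")
    r = np.corrcoef(en, em)[0, 1]
    if abs(r) > 0.999:
        raise ValueError(f"expressions nearly collinear (|r| = {abs(r):.4f})")
    return test_interaction(
        p, covariates, em, en,
        mito_variant_id=mito_label, nuc_variant_id=nuc_label,
    )
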