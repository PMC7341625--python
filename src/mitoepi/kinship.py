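"""Pairwise relatedness (KING-robust) and the realized genetic relatedness
matrix (GRM) feeding the mixed model.

The KING-robust between-family estimator for samples i, j over their
jointly non-missing diploid SNPs is

    phi_hat = (N_het,het - 2 * N_opposite_hom) / (N_het(i) + N_het(j))

where N_het,het counts sites heterozygous in both, N_opposite_hom counts
sites homozygous for opposite alleles, and N_het(.) counts heterozygous
sites of each member within the joint set. It is robust to population
structure and invariant to allele-label flips; a sample against itself
gives exactly 0.5. Kinship above 0.0442 marks third-degree relatives or
closer (full sibs ~ 0.25, first cousins ~ 0.0625).

The realized GRM is Z Z^T / m with Z the MAF-standardized diploid dosage
matrix (missing entries mean-imputed, i.e. zero after centering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from mitoepi.io import GenotypeMatrix
from mitoepi.qc import KINSHIP_THRESHOLD, _standardized_diploid

logger = logging.getLogger(__name__)


@dataclass
class KinshipResult:
    """Pairwise kinship coefficients and (optionally) a GRM.

    ``phi`` and ``n_snps`` are symmetric sample x sample matrices; ``phi`` is
    NaN for pairs with no jointly usable SNP. ``grm`` may be attached by
    :func:`grm_from_genotypes`.
    """

    sample_ids: list[str]
    phi: np.ndarray
    n_snps: np.ndarray
    grm: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.phi.shape != (n, n) or self.n_snps.shape != (n, n):
            raise ValueError("kinship matrices must be n x n")
        if not np.allclose(self.phi, self.phi.T, equal_nan=True):
            raise ValueError("phi must be symmetric")
        if self.grm is not None and not np.allclose(self.grm, self.grm.T):
            raise ValueError("grm must be symmetric")

    def pairs(self, threshold: float | None = None) -> pd.DataFrame:
        """Upper-triangle pairs as a DataFrame (i, j, phi, n_snps_used),
        optionally restricted to phi > threshold."""
        iu, ju = np.triu_indices(len(self.sample_ids), k=1)
        df = pd.DataFrame(
            {
                "i": [self.sample_ids[a] for a in iu],
                "j": [self.sample_ids[b] for b in ju],
                "phi": self.phi[iu, ju],
                "n_snps_used": self.n_snps[iu, ju].astype(int),
            }
        )
        df = df[df["phi"].notna()].reset_index(drop=True)
        if threshold is not None:
            df = df[df["phi"] > threshold].reset_index(drop=True)
        return df


def king_kinship(g: GenotypeMatrix) -> KinshipResult:
    """KING-robust kinship for every sample pair over diploid SNPs.

    Pairs with no jointly usable SNP get phi = NaN and are excluded from
    :meth:`KinshipResult.pairs`, with a warning.
    """
    dip = g.subset_variants(~g.haploid)
    if dip.n_variants < 100:
        logger.warning(
            "king_kinship on %d diploid SNPs; >= 100 recommended", dip.n_variants
        )
    d = dip.dosages
    het = (d == 1.0)
    hom_ref = (d == 0.0)
    hom_alt = (d == 2.0)
    obs = ~np.isnan(d)
    H = het.astype(float)
    A = hom_ref.astype(float)
    B = hom_alt.astype(float)
    M = obs.astype(float)

    n_hethet = H @ H.T
    n_opp = A @ B.T + B @ A.T
    # heterozygote counts restricted to the pair's jointly observed sites
    het_i = H @ M.T
    denom = het_i + het_i.T
    n_joint = M @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_hethet - 2.0 * n_opp) / denom, np.nan)
    undef = (denom == 0) | (n_joint == 0)
    n_undef_pairs = int(np.triu(undef, k=1).sum())
    if n_undef_pairs:
        logger.warning(
            "%d sample pair(s) with no usable SNP: kinship undefined", n_undef_pairs
        )
    phi[n_joint == 0] = np.nan
    return KinshipResult(list(g.sample_ids), phi, n_joint)


def prune_related(
    k: KinshipResult,
    threshold: float = KINSHIP_THRESHOLD,
    call_rates: Mapping[str, float] | None = None,
) -> list[str]:
    """Greedy pruning: repeatedly drop the sample in the most over-threshold
    pairs (ties: lower call rate first, then lexicographically larger id)
    until no pair exceeds ``threshold``. Returns the removal list."""
    ids = k.sample_ids
    n = len(ids)
    over = np.zeros((n, n), dtype=bool)
    with np.errstate(invalid="ignore"):
        over[np.triu_indices(n, k=1)] = (
            k.phi[np.triu_indices(n, k=1)] > threshold
        ) & np.isfinite(k.phi[np.triu_indices(n, k=1)])
    over = over | over.T
    cr = {s: (call_rates or {}).get(s, 1.0) for s in ids}
    removed: list[str] = []
    active = np.ones(n, dtype=bool)
    while True:
        deg = (over & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max(initial=0) == 0:
            break
        cand = np.flatnonzero(deg == deg.max())
        # tie-break: among max-degree samples drop the lowest call rate,
        # then the lexicographically larger id
        best_cr = min(cr[ids[i]] for i in cand)
        pool = [i for i in cand if cr[ids[i]] == best_cr]
        drop = max(pool, key=lambda i: ids[i])
        removed.append(ids[drop])
        active[drop] = False
    return removed


def grm_from_genotypes(g: GenotypeMatrix) -> KinshipResult:
    """Realized GRM = Z Z^T / m over polymorphic diploid SNPs.

    Monomorphic SNPs are skipped (count logged); with very few SNPs the GRM
    is noisy and a warning is emitted. The returned :class:`KinshipResult`
    carries the GRM alongside GRM/2 as the kinship-scale matrix.
    """
    dip = g.subset_variants(~g.haploid)
    if dip.n_variants < 100:
        logger.warning("GRM from %d diploid SNPs; >= 100 recommended", dip.n_variants)
    Z, n_skipped = _standardized_diploid(dip)
    if n_skipped:
        logger.info("grm_from_genotypes: %d monomorphic SNP(s) skipped", n_skipped)
    m = Z.shape[1]
    if m == 0:
        raise ValueError("no polymorphic diploid SNPs for GRM")
    if m == 1:
        logger.warning("GRM computed from a single SNP")
    grm = (Z @ Z.T) / m
    n_mat = np.full(grm.shape, m, dtype=float)
    return KinshipResult(list(g.sample_ids), grm / 2.0, n_mat, grm=grm)


def write_grm(k: KinshipResult, path: str | Path) -> None:
    """Write the GRM as a TSV matrix with a sample-id header column/row."""
    if k.grm is None:
        raise ValueError("KinshipResult carries no GRM")
    df = pd.DataFrame(k.grm, index=k.sample_ids, columns=k.sample_ids)
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def read_grm(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    grm = df.to_numpy(dtype=float)
    if grm.shape[0] != grm.shape[1]:
        raise ValueError("GRM file is not square")
    return [str(s) for s in df.index], grm
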