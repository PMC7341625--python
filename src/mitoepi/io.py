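"""Readers/writers for the formats the pipeline touches and the shared
in-memory data model.

Dosages are stored in a float matrix oriented samples x variants, counting
alternative alleles (0/1/2 at diploid sites, 0/1 at haploid mitochondrial
sites). Missingness is NaN -- a dedicated non-dosage flag -- and every
downstream statistic masks it explicitly. Coordinates are 1-based (VCF
convention).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: contig names treated as the mitochondrial genome (haploid coding)
MITO_CHROMS = frozenset({"chrMT", "chrM", "MT", "M"})


@dataclass(frozen=True)
class VariantInfo:
    """A single biallelic variant."""

    id: str
    chrom: str
    pos: int
    ref: str = "N"
    alt: str = "N"
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")

    @property
    def is_mito(self) -> bool:
        return self.chrom in MITO_CHROMS


class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with per-variant ploidy.

    Parameters
    ----------
    sample_ids
        Ordered unique sample identifiers (rows).
    variants
        One :class:`VariantInfo` per column, ids unique.
    dosages
        Float array, shape ``(n_samples, n_variants)``. Diploid entries in
        {0, 1, 2, NaN}; haploid entries in {0, 1, NaN}.
    haploid
        Boolean per-variant flag; mitochondrial contigs must be haploid.
    meta
        Free-form provenance (e.g. heteroplasmy-coercion counts from
        :func:`read_vcf`).
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variants: Sequence[VariantInfo],
        dosages: np.ndarray,
        haploid: np.ndarray | Sequence[bool] | None = None,
        meta: dict | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.variants = list(variants)
        self.dosages = np.asarray(dosages, dtype=float)
        if haploid is None:
            haploid = [v.is_mito for v in self.variants]
        self.haploid = np.asarray(haploid, dtype=bool)
        self.meta = dict(meta) if meta else {}
        self._validate()

    def _validate(self) -> None:
        n, m = len(self.sample_ids), len(self.variants)
        if self.dosages.shape != (n, m):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{n} samples x {m} variants"
            )
        if self.haploid.shape != (m,):
            raise ValueError("haploid flag length does not match variant count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != m:
            raise ValueError("duplicate variant ids")
        for v, hap in zip(self.variants, self.haploid):
            if v.is_mito and not hap:
                raise ValueError(f"mitochondrial variant {v.id} must be haploid")
        with np.errstate(invalid="ignore"):
            d = self.dosages
            if m:
                dip = d[:, ~self.haploid]
                if not np.all(np.isnan(dip) | np.isin(dip, (0.0, 1.0, 2.0))):
                    raise ValueError("diploid dosages must be 0/1/2 or missing")
                hap_d = d[:, self.haploid]
                if not np.all(np.isnan(hap_d) | np.isin(hap_d, (0.0, 1.0))):
                    raise ValueError("haploid dosages must be 0/1 or missing")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids), list(self.variants), self.dosages.copy(),
            self.haploid.copy(), dict(self.meta),
        )

    def dosage_of(self, variant_id: str) -> np.ndarray:
        """Per-sample dosage vector for one variant (NaN where missing)."""
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None
        return self.dosages[:, j].copy()

    # -- summary statistics ----------------------------------------------

    def sample_call_rate(self) -> np.ndarray:
        if self.n_variants == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing_mask.mean(axis=1)

    def variant_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_variants)
        return 1.0 - self.missing_mask.mean(axis=0)

    def alt_allele_frequency(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls.

        Diploid variants divide by twice the call count; haploid by the call
        count. All-missing variants yield NaN.
        """
        d = self.dosages
        obs = ~np.isnan(d)
        alt = np.nansum(d, axis=0)
        denom = obs.sum(axis=0).astype(float)
        denom[~self.haploid] *= 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(denom > 0, alt / denom, np.nan)
        return af

    def maf(self) -> np.ndarray:
        """Minor-allele frequency: min(af, 1-af)."""
        af = self.alt_allele_frequency()
        return np.minimum(af, 1.0 - af)

    # -- subsetting ------------------------------------------------------

    def subset_samples(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        """Restrict to samples, by id list (preserving the given order) or mask."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], list(self.variants),
            self.dosages[idx, :], self.haploid.copy(), dict(self.meta),
        )

    def subset_variants(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {v: j for j, v in enumerate(self.variant_ids)}
            idx = np.array([pos[v] for v in keep], dtype=int)
        return GenotypeMatrix(
            list(self.sample_ids), [self.variants[j] for j in idx],
            self.dosages[:, idx], self.haploid[idx], dict(self.meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variants == other.variants
            and bool(np.array_equal(self.dosages, other.dosages, equal_nan=True))
            and bool(np.array_equal(self.haploid, other.haploid))
        )


@dataclass
class PhenotypeTable:
    """Per-sample phenotype (BMI, kg/m^2) and covariates.

    ``data`` holds one row per sample with a ``sample_id`` column plus
    ``bmi`` and named numeric covariates. Rows whose BMI failed to parse are
    kept with NaN BMI and listed in ``flagged``.
    """

    data: pd.DataFrame
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise ValueError("phenotype table needs a sample_id column")
        ids = self.data["sample_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        num = self.data.drop(columns=["sample_id"]).select_dtypes(include=[np.number])
        if np.isinf(num.to_numpy(dtype=float)).any():
            raise ValueError("phenotype covariates contain infinities")
        if "bmi" in self.data.columns:
            bmi = self.data["bmi"]
            if ((bmi <= 0) & bmi.notna()).any():
                raise ValueError("BMI must be positive where present")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def bmi(self) -> np.ndarray:
        return self.data["bmi"].to_numpy(dtype=float)

    def covariates(self, names: Sequence[str]) -> np.ndarray:
        missing = [c for c in names if c not in self.data.columns]
        if missing:
            raise KeyError(
                f"covariates {missing} not in table; available: "
                f"{[c for c in self.data.columns if c != 'sample_id']}"
            )
        return self.data[list(names)].to_numpy(dtype=float)

    def subset(self, keep: Sequence[str]) -> "PhenotypeTable":
        sub = self.data.set_index("sample_id").loc[list(keep)].reset_index()
        keep_set = set(keep)
        return PhenotypeTable(sub, [s for s in self.flagged if s in keep_set])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.data, other.data, check_like=True)
        except AssertionError:
            return False
        return self.flagged == other.flagged


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a GT-only VCF into a :class:`GenotypeMatrix`.

    Diploid GTs become alt-allele counts. Records on a mitochondrial contig
    are coded haploid 0/1: haploid calls pass through, homozygous diploid
    calls collapse to one allele, and heterozygous diploid calls (possible
    heteroplasmy) are set to missing -- their count is logged and recorded in
    ``meta['heteroplasmy_set_missing']``.

    Raises
    ------
    ValueError
        On multi-allelic records (pre-split them, e.g. ``bcftools norm -m-``)
        or on a malformed file.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    variants: list[VariantInfo] = []
    cols: list[np.ndarray] = []
    hetero_count = 0
    with vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic or ALT-less record at {rec.chrom}:{rec.pos} "
                    f"({rec.id or '.'}): split multi-allelic sites first "
                    "(bcftools norm -m-)"
                )
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
            info = VariantInfo(vid, rec.chrom, rec.pos, rec.ref, rec.alts[0])
            col = np.full(len(samples), np.nan)
            mito = info.is_mito
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                alleles = tuple(a for a in (gt or ()) if a is not None)
                if not alleles:
                    continue
                if mito:
                    if len(set(alleles)) > 1:
                        hetero_count += 1  # heteroplasmic-looking call
                        continue
                    col[i] = float(alleles[0] > 0)
                else:
                    if len(alleles) != 2:
                        continue  # half-calls treated as missing
                    col[i] = float(sum(a > 0 for a in alleles))
            variants.append(info)
            cols.append(col)
    dos = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    meta = {}
    if hetero_count:
        logger.warning(
            "%d heterozygous chrMT call(s) in %s set to missing "
            "(heteroplasmy out of scope)", hetero_count, path,
        )
        meta["heteroplasmy_set_missing"] = hetero_count
    return GenotypeMatrix(samples, variants, dos, meta=meta)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF 4.2 (haploid GT at haploid variants).

    Round-trips through :func:`read_vcf`, preserving missingness. Output is
    deterministic for a given matrix.
    """
    contigs: list[str] = []
    for v in g.variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(g.sample_ids)
    )
    order = sorted(
        range(g.n_variants),
        key=lambda j: (contigs.index(g.variants[j].chrom), g.variants[j].pos, g.variants[j].id),
    )
    for j in order:
        v = g.variants[j]
        hap = bool(g.haploid[j])
        gts = []
        for d in g.dosages[:, j]:
            if np.isnan(d):
                gts.append("." if hap else "./.")
            elif hap:
                gts.append(str(int(d)))
            else:
                gts.append(["0/0", "0/1", "1/1"][int(d)])
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PLINK-style .raw dosage table
# ---------------------------------------------------------------------------

_PLINK_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def read_raw(path: str | Path, haploid_variants: Iterable[str] = ()) -> GenotypeMatrix:
    """Read a PLINK ``.raw``-style whitespace-delimited dosage table.

    The header carries an ``IID`` column (plus optional FID/PAT/MAT/SEX/
    PHENOTYPE, dropped) followed by one column per variant with integer
    dosages and ``NA`` for missing. Chrom/pos are not encoded in this format;
    variants get chrom ``"NA"`` and pos = column order. Names listed in
    ``haploid_variants`` are coded haploid.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if "IID" not in df.columns:
        raise ValueError(f"{path}: .raw table must have an IID column")
    samples = df["IID"].astype(str).tolist()
    var_cols = [c for c in df.columns if c not in _PLINK_META_COLS]
    hap_set = set(haploid_variants)
    variants = [VariantInfo(c, "NA", j + 1) for j, c in enumerate(var_cols)]
    dosages = df[var_cols].to_numpy(dtype=float)
    haploid = np.array([c in hap_set for c in var_cols])
    return GenotypeMatrix(samples, variants, dosages, haploid)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> PhenotypeTable:
    """Read a phenotype/covariate TSV.

    ``column_map`` maps canonical names (``sample_id``, ``bmi``, ``age``,
    ``sex``, ``glucose``, ...) to file headers; unmapped canonical names
    default to themselves. Rows with unparseable BMI are kept with NaN BMI
    and flagged, never silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    column_map = dict(column_map or {})
    column_map.setdefault("sample_id", "sample_id")
    for canon, src in column_map.items():
        if src not in df.columns:
            raise KeyError(
                f"column {src!r} (for {canon!r}) not in {path}; "
                f"available: {list(df.columns)}"
            )
    # unmapped file columns ride along under their own names
    used = set(column_map.values())
    for col in df.columns:
        if col not in used and col not in column_map:
            column_map[col] = col
    out = pd.DataFrame({"sample_id": df[column_map["sample_id"]].astype(str)})
    flagged: list[str] = []
    for canon, src in column_map.items():
        if canon == "sample_id":
            continue
        vals = pd.to_numeric(df[src], errors="coerce")
        if canon == "bmi":
            bad = vals.isna() & df[src].notna() | df[src].isna()
            flagged = out.loc[bad, "sample_id"].tolist()
        out[canon] = vals
    if flagged:
        logger.warning("%d row(s) with unparseable BMI flagged", len(flagged))
    return PhenotypeTable(out, flagged)


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open, kept as such).

    Returns a DataFrame with columns chrom, start, end, gene.
    """
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: BED needs chrom/start/end/name")
        chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        if end <= start:
            raise ValueError(f"{path}:{ln}: empty or inverted interval")
        rows.append((chrom, start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


# ---------------------------------------------------------------------------
# Cohort alignment and result tables
# ---------------------------------------------------------------------------

def align_cohort(
    g: GenotypeMatrix, p: PhenotypeTable
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Restrict both inputs to their common samples, in genotype-matrix order.

    Idempotent; raises on an empty intersection.
    """
    common = set(g.sample_ids) & set(p.sample_ids)
    if not common:
        raise ValueError("no samples shared between genotypes and phenotypes")
    order = [s for s in g.sample_ids if s in common]
    logger.info("cohort alignment: %d shared samples", len(order))
    return g.subset_samples(order), p.subset(order)


def _fmt(x: object) -> str:
    if isinstance(x, float):
        if np.isnan(x):
            return "NA"
        return f"{x:.6g}"
    if x is None:
        return "NA"
    return str(x)


def write_results_table(rows: Sequence, path: str | Path, kind: type | None = None) -> None:
    """Write result records (dataclasses) as a TSV with a fixed header.

    Floats are formatted at 6 significant digits; rows are sorted by the
    record type's documented sort key (chrom, pos, partner id) so repeated
    writes of the same results are byte-identical.
    """
    if rows:
        kind = type(rows[0])
    if kind is None:
        raise ValueError("empty result list: pass kind= to emit the header")
    cols = [f.name for f in dataclasses.fields(kind)]
    key = getattr(kind, "sort_key", None)
    ordered = sorted(rows, key=key) if key is not None else list(rows)
    lines = ["\t".join(cols)]
    for r in ordered:
        d = dataclasses.asdict(r)
        lines.append("\t".join(_fmt(d[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")
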