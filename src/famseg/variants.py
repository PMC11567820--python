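"""VCF ingest restricted to candidate loci, and genotype/site-level QC.

Genotypes are held in a dense matrix (sites x samples) of alternate-allele
dosages with -1 for missing, alongside per-call DP and GQ. QC follows the
usual joint-calling conventions: genotypes failing depth or quality are set
to missing, then sites whose missing fraction exceeds the call-rate cutoff
are dropped, and rarity is enforced on the reference-population (gnomAD)
allele frequency.

Boundary conventions (all configurable):
  - a genotype is masked iff DP < min_dp or GQ < min_gq, so DP=10 / GQ=20
    survive the default thresholds;
  - a site is dropped iff its missing fraction is strictly greater than
    max_missing_fraction (2 missing of 100 survives the 2% default);
  - a site is rare iff gnomad_af < max_af strictly (AF = 1% is dropped at the
    1% default); a site with no gnomAD record is kept and flagged af_absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotate import ConsequenceClass

logger = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel

__all__ = [
    "MISSING",
    "VariantSite",
    "GenotypeMatrix",
    "VcfError",
    "read_bed_regions",
    "read_vcf_region",
    "read_annotation_table",
    "attach_annotations",
    "mask_low_quality_genotypes",
    "drop_high_missingness_sites",
    "filter_rare",
]


class VcfError(ValueError):
    """Raised for malformed VCF/BED/annotation input."""


@dataclass(frozen=True)
class VariantSite:
    """A single bi-allelic site (multi-allelics are split on read).

    Coordinates are VCF-style 1-based. Annotation fields (gene, consequence,
    CADD phred, gnomAD AF) may be absent until an annotation table is joined.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str = "PASS"
    gene: str | None = None
    consequence: ConsequenceClass = ConsequenceClass.OTHER
    cadd_phred: float | None = None
    gnomad_af: float | None = None
    af_absent: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfError(f"position must be 1-based positive, got {self.pos}")
        if self.ref == self.alt:
            raise VcfError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise VcfError(f"gnomad_af out of [0,1] at {self.key}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Dense per-sample calls for a list of sites.

    ``dosage`` is (n_sites, n_samples) int8 in {0,1,2,MISSING}; ``dp`` and
    ``gq`` are int32 with -1 where the FORMAT field was absent.
    """

    samples: list[str]
    dosage: np.ndarray
    dp: np.ndarray
    gq: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.samples)
        for arr in (self.dosage, self.dp, self.gq):
            if arr.ndim != 2 or arr.shape[1] != n:
                raise VcfError("genotype arrays must be (n_sites, n_samples)")
        if not (self.dosage.shape == self.dp.shape == self.gq.shape):
            raise VcfError("dosage/dp/gq shapes differ")

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def row(self, i: int) -> np.ndarray:
        return self.dosage[i]

    def dosage_for(self, i: int, sample_ids: Sequence[str]) -> np.ndarray:
        idx = [self.samples.index(s) for s in sample_ids]
        return self.dosage[i, idx]

    def subset_sites(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            dosage=self.dosage[keep].copy(),
            dp=self.dp[keep].copy(),
            gq=self.gq[keep].copy(),
        )


def read_bed_regions(bed_path: str | Path) -> dict[str, IntervalTree]:
    """Read BED (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(bed_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise VcfError(f"{bed_path}:{lineno}: expected ≥3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise VcfError(f"{bed_path}:{lineno}: malformed interval") from exc
            if end <= start:
                raise VcfError(f"{bed_path}:{lineno}: end ≤ start")
            trees.setdefault(cols[0], IntervalTree()).addi(start, end)
    return trees


def _overlaps(trees: dict[str, IntervalTree], chrom: str, pos1: int, ref: str) -> bool:
    tree = trees.get(chrom)
    if tree is None:
        return False
    # VCF 1-based inclusive span of the REF allele vs BED half-open interval
    return bool(tree.overlap(pos1 - 1, pos1 - 1 + len(ref)))


def read_vcf_region(
    vcf_path: str | Path,
    regions: str | Path | dict[str, IntervalTree] | None = None,
) -> tuple[list[VariantSite], GenotypeMatrix]:
    """Read a multi-sample VCF, keeping records that overlap ``regions``.

    ``regions`` may be a BED path, pre-built interval trees, or None to keep
    everything. Multi-allelic records are split into one VariantSite per ALT
    with dosages recoded against that allele (a 1/2 genotype contributes
    dosage 1 to each split site); DP/GQ are carried over unchanged.
    """
    from cyvcf2 import VCF

    if isinstance(regions, (str, Path)):
        regions = read_bed_regions(regions)

    vcf = VCF(str(vcf_path))
    if "GT" not in {f["ID"] for f in vcf.header_iter() if f.type == "FORMAT"}:
        raise VcfError(f"{vcf_path}: no GT FORMAT field in header")
    samples = list(vcf.samples)
    n = len(samples)

    sites: list[VariantSite] = []
    dos_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []

    for rec in vcf:
        if regions is not None and not _overlaps(regions, rec.CHROM, rec.POS, rec.REF):
            continue
        gts = np.array(rec.genotypes, dtype=object)  # [a0, a1, phased]
        a0 = np.array([g[0] for g in gts], dtype=np.int16)
        a1 = np.array([g[1] for g in gts], dtype=np.int16)
        try:
            dp = rec.format("DP")
            dp = (
                np.full(n, -1, dtype=np.int32)
                if dp is None
                else np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32)
            )
        except KeyError:
            dp = np.full(n, -1, dtype=np.int32)
        try:
            gq = rec.format("GQ")
            gq = (
                np.full(n, -1, dtype=np.int32)
                if gq is None
                else np.where(gq[:, 0] < 0, -1, gq[:, 0]).astype(np.int32)
            )
        except KeyError:
            gq = np.full(n, -1, dtype=np.int32)

        filt = rec.FILTER if rec.FILTER is not None else "PASS"
        missing_mask = (a0 < 0) | (a1 < 0)
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            dosage = (a0 == alt_idx).astype(np.int8) + (a1 == alt_idx).astype(np.int8)
            dosage[missing_mask] = MISSING
            sites.append(
                VariantSite(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                            filter_status=filt)
            )
            dos_rows.append(dosage)
            dp_rows.append(dp)
            gq_rows.append(gq)

    shape = (len(sites), n)
    matrix = GenotypeMatrix(
        samples=samples,
        dosage=np.vstack(dos_rows) if sites else np.empty(shape, dtype=np.int8),
        dp=np.vstack(dp_rows) if sites else np.empty(shape, dtype=np.int32),
        gq=np.vstack(gq_rows) if sites else np.empty(shape, dtype=np.int32),
    )
    return sites, matrix


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read the per-variant annotation TSV.

    Header: chrom, pos, ref, alt, gene, consequence, cadd_phred, gnomad_af.
    Empty cadd_phred / gnomad_af cells mean "absent".
    """
    tbl = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "ref": str, "alt": str, "gene": str,
               "consequence": str},
    )
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence",
                "cadd_phred", "gnomad_af"}
    missing = required - set(tbl.columns)
    if missing:
        raise VcfError(f"annotation table lacks columns: {sorted(missing)}")
    return tbl


def _opt_float(value) -> float | None:
    """Empty strings and NaN mean 'absent'."""
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return None
    if pd.isna(value):
        return None
    return float(value)


def attach_annotations(
    sites: Sequence[VariantSite],
    annotations: pd.DataFrame,
    synonym_map: dict[str, str] | None = None,
) -> list[VariantSite]:
    """Join annotations onto sites by (chrom, pos, ref, alt).

    Unannotated sites are passed through unchanged (gene=None,
    consequence=other); the caller decides whether that is an error.
    """
    from .annotate import classify_consequence

    index: dict[tuple[str, int, str, str], pd.Series] = {}
    for _, row in annotations.iterrows():
        index[(str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])] = row

    out: list[VariantSite] = []
    for site in sites:
        row = index.get((site.chrom, site.pos, site.ref, site.alt))
        if row is None:
            out.append(site)
            continue
        cadd = _opt_float(row["cadd_phred"])
        af = _opt_float(row["gnomad_af"])
        out.append(
            replace(
                site,
                gene=None if pd.isna(row["gene"]) else str(row["gene"]),
                consequence=classify_consequence(row["consequence"], synonym_map),
                cadd_phred=cadd,
                gnomad_af=af,
                af_absent=af is None,
            )
        )
    return out


def mask_low_quality_genotypes(
    matrix: GenotypeMatrix, min_dp: int = 10, min_gq: int = 20
) -> GenotypeMatrix:
    """Set genotypes with DP < min_dp or GQ < min_gq to missing.

    A call with an absent DP or GQ field is not masked on that field. The
    number of newly masked genotypes is logged.
    """
    if min_dp < 0 or min_gq < 0:
        raise ValueError("thresholds must be ≥ 0")
    bad = ((matrix.dp >= 0) & (matrix.dp < min_dp)) | (
        (matrix.gq >= 0) & (matrix.gq < min_gq)
    )
    newly = int(np.count_nonzero(bad & (matrix.dosage != MISSING)))
    dosage = matrix.dosage.copy()
    dosage[bad] = MISSING
    logger.info("masked %d genotypes at DP<%d or GQ<%d", newly, min_dp, min_gq)
    return GenotypeMatrix(samples=list(matrix.samples), dosage=dosage,
                          dp=matrix.dp.copy(), gq=matrix.gq.copy())


def drop_high_missingness_sites(
    sites: Sequence[VariantSite],
    matrix: GenotypeMatrix,
    max_missing_fraction: float = 0.02,
) -> tuple[list[VariantSite], GenotypeMatrix]:
    """Drop sites whose missing-genotype fraction exceeds the cutoff.

    Strict inequality: a site at exactly the cutoff is retained. Intended to
    run after :func:`mask_low_quality_genotypes`.
    """
    if matrix.n_sites != len(sites):
        raise VcfError("sites/matrix length mismatch")
    if matrix.dosage.shape[1] == 0:
        return list(sites), matrix
    frac = np.mean(matrix.dosage == MISSING, axis=1)
    keep = np.flatnonzero(frac <= max_missing_fraction)
    dropped = matrix.n_sites - keep.size
    if dropped:
        logger.info("dropped %d sites with missingness > %g", dropped,
                    max_missing_fraction)
    return [sites[i] for i in keep], matrix.subset_sites(keep)


def filter_rare(
    sites: Sequence[VariantSite], max_af: float = 0.01
) -> list[VariantSite]:
    """Keep sites rare in the reference population (gnomad_af < max_af).

    Sites absent from gnomAD are treated as unobserved-in-reference: kept,
    with ``af_absent`` set.
    """
    out: list[VariantSite] = []
    for site in sites:
        if site.gnomad_af is None:
            out.append(replace(site, af_absent=True))
        elif site.gnomad_af < max_af:
            out.append(site)
    return out
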