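"""End-to-end orchestration: QC → prioritization → segregation → report.

The pipeline consumes either the simulator's in-memory output or the file
set (per-cohort VCF + PED/FAM + phenotype TSV, shared BED regions,
annotation TSV and index-SNP TSV) and produces per-(variant, family)
segregation calls, cohort-level incomplete-segregation labels, APOE e4
calls, per-family explanation labels, LD against locus index SNPs, cohort
summaries and the variant report table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import DamagingCall, is_damaging
from .apoe import (
    APOE_RS429358_GRCH38,
    APOE_RS7412_GRCH38,
    apoe_e4_segregation,
    call_apoe_diplotype,
    cosegregates_with_apoe,
)
from .ld import (
    LDUndefinedError,
    cosegregates_with_index,
    genotype_r2,
    index_carrier_count,
)
from .pedigree import FamilyCohort, filter_families_min_affected, read_pedigree
from .report import CohortSummary, summarize_cohorts, variant_report
from .segregation import (
    FamilyExplanation,
    SegregationCall,
    SegregationStatus,
    classify_cohort_incomplete,
    classify_family_explanation,
    classify_family_segregation,
    cross_family_consistency,
)
from .variants import (
    MISSING,
    GenotypeMatrix,
    VariantSite,
    attach_annotations,
    drop_high_missingness_sites,
    filter_rare,
    mask_low_quality_genotypes,
    read_annotation_table,
    read_vcf_region,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "CohortInputs",
    "PipelineResult",
    "load_cohort_inputs",
    "inputs_from_study",
    "run_study",
    "evaluate_concordance",
]


@dataclass
class PipelineConfig:
    """Thresholds and rule options for a pipeline run (study defaults)."""

    min_dp: int = 10
    min_gq: int = 20
    max_missing_fraction: float = 0.02
    max_af: float = 0.01
    cadd_threshold: float = 20.0
    buffer_years: float = 5.0
    onset_reference: str = "carrier_mean"
    strict_cross_family: bool = True
    min_affected: int = 2
    require_pass: bool = False
    apoe_rs429358: tuple = APOE_RS429358_GRCH38
    apoe_rs7412: tuple = APOE_RS7412_GRCH38
    ld_r2_threshold: float = 0.2


@dataclass
class CohortInputs:
    cohort: FamilyCohort
    sites: list[VariantSite]
    matrix: GenotypeMatrix


@dataclass
class PipelineResult:
    seg_calls: dict[str, list[SegregationCall]]
    incomplete: dict[str, dict[str, SegregationStatus]]
    apoe_calls: dict[str, dict[str, SegregationCall]]
    explanations: dict[str, list[FamilyExplanation]]
    summaries: dict[str, CohortSummary]
    report: pd.DataFrame
    ld: pd.DataFrame
    damaging_sites: dict[str, list[VariantSite]]
    variant_info: dict[str, dict] = field(default_factory=dict)


def load_cohort_inputs(
    vcf_path: str | Path,
    ped_path: str | Path,
    phenotype_path: str | Path,
    regions: str | Path | None,
    annotations: str | Path | pd.DataFrame,
    cohort_id: str | None = None,
) -> CohortInputs:
    """File-based ingest for one cohort."""
    cohort = read_pedigree(ped_path, phenotype_path, cohort_id=cohort_id)
    sites, matrix = read_vcf_region(vcf_path, regions)
    if not isinstance(annotations, pd.DataFrame):
        annotations = read_annotation_table(annotations)
    sites = attach_annotations(sites, annotations)
    return CohortInputs(cohort=cohort, sites=sites, matrix=matrix)


def inputs_from_study(study) -> tuple[dict[str, CohortInputs], pd.DataFrame]:
    """Build pipeline inputs directly from a SimulatedStudy (no file I/O)."""
    out: dict[str, CohortInputs] = {}
    for cid, cohort in study.cohorts.items():
        samples = study.samples[cid]
        site_rows = study.sites[cid]
        keys = [
            f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
            for r in site_rows.itertuples(index=False)
        ]
        sites = [
            VariantSite(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt)
            for r in site_rows.itertuples(index=False)
        ]
        sites = attach_annotations(sites, study.annotations)
        dosage = np.vstack([study.dosages[cid][k] for k in keys]).astype(np.int8)
        dp = np.vstack([study.dp[cid][k] for k in keys]).astype(np.int32)
        gq = np.vstack([study.gq[cid][k] for k in keys]).astype(np.int32)
        matrix = GenotypeMatrix(samples=list(samples), dosage=dosage, dp=dp, gq=gq)
        out[cid] = CohortInputs(cohort=cohort, sites=sites, matrix=matrix)
    return out, study.index_snps


def _family_dosage(
    matrix_row: np.ndarray,
    sample_index: Mapping[str, int],
    members: Sequence,
) -> dict[str, int]:
    out = {}
    for m in members:
        j = sample_index.get(m.individual_id)
        out[m.individual_id] = int(matrix_row[j]) if j is not None else MISSING
    return out


def run_study(
    inputs: Mapping[str, CohortInputs],
    index_snps: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis over one or more cohorts."""
    cfg = config or PipelineConfig()

    seg_calls: dict[str, list[SegregationCall]] = {}
    incomplete: dict[str, dict[str, SegregationStatus]] = {}
    apoe_calls: dict[str, dict[str, SegregationCall]] = {}
    explanations: dict[str, list[FamilyExplanation]] = {}
    damaging_by_cohort: dict[str, list[VariantSite]] = {}
    variant_info: dict[str, dict] = {}
    ld_rows: list[dict] = []
    index_carriers: dict[tuple[str, str], int] = {}
    cohorts_filtered: dict[str, FamilyCohort] = {}
    apoe_flat: dict[str, SegregationCall] = {}

    index_by_gene: dict[str, str] = {}
    if index_snps is not None and len(index_snps):
        for r in index_snps.itertuples(index=False):
            index_by_gene[str(r.locus_gene)] = (
                f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
            )

    for cid, inp in inputs.items():
        cohort = filter_families_min_affected(inp.cohort, cfg.min_affected)
        cohorts_filtered[cid] = cohort
        sample_index = {s: j for j, s in enumerate(inp.matrix.samples)}
        sample_family: dict[str, str] = {
            m.individual_id: fid
            for fid, members in cohort.families.items()
            for m in members
        }

        sites = inp.sites
        matrix = mask_low_quality_genotypes(inp.matrix, cfg.min_dp, cfg.min_gq)
        if cfg.require_pass:
            keep = [
                i for i, s in enumerate(sites)
                if s.filter_status in ("PASS", ".", None)
            ]
            sites = [sites[i] for i in keep]
            matrix = matrix.subset_sites(keep)
        sites, matrix = drop_high_missingness_sites(
            sites, matrix, cfg.max_missing_fraction
        )
        row_of = {s.key: i for i, s in enumerate(sites)}

        # APOE dosages come from the post-QC, pre-rarity matrix (the two
        # APOE SNPs are common and would never survive the rarity filter)
        apoe_keys = tuple(
            f"{c}:{p}:{r}:{a}" for c, p, r, a in (cfg.apoe_rs429358, cfg.apoe_rs7412)
        )
        index_keys = set(index_by_gene.values())

        rare = filter_rare(sites, cfg.max_af)
        damaging = [
            s for s in rare
            if s.key not in apoe_keys
            and s.key not in index_keys
            and is_damaging(s, cfg.cadd_threshold) is not DamagingCall.NOT_DAMAGING
        ]
        damaging_by_cohort[cid] = damaging
        for s in damaging:
            call = is_damaging(s, cfg.cadd_threshold)
            variant_info.setdefault(
                s.key,
                {
                    "gene": s.gene or "",
                    "variant_type": (
                        "LoF" if call is DamagingCall.LOF else "Missense"
                    ),
                    "index_snp": index_by_gene.get(s.gene or "", ""),
                },
            )

        # --- APOE e4 calls per family -------------------------------
        calls_apoe: dict[str, SegregationCall] = {}
        have_apoe = all(k in row_of for k in apoe_keys)
        if not have_apoe:
            logger.warning("cohort %s: APOE SNPs absent; no e4 calls", cid)
        for fid, members in cohort.families.items():
            if have_apoe:
                d4 = _family_dosage(
                    matrix.dosage[row_of[apoe_keys[0]]], sample_index, members
                )
                d2 = _family_dosage(
                    matrix.dosage[row_of[apoe_keys[1]]], sample_index, members
                )
                dips = {
                    iid: call_apoe_diplotype(d4[iid], d2[iid]) for iid in d4
                }
                call = apoe_e4_segregation(
                    members, dips, buffer=cfg.buffer_years,
                    onset_reference=cfg.onset_reference,
                )
            else:
                call = SegregationCall(
                    "APOE_e4", fid, SegregationStatus.NONE, 0, 0, 0, 0
                )
            calls_apoe[fid] = call
            apoe_flat[fid] = call
        apoe_calls[cid] = calls_apoe

        # --- per-(variant, family) complete-segregation calls ---------
        cohort_seg: list[SegregationCall] = []
        carrying: dict[str, list[str]] = {}
        for s in damaging:
            row = matrix.dosage[row_of[s.key]]
            fams = sorted(
                {
                    sample_family[inp.matrix.samples[j]]
                    for j in np.flatnonzero(row >= 1)
                    if inp.matrix.samples[j] in sample_family
                }
            )
            carrying[s.key] = fams
            for fid in fams:
                members = cohort.families[fid]
                call = classify_family_segregation(
                    members,
                    _family_dosage(row, sample_index, members),
                    s,
                    buffer=cfg.buffer_years,
                    onset_reference=cfg.onset_reference,
                )
                cohort_seg.append(call)

        cohort_seg = cross_family_consistency(
            cohort_seg, strict=cfg.strict_cross_family
        )
        seg_calls[cid] = cohort_seg

        # --- cohort-level incomplete segregation ----------------------
        complete_keys = {
            c.variant_key for c in cohort_seg
            if c.status is SegregationStatus.COMPLETE
        }
        inc: dict[str, SegregationStatus] = {}
        for s in damaging:
            if s.key in complete_keys:
                continue
            fam_data = {
                fid: (
                    cohort.families[fid],
                    _family_dosage(
                        matrix.dosage[row_of[s.key]],
                        sample_index,
                        cohort.families[fid],
                    ),
                )
                for fid in carrying[s.key]
            }
            status = classify_cohort_incomplete(
                s, fam_data, buffer=cfg.buffer_years,
                onset_reference=cfg.onset_reference,
            )
            if status is SegregationStatus.INCOMPLETE:
                inc[s.key] = status
        incomplete[cid] = inc

        # --- family explanations --------------------------------------
        by_family: dict[str, list[SegregationCall]] = {
            fid: [] for fid in cohort.families
        }
        for c in cohort_seg:
            by_family.setdefault(c.family_id, []).append(c)
        explanations[cid] = [
            classify_family_explanation(fid, by_family[fid], calls_apoe.get(fid))
            for fid in cohort.families
        ]

        # --- LD and index-SNP co-segregation ---------------------------
        for c in cohort_seg:
            if c.status is not SegregationStatus.COMPLETE:
                continue
            info = variant_info.get(c.variant_key, {})
            idx_key = info.get("index_snp", "")
            if not idx_key or idx_key not in row_of:
                continue
            members = cohort.families[c.family_id]
            idx_dos = _family_dosage(
                matrix.dosage[row_of[idx_key]], sample_index, members
            )
            index_carriers[(c.variant_key, c.family_id)] = index_carrier_count(
                members, idx_dos
            )
        for s in damaging:
            idx_key = variant_info.get(s.key, {}).get("index_snp", "")
            if not idx_key or idx_key not in row_of or s.key not in row_of:
                continue
            n_complete_fams = sum(
                1 for c in cohort_seg
                if c.variant_key == s.key
                and c.status is SegregationStatus.COMPLETE
            )
            try:
                ld = genotype_r2(
                    matrix.dosage[row_of[s.key]],
                    matrix.dosage[row_of[idx_key]],
                    name_a=s.key, name_b=idx_key,
                )
                r2, n_used = ld.r2, ld.n_samples
            except LDUndefinedError as exc:
                r2, n_used = float("nan"), 0
                logger.info("LD undefined for %s vs %s: %s", s.key, idx_key, exc)
            coseg_any = False
            for c in cohort_seg:
                if (
                    c.variant_key == s.key
                    and c.status is SegregationStatus.COMPLETE
                ):
                    members = cohort.families[c.family_id]
                    idx_dos = _family_dosage(
                        matrix.dosage[row_of[idx_key]], sample_index, members
                    )
                    if cosegregates_with_index(
                        c, members, idx_dos, buffer=cfg.buffer_years,
                        onset_reference=cfg.onset_reference,
                    ):
                        coseg_any = True
                        break
            ld_rows.append(
                {
                    "cohort": cid,
                    "variant": s.key,
                    "gene": s.gene or "",
                    "index_SNP": idx_key,
                    "r2": r2,
                    "n": n_used,
                    "method": "genotype_corr",
                    "in_ld": bool(r2 >= cfg.ld_r2_threshold)
                    if r2 == r2
                    else False,
                    "n_families_complete": n_complete_fams,
                    "coseg_with_index": coseg_any,
                }
            )

    summaries = summarize_cohorts(
        cohorts_filtered,
        explanations,
        seg_calls,
        {k: v.get("gene") for k, v in variant_info.items()},
    )
    report = variant_report(seg_calls, variant_info, apoe_flat, index_carriers)
    ld_df = pd.DataFrame(
        ld_rows,
        columns=[
            "cohort", "variant", "gene", "index_SNP", "r2", "n", "method",
            "in_ld", "n_families_complete", "coseg_with_index",
        ],
    )
    return PipelineResult(
        seg_calls=seg_calls,
        incomplete=incomplete,
        apoe_calls=apoe_calls,
        explanations=explanations,
        summaries=summaries,
        report=report,
        ld=ld_df,
        damaging_sites=damaging_by_cohort,
        variant_info=variant_info,
    )


def evaluate_concordance(truth: pd.DataFrame, result: PipelineResult) -> dict:
    """Compare pipeline output against the simulator's planted truth.

    Returns per-record-type and overall concordance fractions. A planted
    (variant, family) record with no corresponding call (for example a site
    dropped by QC) counts as NONE.
    """
    call_index: dict[tuple[str, str], SegregationStatus] = {}
    for calls in result.seg_calls.values():
        for c in calls:
            call_index[(c.variant_key, c.family_id)] = c.status
    label_index: dict[str, str] = {}
    for exps in result.explanations.values():
        for e in exps:
            label_index[e.family_id] = e.label.value

    counts = {"variant_family": [0, 0], "variant_cohort": [0, 0], "family": [0, 0]}
    mismatches: list[dict] = []
    for row in truth.itertuples(index=False):
        rtype = row.record_type
        if rtype == "variant_family":
            got = call_index.get(
                (row.variant_key, row.family_id), SegregationStatus.NONE
            ).value
            want = row.planted_status
        elif rtype == "variant_cohort":
            got = result.incomplete.get(row.cohort, {}).get(
                row.variant_key, SegregationStatus.NONE
            ).value
            want = row.planted_status
        elif rtype == "family":
            got = label_index.get(row.family_id, "MISSING")
            want = row.planted_family_label
        else:
            continue
        counts[rtype][1] += 1
        if got == want:
            counts[rtype][0] += 1
        else:
            mismatches.append(
                {
                    "record_type": rtype,
                    "cohort": row.cohort,
                    "family_id": row.family_id,
                    "variant_key": row.variant_key,
                    "want": want,
                    "got": got,
                }
            )

    total_ok = sum(v[0] for v in counts.values())
    total = sum(v[1] for v in counts.values())
    return {
        "n_records": total,
        "n_concordant": total_ok,
        "overall": total_ok / total if total else 1.0,
        "by_type": {
            k: (v[0] / v[1] if v[1] else 1.0) for k, v in counts.items()
        },
        "mismatches": mismatches,
    }
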