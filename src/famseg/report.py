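"""Cohort summaries and segregating-variant report tables.

Percentages follow the study's printed style: one decimal place, rounded
half-away-from-zero, computed from integer counts. The variant report has
one row per (variant, cohort) that completely segregates in at least one
family, with the number of segregating families, affected carriers and
unaffected (healthy) carriers in those families, APOE e4 co-segregation,
and the locus index SNP with its family carrier count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pedigree import Affection, FamilyCohort
from .segregation import (
    ExplanationLabel,
    FamilyExplanation,
    SegregationCall,
    SegregationStatus,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSummary",
    "percent",
    "summarize_cohorts",
    "variant_report",
    "VARIANT_REPORT_COLUMNS",
]


def percent(numerator: int, denominator: int) -> float:
    """100·num/den rounded half-away-from-zero to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortSummary:
    cohort_id: str
    n_families: int
    n_individuals: int
    n_affected: int
    n_unaffected: int
    n_variants_complete: int
    n_genes_complete: int
    n_families_with_complete: int
    n_families_apoe_only: int
    n_families_unexplained: int

    def __post_init__(self) -> None:
        total = (
            self.n_families_with_complete
            + self.n_families_apoe_only
            + self.n_families_unexplained
        )
        if total != self.n_families:
            raise ValueError(
                f"{self.cohort_id}: explanation labels ({total}) do not "
                f"partition the {self.n_families} families"
            )

    @property
    def pct_families_with_complete(self) -> float:
        return percent(self.n_families_with_complete, self.n_families)

    @property
    def pct_families_apoe_only(self) -> float:
        return percent(self.n_families_apoe_only, self.n_families)

    @property
    def pct_families_unexplained(self) -> float:
        return percent(self.n_families_unexplained, self.n_families)

    def as_dict(self) -> dict:
        d = {
            "cohort_id": self.cohort_id,
            "n_families": self.n_families,
            "n_individuals": self.n_individuals,
            "n_affected": self.n_affected,
            "n_unaffected": self.n_unaffected,
            "n_variants_complete": self.n_variants_complete,
            "n_genes_complete": self.n_genes_complete,
            "n_families_rare_explained": self.n_families_with_complete,
            "n_families_apoe_only": self.n_families_apoe_only,
            "n_families_unexplained": self.n_families_unexplained,
        }
        if self.n_families:
            d.update(
                pct_families_rare_explained=self.pct_families_with_complete,
                pct_families_apoe_only=self.pct_families_apoe_only,
                pct_families_unexplained=self.pct_families_unexplained,
            )
        return d


def _label_counts(explanations: Iterable[FamilyExplanation]) -> dict:
    counts = {label: 0 for label in ExplanationLabel}
    for e in explanations:
        counts[e.label] += 1
    return counts


def summarize_cohorts(
    cohorts: Mapping[str, FamilyCohort],
    explanations: Mapping[str, Sequence[FamilyExplanation]],
    seg_calls: Mapping[str, Sequence[SegregationCall]],
    variant_genes: Mapping[str, str | None] | None = None,
) -> dict[str, CohortSummary]:
    """Per-cohort summaries plus a pooled ``combined`` summary.

    ``seg_calls`` maps cohort_id to the (post cross-family-consistency)
    calls on damaging variants; distinct variants deduplicate on the
    chrom:pos:ref:alt key and distinct genes on the gene symbol, per cohort
    and again globally for the combined row.
    """
    variant_genes = variant_genes or {}
    out: dict[str, CohortSummary] = {}
    for cohort_id, cohort in cohorts.items():
        if cohort.n_families == 0:
            logger.warning("cohort %s has no families; zeroed summary", cohort_id)
        members = list(cohort.individuals())
        labels = _label_counts(explanations.get(cohort_id, ()))
        complete = [
            c for c in seg_calls.get(cohort_id, ())
            if c.status is SegregationStatus.COMPLETE
        ]
        variants = {c.variant_key for c in complete}
        genes = {
            g for g in (variant_genes.get(k) for k in variants) if g is not None
        }
        out[cohort_id] = CohortSummary(
            cohort_id=cohort_id,
            n_families=cohort.n_families,
            n_individuals=len(members),
            n_affected=sum(m.affection is Affection.AFFECTED for m in members),
            n_unaffected=sum(m.affection is Affection.UNAFFECTED for m in members),
            n_variants_complete=len(variants),
            n_genes_complete=len(genes),
            n_families_with_complete=labels[ExplanationLabel.RARE_EXPLAINED],
            n_families_apoe_only=labels[ExplanationLabel.APOE_ONLY],
            n_families_unexplained=labels[ExplanationLabel.UNEXPLAINED],
        )

    all_complete = {
        c.variant_key
        for calls in seg_calls.values()
        for c in calls
        if c.status is SegregationStatus.COMPLETE
    }
    all_genes = {
        g for g in (variant_genes.get(k) for k in all_complete) if g is not None
    }
    out["combined"] = CohortSummary(
        cohort_id="combined",
        n_families=sum(s.n_families for s in out.values()),
        n_individuals=sum(s.n_individuals for s in out.values()),
        n_affected=sum(s.n_affected for s in out.values()),
        n_unaffected=sum(s.n_unaffected for s in out.values()),
        n_variants_complete=len(all_complete),
        n_genes_complete=len(all_genes),
        n_families_with_complete=sum(
            s.n_families_with_complete for s in out.values()
        ),
        n_families_apoe_only=sum(s.n_families_apoe_only for s in out.values()),
        n_families_unexplained=sum(s.n_families_unexplained for s in out.values()),
    )
    return out


VARIANT_REPORT_COLUMNS = [
    "variant",
    "gene",
    "variant_type",
    "cohort",
    "families_complete",
    "n_affected_in_segregating_families",
    "n_healthy_in_segregating_families",
    "coseg_APOE",
    "index_SNP",
    "n_members_carrying_index_SNP",
]

_CHROM_RE = re.compile(r"^chr(\w+)$")


def _chrom_order(chrom: str) -> tuple[int, str]:
    m = _CHROM_RE.match(chrom)
    body = m.group(1) if m else chrom
    return (int(body), "") if body.isdigit() else (99, body)


def variant_report(
    seg_calls: Mapping[str, Sequence[SegregationCall]],
    variant_info: Mapping[str, Mapping] | None = None,
    apoe_calls: Mapping[str, SegregationCall] | None = None,
    index_carriers: Mapping[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """One row per (variant, cohort) with at least one segregating family.

    ``seg_calls`` maps cohort_id to calls; ``variant_info`` maps variant key
    to gene / variant_type / index_snp; ``apoe_calls`` maps family_id to the
    family's APOE e4 call; ``index_carriers`` maps (variant key, family_id)
    to the family's index-SNP carrier count. Affected/healthy columns sum the
    carrier counts over the families where the variant completely segregates;
    coseg_APOE is "Yes" if e4 also segregates in any of those families.
    Row order is deterministic: (chrom, pos, alt, cohort).
    """
    variant_info = variant_info or {}
    apoe_calls = apoe_calls or {}
    index_carriers = index_carriers or {}

    rows = []
    for cohort_id, calls in seg_calls.items():
        per_variant: dict[str, list[SegregationCall]] = {}
        for c in calls:
            if c.status is SegregationStatus.COMPLETE:
                per_variant.setdefault(c.variant_key, []).append(c)
        for key, group in per_variant.items():
            info = variant_info.get(key, {})
            coseg = any(
                (apoe := apoe_calls.get(c.family_id)) is not None
                and apoe.status is SegregationStatus.COMPLETE
                for c in group
            )
            rows.append(
                {
                    "variant": key,
                    "gene": info.get("gene", ""),
                    "variant_type": info.get("variant_type", ""),
                    "cohort": cohort_id,
                    "families_complete": len(group),
                    "n_affected_in_segregating_families": sum(
                        c.n_affected_carriers for c in group
                    ),
                    "n_healthy_in_segregating_families": sum(
                        c.n_unaffected_carriers for c in group
                    ),
                    "coseg_APOE": "Yes" if coseg else "No",
                    "index_SNP": info.get("index_snp", ""),
                    "n_members_carrying_index_SNP": sum(
                        index_carriers.get((key, c.family_id), 0) for c in group
                    ),
                }
            )

    df = pd.DataFrame(rows, columns=VARIANT_REPORT_COLUMNS)
    if df.empty:
        return df
    parts = df["variant"].str.split(":", expand=True)
    df["_c"] = [_chrom_order(c) for c in parts[0]]
    df["_p"] = parts[1].astype(int)
    df["_a"] = parts[3]
    df = (
        df.sort_values(["_c", "_p", "_a", "cohort"], kind="mergesort")
        .drop(columns=["_c", "_p", "_a"])
        .reset_index(drop=True)
    )
    return df
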