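"""Family and cohort-level segregation classification.

The central rule set, applied to each (variant, family) pair under a
dominant carrier model (carrier = at least one alternate allele):

Complete segregation within a family requires
  (a) every affected member with a non-missing genotype carries the variant,
  (b) at least two affected carriers, and
  (c) every unaffected carrier is at least ``buffer`` years (default 5)
      younger than the reference age at onset, so their carriage remains
      consistent with pre-symptomatic status.

The reference onset age is, by default, the mean onset of the affected
carriers of the variant under test; the family-wide mean over all affected
members is available via ``onset_reference="family_mean"``.

Incomplete segregation is a cohort-scope pattern for variants that do not
completely segregate: at least four affected carriers pooled across the
cohort's families, more affected than unaffected carriers, and every
unaffected carrier passing the age buffer against their own family's
reference onset.

A cross-family consistency rule demotes variants that completely segregate
in one family but are carried by unaffected members in another: in strict
mode any unaffected carrier elsewhere demotes the variant; in lenient mode
buffer-qualifying unaffected carriers are tolerated.

Members with unknown affection are excluded from both the all-affected-carry
test and the unaffected-carrier test (configurable upstream of this module
by recoding their affection).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .pedigree import Affection, IndividualRecord
from .variants import MISSING, VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "SegregationStatus",
    "ExplanationLabel",
    "SegregationCall",
    "FamilyExplanation",
    "unaffected_qualifies",
    "classify_family_segregation",
    "classify_cohort_incomplete",
    "cross_family_consistency",
    "classify_family_explanation",
]


class SegregationStatus(enum.Enum):
    COMPLETE = "COMPLETE"
    INCOMPLETE = "INCOMPLETE"
    NONE = "NONE"


class ExplanationLabel(enum.Enum):
    RARE_EXPLAINED = "RARE_EXPLAINED"
    APOE_ONLY = "APOE_ONLY"
    UNEXPLAINED = "UNEXPLAINED"


@dataclass(frozen=True)
class SegregationCall:
    """Per (variant, family) verdict with the carrier counts behind it."""

    variant_key: str
    family_id: str
    status: SegregationStatus
    n_affected_carriers: int
    n_affected_genotyped: int
    n_unaffected_carriers: int
    n_unaffected_carriers_qualifying: int

    def carried(self) -> bool:
        return self.n_affected_carriers + self.n_unaffected_carriers > 0


@dataclass(frozen=True)
class FamilyExplanation:
    family_id: str
    label: ExplanationLabel


Dosages = Mapping[str, int]  # individual_id -> {0,1,2,MISSING}


def unaffected_qualifies(
    unaffected_age: float | None,
    reference_onset: float | None,
    buffer: float = 5.0,
) -> bool:
    """True iff the unaffected carrier is ≥ buffer years below the reference onset.

    The comparison is inclusive: exactly ``buffer`` years younger qualifies.
    A missing age on either side does not qualify (logged).
    """
    if unaffected_age is None or reference_onset is None:
        logger.debug("age buffer check with missing age; treating as not qualifying")
        return False
    return (reference_onset - unaffected_age) >= buffer


def _dosage(dosages: Dosages, individual_id: str) -> int:
    return dosages.get(individual_id, MISSING)


def _reference_onset(
    members: Sequence[IndividualRecord],
    dosages: Dosages,
    onset_reference: str,
) -> float | None:
    """Mean onset of affected carriers (default) or of all affected members.

    Falls back to the family-wide mean when no affected carrier has a usable
    genotype/age, so the unaffected buffer is still evaluable for variants
    carried only by unaffected members.
    """
    affected = [
        m for m in members
        if m.affection is Affection.AFFECTED and m.age_years is not None
    ]
    if onset_reference == "carrier_mean":
        carriers = [m for m in affected if _dosage(dosages, m.individual_id) >= 1]
        pool = carriers or affected
    elif onset_reference == "family_mean":
        pool = affected
    else:
        raise ValueError(f"unknown onset_reference {onset_reference!r}")
    if not pool:
        return None
    return sum(m.age_years for m in pool) / len(pool)


def classify_family_segregation(
    members: Sequence[IndividualRecord],
    dosages: Dosages,
    variant: VariantSite | str,
    buffer: float = 5.0,
    onset_reference: str = "carrier_mean",
    min_affected_carriers: int = 2,
) -> SegregationCall:
    """Apply the three-condition complete-segregation rule to one family.

    Returns COMPLETE or NONE; the INCOMPLETE label exists only at cohort
    scope (see :func:`classify_cohort_incomplete`). Affected members with
    missing genotypes are excluded from the all-carry condition rather than
    counted as non-carriers.
    """
    key = variant.key if isinstance(variant, VariantSite) else variant
    family_id = members[0].family_id if members else ""

    n_aff_geno = 0
    n_aff_carr = 0
    unaff_carriers: list[IndividualRecord] = []
    for m in members:
        d = _dosage(dosages, m.individual_id)
        if m.affection is Affection.AFFECTED:
            if d != MISSING:
                n_aff_geno += 1
                if d >= 1:
                    n_aff_carr += 1
        elif m.affection is Affection.UNAFFECTED:
            if d != MISSING and d >= 1:
                unaff_carriers.append(m)
        # unknown affection: excluded from both conditions

    ref = _reference_onset(members, dosages, onset_reference)
    n_unaff_qual = sum(
        unaffected_qualifies(m.age_years, ref, buffer) for m in unaff_carriers
    )

    complete = (
        n_aff_geno > 0
        and n_aff_carr == n_aff_geno
        and n_aff_carr >= min_affected_carriers
        and n_unaff_qual == len(unaff_carriers)
    )
    return SegregationCall(
        variant_key=key,
        family_id=family_id,
        status=SegregationStatus.COMPLETE if complete else SegregationStatus.NONE,
        n_affected_carriers=n_aff_carr,
        n_affected_genotyped=n_aff_geno,
        n_unaffected_carriers=len(unaff_carriers),
        n_unaffected_carriers_qualifying=n_unaff_qual,
    )


def classify_cohort_incomplete(
    variant: VariantSite | str,
    cohort_families: Mapping[str, tuple[Sequence[IndividualRecord], Dosages]],
    buffer: float = 5.0,
    onset_reference: str = "carrier_mean",
    min_affected_carriers: int = 4,
) -> SegregationStatus:
    """Cohort-pooled incomplete-segregation test for one variant.

    INCOMPLETE iff, pooling carriers across the cohort's families: affected
    carriers ≥ ``min_affected_carriers`` (default 4), strictly more affected
    than unaffected carriers, and every unaffected carrier passes the age
    buffer against their own family's reference onset. Meant for variants
    that are not COMPLETE in the family under consideration.
    """
    n_aff = 0
    n_unaff = 0
    all_qualify = True
    for members, dosages in cohort_families.values():
        ref = _reference_onset(members, dosages, onset_reference)
        for m in members:
            d = _dosage(dosages, m.individual_id)
            if d == MISSING or d < 1:
                continue
            if m.affection is Affection.AFFECTED:
                n_aff += 1
            elif m.affection is Affection.UNAFFECTED:
                n_unaff += 1
                if not unaffected_qualifies(m.age_years, ref, buffer):
                    all_qualify = False
    if n_aff >= min_affected_carriers and n_aff > n_unaff and all_qualify:
        return SegregationStatus.INCOMPLETE
    return SegregationStatus.NONE


def cross_family_consistency(
    calls: Sequence[SegregationCall],
    strict: bool = True,
) -> list[SegregationCall]:
    """Demote variants that segregate in one family but leak elsewhere.

    If a variant is COMPLETE in at least one family and carried in another
    family where it is not COMPLETE, it remains qualifying only if in those
    families all carriers are affected (strict mode, the default) or any
    unaffected carriers pass the age buffer (lenient mode). Otherwise every
    call for the variant is demoted to NONE; demotions are logged.

    ``calls`` may cover many variants; grouping is internal.
    """
    by_variant: dict[str, list[SegregationCall]] = {}
    for call in calls:
        by_variant.setdefault(call.variant_key, []).append(call)

    demoted: set[str] = set()
    for key, group in by_variant.items():
        if not any(c.status is SegregationStatus.COMPLETE for c in group):
            continue
        for c in group:
            if c.status is SegregationStatus.COMPLETE or not c.carried():
                continue
            if strict:
                ok = c.n_unaffected_carriers == 0
            else:
                ok = c.n_unaffected_carriers == c.n_unaffected_carriers_qualifying
            if not ok:
                demoted.add(key)
                logger.info(
                    "variant %s demoted: carried by unaffected members of "
                    "family %s", key, c.family_id,
                )
                break

    return [
        replace(c, status=SegregationStatus.NONE)
        if c.variant_key in demoted
        else c
        for c in calls
    ]


def classify_family_explanation(
    family_id: str,
    seg_calls: Iterable[SegregationCall],
    apoe_call: SegregationCall | None,
) -> FamilyExplanation:
    """Label the family by what accounts for its disease.

    RARE_EXPLAINED if any damaging variant completely segregates in the
    family (regardless of APOE); else APOE_ONLY if the e4 allele segregates;
    else UNEXPLAINED. ``seg_calls`` must already be restricted to this
    family's calls on damaging variants.
    """
    for call in seg_calls:
        if call.family_id != family_id:
            raise ValueError(
                f"call for family {call.family_id!r} passed to {family_id!r}"
            )
        if call.status is SegregationStatus.COMPLETE:
            return FamilyExplanation(family_id, ExplanationLabel.RARE_EXPLAINED)
    if apoe_call is not None and apoe_call.status is SegregationStatus.COMPLETE:
        return FamilyExplanation(family_id, ExplanationLabel.APOE_ONLY)
    return FamilyExplanation(family_id, ExplanationLabel.UNEXPLAINED)
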