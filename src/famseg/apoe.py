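"""APOE e2/e3/e4 diplotype calling and e4 segregation.

The three common APOE haplotypes are defined jointly by two coding SNPs:
rs429358 (T>C) and rs7412 (C>T). On a haplotype, rs429358-C with rs7412-C is
e4; T with C is e3; T with T is e2. From unphased genotypes the diplotype is
recovered by allele counting: each rs429358 alternate (C) allele contributes
an e4 haplotype, and each rs7412 alternate (T) allele among the remaining
haplotypes contributes an e2. The double heterozygote is phase-ambiguous
(e2/e4 vs the rare e1/e3) and is resolved to e2/e4 on population-frequency
grounds, flagged ``ambiguous``. Genotype pairs that would imply an e1
haplotype (rs429358-C with rs7412-T in excess) are mapped to the nearest
diplotype in {e2,e3,e4}; e1 is not modeled.

e4 segregation within a family uses the identical three-condition rule as
rare variants, with carrier = at least one e4 allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .pedigree import IndividualRecord
from .segregation import (
    SegregationCall,
    SegregationStatus,
    classify_family_segregation,
)
from .variants import MISSING

logger = logging.getLogger(__name__)

__all__ = [
    "APOE_RS429358_GRCH38",
    "APOE_RS7412_GRCH38",
    "ApoeDiplotype",
    "call_apoe_diplotype",
    "e4_dosage",
    "apoe_e4_segregation",
    "cosegregates_with_apoe",
]

# Default GRCh38 coordinates for the two APOE SNPs; configuration constants,
# overridable by the user (chrom, pos, ref, alt).
APOE_RS429358_GRCH38 = ("chr19", 44908684, "T", "C")
APOE_RS7412_GRCH38 = ("chr19", 44908822, "C", "T")


@dataclass(frozen=True)
class ApoeDiplotype:
    """Unordered pair of APOE alleles, each one of 'e2', 'e3', 'e4'."""

    alleles: tuple[str, str]
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if any(a not in {"e2", "e3", "e4"} for a in self.alleles):
            raise ValueError(f"invalid APOE alleles {self.alleles}")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def n_e4(self) -> int:
        return sum(a == "e4" for a in self.alleles)

    def __str__(self) -> str:
        return "/".join(self.alleles)


def call_apoe_diplotype(
    dosage_rs429358: int, dosage_rs7412: int
) -> ApoeDiplotype | None:
    """Call the diplotype from alternate-allele dosages at the two SNPs.

    ``dosage_rs429358`` counts C alleles (T>C); ``dosage_rs7412`` counts T
    alleles (C>T). Returns None when either genotype is missing, in which
    case the individual is excluded from e4 segregation (logged).
    """
    c4, c2 = dosage_rs429358, dosage_rs7412
    if c4 == MISSING or c2 == MISSING or c4 < 0 or c2 < 0:
        logger.warning("APOE diplotype with a missing genotype; excluded")
        return None
    if not (0 <= c4 <= 2 and 0 <= c2 <= 2):
        raise ValueError(f"dosages must be in 0..2, got ({c4}, {c2})")
    n_e4 = c4
    # T alleles at rs7412 beyond what the non-e4 haplotypes can absorb imply
    # e1 and are folded into e4 (not modeled).
    n_e2 = min(c2, 2 - n_e4)
    n_e3 = 2 - n_e4 - n_e2
    alleles = tuple(["e4"] * n_e4 + ["e2"] * n_e2 + ["e3"] * n_e3)
    return ApoeDiplotype(alleles=alleles, ambiguous=(c4 == 1 and c2 == 1))


def e4_dosage(
    diplotypes: Mapping[str, ApoeDiplotype | None],
    exclude_ambiguous: bool = False,
) -> dict[str, int]:
    """Per-individual e4 carrier dosage; missing/excluded become MISSING."""
    out: dict[str, int] = {}
    for iid, dip in diplotypes.items():
        if dip is None or (exclude_ambiguous and dip.ambiguous):
            out[iid] = MISSING
        else:
            out[iid] = dip.n_e4
    return out


def apoe_e4_segregation(
    members: Sequence[IndividualRecord],
    diplotypes: Mapping[str, ApoeDiplotype | None],
    buffer: float = 5.0,
    onset_reference: str = "carrier_mean",
    exclude_ambiguous: bool = False,
    apply_buffer: bool = True,
) -> SegregationCall:
    """Evaluate e4 family segregation with the rare-variant rule.

    ``apply_buffer=False`` ignores unaffected e4 carriers entirely (an
    alternative reading for a common allele); the default applies the same
    age-buffer rule as for rare variants.
    """
    dosages = e4_dosage(diplotypes, exclude_ambiguous=exclude_ambiguous)
    call = classify_family_segregation(
        members, dosages, "APOE_e4", buffer=buffer, onset_reference=onset_reference
    )
    if not apply_buffer and call.status is SegregationStatus.NONE:
        # re-evaluate condition (a)+(b) only
        if (
            call.n_affected_genotyped > 0
            and call.n_affected_carriers == call.n_affected_genotyped
            and call.n_affected_carriers >= 2
        ):
            call = SegregationCall(
                variant_key=call.variant_key,
                family_id=call.family_id,
                status=SegregationStatus.COMPLETE,
                n_affected_carriers=call.n_affected_carriers,
                n_affected_genotyped=call.n_affected_genotyped,
                n_unaffected_carriers=call.n_unaffected_carriers,
                n_unaffected_carriers_qualifying=call.n_unaffected_carriers_qualifying,
            )
    return call


def cosegregates_with_apoe(
    variant_call: SegregationCall, apoe_call: SegregationCall
) -> bool:
    """True iff both the variant and e4 completely segregate in the family."""
    if variant_call.family_id != apoe_call.family_id:
        raise ValueError("co-segregation requires calls from the same family")
    return (
        variant_call.status is SegregationStatus.COMPLETE
        and apoe_call.status is SegregationStatus.COMPLETE
    )
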