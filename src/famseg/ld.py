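"""Linkage disequilibrium between common index SNPs and rare variants.

Two r² estimators are provided. The default is the squared Pearson
correlation of alternate-allele dosages over pairwise-complete samples (the
composite/genotype r² most LD tools report for unphased data). The optional
companion is a two-locus EM estimator of the four haplotype frequencies,
from which r² = D² / (pA·qA·pB·qB); with no double heterozygotes the EM
fixed point equals direct haplotype counting, and under random mating the
two estimators agree in large samples.

Co-segregation of a common index SNP with a rare segregating variant is
checked by applying the same complete-segregation rule to the index SNP in
the same family.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .pedigree import IndividualRecord
from .segregation import (
    SegregationCall,
    SegregationStatus,
    classify_family_segregation,
)
from .variants import MISSING

logger = logging.getLogger(__name__)

__all__ = [
    "LDMethod",
    "LDResult",
    "LDUndefinedError",
    "EMConvergenceError",
    "genotype_r2",
    "em_haplotype_frequencies",
    "em_haplotype_r2",
    "r2_from_haplotype_freqs",
    "index_carrier_count",
    "cosegregates_with_index",
]


class LDMethod(enum.Enum):
    GENOTYPE_CORR = "genotype_corr"
    EM_HAPLOTYPE = "em_haplotype"


class LDUndefinedError(ValueError):
    """r² is undefined (monomorphic locus or too few complete pairs)."""


class EMConvergenceError(RuntimeError):
    def __init__(self, message: str, last_freqs: np.ndarray):
        super().__init__(message)
        self.last_freqs = last_freqs


@dataclass(frozen=True)
class LDResult:
    variant_a: str
    variant_b: str
    r2: float
    n_samples: int
    method: LDMethod

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1.0 + 1e-9):
            raise ValueError(f"r2 out of [0,1]: {self.r2}")


def _complete_pairs(
    dosages_a: Sequence[int], dosages_b: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    keep = (a != MISSING) & (b != MISSING)
    return a[keep], b[keep]


def genotype_r2(
    dosages_a: Sequence[int],
    dosages_b: Sequence[int],
    name_a: str = "a",
    name_b: str = "b",
) -> LDResult:
    """Squared Pearson correlation of dosages over pairwise-complete samples.

    Symmetric in its arguments and invariant to swapping ref/alt labels at
    either locus (which only flips the correlation's sign). Raises
    :class:`LDUndefinedError` when fewer than two complete pairs remain or
    either vector is constant.
    """
    a, b = _complete_pairs(dosages_a, dosages_b)
    n = a.size
    if n < 2:
        raise LDUndefinedError(f"only {n} pairwise-complete samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise LDUndefinedError("constant dosage vector: r² undefined")
    r = np.corrcoef(a, b)[0, 1]
    r2 = min(float(r * r), 1.0)
    return LDResult(name_a, name_b, r2, n, LDMethod.GENOTYPE_CORR)


def r2_from_haplotype_freqs(freqs: Sequence[float]) -> float:
    """Closed-form r² from the four haplotype frequencies (AB, Ab, aB, ab)."""
    f = np.asarray(freqs, dtype=float)
    if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("freqs must be a non-negative 4-vector summing to 1")
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise LDUndefinedError("monomorphic locus: r² undefined")
    d = f[0] - pA * pB
    return float(d * d / denom)


def em_haplotype_frequencies(
    dosages_a: Sequence[int],
    dosages_b: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int]:
    """EM estimate of the four haplotype frequencies (AB, Ab, aB, ab).

    Only the double heterozygote is phase-ambiguous; the E-step splits its
    2n contributions between AB/ab and Ab/aB in proportion to the current
    haplotype-product weights. Frequencies are non-negative and sum to one
    at every iteration.
    """
    a, b = _complete_pairs(dosages_a, dosages_b)
    n = a.size
    if n < 2:
        raise LDUndefinedError(f"only {n} pairwise-complete samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise LDUndefinedError("constant dosage vector: r² undefined")

    # 3x3 genotype table; counts[i, j] = #samples with dosage_a=i, dosage_b=j
    counts = np.zeros((3, 3), dtype=float)
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.count_nonzero((a == i) & (b == j))

    # Unambiguous haplotype contributions per genotype cell. Order:
    # 0=AB (alt_a,alt_b), 1=Ab, 2=aB, 3=ab  — "A"/"B" denote the ALT alleles.
    fixed = np.zeros(4)
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            # haplotypes per individual: i copies of alt_a, j of alt_b,
            # phase known for all cells except the double het
            n_AB = min(i, j)
            n_Ab = i - n_AB
            n_aB = j - n_AB
            n_ab = 2 - n_AB - n_Ab - n_aB
            fixed += c * np.array([n_AB, n_Ab, n_aB, n_ab], dtype=float)

    n_dh = counts[1, 1]
    total = 2.0 * n
    freqs = np.full(4, 0.25)
    for iteration in range(1, max_iter + 1):
        w_cis = freqs[0] * freqs[3]
        w_trans = freqs[1] * freqs[2]
        denom = w_cis + w_trans
        p_cis = 0.5 if denom == 0 else w_cis / denom
        counts_h = fixed + n_dh * np.array(
            [p_cis, 1 - p_cis, 1 - p_cis, p_cis], dtype=float
        )
        new = counts_h / total
        if np.max(np.abs(new - freqs)) < tol:
            return new, iteration
        freqs = new
    raise EMConvergenceError(
        f"EM did not converge in {max_iter} iterations", freqs
    )


def em_haplotype_r2(
    dosages_a: Sequence[int],
    dosages_b: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 1000,
    name_a: str = "a",
    name_b: str = "b",
) -> LDResult:
    """EM haplotype-frequency r² = D²/(pA·qA·pB·qB)."""
    a, b = _complete_pairs(dosages_a, dosages_b)
    freqs, _ = em_haplotype_frequencies(dosages_a, dosages_b, tol, max_iter)
    return LDResult(name_a, name_b, min(r2_from_haplotype_freqs(freqs), 1.0),
                    int(a.size), LDMethod.EM_HAPLOTYPE)


def index_carrier_count(
    members: Sequence[IndividualRecord],
    index_dosages: Mapping[str, int],
) -> int:
    """Family members (any affection) with ≥1 index-SNP alternate allele."""
    if members and all(
        index_dosages.get(m.individual_id, MISSING) == MISSING for m in members
    ):
        logger.warning(
            "family %s: all index-SNP genotypes missing", members[0].family_id
        )
    return sum(
        1
        for m in members
        if index_dosages.get(m.individual_id, MISSING) not in (MISSING,)
        and index_dosages.get(m.individual_id, MISSING) >= 1
    )


def cosegregates_with_index(
    variant_call: SegregationCall,
    members: Sequence[IndividualRecord],
    index_dosages: Mapping[str, int],
    buffer: float = 5.0,
    onset_reference: str = "carrier_mean",
) -> bool:
    """True iff the index SNP itself completely segregates in this family.

    Only meaningful for a variant that completely segregates there;
    violating that precondition is an error.
    """
    if variant_call.status is not SegregationStatus.COMPLETE:
        raise ValueError(
            "index co-segregation is defined only for completely "
            "segregating variants"
        )
    index_call = classify_family_segregation(
        members, index_dosages, "index_snp", buffer=buffer,
        onset_reference=onset_reference,
    )
    return index_call.status is SegregationStatus.COMPLETE
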