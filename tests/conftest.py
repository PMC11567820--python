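"""Shared fixtures and independent brute-force oracles.

The oracles re-state the classification and QC rules as literal loops,
kept deliberately independent of the package's implementation so that
agreement between the two is informative.
"""

from __future__ import annotations

import pytest

from famseg.pedigree import Affection, IndividualRecord, Sex
from famseg.pipeline import inputs_from_study, run_study
from famseg.simulate import SimulationConfig, simulate_cohorts

MISSING = -1


def make_member(
    fid: str,
    iid: str,
    affection: str,
    age: float | None,
) -> IndividualRecord:
    return IndividualRecord(
        family_id=fid,
        individual_id=iid,
        father_id="0",
        mother_id="0",
        sex=Sex.UNKNOWN,
        affection=Affection(affection),
        age_years=age,
    )


def brute_force_segregation(
    members, dosages, buffer=5.0, onset_reference="carrier_mean"
) -> str:
    """Literal restatement of the complete-segregation rule.

    (a) all genotyped affected members carry; (b) ≥2 affected carriers;
    (c) every unaffected carrier is ≥ buffer years below the reference
    onset (mean onset of affected carriers by default, family mean
    otherwise). Unknown-affection members are ignored.
    """
    affected = [m for m in members if m.affection is Affection.AFFECTED]
    unaffected = [m for m in members if m.affection is Affection.UNAFFECTED]
    genotyped = [m for m in affected if dosages.get(m.individual_id, MISSING) != MISSING]
    carriers = [m for m in genotyped if dosages[m.individual_id] >= 1]
    if len(genotyped) == 0:
        return "NONE"
    if len(carriers) != len(genotyped) or len(carriers) < 2:
        return "NONE"
    if onset_reference == "carrier_mean":
        pool = [m for m in carriers if m.age_years is not None] or [
            m for m in affected if m.age_years is not None
        ]
    else:
        pool = [m for m in affected if m.age_years is not None]
    ref = sum(m.age_years for m in pool) / len(pool) if pool else None
    for m in unaffected:
        d = dosages.get(m.individual_id, MISSING)
        if d != MISSING and d >= 1:
            if (
                m.age_years is None
                or ref is None
                or not (ref - m.age_years >= buffer)
            ):
                return "NONE"
    return "COMPLETE"


def brute_force_mask_count(dp, gq, dosage, min_dp=10, min_gq=20) -> int:
    """Count genotypes a literal reading of the QC rule would mask."""
    n = 0
    for i in range(len(dp)):
        for j in range(len(dp[i])):
            if dosage[i][j] == MISSING:
                continue
            bad_dp = dp[i][j] >= 0 and dp[i][j] < min_dp
            bad_gq = gq[i][j] >= 0 and gq[i][j] < min_gq
            if bad_dp or bad_gq:
                n += 1
    return n


@pytest.fixture(scope="session")
def small_study():
    """A modest two-cohort simulation with zero QC noise."""
    return simulate_cohorts(SimulationConfig(seed=11, n_families=40))


@pytest.fixture(scope="session")
def small_result(small_study):
    inputs, index_snps = inputs_from_study(small_study)
    return run_study(inputs, index_snps)
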