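"""Pedigree and phenotype I/O for multiplex family cohorts.

Families are the unit of analysis: a cohort is a set of families, each a list
of individuals with affection status and a single age field whose meaning
depends on status — age at onset for affected individuals (the age at which
the family first observed cognitive impairment) and age at the last
dementia-free examination for unaffected ones.

The file formats are the field's standard PED/FAM six leading columns plus a
separate phenotype TSV carrying affection and age (PED has no age column).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

FOUNDER = "0"  # PED convention for an absent parent

__all__ = [
    "FOUNDER",
    "Sex",
    "Affection",
    "IndividualRecord",
    "FamilyCohort",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "filter_families_min_affected",
    "mean_onset_age",
]


class PedigreeError(ValueError):
    """Raised for malformed or inconsistent pedigree/phenotype input."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def from_ped_code(cls, code: str) -> "Sex":
        return {"1": cls.MALE, "2": cls.FEMALE}.get(code, cls.UNKNOWN)

    def to_ped_code(self) -> str:
        return {Sex.MALE: "1", Sex.FEMALE: "2"}.get(self, "0")


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class IndividualRecord:
    """One pedigree member.

    ``age_years`` is age at onset if affected, age at last dementia-free exam
    if unaffected; it may be None only for non-affected individuals.
    """

    family_id: str
    individual_id: str
    father_id: str = FOUNDER
    mother_id: str = FOUNDER
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    age_years: float | None = None

    def __post_init__(self) -> None:
        if self.age_years is not None and not (0.0 <= self.age_years <= 130.0):
            raise PedigreeError(
                f"age_years={self.age_years} out of [0, 130] for "
                f"{self.family_id}/{self.individual_id}"
            )
        # affected members should carry an onset age; PED-only input has no
        # age column, so this is enforced where ages are actually read
        # (the phenotype TSV path) rather than here

    @property
    def sample_id(self) -> str:
        return self.individual_id


@dataclass
class FamilyCohort:
    """A named cohort: mapping family_id -> members."""

    cohort_id: str
    families: dict[str, list[IndividualRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for fid, members in self.families.items():
            ids = {m.individual_id for m in members}
            for m in members:
                key = (fid, m.individual_id)
                if key in seen:
                    raise PedigreeError(f"duplicate individual {key}")
                seen.add(key)
                if m.family_id != fid:
                    raise PedigreeError(
                        f"member {m.individual_id} carries family_id "
                        f"{m.family_id!r} but is filed under {fid!r}"
                    )
                for parent in (m.father_id, m.mother_id):
                    if parent != FOUNDER and parent not in ids:
                        raise PedigreeError(
                            f"{fid}/{m.individual_id}: parent {parent!r} is "
                            "neither a member nor the founder marker"
                        )

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_individuals(self) -> int:
        return sum(len(m) for m in self.families.values())

    def individuals(self) -> Iterable[IndividualRecord]:
        for members in self.families.values():
            yield from members

    def sample_ids(self) -> list[str]:
        return [m.individual_id for m in self.individuals()]


_PED_AFFECTION = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}


def read_pedigree(
    ped_path: str | Path,
    phenotype_path: str | Path | None = None,
    cohort_id: str | None = None,
) -> FamilyCohort:
    """Read a PED/FAM file plus a phenotype TSV into a FamilyCohort.

    The phenotype TSV (header: family_id, individual_id, affection, age_years)
    overrides the PED 6th column; individuals present in PED but missing from
    the TSV get affection=unknown. Without a TSV the PED codes are used
    (2=affected, 1=unaffected, other=unknown) and ages are absent.
    """
    ped_path = Path(ped_path)
    pheno: dict[tuple[str, str], tuple[Affection, float | None]] = {}
    if phenotype_path is not None:
        tbl = pd.read_csv(phenotype_path, sep="\t", dtype=str)
        required = {"family_id", "individual_id", "affection", "age_years"}
        missing = required - set(tbl.columns)
        if missing:
            raise PedigreeError(f"phenotype file lacks columns: {sorted(missing)}")
        for i, row in tbl.iterrows():
            key = (row["family_id"], row["individual_id"])
            if key in pheno:
                raise PedigreeError(f"duplicate phenotype row for {key}")
            raw_age = row["age_years"]
            if pd.isna(raw_age) or raw_age == "":
                age: float | None = None
            else:
                try:
                    age = float(raw_age)
                except ValueError as exc:
                    raise PedigreeError(
                        f"phenotype row {i + 1} ({key[0]}/{key[1]}): "
                        f"unparseable age {raw_age!r}"
                    ) from exc
                if not (0.0 <= age <= 130.0):
                    raise PedigreeError(
                        f"phenotype row {i + 1} ({key[0]}/{key[1]}): "
                        f"age {age} out of [0, 130]"
                    )
            try:
                affection = Affection(row["affection"])
            except ValueError as exc:
                raise PedigreeError(
                    f"phenotype row {i + 1}: unknown affection "
                    f"{row['affection']!r}"
                ) from exc
            if affection is Affection.AFFECTED and age is None:
                raise PedigreeError(
                    f"phenotype row {i + 1} ({key[0]}/{key[1]}): affected "
                    "individual without an age at onset"
                )
            pheno[key] = (affection, age)

    families: dict[str, list[IndividualRecord]] = {}
    with open(ped_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedigreeError(f"{ped_path}:{lineno}: expected ≥6 columns")
            fid, iid, father, mother, sex_code, ped_pheno = cols[:6]
            if phenotype_path is not None:
                affection, age = pheno.get((fid, iid), (Affection.UNKNOWN, None))
            else:
                affection = _PED_AFFECTION.get(ped_pheno, Affection.UNKNOWN)
                age = None
            rec = IndividualRecord(
                family_id=fid,
                individual_id=iid,
                father_id=father,
                mother_id=mother,
                sex=Sex.from_ped_code(sex_code),
                affection=affection,
                age_years=age,
            )
            families.setdefault(fid, []).append(rec)

    return FamilyCohort(cohort_id=cohort_id or ped_path.stem, families=families)


def write_pedigree(
    cohort: FamilyCohort, ped_path: str | Path, phenotype_path: str | Path
) -> None:
    """Write PED + phenotype TSV; round-trips with :func:`read_pedigree`."""
    with open(ped_path, "w", encoding="utf-8") as fh:
        for m in cohort.individuals():
            code = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1"}.get(
                m.affection, "0"
            )
            fh.write(
                f"{m.family_id}\t{m.individual_id}\t{m.father_id}\t"
                f"{m.mother_id}\t{m.sex.to_ped_code()}\t{code}\n"
            )
    with open(phenotype_path, "w", encoding="utf-8") as fh:
        fh.write("family_id\tindividual_id\taffection\tage_years\n")
        for m in cohort.individuals():
            age = "" if m.age_years is None else f"{m.age_years:g}"
            fh.write(
                f"{m.family_id}\t{m.individual_id}\t{m.affection.value}\t{age}\n"
            )


def filter_families_min_affected(
    cohort: FamilyCohort, min_affected: int = 2
) -> FamilyCohort:
    """Keep only families with at least ``min_affected`` affected members.

    This is the study-inclusion filter for multiplex families; members of the
    retained families are untouched. Idempotent.
    """
    if min_affected < 1:
        raise ValueError("min_affected must be ≥ 1")
    kept = {
        fid: list(members)
        for fid, members in cohort.families.items()
        if sum(m.affection is Affection.AFFECTED for m in members) >= min_affected
    }
    return FamilyCohort(cohort_id=cohort.cohort_id, families=kept)


def mean_onset_age(family: Iterable[IndividualRecord]) -> float:
    """Arithmetic mean age at onset over a family's affected members."""
    ages = [
        m.age_years
        for m in family
        if m.affection is Affection.AFFECTED and m.age_years is not None
    ]
    if not ages:
        raise PedigreeError("no affected member with an onset age")
    return float(sum(ages) / len(ages))
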