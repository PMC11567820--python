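"""Two-cohort family simulator with planted segregation structure.

The generator emulates the structure of a two-cohort late-onset familial AD
study: multiplex families (each with at least two affected members), age at
onset drawn from Normal(75.2, 8.0) years for affected members, ages at last
dementia-free exam for unaffected members, rare (AF < 1%) damaging variants
planted with complete, incomplete or no segregation, APOE-only families,
unexplained families, common GWAS index SNPs, and tunable two-locus LD.

Carrier status is assigned directly to satisfy the planted patterns rather
than transmitted through the pedigree (parent ids are cosmetic): the
downstream classifiers use carrier status and ages only, so Mendelian
transmission would add machinery without adding test power.

Every family receives a truth label (RARE_EXPLAINED / APOE_ONLY /
UNEXPLAINED) and every planted qualifying variant a truth status
(COMPLETE per family, INCOMPLETE per cohort, or NONE), written to
``truth.tsv``. Planted complete-segregation patterns are verified against
the package's own classifier before anything is written (self-check); the
check runs on the clean genotypes, before QC noise is injected.

All randomness flows from a single integer seed; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotate import ConsequenceClass
from .apoe import APOE_RS429358_GRCH38, APOE_RS7412_GRCH38
from .pedigree import Affection, FamilyCohort, IndividualRecord, Sex, write_pedigree
from .segregation import SegregationStatus, classify_family_segregation
from .variants import MISSING

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "SimulationError",
    "DEFAULT_LOCI",
    "simulate_cohorts",
    "plant_ld_pair",
    "haplotype_freqs_for_r2",
]


class SimulationError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


# Candidate loci used for planting: (gene, chrom, anchor position). Loosely
# modeled on AD GWAS genes; positions only need to be internally consistent
# with the emitted BED.
DEFAULT_LOCI: list[tuple[str, str, int]] = [
    ("ABCA7", "chr19", 1040101),
    ("BIN1", "chr2", 127048027),
    ("CR1", "chr1", 207496147),
    ("CLU", "chr8", 27596917),
    ("PICALM", "chr11", 85957884),
    ("SORL1", "chr11", 121452314),
    ("TREM2", "chr6", 41158506),
    ("ABCA1", "chr9", 104781006),
    ("AKAP9", "chr7", 91940862),
    ("ANK3", "chr10", 60026298),
    ("MYO15A", "chr17", 18110710),
    ("SLC26A1", "chr4", 984154),
    ("PSEN1", "chr14", 73136418),
    ("PLCG2", "chr16", 81739098),
    ("EPHA1", "chr7", 143391679),
    ("PTK2B", "chr8", 27311265),
]

_LOF_CLASSES = [
    ConsequenceClass.STOPGAIN,
    ConsequenceClass.FRAMESHIFT,
    ConsequenceClass.SPLICE_ACCEPTOR,
    ConsequenceClass.SPLICE_DONOR,
    ConsequenceClass.STOPLOSS,
]


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the emulated study: two cohorts of multiplex families,
    affected onset ~ Normal(75.2, 8.0) years, and family-class fractions
    (rare-explained, APOE-only, unexplained) = (0.175, 0.226, 0.599).
    """

    seed: int = 0
    n_families: int = 200  # per cohort
    cohort_ids: tuple[str, str] = ("AD-FBS", "EFIGA")
    family_size_min: int = 4
    family_size_max: int = 8
    n_affected_min: int = 2
    n_affected_max: int = 4
    onset_mean: float = 75.2
    onset_sd: float = 8.0
    unaffected_age_mean: float = 72.0
    unaffected_age_sd: float = 10.0
    fraction_rare_explained: float = 0.175
    fraction_apoe_only: float = 0.226
    fraction_unexplained: float = 0.599
    buffer_years: float = 5.0
    # cohort-level incomplete-segregation variant (one per cohort)
    incomplete_affected_carriers: int = 5
    incomplete_unaffected_carriers: int = 1
    # probabilities of optional structure inside families
    p_unaffected_qualifying_carrier: float = 0.3
    p_apoe_coseg_in_rare_family: float = 0.3
    p_index_coseg_in_rare_family: float = 0.5
    p_decoy_in_family: float = 0.2
    index_snp_af: float = 0.2
    apoe_e4_background_af: float = 0.15
    apoe_e2_background_af: float = 0.06
    # QC noise rates per genotype call
    qc_noise_dp: float = 0.0
    qc_noise_gq: float = 0.0
    qc_noise_missing: float = 0.0

    def validate(self) -> None:
        fr = (
            self.fraction_rare_explained
            + self.fraction_apoe_only
            + self.fraction_unexplained
        )
        if abs(fr - 1.0) > 1e-9:
            raise SimulationError(f"family-class fractions sum to {fr}, not 1")
        if self.onset_sd <= 0:
            raise SimulationError("onset_sd must be > 0")
        if self.n_affected_min < 2:
            raise SimulationError(
                "rare-explained families need ≥2 affected members"
            )
        if self.family_size_min < self.n_affected_min + 1:
            raise SimulationError(
                "family_size_min must allow at least one unaffected member"
            )
        if self.family_size_max < self.family_size_min:
            raise SimulationError("family_size_max < family_size_min")
        if self.n_families < 0:
            raise SimulationError("n_families must be ≥ 0")
        for rate in (self.qc_noise_dp, self.qc_noise_gq, self.qc_noise_missing):
            if not (0.0 <= rate <= 1.0):
                raise SimulationError("qc noise rates must be in [0, 1]")
        if self.n_families > 0 and self.incomplete_affected_carriers > max(
            1, self.n_families
        ) * self.n_affected_max:
            raise SimulationError("incomplete variant needs more carriers than exist")


@dataclass
class _CohortData:
    """Internal per-cohort accumulator."""

    cohort: FamilyCohort
    sites: list[dict] = field(default_factory=list)  # VCF-row dicts
    dosages: dict[str, np.ndarray] = field(default_factory=dict)
    sample_index: dict[str, int] = field(default_factory=dict)


@dataclass
class SimulatedStudy:
    """In-memory simulation output; ``write`` materializes the file set."""

    config: SimulationConfig
    cohorts: dict[str, FamilyCohort]
    sites: dict[str, pd.DataFrame]  # per cohort: chrom,pos,ref,alt rows
    dosages: dict[str, dict[str, np.ndarray]]  # cohort -> key -> dosage
    dp: dict[str, dict[str, np.ndarray]]
    gq: dict[str, dict[str, np.ndarray]]
    samples: dict[str, list[str]]
    annotations: pd.DataFrame
    index_snps: pd.DataFrame
    truth: pd.DataFrame
    regions: pd.DataFrame  # chrom, start, end (BED half-open)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the full file set; returns the paths by role."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        for cid, cohort in self.cohorts.items():
            ped = out / f"{cid}.fam"
            pheno = out / f"{cid}.phenotypes.tsv"
            write_pedigree(cohort, ped, pheno)
            paths[f"ped:{cid}"] = ped
            paths[f"pheno:{cid}"] = pheno
            vcf = out / f"{cid}.vcf"
            self._write_vcf(cid, vcf)
            paths[f"vcf:{cid}"] = vcf

        ann = out / "annotations.tsv"
        self.annotations.to_csv(ann, sep="\t", index=False)
        paths["annotations"] = ann
        idx = out / "index_snps.tsv"
        self.index_snps.to_csv(idx, sep="\t", index=False)
        paths["index_snps"] = idx
        truth = out / "truth.tsv"
        self.truth.to_csv(truth, sep="\t", index=False)
        paths["truth"] = truth
        bed = out / "regions.bed"
        self.regions.to_csv(bed, sep="\t", index=False, header=False)
        paths["regions"] = bed
        return paths

    def _write_vcf(self, cohort_id: str, path: Path) -> None:
        import gzip

        samples = self.samples[cohort_id]
        sites = self.sites[cohort_id]
        dosages = self.dosages[cohort_id]
        dp = self.dp[cohort_id]
        gq = self.gq[cohort_id]
        opener = gzip.open if str(path).endswith(".gz") else open
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with opener(path, "wt", encoding="utf-8") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fh.write(
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                'Description="Genotype quality">\n'
            )
            for chrom in sites["chrom"].unique():
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples)
                + "\n"
            )
            for _, row in sites.iterrows():
                key = f"{row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}"
                d = dosages[key]
                dps = dp[key]
                gqs = gq[key]
                calls = "\t".join(
                    f"{gt_str[int(d[i])]}:{int(dps[i])}:{int(gqs[i])}"
                    if d[i] != MISSING
                    else "./.:.:."
                    for i in range(len(samples))
                )
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t"
                    f"{row['alt']}\t.\tPASS\t.\tGT:DP:GQ\t{calls}\n"
                )


def haplotype_freqs_for_r2(
    r2: float, p_a: float = 0.5, p_b: float = 0.5
) -> np.ndarray:
    """Four haplotype frequencies (AB, Ab, aB, ab) with the requested r².

    Solves D = sqrt(r² · pA·qA·pB·qB) with positive D; raises if the target
    is unattainable for the given allele frequencies.
    """
    if not (0.0 <= r2 <= 1.0):
        raise ValueError("r2 must be in [0, 1]")
    d = math.sqrt(r2 * p_a * (1 - p_a) * p_b * (1 - p_b))
    freqs = np.array(
        [
            p_a * p_b + d,
            p_a * (1 - p_b) - d,
            (1 - p_a) * p_b - d,
            (1 - p_a) * (1 - p_b) + d,
        ]
    )
    if np.any(freqs < -1e-12):
        raise ValueError(f"r²={r2} unattainable at AFs ({p_a}, {p_b})")
    return np.clip(freqs, 0.0, 1.0)


def plant_ld_pair(
    haplotype_freqs, n_samples: int, rng: np.random.Generator | int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw genotype dosages at two loci from given haplotype frequencies.

    Each individual receives two independent haplotypes from the categories
    (AB, Ab, aB, ab); dosages are the per-locus alternate-allele counts. The
    expected r² equals D²/(pA·qA·pB·qB) computed from the input frequencies.
    """
    freqs = np.asarray(haplotype_freqs, dtype=float)
    if freqs.shape != (4,) or np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
        raise SimulationError("haplotype_freqs must be a 4-simplex vector")
    p_a = freqs[0] + freqs[1]
    p_b = freqs[0] + freqs[2]
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise SimulationError("degenerate (monomorphic) haplotype frequencies")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    haps = rng.choice(4, size=(n_samples, 2), p=freqs)
    has_a = np.isin(haps, (0, 1))
    has_b = np.isin(haps, (0, 2))
    return has_a.sum(axis=1).astype(np.int8), has_b.sum(axis=1).astype(np.int8)


def _round_down(x: float) -> float:
    return math.floor(x * 10.0) / 10.0


class _Simulator:
    def __init__(self, config: SimulationConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.truth_rows: list[dict] = []
        self.annotation_rows: list[dict] = []
        self.index_rows: list[dict] = []
        self._pos_counters: dict[str, int] = {}

    # ---- helpers -------------------------------------------------------

    def _next_pos(self, gene: str, anchor: int) -> int:
        c = self._pos_counters.get(gene, 0)
        self._pos_counters[gene] = c + 1
        return anchor + 1000 + 137 * c

    def _draw_onset(self) -> float:
        cfg = self.cfg
        return _round_down(
            float(np.clip(self.rng.normal(cfg.onset_mean, cfg.onset_sd), 45.0, 105.0))
        )

    def _draw_unaffected_age(self) -> float:
        cfg = self.cfg
        return _round_down(
            float(
                np.clip(
                    self.rng.normal(cfg.unaffected_age_mean, cfg.unaffected_age_sd),
                    40.0,
                    100.0,
                )
            )
        )

    def _qualifying_age(self, reference_onset: float) -> float:
        """An unaffected age at or below reference − buffer (grid of 0.1y).

        The small epsilon and the correction loop guard against the 0.1-grid
        rounding landing a hair above the buffer boundary in float
        arithmetic; the planted age must satisfy the classifier's inclusive
        comparison exactly as stored.
        """
        buffer = self.cfg.buffer_years
        slack = float(self.rng.choice([0.0, 0.5, 1.5, 3.0, 6.0]))
        age = _round_down(reference_onset - buffer - 1e-9) - slack
        while reference_onset - age < buffer:
            age -= 0.1
        return max(40.0, age)

    @staticmethod
    def _set_age(members: list[IndividualRecord], individual_id: str, age: float) -> None:
        for i, m in enumerate(members):
            if m.individual_id == individual_id:
                members[i] = IndividualRecord(
                    family_id=m.family_id,
                    individual_id=m.individual_id,
                    father_id=m.father_id,
                    mother_id=m.mother_id,
                    sex=m.sex,
                    affection=m.affection,
                    age_years=age,
                )
                return
        raise KeyError(individual_id)

    def _non_qualifying_age(self, reference_onset: float) -> float:
        gap = float(self.rng.uniform(0.2, self.cfg.buffer_years - 0.2))
        return min(100.0, math.ceil((reference_onset - gap) * 10.0) / 10.0)

    # ---- family construction ------------------------------------------

    def _make_family(self, cohort_tag: str, idx: int, label: str):
        cfg = self.cfg
        fid = f"{cohort_tag}F{idx:04d}"
        size = int(self.rng.integers(cfg.family_size_min, cfg.family_size_max + 1))
        n_aff = int(
            self.rng.integers(cfg.n_affected_min, min(cfg.n_affected_max, size - 1) + 1)
        )
        members: list[IndividualRecord] = []
        onsets = [self._draw_onset() for _ in range(n_aff)]
        mean_onset = sum(onsets) / len(onsets)
        father = f"{fid}_01"
        mother = f"{fid}_02"
        for i in range(size):
            iid = f"{fid}_{i + 1:02d}"
            affected = i < n_aff
            members.append(
                IndividualRecord(
                    family_id=fid,
                    individual_id=iid,
                    father_id="0" if i < 2 else father,
                    mother_id="0" if i < 2 else mother,
                    sex=Sex.MALE if i % 2 == 0 else Sex.FEMALE,
                    affection=Affection.AFFECTED if affected else Affection.UNAFFECTED,
                    age_years=onsets[i] if affected else self._draw_unaffected_age(),
                )
            )
        return fid, members, mean_onset

    # ---- main ----------------------------------------------------------

    def run(self) -> SimulatedStudy:
        cfg = self.cfg
        cohorts: dict[str, FamilyCohort] = {}
        all_sites: dict[str, pd.DataFrame] = {}
        all_dos: dict[str, dict[str, np.ndarray]] = {}
        all_dp: dict[str, dict[str, np.ndarray]] = {}
        all_gq: dict[str, dict[str, np.ndarray]] = {}
        all_samples: dict[str, list[str]] = {}

        # index SNPs are shared locus-level metadata, emitted once
        for gene, chrom, anchor in DEFAULT_LOCI:
            self.index_rows.append(
                {
                    "locus_gene": gene,
                    "chrom": chrom,
                    "pos": anchor - 2000,
                    "ref": "T",
                    "alt": "C",
                }
            )
            self.annotation_rows.append(
                {
                    "chrom": chrom,
                    "pos": anchor - 2000,
                    "ref": "T",
                    "alt": "C",
                    "gene": gene,
                    "consequence": "intron_variant",
                    "cadd_phred": "",
                    "gnomad_af": cfg.index_snp_af,
                }
            )
        for (chrom, pos, ref, alt), af, name in (
            (APOE_RS429358_GRCH38, cfg.apoe_e4_background_af, "rs429358"),
            (APOE_RS7412_GRCH38, cfg.apoe_e2_background_af, "rs7412"),
        ):
            self.annotation_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": "APOE",
                    "consequence": "missense_variant",
                    "cadd_phred": 15.0,
                    "gnomad_af": af,
                }
            )

        for cohort_idx, cid in enumerate(cfg.cohort_ids):
            data = self._simulate_cohort(cid, cohort_idx)
            cohorts[cid] = data["cohort"]
            all_sites[cid] = data["sites"]
            all_dos[cid] = data["dosages"]
            all_dp[cid] = data["dp"]
            all_gq[cid] = data["gq"]
            all_samples[cid] = data["samples"]

        regions = self._make_regions()
        annotations = (
            pd.DataFrame(
                self.annotation_rows,
                columns=[
                    "chrom", "pos", "ref", "alt", "gene", "consequence",
                    "cadd_phred", "gnomad_af",
                ],
            )
            .drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
            .reset_index(drop=True)
        )
        truth = pd.DataFrame(
            self.truth_rows,
            columns=[
                "record_type", "cohort", "family_id", "variant_key",
                "planted_status", "planted_family_label",
            ],
        )
        study = SimulatedStudy(
            config=cfg,
            cohorts=cohorts,
            sites=all_sites,
            dosages=all_dos,
            dp=all_dp,
            gq=all_gq,
            samples=all_samples,
            annotations=annotations,
            index_snps=pd.DataFrame(
                self.index_rows, columns=["locus_gene", "chrom", "pos", "ref", "alt"]
            ),
            truth=truth,
            regions=regions,
        )
        return study

    def _make_regions(self) -> pd.DataFrame:
        rows = []
        for gene, chrom, anchor in DEFAULT_LOCI:
            rows.append({"chrom": chrom, "start": anchor - 3000, "end": anchor + 120000})
        apoe_chrom, apoe_pos, _, _ = APOE_RS429358_GRCH38
        rows.append({"chrom": apoe_chrom, "start": apoe_pos - 1500, "end": apoe_pos + 1500})
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def _simulate_cohort(self, cid: str, cohort_idx: int) -> dict:
        cfg = self.cfg
        rng = self.rng
        tag = f"C{cohort_idx}"
        labels = rng.choice(
            ["RARE_EXPLAINED", "APOE_ONLY", "UNEXPLAINED"],
            size=cfg.n_families,
            p=[
                cfg.fraction_rare_explained,
                cfg.fraction_apoe_only,
                cfg.fraction_unexplained,
            ],
        )

        families: dict[str, list[IndividualRecord]] = {}
        family_meta: dict[str, dict] = {}
        samples: list[str] = []
        for i in range(cfg.n_families):
            fid, members, mean_onset = self._make_family(tag, i, labels[i])
            families[fid] = members
            family_meta[fid] = {"label": labels[i], "mean_onset": mean_onset}
            samples.extend(m.individual_id for m in members)
        cohort = FamilyCohort(cohort_id=cid, families=families)
        sample_index = {s: j for j, s in enumerate(samples)}
        n = len(samples)

        sites: list[dict] = []
        dosages: dict[str, np.ndarray] = {}

        def add_site(chrom, pos, ref, alt, dosage, *, gene, consequence, cadd, af):
            key = f"{chrom}:{pos}:{ref}:{alt}"
            sites.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
            dosages[key] = dosage
            self.annotation_rows.append(
                {
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "gene": gene, "consequence": consequence,
                    "cadd_phred": cadd, "gnomad_af": af,
                }
            )
            return key

        def fam_dosage_map(fid, key):
            return {
                m.individual_id: int(dosages[key][sample_index[m.individual_id]])
                for m in families[fid]
            }

        # ---- APOE genotypes for every sample ---------------------------
        apoe4 = np.zeros(n, dtype=np.int8)  # rs429358 alt (C) dosage
        apoe2_base = (
            rng.random(n) < cfg.apoe_e2_background_af
        ).astype(np.int8)  # rs7412 sprinkle; never changes e4 carrier status

        # ---- per-family planting ---------------------------------------
        lof_cycle = 0
        refs = "ACGT"
        for i, (fid, members) in enumerate(families.items()):
            meta = family_meta[fid]
            label = meta["label"]
            mean_onset = meta["mean_onset"]
            affected = [m for m in members if m.affection is Affection.AFFECTED]
            unaffected = [m for m in members if m.affection is Affection.UNAFFECTED]

            apoe_seg = label == "APOE_ONLY" or (
                label == "RARE_EXPLAINED"
                and rng.random() < cfg.p_apoe_coseg_in_rare_family
            )
            meta["apoe_seg"] = apoe_seg
            if apoe_seg:
                for m in affected:
                    apoe4[sample_index[m.individual_id]] = int(
                        rng.choice([1, 1, 2])
                    )
                # unaffected: mostly non-carriers; carriers get qualifying ages
                for m in unaffected:
                    if rng.random() < 0.35:
                        apoe4[sample_index[m.individual_id]] = 1
                        self._set_age(
                            families[fid], m.individual_id,
                            self._qualifying_age(mean_onset),
                        )
            else:
                # ensure e4 does NOT segregate: ≥1 affected non-carrier
                carriers = rng.random(len(affected)) < cfg.apoe_e4_background_af
                carriers[int(rng.integers(len(affected)))] = False
                for m, c in zip(affected, carriers):
                    apoe4[sample_index[m.individual_id]] = int(c)
                # unaffected e4 carriers are harmless here (no segregation)
                for m in unaffected:
                    if rng.random() < cfg.apoe_e4_background_af:
                        apoe4[sample_index[m.individual_id]] = 1

            if label == "RARE_EXPLAINED":
                gene, chrom, anchor = DEFAULT_LOCI[
                    int(rng.integers(len(DEFAULT_LOCI)))
                ]
                pos = self._next_pos(gene, anchor)
                if rng.random() < 0.3:
                    consequence = _LOF_CLASSES[lof_cycle % len(_LOF_CLASSES)].value
                    lof_cycle += 1
                    cadd = ""
                else:
                    consequence = "missense_variant"
                    cadd = round(float(rng.uniform(20.5, 45.0)), 1)
                ref = refs[int(rng.integers(4))]
                alt = refs[(refs.index(ref) + 1 + int(rng.integers(3))) % 4]
                if consequence == "frameshift":
                    alt = ref + "A"
                dosage = np.zeros(n, dtype=np.int8)
                for m in affected:
                    dosage[sample_index[m.individual_id]] = 1
                # optionally one qualifying unaffected carrier
                unaffected_now = [
                    m for m in families[fid]
                    if m.affection is Affection.UNAFFECTED
                ]
                if unaffected_now and (
                    rng.random() < cfg.p_unaffected_qualifying_carrier
                ):
                    m = unaffected_now[int(rng.integers(len(unaffected_now)))]
                    dosage[sample_index[m.individual_id]] = 1
                    self._set_age(
                        families[fid], m.individual_id,
                        self._qualifying_age(mean_onset),
                    )
                key = add_site(
                    chrom, pos, ref, alt, dosage,
                    gene=gene, consequence=consequence, cadd=cadd,
                    af=round(float(rng.uniform(1e-4, 5e-3)), 6),
                )
                meta["rare_key"] = key
                meta["rare_gene"] = gene
                self.truth_rows.append(
                    {
                        "record_type": "variant_family",
                        "cohort": cid,
                        "family_id": fid,
                        "variant_key": key,
                        "planted_status": "COMPLETE",
                        "planted_family_label": "",
                    }
                )
            elif label in ("APOE_ONLY", "UNEXPLAINED") and (
                rng.random() < cfg.p_decoy_in_family and len(affected) >= 2
            ):
                # decoy rare damaging variant that does NOT segregate:
                # carried by exactly one affected member
                gene, chrom, anchor = DEFAULT_LOCI[
                    int(rng.integers(len(DEFAULT_LOCI)))
                ]
                pos = self._next_pos(gene, anchor)
                ref = refs[int(rng.integers(4))]
                alt = refs[(refs.index(ref) + 1 + int(rng.integers(3))) % 4]
                dosage = np.zeros(n, dtype=np.int8)
                dosage[sample_index[affected[0].individual_id]] = 1
                key = add_site(
                    chrom, pos, ref, alt, dosage,
                    gene=gene, consequence="missense_variant",
                    cadd=round(float(rng.uniform(21.0, 40.0)), 1),
                    af=round(float(rng.uniform(1e-4, 5e-3)), 6),
                )
                self.truth_rows.append(
                    {
                        "record_type": "variant_family",
                        "cohort": cid,
                        "family_id": fid,
                        "variant_key": key,
                        "planted_status": "NONE",
                        "planted_family_label": "",
                    }
                )

            self.truth_rows.append(
                {
                    "record_type": "family",
                    "cohort": cid,
                    "family_id": fid,
                    "variant_key": "",
                    "planted_status": "",
                    "planted_family_label": label,
                }
            )

        # ---- APOE sites -------------------------------------------------
        c4_chrom, c4_pos, c4_ref, c4_alt = APOE_RS429358_GRCH38
        c2_chrom, c2_pos, c2_ref, c2_alt = APOE_RS7412_GRCH38
        # avoid implying e1: no rs7412 alt where rs429358 is homozygous alt
        apoe2 = np.where(apoe4 == 2, 0, apoe2_base).astype(np.int8)
        key4 = f"{c4_chrom}:{c4_pos}:{c4_ref}:{c4_alt}"
        sites.append({"chrom": c4_chrom, "pos": c4_pos, "ref": c4_ref, "alt": c4_alt})
        dosages[key4] = apoe4
        key2 = f"{c2_chrom}:{c2_pos}:{c2_ref}:{c2_alt}"
        sites.append({"chrom": c2_chrom, "pos": c2_pos, "ref": c2_ref, "alt": c2_alt})
        dosages[key2] = apoe2

        # ---- cohort-wide incomplete-segregation variant -----------------
        if cfg.n_families >= max(3, cfg.incomplete_affected_carriers):
            self._plant_incomplete(
                cid, families, family_meta, sample_index, n, add_site
            )

        # ---- index SNPs: HWE background + planted co-segregation --------
        for row in self.index_rows:
            gene = row["locus_gene"]
            key = f"{row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}"
            p = cfg.index_snp_af
            dosage = rng.binomial(2, p, size=n).astype(np.int8)
            for fid, meta in family_meta.items():
                if meta.get("rare_gene") == gene and (
                    rng.random() < cfg.p_index_coseg_in_rare_family
                ):
                    # index SNP mirrors the rare variant in this family
                    rare = dosages[meta["rare_key"]]
                    for m in families[fid]:
                        j = sample_index[m.individual_id]
                        dosage[j] = rare[j]
            sites.append(
                {"chrom": row["chrom"], "pos": row["pos"],
                 "ref": row["ref"], "alt": row["alt"]}
            )
            dosages[key] = dosage

        # ---- decoys exercising the QC / rarity / CADD filters -----------
        self._plant_filter_decoys(n, add_site)

        # ---- self-check planted patterns (pre-noise) --------------------
        from .apoe import apoe_e4_segregation, call_apoe_diplotype

        for fid, meta in family_meta.items():
            dips = {
                m.individual_id: call_apoe_diplotype(
                    int(apoe4[sample_index[m.individual_id]]),
                    int(apoe2[sample_index[m.individual_id]]),
                )
                for m in families[fid]
            }
            call = apoe_e4_segregation(
                families[fid], dips, buffer=cfg.buffer_years
            )
            if (call.status is SegregationStatus.COMPLETE) != meta["apoe_seg"]:
                raise SimulationError(
                    f"self-check failed: APOE e4 in {fid} classified "
                    f"{call.status.value}, planted "
                    f"{'COMPLETE' if meta['apoe_seg'] else 'NONE'}"
                )
        for row in self.truth_rows:
            if row["cohort"] != cid or row["record_type"] != "variant_family":
                continue
            fid, key = row["family_id"], row["variant_key"]
            call = classify_family_segregation(
                families[fid], fam_dosage_map(fid, key), key,
                buffer=cfg.buffer_years,
            )
            expected = SegregationStatus(row["planted_status"])
            if call.status is not expected:
                raise SimulationError(
                    f"self-check failed: {key} in {fid} classified "
                    f"{call.status.value}, planted {expected.value}"
                )

        # ---- assemble DP/GQ and inject QC noise --------------------------
        dp: dict[str, np.ndarray] = {}
        gq: dict[str, np.ndarray] = {}
        for key, dosage in dosages.items():
            dp[key] = rng.integers(20, 60, size=n).astype(np.int32)
            gq[key] = np.minimum(
                99, rng.integers(60, 100, size=n)
            ).astype(np.int32)
            if cfg.qc_noise_dp > 0:
                hit = rng.random(n) < cfg.qc_noise_dp
                dp[key][hit] = rng.integers(0, 10, size=int(hit.sum()))
            if cfg.qc_noise_gq > 0:
                hit = rng.random(n) < cfg.qc_noise_gq
                gq[key][hit] = rng.integers(0, 20, size=int(hit.sum()))
            if cfg.qc_noise_missing > 0:
                hit = rng.random(n) < cfg.qc_noise_missing
                dosage = dosage.copy()
                dosage[hit] = MISSING
                dosages[key] = dosage

        sites_df = (
            pd.DataFrame(sites, columns=["chrom", "pos", "ref", "alt"])
            .sort_values(["chrom", "pos", "alt"], kind="mergesort")
            .reset_index(drop=True)
        )
        return {
            "cohort": cohort,
            "sites": sites_df,
            "dosages": dosages,
            "dp": dp,
            "gq": gq,
            "samples": samples,
        }

    def _plant_incomplete(
        self, cid, families, family_meta, sample_index, n, add_site
    ) -> None:
        """One cohort-level incomplete-segregation variant.

        One affected carrier in each of k distinct families (never two in one
        family, so no family can reach the ≥2-carrier complete floor), plus
        qualifying unaffected carriers, keeping affected > unaffected.
        """
        cfg = self.cfg
        rng = self.rng
        gene, chrom, anchor = DEFAULT_LOCI[int(rng.integers(len(DEFAULT_LOCI)))]
        pos = self._next_pos(gene, anchor)
        dosage = np.zeros(n, dtype=np.int8)
        fids = list(families)
        chosen = rng.choice(
            len(fids), size=cfg.incomplete_affected_carriers, replace=False
        )
        first_fid = None
        for c in chosen:
            fid = fids[int(c)]
            affected = [
                m for m in families[fid] if m.affection is Affection.AFFECTED
            ]
            carrier = affected[int(rng.integers(len(affected)))]
            dosage[sample_index[carrier.individual_id]] = 1
            if first_fid is None:
                first_fid = fid
        # qualifying unaffected carriers in the first chosen family
        placed = 0
        for m in list(families[first_fid]):
            if placed >= cfg.incomplete_unaffected_carriers:
                break
            if m.affection is not Affection.UNAFFECTED:
                continue
            carrier_onsets = [
                x.age_years
                for x in families[first_fid]
                if x.affection is Affection.AFFECTED
                and dosage[sample_index[x.individual_id]] >= 1
            ]
            all_onsets = [
                x.age_years
                for x in families[first_fid]
                if x.affection is Affection.AFFECTED
            ]
            # qualify against both the variant-carrier onset and the family
            # mean, so lowering this member's age cannot break any other
            # planted pattern it participates in
            ref_onset = min(
                sum(carrier_onsets) / len(carrier_onsets),
                sum(all_onsets) / len(all_onsets),
            )
            dosage[sample_index[m.individual_id]] = 1
            self._set_age(
                families[first_fid], m.individual_id,
                self._qualifying_age(ref_onset),
            )
            placed += 1
        key = add_site(
            chrom, pos, "G", "T", dosage,
            gene=gene, consequence="stop_gained", cadd="",
            af=round(float(rng.uniform(1e-4, 5e-3)), 6),
        )
        self.truth_rows.append(
            {
                "record_type": "variant_cohort",
                "cohort": cid,
                "family_id": "",
                "variant_key": key,
                "planted_status": "INCOMPLETE",
                "planted_family_label": "",
            }
        )

    def _plant_filter_decoys(self, n, add_site) -> None:
        """Sites that must be removed by rarity/CADD/consequence filters."""
        rng = self.rng
        gene, chrom, anchor = DEFAULT_LOCI[0]
        # common damaging-looking variant: removed by the rarity filter
        add_site(
            chrom, self._next_pos(gene, anchor), "C", "T",
            rng.binomial(2, 0.1, size=n).astype(np.int8),
            gene=gene, consequence="missense_variant", cadd=30.0, af=0.05,
        )
        # rare low-CADD missense: removed by the CADD>20 prioritization
        add_site(
            chrom, self._next_pos(gene, anchor), "A", "G",
            rng.binomial(2, 0.002, size=n).astype(np.int8),
            gene=gene, consequence="missense_variant", cadd=9.5, af=0.002,
        )
        # rare synonymous: removed by consequence classification
        add_site(
            chrom, self._next_pos(gene, anchor), "G", "A",
            rng.binomial(2, 0.002, size=n).astype(np.int8),
            gene=gene, consequence="synonymous_variant", cadd=2.0, af=0.003,
        )


def simulate_cohorts(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedStudy:
    """Generate the synthetic two-cohort study; optionally write the files.

    Deterministic: identical configs (including seed) produce identical
    in-memory structures and byte-identical files.
    """
    study = _Simulator(config).run()
    if out_dir is not None:
        study.write(out_dir)
    return study
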