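"""VCF ingest, genotype masking, site missingness and rarity filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famseg.variants import (
    MISSING,
    GenotypeMatrix,
    VariantSite,
    drop_high_missingness_sites,
    filter_rare,
    mask_low_quality_genotypes,
    read_bed_regions,
    read_vcf_region,
)

from .conftest import brute_force_mask_count

VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##contig=<ID=chr1>
##contig=<ID=chr2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\t.\tA\tC,T\t.\tPASS\t.\tGT:DP:GQ\t1/2:30:99\t0/1:9:99\t0/0:30:99
chr1\t500\t.\tG\tA\t.\tLowQual\t.\tGT:DP:GQ\t0/1:30:19\t1/1:10:20\t./.:.:.
chr2\t100\t.\tT\tG\t.\tPASS\t.\tGT:DP:GQ\t0/0:30:99\t0/1:30:99\t0/1:30:99
chr2\t900\t.\tC\tA\t.\tPASS\t.\tGT:DP:GQ\t0/1:30:99\t0/0:30:99\t0/0:30:99
"""

BED_TEXT = "chr1\t0\t600\nchr2\t0\t200\n"


@pytest.fixture()
def vcf_and_bed(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(VCF_TEXT)
    bed = tmp_path / "toy.bed"
    bed.write_text(BED_TEXT)
    return vcf, bed


def test_region_restriction_and_multiallelic_split(vcf_and_bed):
    vcf, bed = vcf_and_bed
    sites, matrix = read_vcf_region(vcf, bed)
    # chr2:900 is outside the BED; the chr1:100 record splits into two sites
    keys = [s.key for s in sites]
    assert keys == [
        "chr1:100:A:C", "chr1:100:A:T", "chr1:500:G:A", "chr2:100:T:G"
    ]
    # S1 is 1/2: one copy of each split alternate
    assert matrix.dosage[0].tolist() == [1, 1, 0]
    assert matrix.dosage[1].tolist() == [1, 0, 0]
    # FILTER passes through
    assert sites[2].filter_status == "LowQual"
    # missing genotype is missing on every split allele
    assert matrix.dosage[2].tolist() == [1, 2, MISSING]


def test_masking_boundaries_keep_dp10_gq20(vcf_and_bed):
    vcf, bed = vcf_and_bed
    sites, matrix = read_vcf_region(vcf, bed)
    masked = mask_low_quality_genotypes(matrix, min_dp=10, min_gq=20)
    # chr1:100 S2 has DP=9 -> masked despite GQ=99
    assert masked.dosage[0].tolist() == [1, MISSING, 0]
    # chr1:500 S1 has GQ=19 -> masked; S2 DP=10,GQ=20 is a kept boundary
    assert masked.dosage[2].tolist() == [MISSING, 2, MISSING]
    # untouched good calls
    assert masked.dosage[3].tolist() == [0, 1, 1]


def test_missingness_filter_is_strictly_greater_than():
    samples = [f"S{i}" for i in range(100)]
    dosage = np.zeros((3, 100), dtype=np.int8)
    dosage[0, :3] = MISSING  # 3% -> dropped
    dosage[1, :2] = MISSING  # exactly 2% -> kept
    dp = np.full((3, 100), 30, dtype=np.int32)
    gq = np.full((3, 100), 99, dtype=np.int32)
    sites = [
        VariantSite("chr1", p, "A", "C") for p in (1, 2, 3)
    ]
    matrix = GenotypeMatrix(samples, dosage, dp, gq)
    kept, kept_m = drop_high_missingness_sites(sites, matrix, 0.02)
    assert [s.pos for s in kept] == [2, 3]
    assert kept_m.n_sites == 2


def test_rarity_filter_boundaries_and_absent_af():
    sites = [
        VariantSite("chr1", 1, "A", "C", gnomad_af=0.009),
        VariantSite("chr1", 2, "A", "C", gnomad_af=0.01),
        VariantSite("chr1", 3, "A", "C", gnomad_af=None),
    ]
    kept = filter_rare(sites, 0.01)
    assert [s.pos for s in kept] == [1, 3]
    flagged = [s for s in kept if s.pos == 3][0]
    assert flagged.af_absent


def test_masked_count_matches_brute_force_on_planted_values():
    rng = np.random.default_rng(5)
    n_sites, n_samples = 12, 40
    dosage = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    dosage[rng.random((n_sites, n_samples)) < 0.05] = MISSING
    dp = rng.integers(0, 40, size=(n_sites, n_samples)).astype(np.int32)
    gq = rng.integers(0, 100, size=(n_sites, n_samples)).astype(np.int32)
    dp[rng.random((n_sites, n_samples)) < 0.1] = -1  # absent field
    matrix = GenotypeMatrix([f"S{j}" for j in range(n_samples)], dosage, dp, gq)
    masked = mask_low_quality_genotypes(matrix, 10, 20)
    got = int(((masked.dosage == MISSING) & (dosage != MISSING)).sum())
    want = brute_force_mask_count(dp.tolist(), gq.tolist(), dosage.tolist())
    assert got == want


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    min_dp=st.integers(0, 40),
    min_gq=st.integers(0, 100),
    seed=st.integers(0, 10_000),
)
def test_surviving_genotypes_monotone_in_thresholds(min_dp, min_gq, seed):
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, size=(5, 20)).astype(np.int8)
    dp = rng.integers(0, 50, size=(5, 20)).astype(np.int32)
    gq = rng.integers(0, 100, size=(5, 20)).astype(np.int32)
    matrix = GenotypeMatrix([f"S{j}" for j in range(20)], dosage, dp, gq)

    def surviving(d, g):
        return int(
            (mask_low_quality_genotypes(matrix, d, g).dosage != MISSING).sum()
        )

    assert surviving(min_dp + 1, min_gq) <= surviving(min_dp, min_gq)
    assert surviving(min_dp, min_gq + 1) <= surviving(min_dp, min_gq)


def test_masking_commutes_with_sample_reordering():
    rng = np.random.default_rng(9)
    dosage = rng.integers(0, 3, size=(4, 10)).astype(np.int8)
    dp = rng.integers(0, 40, size=(4, 10)).astype(np.int32)
    gq = rng.integers(0, 100, size=(4, 10)).astype(np.int32)
    samples = [f"S{j}" for j in range(10)]
    matrix = GenotypeMatrix(samples, dosage, dp, gq)
    perm = rng.permutation(10)
    permuted = GenotypeMatrix(
        [samples[j] for j in perm], dosage[:, perm], dp[:, perm], gq[:, perm]
    )
    a = mask_low_quality_genotypes(matrix).dosage[:, perm]
    b = mask_low_quality_genotypes(permuted).dosage
    assert np.array_equal(a, b)
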