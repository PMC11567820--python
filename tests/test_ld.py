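"""LD estimators: dosage correlation, two-locus EM, and planted-frequency
recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famseg.ld import (
    LDUndefinedError,
    em_haplotype_frequencies,
    em_haplotype_r2,
    genotype_r2,
    index_carrier_count,
    cosegregates_with_index,
    r2_from_haplotype_freqs,
)
from famseg.segregation import SegregationCall, SegregationStatus
from famseg.simulate import haplotype_freqs_for_r2, plant_ld_pair
from famseg.variants import MISSING

from .conftest import make_member


class TestGenotypeR2:
    def test_self_correlation_is_one(self):
        a = [0, 1, 2, 0, 1]
        assert genotype_r2(a, a).r2 == pytest.approx(1.0)

    def test_perfect_anticorrelation_squares_to_one(self):
        assert genotype_r2([0, 0, 1, 1], [1, 1, 0, 0]).r2 == pytest.approx(1.0)

    def test_matches_direct_pearson_oracle(self):
        # by hand: a=(0,1,2,0,1), b=(0,1,1,0,2), means 0.8/0.8,
        # Σ ca·cb = 1.8, Σ ca² = Σ cb² = 2.8, r = 9/14, r² = 81/196
        a = np.array([0, 1, 2, 0, 1], dtype=float)
        b = np.array([0, 1, 1, 0, 2], dtype=float)
        ca, cb = a - a.mean(), b - b.mean()
        r = (ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum())
        assert genotype_r2(a, b).r2 == pytest.approx(r * r, abs=1e-15)
        assert genotype_r2(a, b).r2 == pytest.approx(81.0 / 196.0, abs=1e-12)

    def test_pairwise_complete_handling(self):
        a = [0, 1, 2, MISSING, 1, 0]
        b = [0, 1, 2, 1, MISSING, 0]
        res = genotype_r2(a, b)
        assert res.n_samples == 4
        assert res.r2 == pytest.approx(1.0)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(LDUndefinedError):
            genotype_r2([1, 1, 1, 1], [0, 1, 2, 0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_allele_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, size=30)
        b = rng.integers(0, 3, size=30)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return
        r_ab = genotype_r2(a, b).r2
        assert genotype_r2(b, a).r2 == pytest.approx(r_ab, abs=1e-12)
        # swapping ref/alt labels means dosage -> 2 - dosage
        assert genotype_r2(2 - a, b).r2 == pytest.approx(r_ab, abs=1e-12)
        assert genotype_r2(a, 2 - b).r2 == pytest.approx(r_ab, abs=1e-12)


class TestEMHaplotypeR2:
    def test_em_equals_direct_counting_without_double_hets(self):
        # genotypes built from known haplotypes, no (1,1) cell
        a = [0, 0, 2, 2, 0, 2, 0, 1]
        b = [0, 0, 2, 2, 0, 2, 1, 0]
        freqs, _ = em_haplotype_frequencies(a, b)
        # count haplotypes directly: each individual is two haplotypes
        # with known phase (no double het)
        direct = np.zeros(4)
        for da, db in zip(a, b):
            n_ab = min(da, db)
            direct += [n_ab, da - n_ab, db - n_ab, 2 - da - db + n_ab]
        direct /= direct.sum()
        assert np.allclose(freqs, direct, atol=1e-10)

    def test_two_haplotype_system_gives_r2_one(self):
        a = [0, 0, 2, 2, 0, 2]
        b = [0, 0, 2, 2, 0, 2]
        assert em_haplotype_r2(a, b).r2 == pytest.approx(1.0, abs=1e-9)

    def test_frequencies_form_a_simplex(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 3, 200)
        freqs, _ = em_haplotype_frequencies(a, b)
        assert np.all(freqs >= 0)
        assert freqs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_recovers_planted_r2_within_sampling_error(self):
        target = 0.5
        freqs = haplotype_freqs_for_r2(target, 0.3, 0.3)
        assert r2_from_haplotype_freqs(freqs) == pytest.approx(target)
        n = 10_000
        a, b = plant_ld_pair(freqs, n, rng=42)
        est = em_haplotype_r2(a, b).r2
        # r2-hat is asymptotically normal; 3 SE with SE ~ sqrt(var/n)
        se = np.sqrt(2.0 / n) * (1 - target) * 2  # conservative bound
        assert abs(est - target) < max(3 * se, 0.05)

    def test_agrees_with_dosage_r2_on_phased_equivalent_data(self):
        # phased-equivalent diplotypes (each individual carries two copies
        # of one haplotype): no heterozygote exists, both estimators reduce
        # to the same haplotype-frequency computation and agree exactly
        freqs = haplotype_freqs_for_r2(0.4, 0.4, 0.4)
        rng = np.random.default_rng(7)
        haps = rng.choice(4, size=10_000, p=freqs)
        a = (2 * np.isin(haps, (0, 1))).astype(np.int8)
        b = (2 * np.isin(haps, (0, 2))).astype(np.int8)
        r2_dosage = genotype_r2(a, b).r2
        r2_em = em_haplotype_r2(a, b).r2
        assert abs(r2_dosage - r2_em) < 1e-6


class TestPlantLdPair:
    def test_two_haplotype_system_expected_r2_one(self):
        a, b = plant_ld_pair([0.5, 0.0, 0.0, 0.5], 2000, rng=1)
        assert genotype_r2(a, b).r2 == pytest.approx(1.0, abs=0.02)

    def test_independent_haplotypes_give_near_zero_r2(self):
        a, b = plant_ld_pair([0.25, 0.25, 0.25, 0.25], 20_000, rng=2)
        assert genotype_r2(a, b).r2 < 0.005

    def test_degenerate_frequencies_rejected(self):
        from famseg.simulate import SimulationError

        with pytest.raises(SimulationError):
            plant_ld_pair([1.0, 0.0, 0.0, 0.0], 100, rng=0)


class TestIndexSnp:
    def _family(self):
        return [
            make_member("F", "I0", "affected", 74.0),
            make_member("F", "I1", "affected", 76.0),
            make_member("F", "I2", "unaffected", 65.0),
            make_member("F", "I3", "unaffected", 73.0),
            make_member("F", "I4", "unaffected", 60.0),
        ]

    def test_carrier_count_any_affection(self):
        members = self._family()
        assert index_carrier_count(
            members, {"I0": 1, "I1": 2, "I2": 0, "I3": 1, "I4": 0}
        ) == 3
        assert index_carrier_count(members, {m.individual_id: 0 for m in members}) == 0
        assert index_carrier_count(
            members, {m.individual_id: MISSING for m in members}
        ) == 0

    def test_index_cosegregation_applies_the_complete_rule(self):
        members = self._family()
        complete = SegregationCall(
            "v", "F", SegregationStatus.COMPLETE, 2, 2, 0, 0
        )
        # index carried by both affected, no unaffected carriers -> True
        assert cosegregates_with_index(
            complete, members, {"I0": 1, "I1": 1, "I2": 0, "I3": 0, "I4": 0}
        )
        # absent from one affected -> False
        assert not cosegregates_with_index(
            complete, members, {"I0": 1, "I1": 0, "I2": 0, "I3": 0, "I4": 0}
        )
        with pytest.raises(ValueError):
            cosegregates_with_index(
                SegregationCall("v", "F", SegregationStatus.NONE, 1, 2, 0, 0),
                members,
                {"I0": 1, "I1": 1, "I2": 0, "I3": 0, "I4": 0},
            )
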