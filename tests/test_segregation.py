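"""The segregation classifier against spec'd cases and a brute-force oracle."""

import itertools

import numpy as np
import pytest

from famseg.segregation import (
    ExplanationLabel,
    SegregationCall,
    SegregationStatus,
    classify_cohort_incomplete,
    classify_family_explanation,
    classify_family_segregation,
    cross_family_consistency,
    unaffected_qualifies,
)

from .conftest import MISSING, brute_force_segregation, make_member


def _family(spec):
    """spec: list of (affection, age, dosage) -> (members, dosages)."""
    members, dosages = [], {}
    for i, (affection, age, dosage) in enumerate(spec):
        iid = f"I{i}"
        members.append(make_member("FAM", iid, affection, age))
        dosages[iid] = dosage
    return members, dosages


class TestAgeBuffer:
    def test_inclusive_boundary(self):
        assert unaffected_qualifies(69.0, 75.0)          # 6 >= 5
        assert not unaffected_qualifies(71.0, 75.0)      # 4 < 5
        assert unaffected_qualifies(70.0, 75.0)          # exactly 5 qualifies

    def test_missing_ages_do_not_qualify(self):
        assert not unaffected_qualifies(None, 75.0)
        assert not unaffected_qualifies(70.0, None)


class TestFamilyClassification:
    def test_all_affected_carry_no_unaffected_carriers(self):
        members, dosages = _family(
            [("affected", 74.0, 1), ("affected", 78.0, 1),
             ("affected", 70.0, 1), ("unaffected", 68.0, 0)]
        )
        call = classify_family_segregation(members, dosages, "v")
        assert call.status is SegregationStatus.COMPLETE
        assert call.n_affected_carriers == 3
        assert call.n_unaffected_carriers == 0

    def test_one_affected_noncarrier_breaks_segregation(self):
        members, dosages = _family(
            [("affected", 74.0, 1), ("affected", 78.0, 1),
             ("affected", 70.0, 0), ("unaffected", 60.0, 0)]
        )
        call = classify_family_segregation(members, dosages, "v")
        assert call.status is SegregationStatus.NONE

    def test_unaffected_carrier_inside_buffer_breaks_segregation(self):
        # carrier-mean onset 75; unaffected carrier aged 72 is only 3y below
        members, dosages = _family(
            [("affected", 74.0, 1), ("affected", 76.0, 1),
             ("unaffected", 72.0, 1)]
        )
        call = classify_family_segregation(members, dosages, "v")
        assert call.status is SegregationStatus.NONE
        assert call.n_unaffected_carriers == 1
        assert call.n_unaffected_carriers_qualifying == 0

    def test_missing_genotypes_excluded_not_counted_as_noncarriers(self):
        members, dosages = _family(
            [("affected", 74.0, 1), ("affected", 76.0, 1),
             ("affected", 70.0, MISSING), ("unaffected", 60.0, 0)]
        )
        call = classify_family_segregation(members, dosages, "v")
        assert call.status is SegregationStatus.COMPLETE
        assert call.n_affected_genotyped == 2

    def test_single_affected_carrier_is_below_the_floor(self):
        members, dosages = _family(
            [("affected", 74.0, 1), ("affected", 76.0, MISSING)]
        )
        call = classify_family_segregation(members, dosages, "v")
        assert call.status is SegregationStatus.NONE

    def test_no_genotyped_affected_gives_none_with_zero_count(self):
        members, dosages = _family(
            [("affected", 74.0, MISSING), ("affected", 76.0, MISSING)]
        )
        call = classify_family_segregation(members, dosages, "v")
        assert call.status is SegregationStatus.NONE
        assert call.n_affected_genotyped == 0

    def test_unknown_affection_is_ignored_on_both_sides(self):
        members, dosages = _family(
            [("affected", 74.0, 1), ("affected", 76.0, 1),
             ("unknown", None, 0), ("unknown", None, 1)]
        )
        call = classify_family_segregation(members, dosages, "v")
        assert call.status is SegregationStatus.COMPLETE

    def test_onset_reference_switch_changes_the_verdict(self):
        # carriers onset mean 80; family mean onset (with non-carrier... all
        # carry here) — use a non-carrier affected young member via missing
        members, dosages = _family(
            [("affected", 84.0, 1), ("affected", 76.0, 1),
             ("affected", 60.0, MISSING), ("unaffected", 70.0, 1)]
        )
        carrier = classify_family_segregation(
            members, dosages, "v", onset_reference="carrier_mean"
        )
        family = classify_family_segregation(
            members, dosages, "v", onset_reference="family_mean"
        )
        # carrier mean 80 -> 70 qualifies (10y); family mean 73.3 -> fails
        assert carrier.status is SegregationStatus.COMPLETE
        assert family.status is SegregationStatus.NONE


class TestBruteForceAgreement:
    AGES = (68.0, 75.0)
    DOSAGES = (0, 1, MISSING)
    AFFECTIONS = ("affected", "unaffected")

    def _check(self, spec, onset_reference="carrier_mean"):
        members, dosages = _family(spec)
        got = classify_family_segregation(
            members, dosages, "v", onset_reference=onset_reference
        ).status.value
        want = brute_force_segregation(
            members, dosages, onset_reference=onset_reference
        )
        assert got == want, spec

    @pytest.mark.parametrize("size", [2, 3, 4])
    def test_exhaustive_small_families(self, size):
        """Every (affection, age, dosage) combination for families of 2-4."""
        member_states = list(
            itertools.product(self.AFFECTIONS, self.AGES, self.DOSAGES)
        )
        for combo in itertools.product(member_states, repeat=size):
            self._check(list(combo))

    @pytest.mark.parametrize("onset_reference", ["carrier_mean", "family_mean"])
    def test_random_larger_families(self, onset_reference):
        rng = np.random.default_rng(17)
        for _ in range(2000):
            size = int(rng.integers(5, 7))
            spec = [
                (
                    self.AFFECTIONS[rng.integers(2)],
                    float(rng.choice([62.0, 68.0, 70.0, 75.0, 81.0])),
                    int(rng.choice([0, 1, 2, MISSING])),
                )
                for _ in range(size)
            ]
            self._check(spec, onset_reference)

    def test_buffer_monotone_never_creates_complete(self):
        rng = np.random.default_rng(23)
        for _ in range(500):
            size = int(rng.integers(2, 6))
            spec = [
                (
                    self.AFFECTIONS[rng.integers(2)],
                    float(rng.choice([66.0, 71.0, 76.0])),
                    int(rng.choice([0, 1, MISSING])),
                )
                for _ in range(size)
            ]
            members, dosages = _family(spec)
            small = classify_family_segregation(
                members, dosages, "v", buffer=2.0
            ).status
            big = classify_family_segregation(
                members, dosages, "v", buffer=8.0
            ).status
            if small is SegregationStatus.NONE:
                assert big is SegregationStatus.NONE

    def test_adding_members_monotonicity(self):
        base = [("affected", 74.0, 1), ("affected", 76.0, 1)]
        members, dosages = _family(base)
        assert classify_family_segregation(members, dosages, "v").status is (
            SegregationStatus.COMPLETE
        )
        # an extra affected non-carrier can never keep it COMPLETE
        members2, dosages2 = _family(base + [("affected", 75.0, 0)])
        assert classify_family_segregation(members2, dosages2, "v").status is (
            SegregationStatus.NONE
        )
        # an extra affected carrier never destroys it
        members3, dosages3 = _family(base + [("affected", 75.0, 1)])
        assert classify_family_segregation(members3, dosages3, "v").status is (
            SegregationStatus.COMPLETE
        )


class TestCohortIncomplete:
    def _cohort(self, fam_specs):
        out = {}
        for i, spec in enumerate(fam_specs):
            members, dosages = [], {}
            for j, (affection, age, dosage) in enumerate(spec):
                iid = f"F{i}_I{j}"
                members.append(make_member(f"F{i}", iid, affection, age))
                dosages[iid] = dosage
            out[f"F{i}"] = (members, dosages)
        return out

    def test_four_affected_with_qualifying_unaffected_is_incomplete(self):
        fams = self._cohort(
            [
                [("affected", 75.0, 1), ("affected", 74.0, 0)],
                [("affected", 76.0, 1), ("affected", 73.0, 0)],
                [("affected", 77.0, 1), ("affected", 73.0, 0)],
                [("affected", 78.0, 1), ("affected", 72.0, 0),
                 ("unaffected", 65.0, 1), ("unaffected", 64.0, 1)],
            ]
        )
        assert classify_cohort_incomplete("v", fams) is (
            SegregationStatus.INCOMPLETE
        )

    def test_three_affected_carriers_is_below_threshold(self):
        fams = self._cohort(
            [
                [("affected", 75.0, 1), ("affected", 74.0, 0)],
                [("affected", 76.0, 1), ("affected", 73.0, 0)],
                [("affected", 77.0, 1), ("affected", 73.0, 0)],
            ]
        )
        assert classify_cohort_incomplete("v", fams) is SegregationStatus.NONE

    def test_equal_affected_and_unaffected_carriers_fails(self):
        fams = self._cohort(
            [
                [("affected", 75.0, 1), ("affected", 74.0, 0),
                 ("unaffected", 60.0, 1)],
                [("affected", 76.0, 1), ("affected", 73.0, 0),
                 ("unaffected", 60.0, 1)],
                [("affected", 77.0, 1), ("affected", 73.0, 0),
                 ("unaffected", 60.0, 1)],
                [("affected", 78.0, 1), ("affected", 72.0, 0),
                 ("unaffected", 60.0, 1)],
            ]
        )
        assert classify_cohort_incomplete("v", fams) is SegregationStatus.NONE

    def test_non_qualifying_unaffected_carrier_fails(self):
        fams = self._cohort(
            [
                [("affected", 75.0, 1), ("affected", 74.0, 0)],
                [("affected", 76.0, 1), ("affected", 73.0, 0)],
                [("affected", 77.0, 1), ("affected", 73.0, 0)],
                [("affected", 78.0, 1), ("affected", 72.0, 0),
                 ("unaffected", 76.0, 1)],  # only 2y below carrier onset
            ]
        )
        assert classify_cohort_incomplete("v", fams) is SegregationStatus.NONE


def _call(key, fid, status, aff, geno, unaff, qual):
    return SegregationCall(key, fid, status, aff, geno, unaff, qual)


class TestCrossFamilyConsistency:
    def test_leak_to_affected_only_remains_qualifying(self):
        calls = [
            _call("v", "A", SegregationStatus.COMPLETE, 3, 3, 0, 0),
            _call("v", "B", SegregationStatus.NONE, 1, 2, 0, 0),
        ]
        out = cross_family_consistency(calls, strict=True)
        assert [c.status for c in out] == [
            SegregationStatus.COMPLETE, SegregationStatus.NONE
        ]

    def test_unaffected_leak_mode_dependent(self):
        # family B: one qualifying unaffected carrier
        calls = [
            _call("v", "A", SegregationStatus.COMPLETE, 3, 3, 0, 0),
            _call("v", "B", SegregationStatus.NONE, 1, 2, 1, 1),
        ]
        strict = cross_family_consistency(calls, strict=True)
        assert all(c.status is SegregationStatus.NONE for c in strict)
        lenient = cross_family_consistency(calls, strict=False)
        assert lenient[0].status is SegregationStatus.COMPLETE

    def test_non_qualifying_unaffected_leak_demotes_in_both_modes(self):
        calls = [
            _call("v", "A", SegregationStatus.COMPLETE, 3, 3, 0, 0),
            _call("v", "B", SegregationStatus.NONE, 0, 2, 1, 0),
        ]
        for strict in (True, False):
            out = cross_family_consistency(calls, strict=strict)
            assert all(c.status is SegregationStatus.NONE for c in out)

    def test_single_family_variant_untouched(self):
        calls = [_call("v", "A", SegregationStatus.COMPLETE, 2, 2, 0, 0)]
        assert cross_family_consistency(calls) == calls


class TestFamilyExplanation:
    apoe_yes = _call("APOE_e4", "F", SegregationStatus.COMPLETE, 2, 2, 0, 0)
    apoe_no = _call("APOE_e4", "F", SegregationStatus.NONE, 1, 2, 0, 0)

    def test_rare_takes_precedence_over_apoe(self):
        seg = [_call("v", "F", SegregationStatus.COMPLETE, 2, 2, 0, 0)]
        label = classify_family_explanation("F", seg, self.apoe_yes).label
        assert label is ExplanationLabel.RARE_EXPLAINED

    def test_apoe_only_when_no_rare_variant_segregates(self):
        seg = [_call("v", "F", SegregationStatus.NONE, 1, 2, 0, 0)]
        label = classify_family_explanation("F", seg, self.apoe_yes).label
        assert label is ExplanationLabel.APOE_ONLY

    def test_unexplained_when_nothing_segregates(self):
        label = classify_family_explanation("F", [], self.apoe_no).label
        assert label is ExplanationLabel.UNEXPLAINED
        assert classify_family_explanation("F", [], None).label is (
            ExplanationLabel.UNEXPLAINED
        )

    def test_labels_partition_simulated_families(self, small_result):
        for cid, summary in small_result.summaries.items():
            assert (
                summary.n_families_with_complete
                + summary.n_families_apoe_only
                + summary.n_families_unexplained
                == summary.n_families
            )
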