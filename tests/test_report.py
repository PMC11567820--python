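"""Percent arithmetic, cohort summaries, and the variant report table."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famseg.pedigree import FamilyCohort
from famseg.published import (
    distinct_variant_counts,
    load_published_counts,
    load_table2,
    load_table3,
    table3_to_calls,
)
from famseg.report import percent, summarize_cohorts, variant_report
from famseg.segregation import (
    ExplanationLabel,
    FamilyExplanation,
    SegregationCall,
    SegregationStatus,
)

from .conftest import make_member


class TestPercent:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(72, 411, 17.5), (0, 197, 0.0), (99, 197, 50.3), (1, 3, 33.3),
         (2, 3, 66.7), (1, 800, 0.1), (1, 1600, 0.1)],  # 0.0625 rounds up
    )
    def test_half_away_from_zero_to_one_decimal(self, num, den, expected):
        assert percent(num, den) == expected

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(num=st.integers(0, 500), den=st.integers(1, 500))
    def test_rounding_closure(self, num, den):
        num = min(num, den)
        total = percent(num, den) + percent(den - num, den)
        assert abs(total - 100.0) <= 0.1 + 1e-9


def _complete(key, fid, aff=2, unaff=0):
    return SegregationCall(
        key, fid, SegregationStatus.COMPLETE, aff, aff, unaff, unaff
    )


class TestVariantReport:
    def test_single_family_minimal_row(self):
        rep = variant_report({"A": [_complete("chr1:10:A:C", "F1")]})
        row = rep.iloc[0]
        assert (
            row.families_complete,
            row.n_affected_in_segregating_families,
            row.n_healthy_in_segregating_families,
        ) == (1, 2, 0)

    def test_two_families_sum_member_counts(self):
        rep = variant_report(
            {"A": [
                _complete("chr1:10:A:C", "F1", aff=2, unaff=1),
                _complete("chr1:10:A:C", "F2", aff=3, unaff=1),
            ]}
        )
        row = rep.iloc[0]
        assert (
            row.families_complete,
            row.n_affected_in_segregating_families,
            row.n_healthy_in_segregating_families,
        ) == (2, 5, 2)

    def test_no_complete_calls_gives_header_only(self):
        rep = variant_report(
            {"A": [SegregationCall("v", "F", SegregationStatus.NONE, 1, 2, 0, 0)]}
        )
        assert rep.empty and list(rep.columns)[0] == "variant"

    def test_row_order_is_deterministic_genomic_order(self):
        calls = {
            "A": [
                _complete("chr10:5:A:C", "F1"),
                _complete("chr2:5:A:C", "F2"),
                _complete("chr2:5:A:G", "F3"),
            ]
        }
        rep = variant_report(calls)
        assert rep.variant.tolist() == [
            "chr2:5:A:C", "chr2:5:A:G", "chr10:5:A:C"
        ]


class TestPackagedTables:
    def test_distinct_variant_counts_per_cohort(self):
        counts = distinct_variant_counts()
        assert counts == {"AD-FBS": 46, "EFIGA": 40}

    def test_shared_variants_counted_in_both_cohorts(self):
        tbl = load_table2()
        shared = tbl[tbl.duplicated("variant", keep=False)]
        assert set(shared.variant) == {
            "chr19:1044708:GGGGCACCTGGT:G", "chr4:987896:C:G"
        }

    def test_table3_round_trip_through_variant_report(self):
        tbl = load_table3()
        seg_calls, info, apoe_calls, idx = table3_to_calls(tbl)
        rep = variant_report(seg_calls, info, apoe_calls, idx)
        merged = rep.merge(
            tbl, on=["variant", "cohort"], suffixes=("_got", "_want")
        )
        assert len(merged) == len(tbl) == 86
        for col in (
            "families_complete",
            "n_affected_in_segregating_families",
            "n_healthy_in_segregating_families",
            "n_members_carrying_index_SNP",
            "coseg_APOE",
        ):
            assert (merged[f"{col}_got"] == merged[f"{col}_want"]).all(), col

    def test_published_family_counts_reproduce_headline_percentages(self):
        counts = load_published_counts()
        combined = counts["combined"]
        assert percent(combined["n_families_rare_explained"],
                       combined["n_families"]) == 17.5
        assert percent(combined["n_families_apoe_only"],
                       combined["n_families"]) == 22.6
        assert percent(combined["n_families_unexplained"],
                       combined["n_families"]) == 60.3


class TestSummaries:
    def _cohort(self, cid, n_fam):
        fams = {}
        for i in range(n_fam):
            fid = f"{cid}F{i}"
            fams[fid] = [
                make_member(fid, f"{fid}_1", "affected", 75.0),
                make_member(fid, f"{fid}_2", "affected", 73.0),
                make_member(fid, f"{fid}_3", "unaffected", 60.0),
            ]
        return FamilyCohort(cid, fams)

    def test_counts_and_combined_pooling(self):
        cohorts = {"X": self._cohort("X", 3), "Y": self._cohort("Y", 2)}
        explanations = {
            "X": [
                FamilyExplanation("XF0", ExplanationLabel.RARE_EXPLAINED),
                FamilyExplanation("XF1", ExplanationLabel.APOE_ONLY),
                FamilyExplanation("XF2", ExplanationLabel.UNEXPLAINED),
            ],
            "Y": [
                FamilyExplanation("YF0", ExplanationLabel.RARE_EXPLAINED),
                FamilyExplanation("YF1", ExplanationLabel.UNEXPLAINED),
            ],
        }
        seg = {
            "X": [_complete("chr1:10:A:C", "XF0")],
            "Y": [_complete("chr1:10:A:C", "YF0")],
        }
        out = summarize_cohorts(
            cohorts, explanations, seg, {"chr1:10:A:C": "GENE1"}
        )
        assert out["X"].n_families == 3 and out["Y"].n_families == 2
        assert out["combined"].n_families == 5
        assert out["combined"].n_individuals == 15
        # the variant is shared: distinct count is 1 in each and combined
        assert out["X"].n_variants_complete == 1
        assert out["combined"].n_variants_complete == 1
        assert out["combined"].n_genes_complete == 1
        assert out["combined"].pct_families_with_complete == 40.0

    def test_empty_cohort_zeroed_summary(self):
        out = summarize_cohorts(
            {"Z": FamilyCohort("Z", {})}, {"Z": []}, {"Z": []}, {}
        )
        assert out["Z"].n_families == 0
        assert out["Z"].as_dict()["n_individuals"] == 0
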