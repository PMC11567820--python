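"""Packaged machine-readable transcriptions of the study's printed tables.

Three fixtures ship with the package:

* ``table2_variants.tsv`` — the per-cohort list of damaging missense/LoF
  variants by gene (one row per variant-cohort occurrence; a variant found
  in both cohorts appears twice);
* ``table3_segregating.tsv`` — the per-variant detail rows for variants that
  completely segregate in at least one family (segregating-family count,
  affected and healthy carriers in those families, APOE co-segregation,
  locus index SNP and its family carrier count);
* ``published_counts.json`` — the printed integer counts behind the headline
  percentages.

These are reporting-test inputs and the default locus list; they are not
used by the classifiers.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .segregation import SegregationCall, SegregationStatus

__all__ = [
    "load_table2",
    "load_table3",
    "load_published_counts",
    "distinct_variant_counts",
    "distinct_gene_counts",
    "table3_to_calls",
]


def _data_path(name: str):
    return resources.files("famseg.data").joinpath(name)


def load_table2() -> pd.DataFrame:
    with resources.as_file(_data_path("table2_variants.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def load_table3() -> pd.DataFrame:
    with resources.as_file(_data_path("table3_segregating.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (
        "families_complete",
        "n_affected_in_segregating_families",
        "n_healthy_in_segregating_families",
        "n_members_carrying_index_SNP",
    ):
        df[col] = df[col].astype(int)
    return df


def load_published_counts() -> dict:
    with resources.as_file(_data_path("published_counts.json")) as path:
        return json.loads(path.read_text(encoding="utf-8"))


def distinct_variant_counts(table2: pd.DataFrame | None = None) -> dict[str, int]:
    """Distinct variants per cohort, deduplicated on chrom:pos:ref:alt.

    A variant shared by both cohorts counts once in each.
    """
    tbl = load_table2() if table2 is None else table2
    return (
        tbl.groupby("cohort")["variant"].nunique().to_dict()
    )


def distinct_gene_counts(table2: pd.DataFrame | None = None) -> dict[str, int]:
    tbl = load_table2() if table2 is None else table2
    return tbl.groupby("cohort")["gene"].nunique().to_dict()


def _split_counts(total: int, parts: int, minimum: int) -> list[int]:
    """Split ``total`` into ``parts`` integers, each ≥ minimum."""
    if total < parts * minimum:
        raise ValueError(f"cannot split {total} into {parts} parts of ≥{minimum}")
    out = [minimum] * parts
    out[-1] += total - parts * minimum
    return out


def table3_to_calls(
    table3: pd.DataFrame | None = None,
) -> tuple[
    dict[str, list[SegregationCall]],
    dict[str, dict],
    dict[str, SegregationCall],
    dict[tuple[str, str], int],
]:
    """Reconstruct per-family segregation calls consistent with the table.

    Each printed row becomes ``families_complete`` synthetic families whose
    affected-carrier counts (each ≥2, the complete-segregation floor) and
    healthy-carrier counts sum to the printed totals. Feeding the result
    through :func:`famseg.report.variant_report` must reproduce the table —
    a round-trip check on the aggregation path.

    Returns (seg_calls by cohort, variant_info, apoe_calls by family,
    index carrier counts by (variant, family)).
    """
    tbl = load_table3() if table3 is None else table3
    seg_calls: dict[str, list[SegregationCall]] = {}
    variant_info: dict[str, dict] = {}
    apoe_calls: dict[str, SegregationCall] = {}
    index_carriers: dict[tuple[str, str], int] = {}

    for _, row in tbl.iterrows():
        key = row["variant"]
        cohort = row["cohort"]
        n_fam = int(row["families_complete"])
        aff_split = _split_counts(
            int(row["n_affected_in_segregating_families"]), n_fam, 2
        )
        heal_split = _split_counts(
            int(row["n_healthy_in_segregating_families"]), n_fam, 0
        )
        idx_split = _split_counts(
            int(row["n_members_carrying_index_SNP"]), n_fam, 0
        )
        variant_info[key] = {
            "gene": row["gene"],
            "variant_type": row["variant_type"],
            "index_snp": row["index_SNP"],
        }
        coseg = row["coseg_APOE"] == "Yes"
        for i in range(n_fam):
            fid = f"{cohort}:{key}:fam{i + 1}"
            seg_calls.setdefault(cohort, []).append(
                SegregationCall(
                    variant_key=key,
                    family_id=fid,
                    status=SegregationStatus.COMPLETE,
                    n_affected_carriers=aff_split[i],
                    n_affected_genotyped=aff_split[i],
                    n_unaffected_carriers=heal_split[i],
                    n_unaffected_carriers_qualifying=heal_split[i],
                )
            )
            apoe_calls[fid] = SegregationCall(
                variant_key="APOE_e4",
                family_id=fid,
                status=(
                    SegregationStatus.COMPLETE if coseg else SegregationStatus.NONE
                ),
                n_affected_carriers=aff_split[i] if coseg else 0,
                n_affected_genotyped=aff_split[i],
                n_unaffected_carriers=0,
                n_unaffected_carriers_qualifying=0,
            )
            index_carriers[(key, fid)] = idx_split[i]

    return seg_calls, variant_info, apoe_calls, index_carriers
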