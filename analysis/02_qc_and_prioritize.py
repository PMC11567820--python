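#!/usr/bin/env python
"""Apply genotype/site QC and damaging-variant prioritization to the
simulated cohorts and tabulate what each filter removes.

QC: genotypes with DP < 10 or GQ < 20 are set to missing; sites with > 2%
missing genotypes are dropped. Prioritization: gnomAD AF < 1%, then LoF or
missense with CADD > 20. Writes results/qc_summary.json.
"""

import json
from pathlib import Path

from famseg.annotate import DamagingCall, is_damaging
from famseg.pipeline import load_cohort_inputs
from famseg.variants import (
    MISSING,
    drop_high_missingness_sites,
    filter_rare,
    mask_low_quality_genotypes,
)

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "sim"


def main() -> None:
    summary = {}
    for vcf in sorted(SIM.glob("*.vcf")):
        cid = vcf.stem
        inputs = load_cohort_inputs(
            vcf,
            SIM / f"{cid}.fam",
            SIM / f"{cid}.phenotypes.tsv",
            SIM / "regions.bed",
            SIM / "annotations.tsv",
            cohort_id=cid,
        )
        masked = mask_low_quality_genotypes(inputs.matrix)
        n_masked = int(
            ((masked.dosage == MISSING) & (inputs.matrix.dosage != MISSING)).sum()
        )
        sites, matrix = drop_high_missingness_sites(inputs.sites, masked)
        rare = filter_rare(sites)
        damaging = [
            s for s in rare
            if is_damaging(s) is not DamagingCall.NOT_DAMAGING
            and (s.gene or "") != "APOE"
        ]
        lof = [s for s in damaging if is_damaging(s) is DamagingCall.LOF]
        summary[cid] = {
            "sites_in_regions": len(inputs.sites),
            "genotypes_masked_dp_gq": n_masked,
            "sites_after_missingness_filter": len(sites),
            "sites_rare_af_lt_1pct": len(rare),
            "damaging_rare_sites": len(damaging),
            "of_which_lof": len(lof),
            "of_which_damaging_missense": len(damaging) - len(lof),
        }
        print(
            f"{cid}: {len(inputs.sites)} sites -> {len(rare)} rare -> "
            f"{len(damaging)} damaging ({len(lof)} LoF)"
        )

    out = ROOT / "results" / "qc_summary.json"
    out.write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
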