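#!/usr/bin/env python
"""Symptom-severity and childhood-trauma associations with DMR methylation.

Uses the DMR call from the previous step (falling back to the published
DMR interval chr8:53252014-53252198 if no run was accepted in this
realization), regresses the per-subject DMR mean rate (%) on each symptom
scale and CTQ measure (dimensional, plus categorical exposure above the
published cutoffs), controlling for age and BMI.  Writes
results/associations.tsv.  p values are raw: this family is exploratory
and carries no multiple-testing correction.
"""

import argparse
import json
from pathlib import Path

from kormeth.associations import association_table
from kormeth.data import DMR_REGION, apply_coverage_filter
from kormeth.pipeline import PipelineConfig, _load_inputs
from kormeth.regions import subject_region_means

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--cohort-subset", choices=["pooled", "BPD", "HC"], default="pooled")
    args = ap.parse_args()

    cfg = PipelineConfig(
        counts_dir=str(args.cohort / "counts"),
        sample_sheet=str(args.cohort / "sample_sheet.csv"),
        registry=str(args.cohort / "regions.tsv"),
    )
    phenotypes, matrix, _ = _load_inputs(cfg)
    groups = dict(zip(phenotypes["subject_id"], phenotypes["group"]))
    filtered, _ = apply_coverage_filter(matrix, 25, groups, 3)

    dmr_file = ROOT / "results" / "dmr.json"
    member_positions = None
    if dmr_file.exists():
        calls = json.loads(dmr_file.read_text())
        accepted = [c for c in calls if c["accepted"]]
        if accepted:
            chrom, start, end = accepted[0]["interval"]
            from kormeth.data import GenomicRegion

            region = GenomicRegion("DMR", chrom, start, end)
            member_positions = accepted[0]["members"]
    if member_positions is None:
        region = DMR_REGION
        print("no accepted DMR call found; using the published DMR interval")

    means = subject_region_means(filtered, region)
    tbl = association_table(means, phenotypes, cohort=args.cohort_subset)
    out = ROOT / "results" / "associations.tsv"
    tbl.to_csv(out, sep="\t", index=False)
    ok = tbl[tbl.error == ""]
    cols = ["predictor", "mode", "slope_b", "se", "p_value", "n_complete"]
    print(ok[cols].round(4).to_string(index=False))
    skipped = tbl[tbl.error != ""]
    if len(skipped):
        print("\nskipped models:")
        for _, row in skipped.iterrows():
            print(f"  {row.predictor}: {row.error}")
    print(f"\nwrote {out} (raw p values, no family-wise correction)")


if __name__ == "__main__":
    main()
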