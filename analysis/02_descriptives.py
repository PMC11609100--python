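#!/usr/bin/env python
"""Group comparisons of the phenotype scales (descriptive table).

Reads the exported sample sheet, compares every scale between BPD and HC
with Welch's t (one-sided for symptom scales, two-sided for the matching
covariates age and BMI), and writes results/descriptives.tsv.  Also
recomputes two published rows (DES, CTQ) directly from their printed group
summaries as a cross-check of the summary-statistic route.
"""

import argparse
from pathlib import Path

from kormeth.data import read_sample_sheet
from kormeth.descriptives import GroupSummary, describe, welch_t_from_summary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    phenotypes = read_sample_sheet(args.cohort / "sample_sheet.csv")
    tbl = describe(phenotypes)
    out = ROOT / "results" / "descriptives.tsv"
    tbl.to_csv(out, sep="\t", index=False)
    print(tbl.round(3).to_string(index=False))
    print(f"\nwrote {out}")

    print("\npublished-summary cross-checks (printed t in parentheses):")
    for name, row, printed in (
        ("DES", GroupSummary("DES", 46, 47, 20.61, 2.26, 14.00, 1.80, "one"), 8.822),
        ("CTQ", GroupSummary("CTQ", 44, 48, 2.34, 1.18, 0.66, 0.25, "one"), 10.997),
    ):
        t, df, p = welch_t_from_summary(row)
        print(f"  {name}: t = {t:.3f} ({printed}), df = {df:.1f}, p = {p:.2e}")


if __name__ == "__main__":
    main()
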