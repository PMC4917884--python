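"""Apply genotype- and site-level QC to the discovery cohort.

Masks calls failing GQ >= 30, het alternate depth >= 3 or the 50/50
allele-balance chi-square (< 10.83), then drops sites failing truth-tranche,
alignability/simple-repeat, Hardy-Weinberg (P <= 1e-8 in either group) or
the 75% per-group call-rate filter.  Writes the per-variant filter report
and prints the QC attrition table.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from common import cli, discovery_spec, load_filtered


def main():
    args = cli(__doc__)
    _, fc = load_filtered(discovery_spec(args.seed))
    report = fc.report
    out = os.path.join(args.out_dir, "filter_report.tsv")
    report.to_csv(out, sep="\t", index=False)

    n = len(report)
    print(f"{n} decomposed variant records")
    for reason, count in report["first_fail_reason"].value_counts().items():
        if reason:
            print(f"  failed {reason}: {count}")
    print(f"  passing: {int(report['pass'].sum())} "
          f"({report['pass'].mean():.1%})")
    tiers = report.loc[report["pass"], "tier"].value_counts()
    for tier, count in tiers.items():
        print(f"  {tier}: {count}")
    print(f"filter report written to {out}")


if __name__ == "__main__":
    main()
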