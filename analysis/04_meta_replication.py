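"""Replication meta-analysis of candidate genes across cohorts.

Genes with nominally significant class-1 burden P in the reduced discovery
set are combined with the whole-genome replication cohort using the
sample-size-weighted Z-score method (weights sqrt(4/(1/Nca+1/Nco))).
"""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from common import cli, discovery_spec, known_config, load_filtered, \
    replication_spec

from crcburden import assoc, burden


def main():
    args = cli(__doc__)
    cohort, fc = load_filtered(discovery_spec(args.seed))
    reduced_fc, _ = burden.reduce_cases(fc, known_config(cohort))
    disc = burden.exome_wide_screen(reduced_fc)

    _, repl_fc = load_filtered(replication_spec(args.seed))
    repl = burden.exome_wide_screen(repl_fc)

    meta = assoc.meta_burden(disc, repl, gate_p=0.05, variant_class=1)
    out = os.path.join(args.out_dir, "meta_replication.tsv")
    meta.to_csv(out, sep="\t", index=False)

    print(f"{len(meta)} genes passed the class-1 P < 0.05 gate and were "
          f"meta-analysed ({reduced_fc.cohort.n_cases}/"
          f"{reduced_fc.cohort.n_controls} + "
          f"{repl_fc.cohort.n_cases}/{repl_fc.cohort.n_controls}):")
    print(meta.head(10).to_string(index=False))
    planted = meta[meta["gene"].str.startswith("RISK")]
    print(f"\nplanted risk genes replicating (meta P < 1e-4): "
          f"{sorted(planted.loc[planted['p_meta'] < 1e-4, 'gene'])}")
    print(f"meta table written to {out}")


if __name__ == "__main__":
    main()
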