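"""Scan for biallelic (recessive-model) carriers of rare damaging variants.

A sample is a biallelic hit in a gene when it is homozygous for one
qualifying variant, or heterozygous for two or more distinct qualifying
variants in that gene (putative compound heterozygote; phase is unknown
without pedigree or read evidence, so trans configuration is assumed and
flagged).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .varfilter import FilteredCohort


def find_biallelic(fc: FilteredCohort, variant_class: int = 2,
                   tier: str = "rare") -> pd.DataFrame:
    """Per-sample, per-gene biallelic hits over qualifying variants.

    Returns a table with columns ``sample_id, status, gene, variants,
    pattern, phase_unknown`` where ``pattern`` is ``homozygous`` or
    ``compound_het`` (homozygosity takes precedence when both occur).
    """
    qual = fc.qualifying(variant_class, tier)
    idx = np.flatnonzero(qual)
    rows = []
    if idx.size:
        v = fc.cohort.variants
        genes = v["gene"].to_numpy()[idx]
        ids = v["variant_id"].to_numpy()[idx]
        gt = fc.genotypes[:, idx]
        samples = fc.cohort.samples
        order = np.argsort(genes, kind="stable")
        genes, ids = genes[order], ids[order]
        gt = gt[:, order]
        bounds = np.flatnonzero(np.r_[True, genes[1:] != genes[:-1]])
        n_het = np.add.reduceat(gt == 1, bounds, axis=1)
        n_hom = np.add.reduceat(gt == 2, bounds, axis=1)
        hit_s, hit_g = np.nonzero((n_hom >= 1) | (n_het >= 2))
        gene_names = genes[bounds]
        ends = np.r_[bounds[1:], len(genes)]
        for s, g in zip(hit_s, hit_g):
            cols = slice(bounds[g], ends[g])
            calls = gt[s, cols]
            if (calls == 2).any():
                pattern = "homozygous"
                var_list = ids[cols][calls == 2]
            else:
                pattern = "compound_het"
                var_list = ids[cols][calls == 1]
            rows.append((samples["sample_id"].iat[s],
                         samples["status"].iat[s],
                         gene_names[g], ",".join(sorted(var_list)),
                         pattern, pattern == "compound_het"))
    out = pd.DataFrame(rows, columns=["sample_id", "status", "gene",
                                      "variants", "pattern", "phase_unknown"])
    return out.sort_values(["status", "gene", "sample_id"],
                           kind="stable").reset_index(drop=True)
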