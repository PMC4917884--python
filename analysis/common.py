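"""Shared study design for the numbered analysis scripts.

The synthetic discovery cohort mirrors the familial early-onset case/control
exome design: 1,006 cases and 1,609 controls, six established predisposition
genes whose curated disruptive alleles account for 143 cases (14.2%), six
planted novel risk genes with relative risks between 3 and 8, one recessive
gene with biallelic case carriers, and a background of null genes with a
0.002 per-variant carrier frequency.  The gene universe is scaled to 2,000
genes so every script runs in seconds; the statistical structure per gene is
unchanged by the scaling.

The replication cohort mirrors the whole-genome follow-up series: 188 cases
against 3,582 population controls, the same planted risk genes, and no
curated-gene carriers (replication cases were pre-screened for known-gene
mutations).
"""

import argparse
import os

from crcburden.burden import KnownGeneConfig
from crcburden.cohortgen import CohortSpec, PlantedGene, generate_cohort
from crcburden.varfilter import apply_filters

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

PLANTED = (
    PlantedGene("RISK1", 1, 8.0),
    PlantedGene("RISK2", 1, 5.0),
    PlantedGene("RISK3", 1, 3.0),
    PlantedGene("RISK4", 2, 6.0),
    PlantedGene("RISK5", 2, 4.0),
    PlantedGene("RISK6", 2, 3.0),
)


def discovery_spec(seed: int = 2016) -> CohortSpec:
    return CohortSpec(
        n_cases=1006, n_controls=1609, n_genes=2000,
        planted_genes=PLANTED, known_gene_carriers=143 / 1006,
        recessive_gene="REC1", recessive_case_carriers=2, seed=seed)


def replication_spec(seed: int = 2016) -> CohortSpec:
    return CohortSpec(
        n_cases=188, n_controls=3582, n_genes=2000,
        planted_genes=PLANTED, known_gene_carriers=0.0, seed=seed + 1)


def known_config(cohort) -> KnownGeneConfig:
    return KnownGeneConfig(
        genes=tuple(cohort.truth["known_genes"]),
        curated_variants=tuple(cohort.truth["curated_variants"]))


def load_filtered(spec: CohortSpec):
    cohort = generate_cohort(spec)
    return cohort, apply_filters(cohort)


def cli(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=2016)
    ap.add_argument("--out-dir", default=RESULTS)
    args = ap.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)
    return args
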