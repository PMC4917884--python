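"""Synthetic case/control exome cohorts with planted risk structure.

The generator emulates the statistical structure a rare-variant collapsing
analysis assumes: a rare-variant site spectrum across thousands of genes with
three non-silent severity classes plus silent variants, per-call genotype
quality and allele-depth fields with configurable failure tails, planted risk
genes whose case carrier frequency follows the family-history-weighted
dominant enrichment model, curated pathogenic carriers in established
predisposition genes, and an optional recessive gene with biallelic case
carriers.

Carrier model: by default each sample carries at most one alternate allele
per gene per draw (a per-gene Bernoulli), matching the empirical observation
that cases do not stack multiple disruptive alleles in one gene; an
independent per-variant option exists.  All carriers are heterozygous except
explicitly planted biallelic samples, appropriate for the per-variant carrier
probabilities (1e-5..5e-3) the generator targets.

Curated pathogenic carrier calls and planted biallelic calls are emitted with
clean quality fields (GQ 99, balanced depths, never missing): such variants
correspond to manually reviewed, curated alleles, so their bookkeeping is
exact by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import Cohort
from .power import EnrichmentModel, DEFAULT_FH_WEIGHTS
from .varfilter import classify_variants

_BASES = np.array(list("ACGT"))

DEFAULT_KNOWN_GENES = ("MLH1", "MSH2", "MSH6", "PMS2", "APC", "MUTYH")


@dataclass(frozen=True)
class PlantedGene:
    gene: str
    variant_class: int          # qualifying severity class planted (1, 2 or 3)
    rr: float                   # relative risk of carriers


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults follow the discovery design of a familial early-onset
    case/control exome study: 1,006 cases, 1,609 controls, ~20,000 genes at
    mean coverage 48x, with a per-variant carrier frequency of 0.002 in
    controls.
    """

    n_cases: int = 1006
    n_controls: int = 1609
    n_genes: int = 20_000
    variants_per_gene: float = 3.0          # Poisson mean (min 1 per gene)
    # (disruptive, missense-damaging, other-nonsynonymous, silent)
    class_probs: Tuple[float, float, float, float] = (0.10, 0.20, 0.45, 0.25)
    baseline_carrier_freq: float = 0.002    # per-variant carrier prob, controls
    planted_genes: Tuple[PlantedGene, ...] = ()
    known_genes: Tuple[str, ...] = DEFAULT_KNOWN_GENES
    known_gene_carriers: float = 0.0        # fraction of cases planted
    recessive_gene: Optional[str] = None
    recessive_case_carriers: int = 2
    fh_weights: Tuple[float, float, float] = DEFAULT_FH_WEIGHTS
    seed: int = 0
    # quality-model knobs
    mean_depth: float = 48.0
    gq_fail_frac: float = 0.01              # P(GQ < 30)
    unbalanced_het_frac: float = 0.01       # contaminant-like het imbalance
    missing_frac: float = 0.02              # per-call missingness
    bad_alignability_frac: float = 0.01
    simple_repeat_frac: float = 0.005
    tranche_fail_frac: float = 0.005
    ext_common_frac: float = 0.002          # sites common in the external ref
    multi_carrier: bool = False             # independent per-variant carriers

    def validate(self) -> None:
        def check_probs(name, vec):
            if any(p < 0 for p in vec):
                raise ValueError(f"{name}: probabilities must be non-negative")
            if abs(sum(vec) - 1.0) > 1e-12:
                raise ValueError(f"{name}: probabilities must sum to 1, "
                                 f"got {sum(vec)!r}")

        check_probs("class_probs", self.class_probs)
        check_probs("fh_weights", self.fh_weights)
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if not (1e-5 <= self.baseline_carrier_freq <= 5e-3):
            raise ValueError("baseline_carrier_freq outside supported range "
                             "[1e-5, 5e-3]")
        if not (0.0 <= self.known_gene_carriers <= 1.0):
            raise ValueError("known_gene_carriers must be a fraction in [0,1]")
        for pg in self.planted_genes:
            if pg.variant_class not in (1, 2, 3):
                raise ValueError(f"planted_genes: bad class {pg.variant_class}")
            if pg.rr < 1.0:
                raise ValueError("planted_genes: relative risk must be >= 1")
            # the per-stratum enrichment must stay a valid frequency
            m = EnrichmentModel(min(self.baseline_carrier_freq * 10, 0.49),
                                pg.rr, self.fh_weights)
            if m.case_frequency() > 1.0:
                raise ValueError("planted_genes: enrichment pushes case "
                                 "frequency above 1")
        special = [pg.gene for pg in self.planted_genes] + list(self.known_genes)
        if self.recessive_gene:
            special.append(self.recessive_gene)
        if len(special) != len(set(special)):
            raise ValueError("planted/known/recessive gene names must be distinct")
        if len(special) > self.n_genes:
            raise ValueError("more special genes than n_genes")


# consequence term pools per class bucket, with within-bucket weights
_BUCKETS = {
    0: (["stop_gained", "frameshift"], [0.5, 0.5]),
    1: (["missense", "splice_acceptor", "splice_donor"], [0.8, 0.1, 0.1]),
    2: (["missense", "splice_region", "inframe_deletion", "inframe_insertion",
         "stop_lost", "initiator_codon"], [0.5, 0.2, 0.1, 0.1, 0.05, 0.05]),
    3: (["synonymous"], [1.0]),
}


def _gene_names(spec: CohortSpec) -> List[str]:
    names = [pg.gene for pg in spec.planted_genes] + list(spec.known_genes)
    if spec.recessive_gene:
        names.append(spec.recessive_gene)
    filler = (f"G{i:05d}" for i in range(spec.n_genes * 2))
    taken = set(names)
    for name in filler:
        if len(names) >= spec.n_genes:
            break
        if name not in taken:
            names.append(name)
    return names[: spec.n_genes]


def _make_variant_table(spec: CohortSpec, rng: np.random.Generator):
    """Annotation table plus per-gene variant index ranges and truth hooks."""
    genes = _gene_names(spec)
    n_genes = len(genes)
    m = np.maximum(rng.poisson(spec.variants_per_gene, n_genes), 1)

    planted_idx = {pg.gene: i for i, pg in enumerate(spec.planted_genes)}
    known = set(spec.known_genes)
    for gi, g in enumerate(genes):
        if g == spec.recessive_gene:
            m[gi] = max(m[gi], 2)

    first = np.concatenate(([0], np.cumsum(m)[:-1]))
    n_var = int(m.sum())
    gene_of_variant = np.repeat(np.array(genes, dtype=object), m)

    # class bucket per variant
    bucket = rng.choice(4, size=n_var, p=spec.class_probs)
    # known genes: background variants never disruptive (pathogenic alleles
    # in established genes are modelled as the curated list below)
    known_var = np.isin(gene_of_variant, list(known))
    redraw = known_var & (bucket == 0)
    if redraw.any():
        sub_p = np.array(spec.class_probs[1:]) / sum(spec.class_probs[1:])
        bucket[redraw] = 1 + rng.choice(3, size=int(redraw.sum()), p=sub_p)

    consequence = np.empty(n_var, dtype=object)
    condel = np.full(n_var, "NA", dtype=object)
    for b, (terms, weights) in _BUCKETS.items():
        sel = bucket == b
        k = int(sel.sum())
        if k == 0:
            continue
        consequence[sel] = rng.choice(terms, size=k, p=weights)
    condel[(bucket == 1) & (consequence == "missense")] = "damaging"
    condel[(bucket == 2) & (consequence == "missense")] = "tolerated"

    # force qualifying content where planting requires it
    curated_variant_of_gene = {}
    for gi, g in enumerate(genes):
        f = first[gi]
        if g in planted_idx:
            pg = spec.planted_genes[planted_idx[g]]
            term = {1: "stop_gained", 2: "missense", 3: "missense"}[pg.variant_class]
            consequence[f] = term
            condel[f] = "damaging" if pg.variant_class == 2 else (
                "tolerated" if pg.variant_class == 3 else "NA")
        elif g in known:
            consequence[f] = "stop_gained"      # the curated pathogenic allele
            condel[f] = "NA"
            curated_variant_of_gene[g] = f
        elif g == spec.recessive_gene:
            consequence[f] = "stop_gained"
            consequence[f + 1] = "stop_gained"
            condel[f] = condel[f + 1] = "NA"

    # coordinates: genes tiled over 22 autosomes, variants 100 bp apart
    gene_idx_of_variant = np.repeat(np.arange(n_genes), m)
    offset = np.concatenate([np.arange(k) for k in m])
    chrom = np.array([f"chr{(gi % 22) + 1}" for gi in gene_idx_of_variant],
                     dtype=object)
    pos = 1_000_000 + (gene_idx_of_variant // 22) * 50_000 + offset * 100 + 1
    ref_i = rng.integers(0, 4, n_var)
    alt_i = (ref_i + rng.integers(1, 4, n_var)) % 4
    ref = _BASES[ref_i].astype(object)
    alt = _BASES[alt_i].astype(object)
    indel = np.isin(consequence, ["frameshift", "inframe_deletion",
                                  "inframe_insertion"])
    for j in np.flatnonzero(indel):
        if consequence[j] == "inframe_insertion":
            alt[j] = ref[j] + "TAG"
        elif consequence[j] == "inframe_deletion":
            ref[j] = ref[j] + "TAG"
            alt[j] = ref[j][0]
        else:
            ref[j] = ref[j] + "T"
            alt[j] = ref[j][0]

    variant_id = np.array([f"{c}:{p}:{r}:{a}" for c, p, r, a
                           in zip(chrom, pos, ref, alt)], dtype=object)

    alignability = np.ones(n_var)
    alignability[rng.random(n_var) < spec.bad_alignability_frac] = 0.5
    simple_repeat = (rng.random(n_var) < spec.simple_repeat_frac).astype(int)
    tranche_fail = (rng.random(n_var) < spec.tranche_fail_frac).astype(int)
    ext_af = np.full(n_var, np.nan)
    ext_af[rng.random(n_var) < spec.ext_common_frac] = 0.05
    # planted / curated / recessive sites must survive the site filters
    forced = np.zeros(n_var, dtype=bool)
    for gi, g in enumerate(genes):
        if g in planted_idx or g in known or g == spec.recessive_gene:
            forced[first[gi]: first[gi] + m[gi]] = True
    alignability[forced] = 1.0
    simple_repeat[forced] = 0
    tranche_fail[forced] = 0
    ext_af[forced] = np.nan

    variants = pd.DataFrame({
        "variant_id": variant_id, "chrom": chrom, "pos": pos,
        "ref": ref, "alt": alt, "gene": gene_of_variant,
        "consequence": consequence, "condel_label": condel,
        "alignability": alignability, "simple_repeat": simple_repeat,
        "tranche_fail": tranche_fail, "ext_af": ext_af,
    })
    return variants, genes, m, first, curated_variant_of_gene


def _draw_carriers(spec: CohortSpec, rng, genes, m, first, variants,
                   strata: np.ndarray, case_mask: np.ndarray,
                   gt: np.ndarray, truth: dict) -> None:
    """Fill heterozygous carrier calls into ``gt`` (in place)."""
    n_s = gt.shape[0]
    p = spec.baseline_carrier_freq
    special = {pg.gene for pg in spec.planted_genes}

    if spec.multi_carrier:
        # independent Bernoulli per variant, in variant blocks
        n_var = gt.shape[1]
        for lo in range(0, n_var, 4096):
            hi = min(lo + 4096, n_var)
            hit = rng.random((n_s, hi - lo)) < p
            gt[:, lo:hi][hit] = 1
    else:
        # at most one carried variant per gene: per-gene Bernoulli then a
        # uniform choice of which variant is carried
        p_gene = 1.0 - (1.0 - p) ** m
        hit = rng.random((n_s, len(genes))) < p_gene[None, :]
        rows, gcols = np.nonzero(hit)
        offs = (rng.random(rows.size) * m[gcols]).astype(np.int64)
        gt[rows, first[gcols] + offs] = 1

    # planted risk genes: redraw the qualifying carrier status of every
    # sample from the enrichment model (cases) / gene-level baseline (controls)
    if special:
        cls = classify_variants(variants)
        truth["planted"] = {}
        for pg in spec.planted_genes:
            gi = genes.index(pg.gene)
            cols = np.arange(first[gi], first[gi] + m[gi])
            qual = cls[f"class{pg.variant_class}"].to_numpy()[cols]
            qcols = cols[qual]
            p0_gene = 1.0 - (1.0 - p) ** len(qcols)
            model = EnrichmentModel(p0_gene, pg.rr, spec.fh_weights)
            f_by_stratum = np.array(
                [p0_gene] + [model.stratum_frequency(k) for k in (1, 2, 3)])
            prob = f_by_stratum[strata]            # stratum 0 = controls
            gt[:, qcols] = 0                       # reset background draws
            carrier = rng.random(n_s) < prob
            rows = np.flatnonzero(carrier)
            choice = qcols[(rng.random(rows.size) * len(qcols)).astype(np.int64)]
            gt[rows, choice] = 1
            truth["planted"][pg.gene] = {
                "variant_class": pg.variant_class,
                "rr": pg.rr,
                "expected_control_freq": p0_gene,
                "expected_case_freq": float(
                    np.dot(spec.fh_weights, f_by_stratum[1:])),
            }


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a synthetic cohort; identical spec (and seed) gives identical
    output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    variants, genes, m, first, curated_of_gene = _make_variant_table(spec, rng)
    n_var = len(variants)
    n_s = spec.n_cases + spec.n_controls

    status = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls,
                      dtype=object)
    case_mask = status == "case"
    # family-history stratum: cases have 1..3 affected first-degree relatives
    strata = np.zeros(n_s, dtype=np.int64)
    strata[case_mask] = 1 + rng.choice(3, size=spec.n_cases,
                                       p=spec.fh_weights)
    samples = pd.DataFrame({
        "sample_id": [f"S{i:05d}" for i in range(n_s)],
        "status": status,
        "cohort": "SIM",
        "n_affected_fdr": strata,
    })

    gt = np.zeros((n_s, n_var), dtype=np.int8)
    truth: dict = {"known_genes": list(spec.known_genes)}
    _draw_carriers(spec, rng, genes, m, first, variants, strata, case_mask,
                   gt, truth)

    # curated pathogenic carriers in known genes (round-robin planting);
    # curated alleles are carried only by the planted carriers, so clear any
    # background draw that landed on a curated column first
    clean = []          # calls exempt from the quality model
    cols = [curated_of_gene[g] for g in spec.known_genes
            if g in curated_of_gene]
    if cols:
        gt[:, cols] = 0
    truth["curated_variants"] = [variants["variant_id"].iat[c] for c in cols]
    truth["curated_carriers"] = []
    n_curated = int(round(spec.known_gene_carriers * spec.n_cases))
    if n_curated:
        carriers = rng.choice(spec.n_cases, size=n_curated, replace=False)
        truth["curated_carriers"] = sorted(
            samples["sample_id"].iat[s] for s in carriers)
        for i, s in enumerate(sorted(carriers)):
            col = cols[i % len(cols)]
            gt[s, col] = 1
            clean.append((s, col))

    # recessive gene: one homozygote, remaining planted samples compound-het
    if spec.recessive_gene:
        gi = genes.index(spec.recessive_gene)
        v1, v2 = first[gi], first[gi] + 1
        picks = rng.choice(spec.n_cases, size=spec.recessive_case_carriers,
                           replace=False)
        rec_samples = []
        for i, s in enumerate(sorted(picks)):
            if i == 0:
                gt[s, v1] = 2
                clean.append((s, v1))
            else:
                gt[s, v1] = 1
                gt[s, v2] = 1
                clean.extend([(s, v1), (s, v2)])
            rec_samples.append(samples["sample_id"].iat[s])
        truth["recessive"] = {"gene": spec.recessive_gene,
                              "samples": rec_samples}

    clean = [(s, c, int(gt[s, c])) for s, c in clean]
    gq, ad_ref, ad_alt = _quality_fields(spec, rng, gt)
    for s, c, val in clean:
        gt[s, c] = val        # exempt from the missingness model
        gq[s, c] = 99
        d = int(round(spec.mean_depth))
        if gt[s, c] == 1:
            ad_ref[s, c] = d // 2
            ad_alt[s, c] = d - d // 2
        else:
            ad_ref[s, c] = 0
            ad_alt[s, c] = d

    return Cohort(genotypes=gt, variants=variants, samples=samples,
                  gq=gq, ad_ref=ad_ref, ad_alt=ad_alt, truth=truth)


def _quality_fields(spec: CohortSpec, rng, gt: np.ndarray):
    """Per-call GQ, allele depths and missingness (mutates ``gt`` for
    missing calls).  Generated in variant blocks to bound peak memory."""
    n_s, n_var = gt.shape
    gq = np.empty((n_s, n_var), dtype=np.int8)
    ad_ref = np.empty((n_s, n_var), dtype=np.int16)
    ad_alt = np.zeros((n_s, n_var), dtype=np.int16)
    block = max(1, int(2e8) // max(n_s, 1) // 8)
    for lo in range(0, n_var, block):
        hi = min(lo + block, n_var)
        shape = (n_s, hi - lo)
        depth = rng.poisson(spec.mean_depth, shape).astype(np.int16)
        g = np.clip(np.rint(rng.normal(65.0, 12.0, shape)), 30, 99)
        low = rng.random(shape) < spec.gq_fail_frac
        g[low] = rng.integers(0, 30, int(low.sum()))
        gq[:, lo:hi] = g.astype(np.int8)
        ad_ref[:, lo:hi] = depth

        blk = gt[:, lo:hi]
        het = np.nonzero(blk == 1)
        if het[0].size:
            d = depth[het]
            frac = np.where(rng.random(het[0].size) < spec.unbalanced_het_frac,
                            0.12, 0.5)
            alt = rng.binomial(d, frac).astype(np.int16)
            ad_alt[:, lo:hi][het] = alt
            ad_ref[:, lo:hi][het] = d - alt
        hom = np.nonzero(blk == 2)
        if hom[0].size:
            ad_alt[:, lo:hi][hom] = depth[hom]
            ad_ref[:, lo:hi][hom] = 0
        miss = rng.random(shape) < spec.missing_frac
        blk[miss] = -1
    return gq, ad_ref, ad_alt


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str) -> dict:
    """Write a cohort as VCF + annotation TSV + sample TSV + truth GMT +
    known-gene YAML config.  Returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "annotation": os.path.join(out_dir, "annotation.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "gmt": os.path.join(out_dir, "truth_sets.gmt"),
        "known_genes": os.path.join(out_dir, "known_genes.yaml"),
    }
    _write_vcf(cohort, paths["vcf"])
    ann = cohort.variants.copy()
    ann.insert(0, "variant_id2", ann.pop("variant_id"))
    ann = ann.rename(columns={"variant_id2": "variant_id"})
    ann.to_csv(paths["annotation"], sep="\t", index=False, na_rep="NA")
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)

    with open(paths["gmt"], "w") as fh:
        truth = cohort.truth
        planted = sorted(truth.get("planted", {}))
        if planted:
            fh.write("PLANTED\tplanted risk genes\t" + "\t".join(planted) + "\n")
        known = truth.get("known_genes", [])
        if known:
            fh.write("KNOWN\testablished predisposition genes\t"
                     + "\t".join(known) + "\n")

    import yaml
    with open(paths["known_genes"], "w") as fh:
        yaml.safe_dump({
            "genes": list(cohort.truth.get("known_genes", [])),
            "curated_variants": list(cohort.truth.get("curated_variants", [])),
        }, fh)
    return paths


_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
"""


def _write_vcf(cohort: Cohort, path: str) -> None:
    v = cohort.variants
    chroms = list(dict.fromkeys(v["chrom"]))
    gt_str = np.array(["./.", "0/1", "1/1", "0/0"], dtype=object)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.samples["sample_id"]) + "\n")
        gq = cohort.gq
        ar, aa = cohort.ad_ref, cohort.ad_alt
        for j in range(cohort.n_variants):
            g = cohort.genotypes[:, j]
            codes = gt_str[np.where(g < 0, 0, np.where(g == 0, 3, g))]
            if gq is None:
                calls = codes
            else:
                calls = [f"{c}:{gq[s, j]}:{ar[s, j]},{aa[s, j]}"
                         for s, c in enumerate(codes)]
            fh.write("\t".join([
                str(v['chrom'].iat[j]), str(v['pos'].iat[j]),
                str(v['variant_id'].iat[j]), str(v['ref'].iat[j]),
                str(v['alt'].iat[j]), ".", "PASS", ".",
                "GT:GQ:AD" if gq is not None else "GT",
            ]) + "\t" + "\t".join(calls) + "\n")
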