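"""File formats, configuration and end-to-end pipeline orchestration.

Readers consume the VCF 4.2 / TSV / GMT / YAML dialects written by
:mod:`crcburden.cohortgen`; multi-allelic VCF records are decomposed into one
record per alternate allele on load.  :func:`run_pipeline` chains the full
analysis — QC filtering, single-variant scan, gene-burden screen on the full
and known-gene-reduced case sets, optional replication meta-analysis, GSEA,
recessive scan and known-gene attribution — writing one TSV per stage plus a
JSON run manifest.  All randomness flows from a single root seed split per
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, MISSING
from . import assoc, burden, gsea, recessive, varfilter
from .burden import KnownGeneConfig

log = logging.getLogger("crcburden")


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run."""

    vcf: str = ""
    annotation: str = ""
    samples: str = ""
    gmt: str = ""
    known_genes: str = ""
    out_dir: str = "results/pipeline"
    seed: int = 0
    # thresholds (legal ranges enforced in validate())
    gq_min: int = 30
    alt_depth_min: int = 3
    balance_chi2_max: float = 10.83
    hwe_p_min: float = 1e-8
    call_rate_min: float = 0.75
    rare_maf: float = 0.01
    low_freq_maf: float = 0.05
    exome_wide_alpha: float = 8.0e-7
    single_variant_alpha: float = 4.0e-7
    gsea_n_perm: int = 10_000
    burden_permute: bool = False
    gsea_class: int = 2

    def validate(self) -> None:
        checks = [
            ("gq_min", 0 <= self.gq_min <= 99),
            ("alt_depth_min", self.alt_depth_min >= 0),
            ("balance_chi2_max", self.balance_chi2_max > 0),
            ("hwe_p_min", 0 <= self.hwe_p_min < 1),
            ("call_rate_min", 0 < self.call_rate_min <= 1),
            ("rare_maf", 0 < self.rare_maf <= self.low_freq_maf <= 0.5),
            ("exome_wide_alpha", 0 < self.exome_wide_alpha <= 1),
            ("single_variant_alpha", 0 < self.single_variant_alpha <= 1),
            ("gsea_n_perm", self.gsea_n_perm >= 1),
            ("gsea_class", self.gsea_class in (1, 2, 3)),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"config field {name} out of legal range")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            cfg = cls(**(yaml.safe_load(fh) or {}))
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> Dict[str, List[str]]:
    """Read a GMT gene-set file (name, description, members...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_known_genes(path: str) -> KnownGeneConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return KnownGeneConfig(genes=tuple(raw["genes"]),
                           curated_variants=tuple(raw.get("curated_variants", ())))


def _decompose_vcf(path: str, sample_order: Sequence[str]):
    """Yield one record per alternate allele from a VCF with GT:GQ:AD calls."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    if list(vcf.samples) != list(sample_order):
        # caller aligns later; here we only need a stable order
        pass
    n_s = len(vcf.samples)
    rows = []
    mats = {"gt": [], "gq": [], "ad_ref": [], "ad_alt": []}
    for rec in vcf:
        geno = np.array([g[:2] for g in rec.genotypes], dtype=np.int64)
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        gq = rec.gt_quals
        for ai, alt in enumerate(rec.ALT):
            allele = ai + 1
            dose = (geno == allele).sum(axis=1).astype(np.int8)
            dose[(geno < 0).any(axis=1)] = MISSING
            vid = rec.ID if (rec.ID and len(rec.ALT) == 1) else \
                f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            rows.append((vid, rec.CHROM, rec.POS, rec.REF, alt))
            mats["gt"].append(dose)
            if gq is not None:
                mats["gq"].append(np.nan_to_num(gq, nan=-1).astype(np.int16))
            if ad is not None:
                mats["ad_ref"].append(ad[:, 0].astype(np.int16))
                mats["ad_alt"].append(ad[:, allele].astype(np.int16))
    return vcf.samples, rows, mats


def read_cohort(vcf_path: str, annotation_path: str,
                samples_path: str) -> Cohort:
    """Load and join a cohort from its on-disk representation.

    Multi-allelic records are decomposed per alternate allele; annotation
    rows for unknown variants are dropped with a warning; VCF samples missing
    from the sample table are an error.
    """
    samples = pd.read_csv(samples_path, sep="\t")
    vcf_samples, rows, mats = _decompose_vcf(vcf_path, samples["sample_id"])
    missing = set(vcf_samples) - set(samples["sample_id"])
    if missing:
        raise ValueError(f"VCF samples absent from sample table: "
                         f"{sorted(missing)}")
    samples = samples.set_index("sample_id").loc[list(vcf_samples)].reset_index()

    sites = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                        "ref", "alt"])
    ann = pd.read_csv(annotation_path, sep="\t",
                      dtype={"condel_label": str}, na_values=["NA"],
                      keep_default_na=True)
    unknown = set(ann["variant_id"]) - set(sites["variant_id"])
    if unknown:
        log.warning("dropping %d annotation rows for unknown variants",
                    len(unknown))
        ann = ann[~ann["variant_id"].isin(unknown)]
    merged = sites.merge(
        ann.drop(columns=[c for c in ("chrom", "pos", "ref", "alt")
                          if c in ann.columns]),
        on="variant_id", how="left", validate="one_to_one")
    if merged["gene"].isna().any():
        n = int(merged["gene"].isna().sum())
        raise ValueError(f"{n} VCF variants lack annotation rows")
    merged["condel_label"] = merged["condel_label"].fillna("NA")

    gt = np.stack(mats["gt"], axis=1)
    gq = np.stack(mats["gq"], axis=1) if mats["gq"] else None
    ad_ref = np.stack(mats["ad_ref"], axis=1) if mats["ad_ref"] else None
    ad_alt = np.stack(mats["ad_alt"], axis=1) if mats["ad_alt"] else None
    return Cohort(genotypes=gt, variants=merged, samples=samples,
                  gq=gq, ad_ref=ad_ref, ad_alt=ad_alt)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _stage_seeds(seed: int, stages: Sequence[str]) -> Dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(stages))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in
            zip(stages, children)}


def run_pipeline(config: PipelineConfig, cohort: Optional[Cohort] = None,
                 replication: Optional[Cohort] = None) -> dict:
    """Run the full analysis and write one table per stage under
    ``config.out_dir``.

    ``cohort`` (and optionally ``replication``) may be passed in memory;
    otherwise they are read from the configured paths.  Returns a dict of
    result tables plus the manifest.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["burden", "burden_reduced", "gsea"])

    if cohort is None:
        cohort = read_cohort(config.vcf, config.annotation, config.samples)
    known = read_known_genes(config.known_genes) if config.known_genes else None
    gene_sets = read_gmt(config.gmt) if config.gmt else {}

    results: dict = {}
    try:
        log.info("filter: %d samples x %d variants", cohort.n_samples,
                 cohort.n_variants)
        fc = varfilter.apply_filters(
            cohort, gq_min=config.gq_min, alt_depth_min=config.alt_depth_min,
            balance_chi2_max=config.balance_chi2_max,
            hwe_p_min=config.hwe_p_min, call_rate_min=config.call_rate_min,
            rare_maf=config.rare_maf, low_freq_maf=config.low_freq_maf)
        report = fc.report.copy()
        report["tier"] = report["tier"].astype(str)
        results["filter_report"] = report
        log.info("filter: %d/%d sites pass", int(report["pass"].sum()),
                 len(report))

        results["variant_assoc"] = assoc.variant_scan(
            fc, alpha=config.single_variant_alpha)

        results["burden_full"] = burden.exome_wide_screen(
            fc, alpha=config.exome_wide_alpha,
            permute=config.burden_permute, seed=seeds["burden"])

        if known is not None:
            reduced_fc, ledger = burden.reduce_cases(fc, known)
            results["reduction_ledger"] = ledger
            results["burden_reduced"] = burden.exome_wide_screen(
                reduced_fc, alpha=config.exome_wide_alpha,
                permute=config.burden_permute, seed=seeds["burden_reduced"])
            attr = burden.attribute_cases(fc, known)
            results["attribution"] = pd.DataFrame(
                sorted(attr.items()), columns=["tier", "case_fraction"])
            log.info("reduction: %d -> %d cases", fc.cohort.n_cases,
                     reduced_fc.cohort.n_cases)

        if replication is not None and known is not None:
            repl_fc = varfilter.apply_filters(replication)
            repl_screen = burden.exome_wide_screen(repl_fc)
            disc = results.get("burden_reduced", results["burden_full"])
            results["meta"] = assoc.meta_burden(disc, repl_screen)

        if gene_sets:
            full = results["burden_full"]
            cls = full[full["variant_class"] == config.gsea_class]
            pcol = "p_perm" if config.burden_permute else "p_exact"
            ranked = gsea.rank_genes(dict(zip(cls["gene"], cls[pcol])),
                                     n_perm=config.gsea_n_perm)
            results["gsea"] = gsea.set_permutation_significance(
                ranked, gene_sets, n_perm=config.gsea_n_perm,
                seed=seeds["gsea"])

        results["recessive"] = recessive.find_biallelic(fc)
    except Exception:
        # remove partial outputs so a failed run leaves no half-written state
        for name in list(results):
            path = os.path.join(config.out_dir, f"{name}.tsv")
            if os.path.exists(path):
                os.remove(path)
        raise

    for name, table in results.items():
        table.to_csv(os.path.join(config.out_dir, f"{name}.tsv"),
                     sep="\t", index=False)

    cfg = asdict(config)
    manifest = {
        "crcburden_version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "stage_seeds": seeds,
        "n_samples": cohort.n_samples,
        "n_variants": cohort.n_variants,
        "tables": sorted(results),
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
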