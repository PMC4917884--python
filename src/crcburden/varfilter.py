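"""Variant classification and genotype/site quality-control filters.

Variants are graded into three nested severity classes used by the gene-level
collapsing test:

* class 1 — disruptive: stop gain and frameshift;
* class 2 — predicted damaging: class 1 plus missense labelled damaging by an
  in-silico predictor, plus essential splice-site (donor/acceptor) variants;
* class 3 — all non-silent coding changes.

Genotype calls are masked to missing unless GQ >= 30; heterozygous calls must
additionally show alternate depth >= 3 and an allele-balance chi-square
``(a - b)^2 / (a + b) < 10.83`` for reference/alternate depths ``a, b``
(the 50/50 expectation for a germline het).  Sites are then dropped when they
fail truth-tranche or mappability annotations, depart from Hardy–Weinberg
equilibrium at P <= 1e-8 in either phenotype group, or fall below a 75%
post-masking call rate in either group.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort

# Controlled consequence vocabulary (canonical-transcript, most-severe term).
DISRUPTIVE = frozenset({"stop_gained", "frameshift"})
ESSENTIAL_SPLICE = frozenset({"splice_acceptor", "splice_donor"})
NON_SILENT = frozenset({
    "transcript_ablation", "splice_acceptor", "splice_donor", "splice_region",
    "stop_gained", "frameshift", "stop_lost", "initiator_codon",
    "transcript_amplification", "inframe_insertion", "inframe_deletion",
    "missense",
})
SILENT = frozenset({"synonymous"})
VOCABULARY = NON_SILENT | SILENT

# QC defaults
GQ_MIN = 30
ALT_DEPTH_MIN = 3
BALANCE_CHI2_MAX = 10.83
HWE_P_MIN = 1e-8
CALL_RATE_MIN = 0.75
RARE_MAF = 0.01
LOW_FREQ_MAF = 0.05


def normalize_consequence(term: str) -> str:
    """Map a raw consequence term onto the controlled vocabulary.

    Any term containing ``frameshift`` is a frameshift; otherwise the term
    must already be in the vocabulary.
    """
    term = term.strip()
    if "frameshift" in term:
        return "frameshift"
    if term not in VOCABULARY:
        raise ValueError(
            f"unknown consequence term {term!r}; accepted terms: "
            f"{sorted(VOCABULARY)}"
        )
    return term


@dataclass(frozen=True)
class ClassAssignment:
    variant_id: str
    class1: bool
    class2: bool
    class3: bool


def classify(variant_id: str, consequence: str,
             condel_label: Optional[str] = None) -> ClassAssignment:
    """Assign the nested severity classes for one variant."""
    term = normalize_consequence(consequence)
    c1 = term in DISRUPTIVE
    c2 = c1 or term in ESSENTIAL_SPLICE or (
        term == "missense" and condel_label == "damaging")
    c3 = term in NON_SILENT
    # class 2 terms are all non-silent, so nesting holds by construction
    return ClassAssignment(variant_id, c1, c2, c3)


def classify_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`classify` over an annotation table.

    Returns a DataFrame indexed like ``variants`` with boolean columns
    ``class1``/``class2``/``class3``.
    """
    term = variants["consequence"].map(normalize_consequence)
    condel = variants["condel_label"]
    c1 = term.isin(DISRUPTIVE)
    c2 = c1 | term.isin(ESSENTIAL_SPLICE) | (
        (term == "missense") & (condel == "damaging"))
    c3 = term.isin(NON_SILENT)
    return pd.DataFrame({"class1": c1, "class2": c2, "class3": c3},
                        index=variants.index)


# ---------------------------------------------------------------------------
# genotype-level QC
# ---------------------------------------------------------------------------

def balance_chi2(ad_ref, ad_alt):
    """1-df Pearson statistic for departure from a 50/50 allele split."""
    a = np.asarray(ad_ref, dtype=float)
    b = np.asarray(ad_alt, dtype=float)
    total = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(total > 0, (a - b) ** 2 / np.where(total > 0, total, 1), 0.0)
    return chi2


def qc_call(genotype: int, gq, ad_ref, ad_alt, *,
            gq_min: int = GQ_MIN, alt_depth_min: int = ALT_DEPTH_MIN,
            balance_chi2_max: float = BALANCE_CHI2_MAX) -> int:
    """Apply per-call QC to a single genotype; returns the retained genotype
    or :data:`MISSING`.

    Missing GQ/AD fields fail the corresponding check.  Hom-ref and hom-alt
    calls only require GQ; het calls also require alternate depth and allele
    balance.
    """
    if genotype == MISSING:
        return MISSING
    if ad_ref is not None and ad_alt is not None and (ad_ref < 0 or ad_alt < 0):
        raise ValueError("negative allele depth")
    if gq is None or gq < gq_min:
        return MISSING
    if genotype == 1:
        if ad_alt is None or ad_alt < alt_depth_min:
            return MISSING
        if float(balance_chi2(ad_ref, ad_alt)) >= balance_chi2_max:
            return MISSING
    return genotype


def mask_genotypes(genotypes: np.ndarray, gq: Optional[np.ndarray],
                   ad_ref: Optional[np.ndarray], ad_alt: Optional[np.ndarray],
                   *, gq_min: int = GQ_MIN, alt_depth_min: int = ALT_DEPTH_MIN,
                   balance_chi2_max: float = BALANCE_CHI2_MAX) -> np.ndarray:
    """Vectorised :func:`qc_call` over a genotype matrix.

    Returns a new int8 matrix with failing calls set to missing.
    """
    gt = genotypes.copy()
    if gq is None:
        gt[:] = MISSING
        return gt
    if ad_ref is not None and ((ad_ref < 0).any() or (ad_alt < 0).any()):
        raise ValueError("negative allele depth in AD fields")
    fail = gq < gq_min
    het = gt == 1
    if ad_alt is None:
        fail |= het
    else:
        chi2 = balance_chi2(ad_ref[het], ad_alt[het])
        het_fail = (ad_alt[het] < alt_depth_min) | (chi2 >= balance_chi2_max)
        fail[het] |= het_fail
    gt[fail & (gt != MISSING)] = MISSING
    return gt


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def _hwe_midtail(n: int, n_alt: int, n_het_obs: int) -> float:
    """Exact conditional HWE P: total probability of heterozygote counts no
    more probable than the observed one, given n genotyped samples and n_alt
    alternate alleles."""
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor <= 0:
        return 1.0
    # valid het counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # unnormalised log-probabilities of each het count (conditional law)
    from scipy.special import gammaln
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    logp = (hets * np.log(2)
            - gammaln(hom_min + 1) - gammaln(hets + 1) - gammaln(hom_maj + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = np.flatnonzero(hets == n_het_obs)
    if obs.size == 0:
        raise ValueError(
            f"heterozygote count {n_het_obs} impossible for {n_alt} alternate "
            f"alleles in {n} samples")
    p_obs = p[obs[0]]
    return float(p[p <= p_obs * (1 + 1e-12)].sum())


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact test of Hardy–Weinberg equilibrium from genotype counts.

    Sums the conditional probabilities (given allele counts) of all
    heterozygote counts no more probable than the observed count.  A
    monomorphic or all-missing site returns 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_alt = n_het + 2 * n_hom_alt
    return _hwe_midtail(n, n_alt, n_het)


# ---------------------------------------------------------------------------
# site-level filters and MAF stratification
# ---------------------------------------------------------------------------

def _group_stats(gt: np.ndarray, mask: np.ndarray):
    """Call rate, HWE P and alt-allele counts for one phenotype group,
    per variant (columns of ``gt``)."""
    sub = gt[mask]
    n_group = sub.shape[0]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / max(n_group, 1)
    n_het = (sub == 1).sum(axis=0)
    n_hom_alt = (sub == 2).sum(axis=0)
    n_hom_ref = n_called - n_het - n_hom_alt
    hwe = np.fromiter(
        (hwe_exact_test(int(r), int(h), int(a))
         for r, h, a in zip(n_hom_ref, n_het, n_hom_alt)),
        dtype=float, count=gt.shape[1])
    alt_alleles = n_het + 2 * n_hom_alt
    return call_rate, hwe, alt_alleles, 2 * n_called


def fold_maf(alt_freq: float) -> float:
    return min(alt_freq, 1.0 - alt_freq)


def maf_tier(maf_pooled: float, ext_af: Optional[float] = None,
             *, rare_maf: float = RARE_MAF,
             low_freq_maf: float = LOW_FREQ_MAF) -> str:
    """Stratify a folded pooled MAF into rare / low_frequency / common.

    When an external reference frequency is supplied the variant counts as
    rare only if BOTH the cohort MAF and the (folded) external frequency are
    below the rare threshold.
    """
    if maf_pooled < rare_maf:
        if ext_af is not None and not np.isnan(ext_af) \
                and fold_maf(ext_af) >= rare_maf:
            return "low_frequency"
        return "rare"
    if maf_pooled < low_freq_maf:
        return "low_frequency"
    return "common"


@dataclass
class FilteredCohort:
    """QC-masked cohort plus per-variant filter report and class flags."""

    cohort: Cohort
    genotypes: np.ndarray            # masked dosage matrix
    report: pd.DataFrame             # per-variant pass/fail + MAF + tier
    classes: pd.DataFrame            # per-variant class1/2/3 booleans

    def qualifying(self, variant_class: int, tier: str = "rare") -> np.ndarray:
        """Boolean variant mask: passed all site filters, in ``tier``, and in
        the requested severity class."""
        cls = self.classes[f"class{variant_class}"].to_numpy()
        ok = self.report["pass"].to_numpy() & (self.report["tier"] == tier).to_numpy()
        return ok & cls


def apply_filters(cohort: Cohort, *, gq_min: int = GQ_MIN,
                  alt_depth_min: int = ALT_DEPTH_MIN,
                  balance_chi2_max: float = BALANCE_CHI2_MAX,
                  hwe_p_min: float = HWE_P_MIN,
                  call_rate_min: float = CALL_RATE_MIN,
                  rare_maf: float = RARE_MAF,
                  low_freq_maf: float = LOW_FREQ_MAF) -> FilteredCohort:
    """Run the full genotype- and site-level filter chain on a cohort.

    Site failure reasons are recorded in first-failure order:
    tranche, alignability, simple_repeat, hwe, call_rate, no_calls.
    """
    if cohort.n_cases == 0 or cohort.n_controls == 0:
        raise ValueError("cohort must contain at least one case and one control")

    gt = mask_genotypes(cohort.genotypes, cohort.gq, cohort.ad_ref,
                        cohort.ad_alt, gq_min=gq_min,
                        alt_depth_min=alt_depth_min,
                        balance_chi2_max=balance_chi2_max)

    v = cohort.variants
    ca_rate, ca_hwe, ca_alt, ca_chrom = _group_stats(gt, cohort.case_mask)
    co_rate, co_hwe, co_alt, co_chrom = _group_stats(gt, cohort.control_mask)

    with np.errstate(invalid="ignore", divide="ignore"):
        maf_cases = np.where(ca_chrom > 0, ca_alt / np.maximum(ca_chrom, 1), np.nan)
        maf_controls = np.where(co_chrom > 0, co_alt / np.maximum(co_chrom, 1), np.nan)
        pooled_chrom = ca_chrom + co_chrom
        pooled = np.where(pooled_chrom > 0,
                          (ca_alt + co_alt) / np.maximum(pooled_chrom, 1), np.nan)
    maf_cases = np.minimum(maf_cases, 1 - maf_cases)
    maf_controls = np.minimum(maf_controls, 1 - maf_controls)
    maf_pooled = np.minimum(pooled, 1 - pooled)

    n_var = cohort.n_variants
    reason = np.full(n_var, "", dtype=object)

    def mark(mask, label):
        fresh = mask & (reason == "")
        reason[fresh] = label

    mark(v["tranche_fail"].to_numpy().astype(bool), "tranche")
    mark(v["alignability"].to_numpy() != 1, "alignability")
    mark(v["simple_repeat"].to_numpy().astype(bool), "simple_repeat")
    mark((ca_hwe <= hwe_p_min) | (co_hwe <= hwe_p_min), "hwe")
    mark((ca_rate < call_rate_min) | (co_rate < call_rate_min), "call_rate")
    mark(pooled_chrom == 0, "no_calls")
    passed = reason == ""

    ext = v["ext_af"].to_numpy(dtype=float)
    tier = np.array([
        maf_tier(m, e, rare_maf=rare_maf, low_freq_maf=low_freq_maf)
        if np.isfinite(m) else "excluded"
        for m, e in zip(maf_pooled, ext)
    ], dtype=object)

    report = pd.DataFrame({
        "variant_id": v["variant_id"].to_numpy(),
        "pass": passed,
        "first_fail_reason": reason,
        "maf_cases": maf_cases,
        "maf_controls": maf_controls,
        "maf_pooled": maf_pooled,
        "tier": tier,
    })
    classes = classify_variants(v)
    return FilteredCohort(cohort=cohort, genotypes=gt, report=report,
                          classes=classes)
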