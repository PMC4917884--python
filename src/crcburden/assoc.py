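"""Per-variant association tests and cross-cohort meta-analysis.

Single variants are tested with a two-sided Fisher exact test on the 2x2
allele-count table.  Gene-level burden evidence from independent cohorts is
combined with the sample-size-weighted Z-score (Stouffer) method, weighting
each study by the square root of its effective sample size
``4 / (1/N_cases + 1/N_controls)`` — the balanced-design equivalent N for a
case/control study.  An inverse-variance fixed-effects combiner is provided
for single-variant meta-analysis with external array cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm

from .varfilter import FilteredCohort

SINGLE_VARIANT_ALPHA = 4.0e-7


@dataclass
class VariantAssocResult:
    variant_id: str
    case_alt: int
    case_ref: int
    control_alt: int
    control_ref: int
    odds_ratio: float        # nan when undefined (empty margin)
    p_value: float


@dataclass(frozen=True)
class MetaInput:
    """One study's one-sided P and its cohort sizes."""
    p: float
    n_cases: int
    n_controls: int

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"P must lie in (0,1), got {self.p}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be >= 1")


def fisher_variant_test(case_alt: int, case_ref: int, control_alt: int,
                        control_ref: int,
                        variant_id: str = "") -> VariantAssocResult:
    """Two-sided Fisher exact test on an allele-count 2x2 table.

    The odds ratio is the cross-product ratio; when a zero cell makes it
    degenerate, a 0.5 continuity correction is applied for display.  An empty
    margin (no alternate or no reference alleles at all) gives P = 1 and an
    undefined (NaN) odds ratio.
    """
    table = np.array([[case_alt, case_ref], [control_alt, control_ref]])
    if (table < 0).any():
        raise ValueError("negative allele counts")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return VariantAssocResult(variant_id, case_alt, case_ref,
                                  control_alt, control_ref, np.nan, 1.0)
    _, p = fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        t = table + 0.5
        oratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    else:
        oratio = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return VariantAssocResult(variant_id, case_alt, case_ref, control_alt,
                              control_ref, float(oratio), float(p))


def variant_scan(fc: FilteredCohort, tiers: Sequence[str] = ("low_frequency", "common"),
                 alpha: float = SINGLE_VARIANT_ALPHA) -> pd.DataFrame:
    """Per-variant Fisher scan over site-passing variants in the given MAF
    tiers (each alternate allele is one decomposed record)."""
    keep = fc.report["pass"].to_numpy() & fc.report["tier"].isin(tiers).to_numpy()
    gt = fc.genotypes
    case = fc.cohort.case_mask
    rows = []
    for j in np.flatnonzero(keep):
        for mask, pre in ((case, "case"), (~case, "control")):
            g = gt[mask, j]
            called = g >= 0
            alt = int(g[called].sum())
            ref = int(2 * called.sum() - alt)
            if pre == "case":
                ca_alt, ca_ref = alt, ref
            else:
                co_alt, co_ref = alt, ref
        res = fisher_variant_test(ca_alt, ca_ref, co_alt, co_ref,
                                  fc.cohort.variants["variant_id"].iat[j])
        rows.append((res.variant_id, ca_alt, ca_ref, co_alt, co_ref,
                     res.odds_ratio, res.p_value, res.p_value <= alpha))
    return pd.DataFrame(rows, columns=[
        "variant_id", "case_alt", "case_ref", "control_alt", "control_ref",
        "odds_ratio", "p_value", "significant"])


def effective_n(n_cases: int, n_controls: int) -> float:
    """Balanced-design equivalent sample size, ``4/(1/Nca + 1/Nco)``."""
    if n_cases < 1 or n_controls < 1:
        raise ValueError("cohort sizes must be >= 1")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def stouffer_meta(inputs: Sequence[MetaInput]) -> float:
    """Sample-size-weighted Z-score combination of one-sided P-values.

    ``z_i`` is the upper-tail normal quantile of ``P_i``; weights are
    ``sqrt(effective_n_i)``; the combined ``Z = sum(w z) / sqrt(sum w^2)`` is
    returned as its upper-tail probability.
    """
    if not inputs:
        raise ValueError("at least one study required")
    z = np.array([norm.isf(s.p) for s in inputs])
    w = np.sqrt([effective_n(s.n_cases, s.n_controls) for s in inputs])
    Z = float(np.dot(w, z) / np.sqrt(np.dot(w, w)))
    return float(norm.sf(Z))


def fixed_effects_meta(log_or: Sequence[float], se: Sequence[float]):
    """Inverse-variance fixed-effects pooling of per-cohort log odds ratios.

    Cohorts with non-finite standard errors are dropped with a warning.
    Returns ``(pooled_or, pooled_se, two_sided_p)``.
    """
    lo = np.asarray(log_or, dtype=float)
    s = np.asarray(se, dtype=float)
    ok = np.isfinite(lo) & np.isfinite(s) & (s > 0)
    if ok.sum() < len(lo):
        warnings.warn(f"dropping {len(lo) - int(ok.sum())} cohort(s) with "
                      "non-finite effect or SE")
    if ok.sum() < 1:
        raise ValueError("no cohort with finite effect and SE")
    w = 1.0 / s[ok] ** 2
    pooled = float(np.sum(w * lo[ok]) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    z = pooled / pooled_se
    p = 2.0 * float(norm.sf(abs(z)))
    return float(np.exp(pooled)), pooled_se, p


def meta_burden(discovery: pd.DataFrame, replication: pd.DataFrame,
                gate_p: float = 0.05, variant_class: int = 1) -> pd.DataFrame:
    """Replication meta-analysis of gene-burden results across two cohorts.

    Genes with class-``variant_class`` mid-P below ``gate_p`` in the discovery
    screen are combined with the replication cohort by :func:`stouffer_meta`.
    Rows of either table must carry ``gene, variant_class, case_carriers,
    control_carriers, n_cases, n_controls, p_exact``.
    """
    disc = discovery[discovery["variant_class"] == variant_class]
    repl = replication[replication["variant_class"] == variant_class]
    disc = disc[disc["p_exact"] < gate_p]
    repl = repl.set_index("gene")
    rows = []
    for _, d in disc.iterrows():
        gene = d["gene"]
        if gene not in repl.index:
            continue
        r = repl.loc[gene]
        # clamp the degenerate P=1 edge for the normal quantile
        eps = 1e-12
        p_meta = stouffer_meta([
            MetaInput(min(max(d["p_exact"], eps), 1 - eps),
                      int(d["n_cases"]), int(d["n_controls"])),
            MetaInput(min(max(r["p_exact"], eps), 1 - eps),
                      int(r["n_cases"]), int(r["n_controls"])),
        ])
        rows.append((gene, d["case_carriers"], d["control_carriers"],
                     d["p_exact"], r["case_carriers"], r["control_carriers"],
                     r["p_exact"], p_meta))
    out = pd.DataFrame(rows, columns=[
        "gene", "disc_case_carriers", "disc_control_carriers", "disc_p",
        "repl_case_carriers", "repl_control_carriers", "repl_p", "p_meta"])
    return out.sort_values("p_meta", kind="stable").reset_index(drop=True)
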