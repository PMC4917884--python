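"""Gene-level collapsing burden test (T1) with exact mid-P and permutation null.

The T1 statistic for a gene is the number of case samples carrying at least
one qualifying rare allele in that gene.  Under permutation of case/control
labels with the carrier set held fixed, the case-carrier count follows a
hypergeometric law, so the one-sided (case-enrichment) permutation P-value has
the closed form

    P = P(X > k) + 0.5 * P(X = k),    X ~ Hypergeom(N, K, n_cases)

with ``K`` total carriers among ``N`` samples and half weight on ties (mid-P).
The Monte-Carlo estimator in :func:`permutation_pvalue` samples the same law
directly and is provided both for fidelity to a permutation protocol and for
adaptive refinement of small P-values.

The module also implements the known-gene bookkeeping of a predisposition
screen: removing cases attributable to established high-penetrance genes
before searching for novel associations, and attributing case fractions to
known genes per severity class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .cohort import Cohort
from .varfilter import FilteredCohort

EXOME_WIDE_ALPHA = 8.0e-7          # Bonferroni-style: ~20,000 genes x 3 classes
PERM_STAGE1 = 100_000
PERM_STAGE2 = 2_000_000
PERM_REFINE_P = 0.01
PERM_CEILING = 50_000_000


@dataclass(frozen=True)
class KnownGeneConfig:
    """Established predisposition genes and optional curated pathogenic variants."""

    genes: tuple
    curated_variants: tuple = ()

    def __post_init__(self):
        if not self.genes:
            raise ValueError("known-gene list must be non-empty")


@dataclass
class GeneBurdenResult:
    gene: str
    variant_class: int
    variant_ids: list
    case_carriers: int
    control_carriers: int
    n_cases: int
    n_controls: int
    p_exact: float
    p_perm: Optional[float] = None
    n_perm: int = 0


def exact_midp(case_carriers, control_carriers, n_cases, n_controls):
    """One-sided mid-P of the carrier-collapsing test (enrichment in cases).

    Accepts scalars or broadcastable arrays.  ``K = 0`` carriers returns 1.
    """
    k = np.asarray(case_carriers)
    m = np.asarray(control_carriers)
    if np.any(k < 0) or np.any(m < 0):
        raise ValueError("carrier counts must be non-negative")
    if np.any(k > n_cases) or np.any(m > n_controls):
        raise ValueError("carrier counts exceed cohort sizes")
    K = k + m
    N = n_cases + n_controls
    p = hypergeom.sf(k, N, K, n_cases) + 0.5 * hypergeom.pmf(k, N, K, n_cases)
    p = np.where(K == 0, 1.0, p)
    return float(p) if p.ndim == 0 else p


def permutation_pvalue(case_carriers: int, control_carriers: int,
                       n_cases: int, n_controls: int,
                       n_perm: int = PERM_STAGE1, seed=0,
                       adaptive: bool = True):
    """Monte-Carlo label-permutation mid-P for the carrier-collapsing test.

    Case/control labels are permuted with the carrier set held fixed; the
    case-carrier count under one permutation is drawn directly from its exact
    permutation distribution (hypergeometric).  The estimator puts half weight
    on permutations tying the observed statistic.  With ``adaptive`` the
    schedule refines any P below :data:`PERM_REFINE_P` with an additional
    2e6 permutations and reports the combined estimate.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm > PERM_CEILING:
        raise ValueError(f"n_perm exceeds ceiling {PERM_CEILING}")
    K = case_carriers + control_carriers
    N = n_cases + n_controls
    if K == 0:
        return 1.0, n_perm       # untestable gene, same convention as exact_midp
    rng = np.random.default_rng(seed)

    def draw(n):
        if K == 0:
            return np.zeros(n, dtype=np.int64)
        return rng.hypergeometric(K, N - K, n_cases, size=n)

    stats = draw(n_perm)
    exceed = float((stats > case_carriers).sum())
    ties = float((stats == case_carriers).sum())
    used = n_perm
    p = (exceed + 0.5 * ties) / used
    if adaptive and p < PERM_REFINE_P and used + PERM_STAGE2 <= PERM_CEILING:
        extra = draw(PERM_STAGE2)
        exceed += float((extra > case_carriers).sum())
        ties += float((extra == case_carriers).sum())
        used += PERM_STAGE2
        p = (exceed + 0.5 * ties) / used
    return p, used


# ---------------------------------------------------------------------------
# carrier counting
# ---------------------------------------------------------------------------

def _gene_carrier_matrix(genotypes: np.ndarray, gene_of_variant: np.ndarray,
                         variant_mask: np.ndarray):
    """Per-sample, per-gene carrier booleans over the masked qualifying set.

    Returns ``(genes, carriers)`` where ``carriers`` is an
    (n_samples, n_genes) boolean array aligned with ``genes``.
    """
    idx = np.flatnonzero(variant_mask)
    if idx.size == 0:
        return np.array([], dtype=object), np.zeros((genotypes.shape[0], 0), bool)
    genes = gene_of_variant[idx]
    order = np.argsort(genes, kind="stable")
    idx = idx[order]
    genes_sorted = genes[order]
    boundaries = np.flatnonzero(
        np.r_[True, genes_sorted[1:] != genes_sorted[:-1]])
    carrier = genotypes[:, idx] > 0          # missing (-1) is not a carrier
    per_gene = np.logical_or.reduceat(carrier, boundaries, axis=1)
    return genes_sorted[boundaries], per_gene


def t1_counts(gene: str, variant_class: int, fc: FilteredCohort,
              tier: str = "rare"):
    """Case/control carrier counts for one gene and severity class.

    A sample is one carrier if it holds >= 1 non-missing alternate allele
    across the gene's qualifying variants.  Returns
    ``(case_carriers, control_carriers, variant_ids)``.
    """
    qual = fc.qualifying(variant_class, tier)
    gene_mask = qual & (fc.cohort.variants["gene"].to_numpy() == gene)
    ids = list(fc.cohort.variants.loc[gene_mask, "variant_id"])
    if not ids:
        return 0, 0, []
    carrier = (fc.genotypes[:, gene_mask] > 0).any(axis=1)
    return (int(carrier[fc.cohort.case_mask].sum()),
            int(carrier[fc.cohort.control_mask].sum()), ids)


def exome_wide_screen(fc: FilteredCohort, classes: Sequence[int] = (1, 2, 3),
                      alpha: float = EXOME_WIDE_ALPHA, tier: str = "rare",
                      permute: bool = False, seed=0) -> pd.DataFrame:
    """T1 screen of every gene x severity class.

    Returns a table sorted by exact mid-P with an exome-wide-significance
    flag at ``alpha``.  With ``permute`` the adaptive Monte-Carlo estimate is
    added for each gene (stage-1 permutations, refined when P < 0.01).
    """
    gene_of_variant = fc.cohort.variants["gene"].to_numpy()
    all_genes = np.unique(gene_of_variant)
    n_ca, n_co = fc.cohort.n_cases, fc.cohort.n_controls
    case_mask = fc.cohort.case_mask
    frames = []
    for cls in classes:
        genes, carrier = _gene_carrier_matrix(
            fc.genotypes, gene_of_variant, fc.qualifying(cls, tier))
        k_case = carrier[case_mask].sum(axis=0).astype(np.int64)
        k_ctrl = carrier[~case_mask].sum(axis=0).astype(np.int64)
        qual = fc.qualifying(cls, tier)
        n_var = pd.Series(gene_of_variant[qual]).value_counts()
        tested = pd.DataFrame({
            "gene": genes,
            "variant_class": cls,
            "n_variants": n_var.reindex(genes).fillna(0).astype(int).to_numpy(),
            "case_carriers": k_case,
            "control_carriers": k_ctrl,
        })
        absent = np.setdiff1d(all_genes, genes)
        if absent.size:
            tested = pd.concat([tested, pd.DataFrame({
                "gene": absent, "variant_class": cls, "n_variants": 0,
                "case_carriers": 0, "control_carriers": 0})],
                ignore_index=True)
        frames.append(tested)
    out = pd.concat(frames, ignore_index=True)
    out["n_cases"] = n_ca
    out["n_controls"] = n_co
    out["p_exact"] = exact_midp(out["case_carriers"].to_numpy(),
                                out["control_carriers"].to_numpy(), n_ca, n_co)
    if permute:
        rng = np.random.default_rng(seed)
        perms = [
            permutation_pvalue(kc, kk, n_ca, n_co,
                               seed=rng.integers(2**31))
            for kc, kk in zip(out["case_carriers"], out["control_carriers"])
        ]
        out["p_perm"] = [p for p, _ in perms]
        out["n_perm"] = [n for _, n in perms]
    out["significant"] = out["p_exact"] <= alpha
    return out.sort_values(["p_exact", "gene", "variant_class"],
                           kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# known-gene bookkeeping
# ---------------------------------------------------------------------------

def _known_carrier_mask(fc: FilteredCohort, known: KnownGeneConfig) -> np.ndarray:
    """Samples carrying a disruptive (class 1) variant in a known gene or any
    curated pathogenic variant."""
    v = fc.cohort.variants
    known_c1 = (fc.classes["class1"].to_numpy()
                & v["gene"].isin(known.genes).to_numpy())
    curated = v["variant_id"].isin(known.curated_variants).to_numpy()
    mask = known_c1 | curated
    if not mask.any():
        return np.zeros(fc.cohort.n_samples, dtype=bool)
    return (fc.genotypes[:, mask] > 0).any(axis=1)


def reduce_cases(fc: FilteredCohort, known: KnownGeneConfig):
    """Remove cases attributable to established predisposition genes.

    A case is removed when it carries a class-1 variant in a known gene or a
    variant on the curated pathogenic list; controls are untouched.  Returns
    ``(reduced FilteredCohort, removal ledger DataFrame)``.
    """
    hit = _known_carrier_mask(fc, known)
    remove = hit & fc.cohort.case_mask
    v = fc.cohort.variants
    flag = (fc.classes["class1"].to_numpy() & v["gene"].isin(known.genes).to_numpy()) \
        | v["variant_id"].isin(known.curated_variants).to_numpy()
    rows = []
    sample_ids = fc.cohort.samples["sample_id"].to_numpy()
    for s in np.flatnonzero(remove):
        carried = np.flatnonzero((fc.genotypes[s] > 0) & flag)
        for j in carried:
            rows.append((sample_ids[s], v["gene"].iat[j], v["variant_id"].iat[j]))
    ledger = pd.DataFrame(rows, columns=["sample_id", "gene", "variant_id"])
    keep = ~remove
    reduced = Cohort(
        genotypes=fc.cohort.genotypes[keep],
        variants=v,
        samples=fc.cohort.samples.loc[keep].reset_index(drop=True),
        truth=fc.cohort.truth,
    )
    reduced_fc = FilteredCohort(cohort=reduced, genotypes=fc.genotypes[keep],
                                report=fc.report, classes=fc.classes)
    return reduced_fc, ledger


def attribute_cases(fc: FilteredCohort, known: KnownGeneConfig,
                    tier: str = "rare") -> dict:
    """Fraction of cases carrying >= 1 qualifying known-gene variant, per
    severity tier (1, 2, 3, and 3 plus curated variants of any consequence).

    Fractions are monotone non-decreasing across tiers because the classes
    are nested.
    """
    v = fc.cohort.variants
    in_known = v["gene"].isin(known.genes).to_numpy()
    ok = fc.report["pass"].to_numpy() & (fc.report["tier"] == tier).to_numpy()
    curated = v["variant_id"].isin(known.curated_variants).to_numpy()
    case_mask = fc.cohort.case_mask
    n_cases = case_mask.sum()
    out = {}
    for label, extra in (("class1", None), ("class2", None),
                         ("class3", None), ("class3_plus_curated", curated)):
        cls = label.replace("_plus_curated", "")
        qual = fc.classes[cls].to_numpy() & ok & in_known
        # curated variants count regardless of tier/consequence (manual rescue)
        if extra is not None:
            qual = qual | curated
        if qual.any():
            carrier = (fc.genotypes[:, qual] > 0).any(axis=1)
            frac = float(carrier[case_mask].sum()) / n_cases
        else:
            frac = 0.0
        out[label] = frac
    return out
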