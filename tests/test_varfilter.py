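"""Variant classification, genotype/site QC and MAF stratification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crcburden import varfilter as vf
from crcburden.cohort import MISSING

from conftest import make_cohort, make_filtered


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("consequence,condel,expected", [
    ("stop_gained", "NA", (True, True, True)),
    ("frameshift", "NA", (True, True, True)),
    ("frameshift_variant", "NA", (True, True, True)),   # raw-term mapping
    ("missense", "damaging", (False, True, True)),
    ("missense", "tolerated", (False, False, True)),
    ("splice_acceptor", "NA", (False, True, True)),
    ("splice_donor", "NA", (False, True, True)),
    ("splice_region", "NA", (False, False, True)),
    ("inframe_deletion", "NA", (False, False, True)),
    ("stop_lost", "NA", (False, False, True)),
    ("synonymous", "NA", (False, False, False)),
])
def test_classify_examples(consequence, condel, expected):
    a = vf.classify("v", consequence, condel)
    assert (a.class1, a.class2, a.class3) == expected


def test_classify_rejects_unknown_term():
    with pytest.raises(ValueError, match="accepted terms"):
        vf.classify("v", "intergenic")


@given(term=st.sampled_from(sorted(vf.VOCABULARY)),
       condel=st.sampled_from(["damaging", "tolerated", "NA"]))
@settings(max_examples=60, deadline=None)
def test_class_nesting(term, condel):
    a = vf.classify("v", term, condel)
    assert (not a.class1 or a.class2) and (not a.class2 or a.class3)


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("gt,gq,ad,expected", [
    (1, 99, (12, 10), 1),        # chi2 = 4/22 = 0.18 < 10.83
    (1, 99, (50, 10), MISSING),  # chi2 = 1600/60 = 26.7
    (0, 25, (40, 0), MISSING),   # GQ < 30
    (0, 30, (40, 0), 0),
    (1, 99, (40, 2), MISSING),   # alt depth < 3
    (2, 45, (0, 40), 2),
    (MISSING, 99, (20, 20), MISSING),
])
def test_qc_call(gt, gq, ad, expected):
    assert vf.qc_call(gt, gq, ad[0], ad[1]) == expected


def test_qc_call_negative_depth_raises():
    with pytest.raises(ValueError, match="negative"):
        vf.qc_call(1, 99, -1, 10)


def test_mask_genotypes_matches_scalar_qc(rng):
    gt = rng.integers(-1, 3, size=(30, 20)).astype(np.int8)
    gq = rng.integers(0, 100, size=gt.shape).astype(np.int16)
    depth = rng.poisson(40, size=gt.shape).astype(np.int16)
    ad_alt = rng.binomial(depth, 0.5).astype(np.int16)
    ad_ref = (depth - ad_alt).astype(np.int16)
    masked = vf.mask_genotypes(gt, gq, ad_ref, ad_alt)
    for s in range(gt.shape[0]):
        for j in range(gt.shape[1]):
            assert masked[s, j] == vf.qc_call(
                int(gt[s, j]), int(gq[s, j]), int(ad_ref[s, j]),
                int(ad_alt[s, j]))


def test_masking_monotone_in_gq_threshold(rng):
    gt = rng.integers(-1, 3, size=(50, 30)).astype(np.int8)
    gq = rng.integers(0, 100, size=gt.shape).astype(np.int16)
    ad_alt = np.where(gt == 1, 20, 0).astype(np.int16)
    ad_ref = np.where(gt == 2, 0, 20).astype(np.int16)
    retained = [
        (vf.mask_genotypes(gt, gq, ad_ref, ad_alt, gq_min=t) != MISSING).sum()
        for t in (0, 20, 30, 50, 90)]
    assert retained == sorted(retained, reverse=True)


def test_masking_idempotent(rng):
    gt = rng.integers(-1, 3, size=(40, 25)).astype(np.int8)
    gq = rng.integers(0, 100, size=gt.shape).astype(np.int16)
    ad_alt = rng.integers(0, 30, size=gt.shape).astype(np.int16)
    ad_ref = rng.integers(0, 30, size=gt.shape).astype(np.int16)
    once = vf.mask_genotypes(gt, gq, ad_ref, ad_alt)
    twice = vf.mask_genotypes(once, gq, ad_ref, ad_alt)
    assert np.array_equal(once, twice)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Enumerate every assignment of the alternate alleles over 2n ordered
    allele slots; genotypes are consecutive slot pairs.  The HWE P is the
    total probability of heterozygote counts no more probable than observed.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    slots = 2 * n
    counts = {}
    for alt_pos in itertools.combinations(range(slots), n_alt):
        alt = set(alt_pos)
        hets = sum((2 * i in alt) != (2 * i + 1 in alt) for i in range(n))
        counts[hets] = counts.get(hets, 0) + 1
    total = sum(counts.values())
    p_obs = counts[n_het] / total
    return sum(c for h, c in counts.items()
               if c / total <= p_obs * (1 + 1e-12)) / total


@pytest.mark.parametrize("counts", [
    (5, 0, 0), (1, 0, 1), (2, 1, 1), (1, 2, 1), (3, 2, 0),
    (4, 1, 1), (0, 4, 0), (2, 2, 2),
])
def test_hwe_matches_enumeration(counts):
    assert vf.hwe_exact_test(*counts) == pytest.approx(_hwe_oracle(*counts))


def _hwe_comb_oracle(n_hom_ref, n_het, n_hom_alt):
    """Closed-form conditional law via integer combinatorics (math.comb):
    the number of ordered-allele arrangements giving h hets is
    C(n, r, h, a) * 2^h * na! * (2n - na)!, normalised over valid h."""
    from math import comb, factorial
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        weights[h] = (factorial(n) // (factorial(hom_min) * factorial(h)
                                       * factorial(hom_maj))) * 2 ** h
    total = sum(weights.values())
    p_obs = weights[n_het] / total
    return sum(w for w in weights.values()
               if w / total <= p_obs * (1 + 1e-12)) / total


@pytest.mark.parametrize("counts", [
    (5, 10, 5), (40, 5, 1), (100, 1, 0), (10, 0, 10), (50, 50, 50),
])
def test_hwe_matches_comb_formula_moderate_n(counts):
    assert vf.hwe_exact_test(*counts) == pytest.approx(
        _hwe_comb_oracle(*counts), rel=1e-9)


def test_hwe_enumeration_exhaustive_small():
    for n in range(1, 6):
        for n_alt in range(0, 2 * n + 1):
            for het in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
                hom_alt = (n_alt - het) // 2
                hom_ref = n - het - hom_alt
                got = vf.hwe_exact_test(hom_ref, het, hom_alt)
                assert got == pytest.approx(_hwe_oracle(hom_ref, het, hom_alt))
                assert 0 < got <= 1


def test_hwe_monomorphic_and_empty():
    assert vf.hwe_exact_test(10, 0, 0) == 1.0
    assert vf.hwe_exact_test(0, 0, 0) == 1.0
    with pytest.raises(ValueError):
        vf.hwe_exact_test(-1, 0, 0)


# ---------------------------------------------------------------------------
# MAF stratification
# ---------------------------------------------------------------------------

def test_maf_tier_boundaries():
    assert vf.maf_tier(5 / 5230) == "rare"                 # ~0.000956
    assert vf.maf_tier(0.39) == "common"
    assert vf.maf_tier(vf.fold_maf(0.97)) == "low_frequency"   # folds to 0.03
    assert vf.maf_tier(0.01) == "low_frequency"
    assert vf.maf_tier(0.05) == "common"


def test_maf_external_reference_and_rule():
    # rare in-cohort but common in the external reference: not rare
    assert vf.maf_tier(0.001, ext_af=0.05) == "low_frequency"
    assert vf.maf_tier(0.001, ext_af=0.002) == "rare"
    assert vf.maf_tier(0.001, ext_af=np.nan) == "rare"
    assert vf.maf_tier(0.001, ext_af=0.995) == "rare"      # ext folds to 0.005


# ---------------------------------------------------------------------------
# site filters (through the full chain)
# ---------------------------------------------------------------------------

def _chain_cohort(**kw):
    # 4 samples x 3 variants in 2 genes, all calls clean unless overridden
    gt = [[1, 0, 0], [0, 1, 0], [0, 0, 0], [0, 0, 1]]
    return make_cohort(gt, ["GA", "GA", "GB"],
                       ["stop_gained", "missense", "synonymous"],
                       ["case", "case", "control", "control"], **kw)


def test_site_filter_alignability():
    fc = vf.apply_filters(_chain_cohort(alignability=np.array([0.5, 1, 1])))
    assert not fc.report["pass"][0]
    assert fc.report["first_fail_reason"][0] == "alignability"
    assert fc.report["pass"][1:].all()


def test_site_filter_tranche_precedes_alignability():
    fc = vf.apply_filters(_chain_cohort(
        alignability=np.array([0.5, 1, 1]), tranche_fail=np.array([1, 0, 0])))
    assert fc.report["first_fail_reason"][0] == "tranche"


def test_site_filter_call_rate_per_group():
    # 10 cases, 10 controls; variant 0 missing in 4/10 controls (rate 0.6)
    gt = np.zeros((20, 2), dtype=np.int8)
    gt[10:14, 0] = MISSING
    gt[0, 1] = 1
    fc = vf.apply_filters(make_cohort(
        gt, ["GA", "GB"], ["missense", "missense"],
        ["case"] * 10 + ["control"] * 10))
    assert fc.report["first_fail_reason"][0] == "call_rate"
    assert fc.report["pass"][1]


def test_site_filter_hwe():
    # 16 hom-ref + 16 hom-alt cases, zero hets: extreme HWE departure
    gt = np.zeros((33, 1), dtype=np.int8)
    gt[:16, 0] = 2
    assert vf.hwe_exact_test(16, 0, 16) < 1e-8
    fc = vf.apply_filters(make_cohort(
        gt, ["GA"], ["missense"], ["case"] * 32 + ["control"]))
    assert fc.report["first_fail_reason"][0] == "hwe"


def test_every_variant_reported_once():
    fc = make_filtered([[1, 0, 0], [0, 1, 0]], ["GA", "GA", "GB"],
                       ["stop_gained", "missense", "synonymous"],
                       ["case", "control"])
    assert len(fc.report) == 3
    assert fc.report["variant_id"].is_unique
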