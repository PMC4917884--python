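import numpy as np
import pandas as pd
import pytest

from crcburden.cohort import Cohort
from crcburden import varfilter


def make_cohort(genotypes, genes, consequences, statuses,
                condel=None, ext_af=None, alignability=None,
                simple_repeat=None, tranche_fail=None, clean_qc=True):
    """Hand-build a small cohort with clean (passing) QC fields by default.

    ``genotypes`` is (n_samples, n_variants) with -1 for missing.
    """
    gt = np.asarray(genotypes, dtype=np.int8)
    n_s, n_v = gt.shape
    condel = condel or ["NA"] * n_v
    variants = pd.DataFrame({
        "variant_id": [f"chr1:{1000 + i * 100}:A:T" for i in range(n_v)],
        "chrom": "chr1",
        "pos": [1000 + i * 100 for i in range(n_v)],
        "ref": "A", "alt": "T",
        "gene": genes,
        "consequence": consequences,
        "condel_label": condel,
        "alignability": alignability if alignability is not None else np.ones(n_v),
        "simple_repeat": simple_repeat if simple_repeat is not None else np.zeros(n_v, int),
        "tranche_fail": tranche_fail if tranche_fail is not None else np.zeros(n_v, int),
        "ext_af": ext_af if ext_af is not None else np.full(n_v, np.nan),
    })
    samples = pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(n_s)],
        "status": statuses,
        "cohort": "TEST",
        "n_affected_fdr": [1 if s == "case" else 0 for s in statuses],
    })
    kw = {}
    if clean_qc:
        kw["gq"] = np.full(gt.shape, 99, dtype=np.int16)
        ad_alt = np.where(gt == 1, 24, np.where(gt == 2, 48, 0)).astype(np.int16)
        kw["ad_ref"] = (48 - ad_alt).astype(np.int16)
        kw["ad_alt"] = ad_alt
    return Cohort(genotypes=gt, variants=variants, samples=samples, **kw)


def make_filtered(genotypes, genes, consequences, statuses,
                  rare_maf=0.4, low_freq_maf=0.45, **kw):
    """Filtered toy cohort; the rare tier is widened so that hand-built
    carrier configurations (which have large allele fractions at tiny n)
    stay in scope of the burden test.  MAF tier boundaries themselves are
    unit-tested separately at the study thresholds."""
    cohort = make_cohort(genotypes, genes, consequences, statuses, **kw)
    return varfilter.apply_filters(cohort, rare_maf=rare_maf,
                                   low_freq_maf=low_freq_maf)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20161122)
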