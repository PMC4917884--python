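"""Synthetic cohort generator: determinism, planted structure, round trips."""

import numpy as np
import pytest

from crcburden import cohortgen, pipeline_io, varfilter
from crcburden.cohortgen import CohortSpec, PlantedGene, generate_cohort, write_cohort


def test_identical_seed_identical_output():
    spec = CohortSpec(n_cases=50, n_controls=60, n_genes=30, seed=7,
                      planted_genes=(PlantedGene("RISK1", 2, 2.5),),
                      known_gene_carriers=0.1, recessive_gene="REC1")
    a, b = generate_cohort(spec), generate_cohort(spec)
    assert np.array_equal(a.genotypes, b.genotypes)
    assert np.array_equal(a.gq, b.gq)
    assert np.array_equal(a.ad_alt, b.ad_alt)
    assert a.variants.equals(b.variants)
    assert a.truth == b.truth


def test_different_seed_differs():
    s1 = CohortSpec(n_cases=50, n_controls=60, n_genes=30, seed=1)
    s2 = CohortSpec(n_cases=50, n_controls=60, n_genes=30, seed=2)
    assert not np.array_equal(generate_cohort(s1).genotypes,
                              generate_cohort(s2).genotypes)


@pytest.mark.parametrize("field,kw", [
    ("class_probs", dict(class_probs=(0.4, 0.2, 0.2, 0.1))),
    ("fh_weights", dict(fh_weights=(0.5, 0.2, 0.2))),
    ("baseline_carrier_freq", dict(baseline_carrier_freq=0.2)),
    ("known_gene_carriers", dict(known_gene_carriers=1.5)),
    ("planted_genes", dict(planted_genes=(PlantedGene("X", 4, 2.0),))),
    ("planted_genes", dict(planted_genes=(PlantedGene("MLH1", 1, 2.0),))),
])
def test_invalid_spec_raises_naming_field(field, kw):
    with pytest.raises(ValueError, match=field.split("_")[0]):
        CohortSpec(n_cases=10, n_controls=10, n_genes=20, **kw).validate()


def test_rr_one_plants_no_enrichment():
    spec = CohortSpec(n_cases=100, n_controls=100, n_genes=20, seed=3,
                      planted_genes=(PlantedGene("RISK1", 1, 1.0),))
    truth = generate_cohort(spec).truth["planted"]["RISK1"]
    assert truth["expected_case_freq"] == pytest.approx(
        truth["expected_control_freq"])


def test_planted_carrier_frequency_recovery():
    """RR=3 planted gene: observed case carrier fraction matches the
    family-history-weighted enrichment model within 3 binomial s.e."""
    spec = CohortSpec(n_cases=1000, n_controls=1000, n_genes=200, seed=11,
                      planted_genes=(PlantedGene("RISK1", 2, 3.0),),
                      missing_frac=0.0, gq_fail_frac=0.0)
    coh = generate_cohort(spec)
    truth = coh.truth["planted"]["RISK1"]
    cls = varfilter.classify_variants(coh.variants)
    qual = (cls["class2"].to_numpy()
            & (coh.variants["gene"] == "RISK1").to_numpy())
    carrier = (coh.genotypes[:, qual] > 0).any(axis=1)
    f_case = carrier[coh.case_mask].mean()
    f_ctrl = carrier[coh.control_mask].mean()
    for obs, exp in ((f_case, truth["expected_case_freq"]),
                     (f_ctrl, truth["expected_control_freq"])):
        se = np.sqrt(exp * (1 - exp) / 1000)
        assert abs(obs - exp) <= 3 * se


def test_at_most_one_carried_variant_per_gene():
    spec = CohortSpec(n_cases=300, n_controls=300, n_genes=100, seed=5,
                      baseline_carrier_freq=0.005, missing_frac=0.0)
    coh = generate_cohort(spec)
    genes = coh.variants["gene"].to_numpy()
    order = np.argsort(genes, kind="stable")
    bounds = np.flatnonzero(np.r_[True, genes[order][1:] != genes[order][:-1]])
    per_gene = np.add.reduceat(coh.genotypes[:, order] > 0, bounds, axis=1)
    assert per_gene.max() <= 1


def test_quality_field_tails():
    spec = CohortSpec(n_cases=200, n_controls=200, n_genes=150, seed=9,
                      gq_fail_frac=0.05, missing_frac=0.03)
    coh = generate_cohort(spec)
    frac_low_gq = (coh.gq < 30).mean()
    assert frac_low_gq == pytest.approx(0.05, abs=0.01)
    frac_missing = (coh.genotypes < 0).mean()
    assert frac_missing == pytest.approx(0.03, abs=0.01)
    # het allele depths center on balance
    het = coh.genotypes == 1
    ratio = coh.ad_alt[het] / (coh.ad_alt[het] + coh.ad_ref[het])
    assert abs(np.median(ratio) - 0.5) < 0.05


def test_curated_carrier_count_exact():
    spec = CohortSpec(n_cases=200, n_controls=100, n_genes=30, seed=13,
                      known_gene_carriers=0.12)
    coh = generate_cohort(spec)
    assert len(coh.truth["curated_carriers"]) == 24
    curated = coh.variants["variant_id"].isin(
        coh.truth["curated_variants"]).to_numpy()
    carrier = (coh.genotypes[:, curated] > 0).any(axis=1)
    ids = set(coh.samples.loc[carrier, "sample_id"])
    assert ids == set(coh.truth["curated_carriers"])


def test_truth_labels_reference_existing_entities():
    spec = CohortSpec(n_cases=40, n_controls=40, n_genes=25, seed=2,
                      planted_genes=(PlantedGene("RISK1", 1, 2.0),),
                      known_gene_carriers=0.1, recessive_gene="REC1")
    coh = generate_cohort(spec)
    genes = set(coh.variants["gene"])
    samples = set(coh.samples["sample_id"])
    assert set(coh.truth["planted"]) <= genes
    assert set(coh.truth["known_genes"]) <= genes
    assert coh.truth["recessive"]["gene"] in genes
    assert set(coh.truth["recessive"]["samples"]) <= samples
    assert set(coh.truth["curated_carriers"]) <= samples


# ---------------------------------------------------------------------------
# round trips through the pipeline readers
# ---------------------------------------------------------------------------

def test_write_read_round_trip(tmp_path):
    spec = CohortSpec(n_cases=4, n_controls=4, n_genes=6, seed=21,
                      missing_frac=0.1)
    coh = generate_cohort(spec)
    assert (coh.genotypes < 0).any()       # exercise ./. preservation
    paths = write_cohort(coh, str(tmp_path))
    back = pipeline_io.read_cohort(paths["vcf"], paths["annotation"],
                                   paths["samples"])
    assert np.array_equal(back.genotypes, coh.genotypes)
    assert np.array_equal(back.gq, coh.gq)
    assert np.array_equal(back.ad_ref, coh.ad_ref)
    assert np.array_equal(back.ad_alt, coh.ad_alt)
    assert list(back.samples["sample_id"]) == list(coh.samples["sample_id"])
    assert list(back.variants["variant_id"]) == list(coh.variants["variant_id"])
    assert list(back.variants["consequence"]) == list(coh.variants["consequence"])


def test_known_gene_yaml_round_trip(tmp_path):
    spec = CohortSpec(n_cases=10, n_controls=10, n_genes=10, seed=1,
                      known_gene_carriers=0.2)
    coh = generate_cohort(spec)
    paths = write_cohort(coh, str(tmp_path))
    known = pipeline_io.read_known_genes(paths["known_genes"])
    assert set(known.genes) == set(coh.truth["known_genes"])
    assert set(known.curated_variants) == set(coh.truth["curated_variants"])


MULTIALLELIC_VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\t.\tA\tT,G\t.\tPASS\t.\tGT:GQ:AD\t0/1:99:10,12,0\t1/2:88:0,9,11\t./.:.:.
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT:GQ:AD\t0/0:99:20,0\t1/1:77:0,18\t0/1:66:8,9
"""

ANN_TSV = """variant_id\tgene\tconsequence\tcondel_label\talignability\tsimple_repeat\ttranche_fail\text_af
chr1:100:A:T\tGA\tmissense\tdamaging\t1.0\t0\t0\tNA
chr1:100:A:G\tGA\tstop_gained\tNA\t1.0\t0\t0\tNA
chr1:200:C:T\tGB\tsynonymous\tNA\t1.0\t0\t0\t0.02
"""

SAMPLES_TSV = """sample_id\tstatus\tcohort\tn_affected_fdr
S1\tcase\tX\t1
S2\tcase\tX\t2
S3\tcontrol\tX\t0
"""


def _write_trio(tmp_path):
    (tmp_path / "c.vcf").write_text(MULTIALLELIC_VCF)
    (tmp_path / "a.tsv").write_text(ANN_TSV)
    (tmp_path / "s.tsv").write_text(SAMPLES_TSV)
    return tmp_path


def test_multiallelic_site_decomposed_per_alt(tmp_path):
    _write_trio(tmp_path)
    coh = pipeline_io.read_cohort(str(tmp_path / "c.vcf"),
                                  str(tmp_path / "a.tsv"),
                                  str(tmp_path / "s.tsv"))
    assert coh.n_variants == 3          # 2 ALTs at pos 100 + 1 at pos 200
    v = coh.variants.set_index("variant_id")
    gt = coh.genotypes
    # S2 is 1/2: one copy of each alternate allele
    i_t = v.index.get_loc("chr1:100:A:T")
    i_g = v.index.get_loc("chr1:100:A:G")
    assert gt[1, i_t] == 1 and gt[1, i_g] == 1
    assert gt[0, i_t] == 1 and gt[0, i_g] == 0
    assert gt[2, i_t] == -1             # ./. preserved as missing
    assert coh.ad_alt[1, i_g] == 11


def test_vcf_sample_absent_from_table_errors(tmp_path):
    _write_trio(tmp_path)
    (tmp_path / "s.tsv").write_text(SAMPLES_TSV.replace("S3\tcontrol\tX\t0\n", ""))
    with pytest.raises(ValueError, match="S3"):
        pipeline_io.read_cohort(str(tmp_path / "c.vcf"),
                                str(tmp_path / "a.tsv"),
                                str(tmp_path / "s.tsv"))


def test_unknown_annotation_row_dropped_with_warning(tmp_path, caplog):
    _write_trio(tmp_path)
    extra = ANN_TSV + "chr9:1:A:T\tGZ\tmissense\tNA\t1.0\t0\t0\tNA\n"
    (tmp_path / "a.tsv").write_text(extra)
    import logging
    with caplog.at_level(logging.WARNING, logger="crcburden"):
        coh = pipeline_io.read_cohort(str(tmp_path / "c.vcf"),
                                      str(tmp_path / "a.tsv"),
                                      str(tmp_path / "s.tsv"))
    assert coh.n_variants == 3
    assert any("unknown variants" in r.message for r in caplog.records)
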