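"""In-memory case/control exome cohort container.

A cohort joins a sample-by-variant genotype matrix (alternate-allele dosage,
``-1`` for missing) with per-call quality fields (GQ, allele depths), a
per-variant annotation table and a per-sample phenotype table.  All downstream
stages — QC filtering, burden testing, enrichment, recessive scanning —
operate on this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
    "condel_label", "alignability", "simple_repeat", "tranche_fail", "ext_af",
]
SAMPLE_COLUMNS = ["sample_id", "status", "cohort", "n_affected_fdr"]


@dataclass
class Cohort:
    """Genotypes plus annotations for one case/control series.

    Attributes
    ----------
    genotypes : (n_samples, n_variants) int8 array
        Alternate-allele dosage 0/1/2; ``-1`` marks a missing call.
    gq : (n_samples, n_variants) int16 array or None
        Per-call genotype quality.
    ad_ref, ad_alt : (n_samples, n_variants) int16 arrays or None
        Per-call reference / alternate read depths.
    variants : DataFrame with :data:`VARIANT_COLUMNS`
    samples : DataFrame with :data:`SAMPLE_COLUMNS`
    truth : dict
        Simulation truth labels (planted genes, curated carriers, ...);
        empty for cohorts read from files.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    gq: Optional[np.ndarray] = None
    ad_ref: Optional[np.ndarray] = None
    ad_alt: Optional[np.ndarray] = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_s, n_v = self.genotypes.shape
        if len(self.samples) != n_s:
            raise ValueError(
                f"sample table has {len(self.samples)} rows but genotype "
                f"matrix has {n_s} samples"
            )
        if len(self.variants) != n_v:
            raise ValueError(
                f"annotation table has {len(self.variants)} rows but genotype "
                f"matrix has {n_v} variants"
            )
        for name in ("gq", "ad_ref", "ad_alt"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != self.genotypes.shape:
                raise ValueError(f"{name} shape {arr.shape} != genotype shape")
        bad = set(self.samples["status"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown sample status values: {sorted(bad)}")

    # -- convenience views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return (self.samples["status"] == "case").to_numpy()

    @property
    def control_mask(self) -> np.ndarray:
        return (self.samples["status"] == "control").to_numpy()

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_mask.sum())

    def subset_samples(self, keep: np.ndarray) -> "Cohort":
        """Return a cohort restricted to samples where ``keep`` is True."""
        return Cohort(
            genotypes=self.genotypes[keep],
            variants=self.variants,
            samples=self.samples.loc[keep].reset_index(drop=True),
            gq=None if self.gq is None else self.gq[keep],
            ad_ref=None if self.ad_ref is None else self.ad_ref[keep],
            ad_alt=None if self.ad_alt is None else self.ad_alt[keep],
            truth=self.truth,
        )
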