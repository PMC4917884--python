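# Methods

## Study design the package models

The framework targets the familial case/control exome design: an extreme
phenotype case series (early-onset, family-history positive) sequenced
alongside population controls, screened gene-by-gene for an excess of rare
(MAF < 1%) coding alleles in cases, with known-predisposition-gene carriers
removed before the novel-gene screen, replication in an independent
sequencing cohort, a pathway-level enrichment analysis, a recessive
biallelic scan, and a simulation-based power calculation over the
frequency × relative-risk plane.

## Variant classification

Consequence terms are drawn from a controlled vocabulary of canonical
transcript annotations. Three nested severity classes drive all gene-level
tests:

* class 1 (disruptive): `stop_gained`, `frameshift` (any term containing
  "frameshift" is normalised to `frameshift`);
* class 2 (predicted damaging): class 1, plus `missense` labelled
  `damaging` by the in-silico predictor, plus `splice_acceptor` /
  `splice_donor`;
* class 3 (non-synonymous): every non-silent coding term
  (`transcript_ablation`, splice donor/acceptor/region, stop gain/loss,
  frameshift, initiator codon, transcript amplification, in-frame indels,
  missense).

Nesting (1 ⊆ 2 ⊆ 3) holds by construction and is property-tested.

## Quality control

Genotype-level: calls are masked to missing unless GQ ≥ 30; heterozygous
calls additionally need alternate depth ≥ 3 and an allele-balance Pearson
chi-square `(a−b)²/(a+b) < 10.83` against the 50/50 germline expectation
(`a`,`b` = reference/alternate depths). The balance statistic is the 1-df
Pearson form; 10.83 is applied as the stated statistic threshold.

Site-level, in first-failure order: truth-tranche flag; alignability ≠ 1 or
simple-repeat overlap; Hardy–Weinberg exact P ≤ 1e-8 computed separately in
cases and in controls (conjunctive: both groups must pass); post-masking
call rate < 75% in either group. The HWE test is the exact conditional
test: given the allele counts, the probability of every heterozygote count
no more probable than the one observed (computed in log space with a
gammaln kernel, cached per configuration, and validated against two
independent enumeration oracles).

MAF is the pooled case+control alternate-allele frequency over non-missing
chromosomes, folded to ≤ 0.5. Tier boundaries: rare < 0.01 ≤
low-frequency < 0.05 ≤ common. When an external reference frequency is
available, a variant is rare only if both the cohort MAF and the folded
external frequency are < 0.01 (AND rule) — the conservative reading when an
external exome reference is available. Whether pooled or control-only
frequency is used is configurable; pooled is the default. A consequence of
pooled MAF worth knowing: a single very strongly enriched risk allele can
exceed the 1% cap *because of* its case excess and drop out of the rare
tier (the analysis scripts plant one such gene deliberately).

## Collapsing burden test

The statistic is the number of case samples carrying ≥ 1 non-missing
alternate allele across a gene's qualifying variants — carrier count, not
allele count, with each sample counted once per gene. Under permutation of
case/control labels with the carrier set fixed, the case-carrier count is
exactly hypergeometric, so the one-sided (case-enrichment) permutation
P-value is computed in closed form with the mid-P tie rule (half weight on
permutations tying the observed statistic):

    P = P(X > k) + ½ P(X = k),  X ~ Hypergeom(N, K, n_cases).

Genes with zero carriers report P = 1 by convention (untestable), not the
all-ties value 0.5. Mid-P is approximately — not conservatively —
calibrated: on a 20,000-gene null cohort at the discovery design size the
fraction of class-3 gene P-values ≤ 0.05 is ≈ 0.04 (asserted within
[0.03, 0.07]); class-1 counts are far more discrete and reject less often.
The Monte-Carlo permutation estimator samples the hypergeometric law
directly (drawing the statistic of a random label permutation without
materialising the permutation), runs 10⁵ permutations and adds 2×10⁶
whenever P < 0.01, reporting the combined estimate. Equality with explicit
label enumeration is proven exhaustively for all cohorts of ≤ 10 samples.

Significance flags use `P ≤ alpha` so that a degenerate alpha of 1 flags
every tested gene; the exome-wide default alpha is 8.0e-7 (kept verbatim as
the conventional ~20,000 × 3 Bonferroni threshold).

Known-gene bookkeeping: `reduce_cases` removes every case carrying a
class-1 variant in a configured known gene or any variant on the curated
pathogenic list, regardless of site-filter status (curated alleles are
manually reviewed calls, so automated site filters are deliberately not
allowed to rescue a carrier); controls are never removed; the operation is
idempotent. `attribute_cases` reports the case fraction carrying qualifying
known-gene variants per class tier, plus a final tier adding curated
variants of any consequence.

## Meta-analysis

Gene-level evidence across cohorts is combined by the sample-size-weighted
Z-score method with weights √(effective N), effective
N = 4/(1/n_cases + 1/n_controls). This weighting convention reproduces the
reference meta P-values from their component mid-P values, which total-N
weighting does not. The burden meta is one-sided (risk enrichment) and
gated to genes with class-1 P < 0.05 in the reduced discovery screen.
Single-variant tests are two-sided Fisher exact on allele-count tables
(scipy), with an inverse-variance fixed-effects combiner for external array
cohorts and a 0.5 continuity correction on the displayed odds ratio when a
cell is zero.

## Gene-set enrichment

Pre-ranked GSEA over −log₁₀ of the gene burden P (class 2 by default; the
class feeding the published ranking is not documented, so it is
configurable). Ties rank lexicographically for determinism; P = 0 (below
permutation resolution) is clamped to 0.5/n_perm. The running sum uses the
classic weighted form, weight exponent 1: hits add score/Σ(set scores),
misses subtract 1/(N − m); ES is the signed maximal deviation, with only
positive (enrichment) ES used for significance since the ranking metric is
unsigned. The null is set-based: random same-size draws from the ranked
universe, one shared null distribution per set size; nominal P uses the
null tail with a mid-P tie rule and a 0.5/n_perm floor; NES divides ES by
the mean same-sign null ES; Q-values follow the standard NES-based FDR
(fraction of pooled null NES ≥ observed over fraction of observed NES ≥
observed, capped at 1). Sets outside 5–500 members after intersection are
flagged untestable. Leading edges (members at or before the running-sum
peak) are extracted at Q < 0.25. The ES implementation is cross-checked
against an independent pre-ranked GSEA implementation in the test suite.

## Recessive scan

Per sample × gene over qualifying (default class-2, rare-tier) variants: a
homozygous alternate genotype, or heterozygous genotypes at ≥ 2 distinct
variants, is a biallelic hit. Two hets cannot be phased without pedigree or
read data, so compound heterozygotes are reported as putative with an
explicit `phase_unknown` flag. Hits are monotone in the qualifying class
and invariant to variant ordering.

## Power model

Control carrier frequency p₀ is the baseline. A case with k affected
first-degree relatives has carrier frequency, by Bayes' rule under a
dominant single-locus model in which each affected relative of a carrier
shares the allele (and its RR-fold risk) with probability ½:

    f_k = p₀·RR·λᶜᵏ / (p₀·RR·λᶜᵏ + (1 − p₀)),  λᶜ = (1 + RR)/2,

and the case frequency is the family-history-weighted average Σ w_k f_k
over k ∈ {1,2,3}. The per-stratum enrichment derivation is not published;
this dominant allele-sharing form is the package's own construction,
isolated behind `EnrichmentModel` so an alternative can be swapped in. It
satisfies f_k = p₀ at RR = 1 and f₁/p₀ → RR(1+RR)/2 as p₀ → 0. Sampling is
carrier-level (dominant), matching the burden statistic; each cell draws
case/control carrier counts binomially and applies a one-sided Fisher test
at exome-wide alpha. A normal-approximation two-proportion power formula
serves as an independent cross-check for cells with expected carrier
counts ≥ 10 (agreement within 5 percentage points asserted). The default
grid spans frequencies 1e-5..0.01 and relative risks 1.75..4.0 at 10,000
replicates per cell; the analysis script and the property checks use 2,000
replicates per cell, which bounds the Monte-Carlo s.e. at ~0.011.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
not sequence data. Defaults are the discovery design: 1,006 cases, 1,609
controls, ~20,000 genes, Poisson(3) variants per gene (min 1), class mix
(disruptive, damaging-missense, other-nonsynonymous, silent) =
(0.10, 0.20, 0.45, 0.25), per-variant carrier frequency 0.002 in controls,
depth ~ Poisson(48), GQ discretised around 65 with a 1% low-quality tail,
1% of hets drawn with contaminant-like allele imbalance, 2% per-call
missingness, and family-history stratum weights (0.85, 0.12, 0.03) for
1/2/3 affected first-degree relatives (the real distribution is not
published; this is a configurable placeholder).

Carrier model: at most one carried variant per sample per gene (per-gene
Bernoulli, then a uniform choice of the carried variant), matching the
empirical absence of samples stacking multiple disruptive alleles in one
gene; an independent per-variant mode exists but is off by default. All
carriers are heterozygous except explicitly planted biallelic samples —
appropriate at the supported carrier frequencies (1e-5..5e-3), where
Hardy–Weinberg homozygotes are negligible.

Planted risk genes redraw the qualifying-class carrier status of every
sample from the enrichment model: controls at the gene-level baseline
1−(1−p)^m, cases at f_k for their assigned family-history stratum, so the
expected case carrier frequency is exactly the power model's weighted
average (recorded in the truth labels and recovered within binomial error
in tests). Established known genes carry exactly one curated disruptive
variant whose carriers are planted explicitly (an exact count,
round(fraction × n_cases), spread round-robin across the known genes to
keep each curated allele rare); their background variants are drawn from
non-disruptive classes, and curated/biallelic planted calls are emitted
with clean quality fields — curated alleles model manually reviewed
variants, which makes known-gene reduction bookkeeping exact by
construction.

What the generator does **not** emulate: linkage disequilibrium, population
stratification and relatedness, base-level sequencing error, indel
realignment artefacts, X-chromosome dosage. Passing tests therefore
demonstrate the statistical machinery under the idealised sampling model,
not robustness to those real-data phenomena.

## Problem sizes and runtime choices

The analysis scripts run the discovery design at a 2,000-gene universe
(statistical structure per gene unchanged; everything completes in
seconds). Null calibration runs at the full 20,000-gene scale. The power
surface in scripts and property checks uses 2,000 replicates per cell;
cell-level results at 10,000 replicates differ only in Monte-Carlo noise.
All randomness flows from a single root seed split per stage
(`numpy.random.SeedSequence.spawn`), making every table byte-reproducible
under a fixed seed.

## Known limitations

* The pooled-MAF rare threshold can censor extremely enriched alleles (see
  QC section); a control-only MAF source avoids this and is configurable.
* Mid-P calibration degrades for very discrete carrier distributions
  (class 1 at small cohort sizes rejects well below nominal).
* The family-history enrichment construction and stratum weights are the
  package's own modelling choices; absolute power values depend on them,
  while the monotonicity and null properties do not.
* Compound-heterozygote calls assume trans configuration; without phasing
  they are an upper bound on true biallelic carriers.
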