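# Methods

This note documents the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Tetrasomic genotype model

An autotetraploid with random chromosomal segregation and allele frequency
*p* carries a Binomial(4, *p*) number of minor-allele copies at a biallelic
site. We deliberately omit **double reduction** (the small excess of
homozygotes produced by quadrivalent pairing): estimating it requires
pedigree or marker-phase information that association panels of unrelated
cultivars do not provide, and the five-genotype-class representation is
agnostic to it. Allele frequency is estimated as `p̂ = Σ dᵢ / 4N` over
non-missing individuals, which is unbiased under this model (checked by
simulation in the test suite).

### Dosage calling from peak heights

The minor-allele height fraction `f = h_alt / (h_ref + h_alt)` has
noise-free values {0, ¼, ½, ¾, 1} at dosages 0–4. Calls are
nearest-centroid: boundaries at 0.125 / 0.375 / 0.625 / 0.875. The
underlying study read these ratios visually with desktop software, so the
discretization rule is this package's own; the per-call distance to the
assigned centroid is returned as a confidence so users can impose a no-call
band. Triallelic signals are matched by Euclidean distance on the fraction
simplex against all 15 compositions of 4 copies into 3 alleles, ties broken
toward the lexicographically smallest class label.

### Frequency filters

Markers are filtered by **MFA carrier count**, not by frequency directly,
mirroring the study design: ≥ 8 carriers in discovery mode (n = 208; 8
simplex carriers ≈ 1% copy frequency) and ≥ 3 carriers in validation mode
(n = 40; ≈ 2%). Presence/absence-scored markers have no dosage, so two
frequency summaries are exposed — carriers/n and the copy frequency under a
"every carrier is simplex" assumption — and neither is claimed commensurable
with the dosage-based copy frequency. Markers with > 20% missing calls are
flagged but not dropped.

## Association model

Genotype is a **categorical factor** in a one-way fixed-effects ANOVA, not
a linear dosage covariate. Rationale: reported effects include
class-specific patterns (an effect visible only in one homozygous class;
directions that reverse between groups) that a single slope cannot
represent. The effect size is `η² = SS_between / SS_total`, reported as
percent variance explained; the p-value comes from the F distribution with
(k−1, n−k) df. A Kruskal–Wallis option is exposed for users who prefer a
rank test on the ordinal chip scores; the parametric test is the default
and the one the acceptance checks exercise. Ordinal 1–9 scores are analyzed
as numeric responses.

Conventions and edge cases:

- **Singleton classes** (one observation) are merged into the observed
  class nearest in dosage before testing (ties toward the lower dosage);
  merges are logged. This avoids zero-df cells in the sparse extreme
  classes of a tetraploid panel.
- A marker with a single observed class is *not testable* — reported
  distinct from "not significant". Zero total trait variance gives
  η² = 0, p = 1.
- Missing phenotype or genotype values are dropped pairwise per test.
- Tiers: ns (p > 0.05), \* (0.05 > p ≥ 0.01), \*\* (0.01 > p ≥ 0.001),
  \*\*\* (p < 0.001); boundary p = 0.05 is ns, p = 0.01 is \*. A marker is
  "reportable" when p < 0.01 for at least one trait. No multiple-testing
  correction is applied across association tests (the fixed p < 0.01
  reporting threshold is the family-wise control used); FDR correction is
  reserved for the LD family.

**Direction of effect.** Class means are ordered by MFA dosage; the
direction is the sign of the count-weighted least-squares slope of class
mean against dosage. When two successive class-mean differences have
strictly opposite signs and each exceeds τ = 0.25 × pooled within-class SD,
the direction is declared *inconsistent* between genotypic groups. The
0.25 factor is a documented default chosen so that sampling wiggle in a
thin top class does not trigger the call; it is not asserted to match any
published rule.

**Validation mode** applies each trait column's declared log10 transform
before testing (reducing-sugar measurements are approximately log-normal;
the transform restores normality of residuals). Nonpositive values are a
domain error — no silent offset is added.

## Linkage disequilibrium

Gametic phase is unobservable in unphased tetraploid data, so LD is tested
**phase-free**: a χ² test of independence on the genotype-class
contingency table (rows = dosage classes of one marker, columns of the
other), df = (r−1)(c−1). True gametic D/D′/r² would require phase
inference the data cannot support; the composite dosage correlation *r* is
reported as an effect size instead. Dosage classes with expected counts
below 1 are pooled with the adjacent class before testing (tetraploid class
tables at n ≈ 200 are sparse in the extreme classes); pooling merges the
sparsest marginal on whichever axis is thinner, which makes the procedure
symmetric in the two markers. A warning is emitted when expected counts
below 5 remain.

q-values: Benjamini–Hochberg step-up by default; Storey's method with a
fixed-λ π̂₀ estimate (λ = 0.5) as an option, under which q < p is possible
when π̂₀ < 1. **LD blocks** are single-linkage components of same-locus
markers connected by pairs with q ≤ 0.05 within 700 bp — the span observed
for strong within-amplicon blocks — and each block nominates its
lowest-position member as the reporting representative.

## Clone-consensus SNP calling and haplotypes

A clone-derived variant is accepted iff carried by **≥ 3 clones spanning
≥ 2 distinct amplification-batch ids**. "Two independent amplifications" is
interpreted as ≥ 2 batches *among the carrying clones* (not merely two
batches in the experiment) — the stricter and, we believe, intended
reading. With a per-base error rate of 10⁻³ and ≤ 50 clones the probability
that any singleton artifact recurs in three clones is negligible (< 10⁻⁴,
verified by simulation in the tests).

ORF coordinates are 1-based with position 1 at the A of the ATG start
codon; `residue = ⌊(pos−1)/3⌋ + 1`, codon offset `((pos−1) mod 3) + 1`.
Amino-acid-change annotations are carried as input metadata and
cross-checked against this arithmetic; disagreements are **flagged, never
corrected** — the bundled PHO1a matrix contains one such label
(`Thr923Lys` at position 2795, which maps to residue 932), and the package
reports the discrepancy rather than guessing which numbering the annotation
intended. Possible signal-peptide offset conventions cannot be resolved
from the available material; raw ORF arithmetic is the contract.
Third-codon-position partitioning is a proxy for synonymous sites; on the
bundled matrix it coincides exactly with the annotated amino-acid changes
(7 third-position vs 8 changing), but degenerate non-third sites can break
the coincidence on other inputs.

## Synthetic-data generator

The generator reproduces the *statistical structure* the analysis assumes:

- dosages: Binomial(4, p), or four independent two-locus haplotypes drawn
  from (p₁p₂+D, p₁q₂−D, q₁p₂−D, q₁q₂+D) for an LD pair (D admissible iff
  −min(p₁p₂, q₁q₂) ≤ D ≤ min(p₁q₂, q₁p₂));
- traits: y = μ + βd + ε with ε ~ N(0, σ²) and
  β = σ·√(r²/((1−r²)·Var(d))), so the dosage term contributes exactly the
  target variance fraction. Var(d) is the variance of the supplied dosage
  vector — the only population quantity available to the function — so the
  calibration is exact in-sample in expectation;
- ordinal chip scores: equal-probability binning of the latent continuous
  trait into nine categories (the latent scale is unobservable; this is a
  modeling choice, not a claim about the instrument);
- validation-panel sugar traits: the additive model is applied on the
  log10 scale and exponentiated, so the declared log10 transform restores
  an exactly Gaussian additive model;
- peaks: heights ((4−d)/4, d/4) times independent log-normal noise with
  the stated coefficient of variation (the real noise process — dye
  chemistry, local sequence context — is not modeled);
- clones: uniform sampling of true variant columns, uniform batch
  assignment, independent per-base miscalls to a random other base.

Default scales mirror the target study design: a discovery population of
208 individuals with traits CQA, CQS (ordinal 1–9), TSC, TY, TSY, a
causal marker at MFA 8.5% explaining 19.9% (TSC) and 10.3% (TSY) of
variance; a validation panel of 40 individuals with sugar time points
T0–T12; 161 clones over 19 amplification batches.

What passing tests therefore show: the estimators are calibrated and the
filters/rules behave as specified *under the generating model*. They do
not show robustness to population structure, relatedness among breeding
clones, double reduction, genotyping batch effects, or non-Gaussian trait
residuals — none of which the generator emulates and all of which affect
real panels.

## Problem sizes and numerics

Calibration checks use 2000 simulated tests (association null, LD null)
and 200 replicates for parameter recovery — sizes at which the binomial /
KS acceptance intervals are tight enough to detect miscalibration while
keeping the full suite under a minute. η̂² at n = 208 with 3–4 observed
classes carries an upward bias of roughly (k−1)/(n−1)·(1−R²) ≈ 1 point,
visible in the recovery mean (≈ 20.5–21 for a true 19.9); the recovery
tolerance of ±2 points accommodates it, and no bias correction is applied
because the reporting convention is raw η².

All generators accept either an integer seed or a `numpy.random.Generator`;
every pipeline entry point threads a single seed, and reruns are
bit-identical. Genotype files use an explicit `NA` token; writers emit a
`# modes:` header so write→read round trips preserve scoring modes exactly.
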