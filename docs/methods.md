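# Methods

## The genetic model

A trait observation is the replicate mean of line or hybrid *k* in
environment *h*:

y_hk = μ + Σᵢ aᵢ u_Aik + Σᵢ dᵢ u_Dik + Σ_{i<j} (aaᵢⱼ u_AA + adᵢⱼ u_AD +
daᵢⱼ u_DA + ddᵢⱼ u_DD) + e_h + Σᵢ ae_ih u_AE + Σᵢ de_ih u_DE +
Σ_{i<j} (aaeᵢⱼₕ u_AAE + adeᵢⱼₕ u_ADE + daeᵢⱼₕ u_DAE + ddeᵢⱼₕ u_DDE) + ε_hk

Coefficient codings: u_A is +1 for the major homozygote QQ, −1 for qq and 0
for the heterozygote (the heterozygote carries no additive deviation under
this F∞-metric coding); u_D is 1 for Qq and 0 otherwise.  Digenic
coefficients are products of the single-locus factors (AA = A·A, AD = A·D,
DA = D·A, DD = D·D); the coding enumerations for the canonical cells follow
from the product rule, which also fixes the cells the enumerations leave
out (all zero).  For a stored pair (i, j), AD means additive at i times
dominance at j, and DA the reverse.  Environment-specific coefficients equal
their base coefficient in their own environment and 0 elsewhere.  A missing
genotype call zeroes the subject's coefficients for that locus's terms
rather than being imputed — conservative and deterministic.

The environment effect e_h is absorbed into per-environment intercepts
(fixed, flat prior).  With two environments a random environment main effect
is not identifiable anyway, and the intercepts also absorb μ; the reported
population mean per environment is μ + e_h.

## Estimation

The fit is a hierarchical Bayesian linear model.  Each term class (a, d, aa,
ad, da, dd, ae, de, aae, ade, dae, dde) has its own variance component
σ²_c with a scaled-inverse-χ² prior (ν₀ = 4, scale = 0.5 · var(y) by
default — weakly informative; the data dominate at any realistic size); the
residual variance has the same prior form.  Coefficients are conditionally
normal given the variance components.

Sampling is Gibbs with a **blocked coefficient update**: the whole
coefficient vector is drawn from its joint conditional normal
N(A⁻¹X'r/σ²_ε, A⁻¹), A = X'X/σ²_ε + diag(1/σ²_class), via one Cholesky per
iteration.  This matters because the design is intrinsically collinear: an
environment-specific pair of columns sums exactly to its general column
(u_D = u_DE1 + u_DE2), and in a two-tester mating design the dominance
column of a locus is nearly proportional to dominance×additive product
columns (almost all heterozygotes at a tester-segregating locus sit in one
family, where the partner locus offers only two genotype states).
Single-site updates cannot traverse these ridges and can lock into an
aliased mode; the blocked draw samples the exact same posterior with correct
mixing.  Default chain: 20,000 iterations, burn-in 4,000, thinning 10.
Posterior means and SDs come from the retained draws; Monte Carlo SEs use
non-overlapping batch means.  An all-zero column falls back to its class
prior (posterior mean ≈ 0 with prior-scale SE).  The numerical core is
numba-compiled; a fit of 24 terms on 734 observations takes well under a
second after compilation.

## Experiment-wise significance

Significance is controlled family-wise by permutation of the maximum
per-term statistic.  Refitting a full chain for each of 2,000 permutations
is not needed for a threshold: each permutation (and the observed data,
treated identically) is scored by the absolute within-environment
correlation between a term column and the response, and the maximum over
terms is recorded.  Responses are permuted across subjects *within* each
environment, so the environment structure survives.  The critical value is
the (1 − α) upper quantile of the max distribution (quantile method
"higher", so at 20 permutations and α = 0.05 the threshold is the largest
null maximum); P_EW of a term is the empirical tail probability with the +1
correction, floored at 1/(n_perm + 1) and flagged when floored.

A property of this marginal statistic worth knowing: any column correlated
with a true effect — its environment-specific shadow, or an epistatic
product sharing a locus — is genuinely associated with the phenotype and
will also cross the threshold, exactly as markers linked to a QTL light up
in a genome scan.  The permutation null destroys all genotype–phenotype
association, so the family-wise error on null data is controlled (verified
at α = 0.05 over 200 null simulations: empirical rate ≈ 0.05), but the set
of significant terms should be read as "associated", with the posterior
means (which shrink aliased terms toward zero) supplying the effect sizes.

## Heritability partition

Per-effect heritability is reported as a percentage of the model-based
phenotypic variance V_P = V_G + V_GE + V_ε, making per-effect, category
(A, D, I = epistasis, AE, DE, IE) and total percentages additive by
construction.  Two conventions for an effect's variance contribution:

- **empirical (default)** — posterior mean² × design-column variance: the
  realized contribution in this population.  The realized column variance
  already embodies the segregation ratios that the α constants idealize, so
  no α is applied.  On simulated data this recovers the generating total
  (e.g. 85.4% vs a true 85.0%).
- **posterior** — the variance-component convention α · (posterior mean² +
  posterior variance) with α = 2 (a), 1 (d), 4 (aa), 2 (ad/da), 1 (dd),
  environment classes inheriting their genetic part.  This matches the
  convention under which published tables are additive, and
  `component_heritability` implements exactly that arithmetic; as an
  estimator on collinear designs it overstates the total (posterior
  variances of many correlated terms accumulate), which is why it is not
  the default.

Per-category recovery has a structural limit: in a two-tester design the
class contributions are strongly correlated (for the plant-height-like
architecture the marginal per-class variances sum to ~170% of V_P, the
excess being negative covariances), so no additive decomposition can match
all marginal truths; the total — 1 − V_ε/V_P — is the well-identified
summary.  R_Ŷ, the Pearson correlation between fitted genotypic value
(environment intercept + all fitted terms) and the observed response, is
reported pooled and per environment.

## GMDR screening

The screen is a score-based generalized multifactor dimensionality
reduction, reimplemented from its published description (the source study
names only the tool): a subject's score is the mean deviation of its records
from the environment means; a 1–3-locus combination partitions subjects
into 3^d genotype cells; a cell is labeled "high" when its training-fold
mean score is positive (empty cells default to "low"); testing accuracy is
the balanced accuracy of the cell labels against the score's sign on the
held-out fold, averaged over k = 10 folds; cross-validation consistency is
the number of folds in which the combination has the best training accuracy
among its dimension.  Selection keeps combinations with testing accuracy ≥
0.55 and consistency ≥ k/2 (both configurable).  A full 3-locus scan over a
genome-wide panel is combinatorially infeasible, so the default staged mode
feeds the top-m one-locus models into the higher dimensions; the analysis
driver widens m to 50 because a digenic interaction can cancel a locus's
marginal effect and push it down the 1D ranking (the simulated da pair does
exactly that).  Screening power is intrinsically weak for rare variants:
with a tiny minor-homozygote cell, the sign of a subject's score in the
majority cell is noise-dominated, so balanced accuracy stays near 0.5 even
for a sizeable effect.

## Synthetic populations

The generator emulates the study design: 2 female testers × 149 male
inbreds, 216 F1 hybrids (97 + 119), 367 subjects, two environments, three
replicates, SNP minor-allele frequencies uniform in 0.05–0.17.  Inbred
genotypes are i.i.d. per locus (no linkage disequilibrium — the model
treats loci as fixed terms); hybrids derive Mendelianly from their
homozygous parents; environment effects are fixed offsets (at two
environments a random e_h is untestable); noise is Gaussian.  Phenotypes
follow the full model exactly, so with zero residual the empirical variance
decomposition matches the analytic one to machine precision.

Effect-locus placement is a study-design choice with an identifiability
constraint: a dominance contrast at a tester-segregating locus is carried
almost entirely by one family, and the digenic cells separating d from
ad/da — (heterozygote, minor-homozygote) in both orientations — can be
empty by chance, making those effects exactly aliased.
`select_qts_pair` therefore places the two effect loci on SNPs minor in
exactly one (distinct) female each, maximizing the scarcer separating-cell
count; the recovery study uses a 200-SNP panel so such loci always exist.
The residual SD is calibrated so total heritability at the replicate-mean
level hits a target (0.85 for the plant-height-like trait, inside the
58–88% range typical of these traits); the generator reports the realized
truth alongside.

What passing on these simulations does *not* show: robustness to linkage
disequilibrium, population structure beyond the two-tester families,
non-Gaussian residuals, or genotyping error — none of which the generator
emulates.

## Problem sizes and numerics

The validation studies run at the study's design scale (367 subjects × 2
environments): 20 replicate recovery fits at 5,000 iterations; 200 null
datasets × 200 permutations for the family-wise error study; 1,000 random
effect tables (≤ 6 loci) for the enumeration cross-check.  Superior-genotype
search enumerates exactly up to 15 loci (2^L for lines, 3^L for hybrids;
ties break to the lexicographically smallest combination under
QQ < Qq < qq) and offers a certified branch-and-bound beyond.  Degenerate
inputs are guarded rather than fatal: a constant response yields a zero
permutation threshold (flagged), a zero-spread trait skips the outlier
screen, an emptied SNP panel returns an empty matrix with a degenerate-input
note.

## Known limitations

- Marginal permutation statistics declare aliased terms significant (see
  above); a per-term partial statistic is ill-posed under the design's exact
  collinearities.
- Heritability categories inherit the non-orthogonality of the design;
  only their total is a stable estimand here.
- G–P maps condition non-focal loci at the all-QQ reference, not on the
  population distribution.
- No kinship/population-structure adjustment, no imputation, no linkage
  maps; trigenic and higher epistasis out of scope.
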