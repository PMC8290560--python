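# Methods

This note documents the models, numerical choices and limitations of
`eggtraj`.  It is written for users who want to understand what the
package computes and what its tests do and do not establish.

## The random-regression model

Weekly egg number from first egg is treated as a longitudinal Gaussian
trait over weeks of lay t = 1..24.  Fixed effects are the hatch-week ×
week-of-lay interaction (contemporary groups), week × age-at-first-egg
class (classes 29–31, 32–34 and >34 weeks of age), and a body-weight
covariate with a separate slope per week of lay.  Body weight is centered
at its training-data mean before entering the design; this changes only
the fixed-effect parameterization, not any estimable function.  Additive
genetic and permanent environmental effects are order-3 random
regressions on normalized Legendre polynomials,

    phi_k(x) = sqrt((2k+1)/2) P_k(x),   x(t) = -1 + 2 (t - 1) / 23,

so each animal carries 4 additive and (if it has records) 4 permanent
environmental coefficients.  The residual variance is constant within
each of four periods of lay (defaults 1–4, 5–12, 13–17, 18–24) and
independent across weeks.

The normalized basis with week 1 mapped to x = −1 and week 24 to x = +1
is load-bearing: it is the only convention under which the reference
coefficient covariance matrices in `eggtraj.params` reproduce the
reference weekly variance and heritability trajectories (an unnormalized
basis misses the week-1 genetic variance by ~0.24).  Likewise the period
boundaries above are the set that reproduces the reference weekly
heritabilities; the boundary list is configurable
(`RunConfig.residual_periods`).

### Fixed-effect rank handling

Hatch-week × week cells get one dummy each (only observed cells).  The
week × AFE interaction is collinear with the hatch-week × week block
(both sum to the week indicator), so within every week the first observed
AFE class is dropped; dropped levels are recorded in
`FixedEffectsSpec.dropped_levels`.  This makes the design full rank when
hatch weeks and AFE classes are crossed; fully confounded designs (an AFE
class identical to a hatch-week group) remain rank deficient and the
direct solver will report singularity rather than silently regularize.

## Relationship matrices

* A is built by the tabular recursion; inbreeding F = diag(A) − 1.
* A⁻¹ uses Henderson's rules with inbreeding: animal i contributes
  (1/d_i) over its (i, sire, dam) triple with weights (1, −1/2, −1/2) and
  d_i = 1/2 − (F_s + F_d)/4, each unknown parent adding 1/4 to d_i.
  Equivalence with the dense inverse of the tabular A is property-tested
  on random pedigrees up to N = 200.
* A22 is computed from the full pedigree and then sliced to the genotyped
  animals, never rebuilt from a pruned pedigree.
* G is VanRaden's first method with observed allele frequencies of the
  genotyped set (no base-population frequencies are assumed available and
  no post-hoc tuning of G to A22 is applied; the only compatibility
  device is the blend 0.95 G + 0.05 A22, which also guarantees
  invertibility).  QC order is call rate → autosomal → MAF, with MAF
  computed on the post-call-rate panel; surviving missing dosages are
  mean-imputed to 2p.
* H⁻¹ adds the dense correction G⁻¹ − A22⁻¹ to the genotyped block of the
  sparse A⁻¹.

## Solvers

The mixed-model equations are kept in structured form (W, residual
weights, relationship inverse, C⁻¹, P⁻¹) and materialised only when
needed.  Systems up to ~20k unknowns with a sparse relationship inverse
use sparse LU; larger or single-step systems (whose genotyped block is
dense) use conjugate gradients with a block-Jacobi preconditioner (scalar
for fixed effects, exact 4×4 blocks for each animal's coefficients) and a
relative-residual stopping rule (default 1e-10).  Direct and iterative
paths agree to 1e-6 on overlapping instances, and both are checked
against a dense GLS oracle that inverts the full covariance of y on a
30-hen problem.

## Gibbs sampler

A systematic-scan sampler with the location effects integrated into the
scan: fixed effects as scalar Gaussian conditionals, each animal's 4
additive coefficients as one block (coupled to relatives through the
sparse rows of A⁻¹ or H⁻¹), each hen's 4 PE coefficients as one block.
The residual vector is updated incrementally, so one full sweep is O(nnz)
and is implemented as a numba kernel; all Gaussian deviates are consumed
from a pre-generated per-round array, which makes chains bit-reproducible
for a given seed.

Priors are near-flat: improper uniform on fixed effects; inverse-Wishart
with identity scale and df = dim + 2 = 6 (the minimal proper choice) for
C and P; the flat improper limit for each residual variance (draws are
SSE/chi²(n − 2)).  With thousands of animals the identity prior scale
perturbs posterior means by O(1/N).  Non-PD proposals are handled by
diagonal jitter with a retry count reported on the chain
(`PosteriorChain.n_jitter`; zero in all test runs).

Chain defaults follow common practice for this model class: 200k rounds,
20k burn-in, 1:50 thinning (3600 saved samples).  Tests and the recovery
study use a desk-scale chain of 20k rounds / 2k burn-in / 1:10 thinning
(1800 saved samples) on ~1250 hens (~2500 pedigree animals), which runs
in about two minutes and recovers the generating residual variances to
within a few percent with 95% HPD coverage of the weekly genetic
variances at or above the nominal-coverage check (≥80% of 24 weeks).

HPD intervals are the shortest contiguous interval containing the target
mass of the sorted samples, per scalar parameter.  Derived quantities
(weekly variances, h²) are computed per saved sample and then summarised,
which is exact for the variances (linear in C) and respects the
nonlinearity of h².  ESS uses arviz.

## Accuracy statistics

* **Forward validation.**  The youngest fraction (default 10%, floor) of
  recorded hens — by hatch week, ties broken by id — is masked during
  training.  Weekly accuracy is cor(EBV_t, y*_t)/sqrt(h²(t)) over
  validation hens with a week-t record, where y* = y − Xb̂ uses the
  reference-fit fixed solutions and h² is the weekly heritability implied
  by the fitted (genomic-structure) variance components, applied to both
  methods so they are compared on one scale.  Weeks with fewer than 3
  animals or degenerate variance are reported missing.
* **Mendelian-sampling ratio.**  mŝ_i = EBV_i − (EBV_s + EBV_d)/2 per
  week on the trajectory scale, over animals with records and both
  parents known; ν(t) = Var(mŝ_t)/(0.5 σ²ₐ(t)) with the n−1 sample
  variance.  ν lies in [0, 1] up to sampling noise (a soft warning fires
  above 1.05) and, when true breeding values are substituted for EBVs,
  tends to the realised Mendelian-sampling fraction (≈ 1 − F̄ effects),
  which the tests verify at ~750+ trios.  For the single-step structure
  the validate stage reports ν both over all eligible animals and over
  the genotyped eligible subset, since the two populations can differ in
  prediction sharpness.

## Synthetic data

The generator emulates a pedigreed breeding nucleus: discrete
generations (default 8), a small sire team and larger dam team, random
mating without selfing, hatch-week contemporary groups within generation,
records on all non-founder females, genotyping youngest-first.  Default
generating parameters (C, P, residual periods, the weekly mean curve used
for the fixed-effect baseline) are the published estimates for a
commercial turkey female line; the printed C is slightly indefinite from
2-decimal rounding and is repaired by eigenvalue clipping at 1e-4 before
use (this moves the implied weekly genetic variances by <0.005 except at
the weakly-identified trajectory endpoints, at most 0.035 at week 24).

Two trait modes exist:

* **genomic (default).**  Every autosomal SNP carries an iid
  N(0, C/(2Σp(1−p))) 4-vector effect; an animal's additive coefficients
  are the centred dosage-weighted sums.  Founder coefficients then have
  covariance C, transmission and Mendelian-sampling variance arise from
  actual segregation, and the genomic relationship matrix carries real
  information about the trait.  This is required for single-step
  evaluation to have any advantage: if the trait's Mendelian sampling
  were drawn independently of the genomes, marker-based relationship
  deviations would be pure noise for the trait, and ssGBLUP would
  (measurably) *underperform* PBLUP.
* **pedigree.**  Coefficients transmitted directly through the pedigree
  with m_i ~ N(0, d_i C), matching the infinitesimal model exactly;
  markers are neutral.  Used for closed-form transmission checks.

Features of real data the generator does **not** emulate: linkage and LD
(loci are unlinked, so G's information content per SNP is lower than for
a dense panel on a real genome), selection across generations, integer
egg counts (records live on the continuous Gaussian scale the model
assumes; ~1% of simulated week-records fall below zero), age trends in
body weight, and hatch-week effects correlated with season.  Passing
recovery and ordering tests therefore demonstrate internal consistency
of estimator and model, not robustness to model misspecification.

Scale choices in the test suite — ten populations of ~1580 hens with 45%
genotyped for the method-ordering properties, ~1250 hens for the Gibbs
recovery — keep the full suite in a few minutes on one CPU while leaving
the stochastic orderings clearly resolved (the ssGBLUP−PBLUP accuracy gap
at this scale is ~0.05–0.13 correlation points, the ν gap ~0.03–0.06).

## Known limitations

* No genetic groups or metafounders: unknown parents are draws from one
  base population.
* No APY or other large-n approximations of G⁻¹; the genotyped set is
  inverted densely.
* The correlation between 16-week and 24-week cumulative production is
  implemented as the genetic correlation of partial sums of weekly
  genetic values (`partial_sum_correlation`); other readings (e.g. EBV
  correlations from truncated-data fits) are possible.
* Persistency follows the conventional definition (value at peak week
  minus value at a later week over a fixed divisor, defaults 3, 18 and
  16); the divisor is kept at the conventional 16 although the week
  interval is 15.
* The report stage's selected-week correlation table mixes genetic
  (above diagonal) and phenotypic (below diagonal) correlations with
  heritabilities on the diagonal, mirroring the usual presentation in
  the poultry-genetics literature.
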