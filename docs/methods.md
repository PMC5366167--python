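# Methods

## Model and sampler

`subridge` fits the Gaussian whole-genome regression y = 1μ + Xb + e with a
common variance for all marker effects (Bayesian ridge regression /
SNP-BLUP). Both variance components carry scaled-inverse-χ² priors; their
scales are elicited from the phenotypic variance by the R² rule
(`compute_prior_shapes`), splitting σy² into an assumed genetic fraction R²
(default 0.5) and a residual fraction, with νb = νe = 5 degrees of freedom.

Marker effects are sampled coordinate-wise with Gauss-Seidel residual
updating: the full conditional of bj needs only the dot product xj'e and the
precomputed sum of squares dj = xj'xj, and after each draw the length-n
residual vector is updated incrementally (e ← e − xj·Δbj), so a full round
costs about 3pn operations instead of the p³ of a Cholesky solve of the
mixed-model equations.

The subsampling bootstrap Markov chain (SBMC) draws one random bag of
m = round(ψ·n) observations per MCMC round, shared by the intercept update,
all p coefficient updates and the residual-variance update. The bagged
coefficient conditional replaces xj'e by the in-bag dot product x̃j'ẽ and
dj by ψ·dj — the bag is assumed to have the same allele frequencies as the
whole panel, so the sum of squares shrinks linearly and is never recomputed
per round. The residual-variance draw uses the in-bag sum of squares with
ψn + νe degrees of freedom; the genetic-variance draw uses the full effect
vector and is unchanged. At ψ = 1 without replacement every formula reduces
exactly to the full-data sampler, and the test suite asserts bit-for-bit
equality against an independently coded plain GSRU chain sharing the same
RNG stream.

## Choices the update equations leave open

- **Residual bookkeeping.** Only in-bag residuals are needed for the
  updates, but letting out-of-bag entries go stale would corrupt later
  rounds that bag them. The chain therefore maintains the full length-n
  residual: every coefficient change updates all n entries, and the
  ψ-speedup comes from the bagged dot products. The residual identity
  e = y − μ − Xb is enforced as an invariant (drift stays near machine
  precision over hundreds of rounds).
- **Bag size with replacement.** m = round(ψ·n) in both modes; with
  replacement, multiplicities count in the dot products and in ẽ'ẽ, while
  each physical row's residual is updated once.
- **Intercept.** The update rule is not pinned down by the coefficient and
  variance equations; a flat-prior conjugate draw on the bagged residual
  mean is used: μ' ~ N(μ + mean(ẽ), σe²/m), followed by a shift of all n
  residuals.
- **Update order.** Fixed ascending marker order by default (reproducible
  and required for the exact-reduction check); a fresh permutation per round
  is available via `update_order="permuted"`.
- **Initialization.** μ = mean(y), b = 0, and the phenotypic variance split
  by the prior R²: σe² = (1−R²)σy², σb² = R²σy²/Σσ²xj (mirroring the prior
  elicitation).
- **Posterior summary.** No thinning; posterior means over all post-burn-in
  draws (default 4000 iterations, 500 burn-in).
- **Degeneracies.** Variance draws are floored at 1e-12 so λ never divides
  by zero; a marker with dj = 0 (monomorphic column that survived
  filtering) keeps its effect at exactly 0.

## Cost accounting

Wall-clock time depends on hardware and JIT state, so computational cost is
asserted through a deterministic counter of in-bag observation touches: m
per marker dot product per round, i.e. exactly p·round(ψ·n) per round. This
is the quantity that scales as 3pnψ; wall-clock minutes are recorded in all
reports but never asserted.

## Simulated F2 design

The generator crosses two fully inbred lines fixed for opposite alleles,
selfs the uniformly heterozygous F1, and builds each F2 individual from two
independent F1 gametes. Defaults: 10 chromosomes × 50 cM, markers every
1 cM starting at 1 cM (p = 500), one QTL per 10 cM window at positions 5.5,
15.5, 25.5, 35.5, 45.5 cM (midway between two markers; q = 50, excluded
from the marker panel), n = 400.

- **Meiosis** follows the Haldane (no-interference) model: recombination
  fraction c(d) = (1 − e^(−0.02d))/2 between loci d cM apart, independent
  assortment across chromosomes.
- **QTL effects** are i.i.d. standard normal (a conventional default; the
  design fixes only the QTL density). Genetic values use the centered F2
  coding g = Σ aq(zq − 1).
- **Noise** is Gaussian with variance var(g)(1 − h²)/h² computed from the
  realized genetic variance, targeting h² = 0.5.
- Note that in an F2 from inbred lines all loci are in coupling-phase LD:
  the dosage correlation between QTL 10 cM apart is 1 − 2c(10) ≈ 0.82, so
  var(g) differs substantially from the unlinked sum Σaq²/2. The tests
  validate it against the exact form 0.5·a'Ra with R_qr = 1 − 2c(d_qr)
  within a chromosome.
- Markers with minor allele frequency below 0.05 (allele frequency folded
  at 0.5, strict inequality) are removed before fitting; at the F2's
  expected frequency of 0.5 this filter is almost always a no-op on
  simulated panels, but it is part of the standard pipeline for real data.

What the generator does **not** emulate: dominance and epistasis, crossover
interference, genotyping errors or missingness, population structure and
family stratification, and allele-frequency spectra of diverse panels.
Passing tests on this design therefore demonstrate correctness of the
sampler and protocol, not expected predictive ability on real populations,
where LD patterns and genetic architecture differ.

## Evaluation protocol

10-fold cross-validation with balanced random folds; within each fold the
prior shapes and marker sums of squares are recomputed on the training rows
only. Metrics are computed per fold and on the pooled out-of-fold
predictions (pooling uses each observation exactly once; the aggregate is
the headline number): predictive ability (Pearson r between observed and
predicted), MSPE, and dispersion bias as the OLS slope of observations on
predictions. The MAF filter is applied once to the full panel before CV, as
panel preprocessing rather than a per-fold step. The ψ-sweep driver runs
this protocol over a grid of subsampling proportions (default 0.25–1.00 in
steps of 0.01) for both replacement modes, with an optional replicate count
because single-run ψ-curves are noisy.

## Problem sizes used in the checks

The closed-form-ridge comparison uses n = 100, p = 20 with variances frozen
and 10,000 iterations, judged per coefficient against 3 batch-means
Monte-Carlo standard errors. Signal recovery runs the full protocol (n =
400, p = 500, 4000/500 iterations, 5 seeds); the negligible-loss comparison
(ψ = 0.33 without replacement and ψ = 0.5 with replacement vs ψ = 1) uses
1500/250 iterations over 10 replicate seeds — the GSRU chain mixes quickly
on this design, and the comparison is between settings run at identical
lengths. Simulator calibration uses n = 10,000 individuals and 20,000
gametes.

## Known limitations

- Single trait, additive effects, one common effect variance (no
  BayesA/B/Cπ-style mixtures), no GxE, single chain.
- Missing genotypes are rejected, not imputed; binary PLINK (.bed) and VCF
  are out of scope (plain-text matrix and PLINK .raw dialects only).
- ψ is a fixed fraction per run; no adaptive or scheduled subsampling.
- Convergence diagnostics are limited to stored traces of μ, σb², σe²
  (and optionally b).
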