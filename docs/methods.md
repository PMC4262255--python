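# Methods

This note documents the models, numerical choices and limitations of
`ssbr`. It is the package's own account; every number quoted here is
computed by the test suite or the acceptance script.

## Model and assumptions

The single-step marker effects model (MEM) is

    y = X β + J μ_g + W α + Z₁ ε + e,

with W = [M̂₁; M₂] stacking imputed and observed dosage covariates,
M̂₁ = A₁₂A₂₂⁻¹M₂ the best linear prediction of the missing covariates given
the pedigree, ε ~ N(0, (A¹¹)⁻¹σ²_ε) the imputation residual, and
e ~ N(0, Iσ²_e). The key assumptions inherited from the underlying theory:

* Breeding values are completely captured by the marker covariates for
  genotyped animals (no residual polygenic term beyond ε, which exists only
  for non-genotyped animals).
* ε is independent of g₂ — exact under multivariate normality of breeding
  values, a good approximation when many loci contribute.
* Best linear prediction is used for imputation; it is optimal only under
  normality and uses single-locus pedigree information, not linkage or LD.
  Imputed dosages are real-valued and deliberately **not clamped** to
  [0, 2]: clamping would break the exact equivalence between the MEM, the
  breeding-value model (BVM), and the ε-absorbed system.

Three formulations of the mixed model equations are implemented and tested
to agree to 1e−8 on random instances:

1. **MEM** — unknowns (β, μ_g, α, ε); marker diagonal shrunk by
   λ_α = σ²_e/σ²_α, ε block Z₁'Z₁ + λ_ε A¹¹ (sparse).
2. **BVM** — unknowns (β, μ_g, a) with Var(a) induced by a₂ = M₂α,
   a₁ = M̂₁α + ε. Requires M₂M₂' full rank, so it is only usable when
   markers outnumber genotyped animals; the MEM has no such restriction.
3. **ABSORBED** — ε eliminated by absorption through sparse solves against
   (Z₁'Z₁ + λ_ε A¹¹); retained solutions and the corresponding inverse-lhs
   elements equal the full system's. ε̂ is recovered afterwards by one
   back-solve, so predicted breeding values agree across formulations.

A dense single-step covariance matrix H (blending M₂M₂'σ²_α with pedigree
blocks and (A¹¹)⁻¹σ²_ε) is provided as a toy-scale oracle only; BLUP with H
is computed through V = ZHZ' + Iσ²_e, avoiding H⁻¹, and reproduces the MEM
breeding values. The production path never forms H, G, or their inverses.

## Pedigree machinery

A⁻¹ is assembled directly by Henderson's rules with Mendelian-sampling
variances d_i = ½ − ¼(F_s + F_d) (one- and zero-parent variants
accordingly); inbreeding coefficients F come from a memoized tabular
(Quaas-style) recursion, so inbred pedigrees are handled exactly —
verified against the dense tabular A on random pedigrees (max deviation
< 1e−8 over 100 pedigrees up to 200 individuals). Individuals are
re-indexed parents-before-offspring; genotyped ("set 2") ordering follows
the genotype-file row order so M₂ never needs a join. A¹¹ is factorized
once (SuperLU) and the factor reused for all imputation columns, J₁, and
ε solves.

## Samplers

Gibbs sampling uses the corrected-phenotype cache: ycorr = y minus all
current effects; for each effect the full-conditional right-hand side is
rhs_i = w_i'ycorr + (w_i'w_i)·α_i, and ycorr is updated only when the
effect changes. After any number of sweeps the cache agrees with a
from-scratch recomputation to 1e−8 (tested).

* Priors: BayesA (per-locus variances, π = 0), BayesB (mixture +
  per-locus variances), BayesC (mixture + common variance), BayesCπ
  (π ~ Uniform, updated from a Beta full conditional on the inclusion
  counts). The inclusion indicator is sampled from the marginal odds of
  rhs_i under the two mixture components before the effect is drawn.
* Variances have scaled-inverse-chi-square full conditionals; σ²_ε uses
  scale (ε'A¹¹ε + ν_g S²_g) with df n_ε + ν_g. In BayesB a locus variance
  is redrawn from its prior while the locus is excluded — the standard
  resolution where the conditional is otherwise undefined.
* ε is sampled single-site over the sparse A¹¹ rows, or as a block: the
  conditional mean solve plus a correctly covaried deviate built from an
  auxiliary pedigree draw (solve L'x = z against the Cholesky of A¹¹) and
  an auxiliary residual draw. Both strategies give statistically
  indistinguishable summaries (tested at 3 combined Monte-Carlo SEs).
* The **absorbed sampler** runs single-site Gibbs on the ε-absorbed system
  with an incrementally maintained rhs cache v = r − Cθ, updated with one
  column of C only when an effect changes; per-iteration cost is
  independent of the number of records, and with π near 1 almost no
  updates occur per sweep.
* Sampling order per iteration: fixed effects (μ_g last) → markers in
  storage order → ε → variances → π. One seeded `numpy.random.Generator`
  drives everything; identical seeds give bit-identical summaries.

Monte-Carlo standard errors of posterior means are estimated by batch
means (about 50 batches). On the shipped worked example the posterior is
very diffuse — five records inform fifteen location parameters, the
posterior SD of μ_g is ≈ 4.7 and the sweep operator's spectral radius is
0.979 — so posterior-mean breeding values at 50k sweeps carry MC errors of
a few hundredths; agreement with BLUP is therefore asserted at 3 MCSEs,
not at a fixed small tolerance.

## Default hyperparameters

ν_α = ν_e = ν_g = 4; prior scales are set from user-supplied variances by
mode matching, S² = var·(ν + 2)/ν. Burn-in defaults to 20% of the chain;
thinning defaults to 1. All are overridable. Fixed effects get flat priors
(zero shrinkage); rank of the fixed block is checked with tolerance 1e−8
and a confounded set is reported by name (e.g. J collinear with the
intercept when every animal is genotyped). The direct dense solver is the
default; conjugate gradients with a Jacobi preconditioner (relative
residual < 1e−10) are available behind the same contract for large sparse
systems.

## The synthetic halfsib study

`ssbr.simulate` emulates a paternal halfsib design: 20 unrelated sires ×
20 unrelated dams each, one offspring per mating (820 animals); only the
400 offspring are genotyped; phenotypes are recorded for all offspring and
the first 210 dams. Defaults: 100 markers including 50 QTL, h² = 0.5,
founder allele frequencies Uniform(0.1, 0.9) (bounds avoid monomorphic
loci and keep Σ2pq stable for the σ²_g → σ²_α conversion).

Two design choices matter and were made on genetic grounds:

* **Linkage.** Markers sit on a single 1-Morgan chromosome; founder
  haplotypes are in linkage equilibrium and offspring gametes are dropped
  with Haldane recombination. Within halfsib families, linked markers then
  co-segregate in parental chunks, which is what makes a few hundred
  records informative about a 100-marker panel (and what makes accuracy
  *fall*, not collapse, when the panel grows into the thousands). Fully
  unlinked loci cannot produce that regime: they push the effective number
  of independent segments to the marker count and depress accuracy for
  any panel much wider than the record count.
* **Effect scaling with a non-null mean.** QTL deviations are scaled so
  their founder genetic variance equals h² against a unit environmental
  baseline; the mean shift μ_α is then added in trait units and the
  environmental variance is re-set from the realized total genetic
  variance so h² is exact. Scaling mean and deviations jointly would leave
  every accuracy invariant to μ_α (BLUP is scale-free), erasing the very
  phenomenon the centering study examines: with uncentered covariates and
  no μ_g, a non-null effect mean biases records of non-genotyped animals
  relative to genotyped ones and drags down accuracy.

What the generator does **not** emulate: population-level LD among
founders (founders are in linkage equilibrium), selection, multiple
generations, genotyping errors, and non-normal effect distributions.
Passing the accuracy checks therefore demonstrates correct single-step
machinery under an idealized mapping design, not calibrated performance on
real livestock data.

With these conditions, 20-replicate mean accuracies of centered single-step
BLUP are ≈ 0.65 (non-genotyped) and ≈ 0.92 (genotyped) at μ_α = 0, the
centered and uncentered-plus-μ_g variants agree to two decimals everywhere,
and at μ_α = 0.2 the no-centering/no-μ_g variant loses ≈ 0.07 of genotyped
accuracy. The size of that penalty (though not its presence or direction)
depends on the ratio of μ_α to the QTL-effect SD, which the emulated study
design does not pin down; under our convention the ratio is ≈ 1.25.

## Problem sizes

Test-suite simulations use the full 820-animal halfsib design with 100
markers (20 replicates per scenario) and a 2,000-marker variant (the
many-marker regime) with 2 replicates; parameter recovery uses 500
genotyped individuals × 200 markers with a 3,000-sweep chain; the
sampler–BLUP check uses a 50,000-sweep chain on the worked example. These
sizes make every result reproducible in minutes on one core while keeping
each check in its intended statistical regime.

## Known limitations

* BVM requires a full-rank M₂M₂' (markers ≥ genotyped animals); use MEM
  otherwise — this mirrors the rank deficiency of G itself.
* The J covariate is a BLP weight row-sum; outside simple designs it can
  fall below −1 (it is not clamped), and likewise imputed dosages can
  exit [0, 2].
* Single-trait, single-record-class models only; no genetic groups,
  metafounders, maternal effects, or linkage/LD-based imputation.
* The samplers are serial; the chunked crossproduct preserves the
  contract needed for parallel assembly but runs chunks serially here.
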