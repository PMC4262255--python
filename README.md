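# ssbr — single-step Bayesian regression for genomic prediction

`ssbr` estimates breeding values by combining three sources of information in
one model: phenotypes, a pedigree, and SNP genotypes that are available for
only a subset of the animals. It is aimed at animal and plant breeders and
quantitative geneticists who want single-step evaluations with
marker-effect (whole-genome regression) models — including Bayesian
variable-selection priors — instead of assembling and inverting a genomic
relationship matrix **G**.

## The model

Phenotypes are regressed on marker covariates for *all* animals:

```
y = X β + J μ_g + W α + Z₁ ε + e
```

* `W` stacks observed allele dosages **M₂** for genotyped animals and
  pedigree-imputed covariates **M̂₁ = A₁₂ A₂₂⁻¹ M₂** for the rest. The
  imputation is computed without dense inverses by solving the very sparse
  system `A¹¹ M̂₁ = −A¹² M₂`, where `Aⁱʲ` are blocks of the pedigree
  relationship inverse **A⁻¹** (built directly from Henderson's rules with
  inbreeding by the Meuwissen–Luo/Quaas recursion).
* `ε` is the **imputation residual** — the deviation of a non-genotyped
  animal's breeding value from its imputed prediction — with
  `Var(ε) = (A¹¹)⁻¹ σ²_ε`, so its *precision* is sparse.
* `μ_g = k'α` is a fixed effect that replaces centering of marker covariates
  when founder allele frequencies `k'/2` are unknown; its covariate `J` is
  −1 for genotyped animals and the solution of `A¹¹ J₁ = −A¹² J₂` otherwise.
* `α` carries the marker-effect prior: normal (BLUP / BayesC with π = 0),
  *t*-like per-locus variances (BayesA), or spike-and-slab mixtures with
  exclusion probability π (BayesB, BayesC, BayesCπ with π unknown).

BLUP solutions come from any of three equivalent systems — the marker
effects MME, the equivalent breeding-value model, or the ε-absorbed MME —
and predicted breeding values are `ĝ₂ = M₂ α̂ + J₂ μ̂_g` and
`ĝ₁ = M̂₁ α̂ + J₁ μ̂_g + ε̂`. Bayesian posteriors come from Gibbs samplers
with corrected-phenotype (`ycorr`) caching, so each full-conditional
right-hand side is one dot product. Nothing ever forms or inverts **G**,
and the MME do not grow as more animals are genotyped.

## Worked example

A six-animal pedigree ships with the package: three founders, two full sibs
and one half sib; animals 1, 2 and 4 are genotyped at ten markers; five
animals have phenotypes. With variance ratios λ_α = σ²_e/σ²_α = 10/9 and
λ_ε = σ²_e/σ²_ε = 1/9:

```python
import ssbr

ped, markers, phenotypes, cfg = ssbr.load_worked_example()
data = ssbr.SSBRData(ped, markers, phenotypes)
est = ssbr.SingleStepBLUP(var_e=1.0, lambda_alpha=10/9, lambda_eps=1/9)
est.fit(data)
print(est.solution_[["mu", "mu_g"]].round(3))
print(est.bv_.round(3))
```

prints

```
mu     -0.341
mu_g   -1.618
3   -0.000
5    1.610
6    0.802
1    1.617
2    1.598
4    1.633
```

`mu` is the general mean of the five records and `mu_g` the breeding-value
mean carried by the J covariate. The per-animal values are single-step BLUP
breeding values: the unphenotyped sire (animal 1) is evaluated from its
genotype and its relatives' records, the non-genotyped full sib (animal 5)
from its imputed covariates, and the unrelated non-genotyped founder
(animal 3) only through its own record via ε — hence a value near zero.
Swapping `formulation="bvm"` or `"absorbed"` reproduces the same numbers to
solver precision, and `SingleStepBayes(method="BayesC", pi=0.0, ...)` with
fixed variances converges to them in posterior mean.

The same workflow is available from the shell:

```
ssbr fixture -o example
ssbr blup -p example/pedigree.txt -g example/genotypes.txt \
          -y example/phenotypes.txt -c example/config.txt -o out
ssbr mcmc -p example/pedigree.txt -g example/genotypes.txt \
          -y example/phenotypes.txt -c example/config.txt \
          --method bayesC --chain 50000 --seed 42 -o out-mcmc
ssbr simulate --markers 100 --qtl 50 --seed 7 -o sim
```

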