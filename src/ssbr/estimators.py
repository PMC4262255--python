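"""Scikit-learn style estimators wrapping the single-step machinery.

Because a single-step analysis needs three linked inputs -- a pedigree, a
genotype matrix over a subset of individuals, and a phenotype table -- the
estimators take a single :class:`SSBRData` bundle in ``fit`` rather than an
(X, y) pair. Otherwise they follow the scikit-learn contract: parameters set
in ``__init__`` and reachable via ``get_params``/``set_params``, fitted
state in trailing-underscore attributes, ``predict`` for breeding values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import imputation, mme as mme_mod
from .imputation import ImputedCovariates, MarkerData
from .mme import Design, Formulation, ModelSpec
from .pedigree import Pedigree, RelationshipSystem, build_A_inverse

__all__ = ["SSBRData", "SingleStepBLUP", "SingleStepBayes"]


@dataclass
class SSBRData:
    """Pedigree + genotypes + phenotypes, with derived quantities cached.

    ``genotype_ids`` gives the genotype-file row order; set-2 ordering
    follows it so M2 rows never need re-joining.
    """

    pedigree: Pedigree
    markers: MarkerData
    phenotypes: pd.DataFrame
    rel: RelationshipSystem = field(default=None, repr=False)

    def __post_init__(self):
        if self.rel is None:
            self.rel = build_A_inverse(self.pedigree)
        if self.markers.M2.shape[0] != self.rel.n2:
            raise ValueError("genotype rows do not match genotyped set of pedigree")

    @classmethod
    def from_tables(cls, pedigree_records, genotype_ids, markers: MarkerData,
                    phenotypes: pd.DataFrame) -> "SSBRData":
        ped = Pedigree.from_records(
            pedigree_records, genotype_ids, genotyped_order=list(genotype_ids)
        )
        return cls(ped, markers, phenotypes)

    def imputed(self, centering=None) -> tuple[MarkerData, ImputedCovariates]:
        md = self.markers
        if centering is not None and centering != "none":
            md = imputation.center_markers(md, centering)
        return md, imputation.impute_markers(self.rel, md)


class SingleStepBLUP(BaseEstimator):
    """Single-step BLUP of breeding values via the marker effects model.

    Parameters
    ----------
    formulation : "mem", "bvm" or "absorbed" -- which of the three
        equivalent mixed-model formulations to assemble and solve.
    var_e, var_alpha, var_eps : variance components (alternatively the
        ratios lambda_alpha = var_e/var_alpha, lambda_eps = var_e/var_eps).
    fit_mu_g : fit the fixed effect mu_g with the J covariate instead of
        centering marker covariates.
    centering : None/"none", "observed-mean", or a per-marker vector k'.
    fixed_effects : names of extra fixed-effect columns in the phenotypes.
    solver : "direct" or "cg".

    Attributes (after fit)
    ----------------------
    solution_ : labeled solutions of the mixed model equations.
    bv_ : predicted breeding value per individual (pandas Series).
    mme_ : the assembled :class:`MMESystem`.
    """

    def __init__(self, formulation="mem", var_e=1.0, var_alpha=None,
                 var_eps=None, lambda_alpha=None, lambda_eps=None,
                 fit_mu_g=True, centering=None, fixed_effects=(),
                 solver="direct", tol=1e-10):
        self.formulation = formulation
        self.var_e = var_e
        self.var_alpha = var_alpha
        self.var_eps = var_eps
        self.lambda_alpha = lambda_alpha
        self.lambda_eps = lambda_eps
        self.fit_mu_g = fit_mu_g
        self.centering = centering
        self.fixed_effects = fixed_effects
        self.solver = solver
        self.tol = tol

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            var_e=self.var_e, var_alpha=self.var_alpha, var_eps=self.var_eps,
            lambda_alpha=self.lambda_alpha, lambda_eps=self.lambda_eps,
            fit_mu_g=self.fit_mu_g, fixed_effects=tuple(self.fixed_effects),
        )

    def fit(self, data: SSBRData, y=None) -> "SingleStepBLUP":
        if not isinstance(data, SSBRData):
            raise TypeError("fit expects an SSBRData bundle")
        spec = self._spec()
        md, cov = data.imputed(self.centering)
        design = mme_mod.build_W(cov, md, data.pedigree, data.phenotypes,
                                 fixed_effects=self.fixed_effects)
        form = Formulation(self.formulation)
        if form is Formulation.BVM:
            system = mme_mod.build_mme_bvm(md, cov, data.rel, spec, design)
        else:
            system = mme_mod.build_mme_mem(design, data.rel, spec, md.marker_ids)
            if form is Formulation.ABSORBED:
                system = mme_mod.absorb_epsilon(system, data.rel)
        self.solution_ = mme_mod.solve_blup(system, method=self.solver, tol=self.tol)
        self.bv_ = mme_mod.predict_bv(self.solution_, cov, md, system)
        self.mme_ = system
        self.covariates_ = cov
        self.markers_ = md
        self.spec_ = spec
        return self

    def predict(self, ids=None) -> np.ndarray:
        """Breeding values for ``ids`` (default: all individuals)."""
        if not hasattr(self, "bv_"):
            raise AttributeError("estimator is not fitted")
        if ids is None:
            return self.bv_.to_numpy()
        return self.bv_.loc[[str(i) for i in ids]].to_numpy()


class SingleStepBayes(BaseEstimator):
    """Single-step Bayesian regression (BayesA/B/C/Cpi) by Gibbs sampling.

    Parameters mirror :class:`SingleStepBLUP` for variances, plus the prior
    family (``method``), the prior exclusion probability ``pi``, chain
    controls, and ``estimate_variances`` to toggle variance-component
    sampling (fixed-variance BayesC with pi=0 is BLUP in expectation).

    Attributes (after fit)
    ----------------------
    summary_ : :class:`ssbr.mcmc.PosteriorSummary`.
    bv_ : posterior-mean breeding values (pandas Series).
    """

    def __init__(self, method="BayesC", pi=0.0, var_e=1.0, var_alpha=None,
                 var_eps=None, lambda_alpha=None, lambda_eps=None,
                 fit_mu_g=True, centering=None, fixed_effects=(),
                 n_iter=10000, burn_in=None, thin=1, seed=0,
                 estimate_variances=True, eps_strategy="single-site",
                 nu_alpha=4.0, nu_e=4.0, nu_g=4.0):
        self.method = method
        self.pi = pi
        self.var_e = var_e
        self.var_alpha = var_alpha
        self.var_eps = var_eps
        self.lambda_alpha = lambda_alpha
        self.lambda_eps = lambda_eps
        self.fit_mu_g = fit_mu_g
        self.centering = centering
        self.fixed_effects = fixed_effects
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.estimate_variances = estimate_variances
        self.eps_strategy = eps_strategy
        self.nu_alpha = nu_alpha
        self.nu_e = nu_e
        self.nu_g = nu_g

    def fit(self, data: SSBRData, y=None) -> "SingleStepBayes":
        from . import mcmc

        if not isinstance(data, SSBRData):
            raise TypeError("fit expects an SSBRData bundle")
        spec = ModelSpec(
            var_e=self.var_e, var_alpha=self.var_alpha, var_eps=self.var_eps,
            lambda_alpha=self.lambda_alpha, lambda_eps=self.lambda_eps,
            fit_mu_g=self.fit_mu_g, fixed_effects=tuple(self.fixed_effects),
            pi=self.pi, nu_alpha=self.nu_alpha, nu_e=self.nu_e, nu_g=self.nu_g,
        ).scales_from_mode()
        md, cov = data.imputed(self.centering)
        design = mme_mod.build_W(cov, md, data.pedigree, data.phenotypes,
                                 fixed_effects=self.fixed_effects)
        self.summary_ = mcmc.run_chain(
            design, data.rel, spec, method=self.method, n_iter=self.n_iter,
            burn_in=self.burn_in, thin=self.thin, seed=self.seed,
            estimate_variances=self.estimate_variances,
            eps_strategy=self.eps_strategy,
        )
        self.bv_ = self.summary_.bv_mean
        self.covariates_ = cov
        self.markers_ = md
        self.spec_ = spec
        return self

    def predict(self, ids=None) -> np.ndarray:
        if not hasattr(self, "bv_"):
            raise AttributeError("estimator is not fitted")
        if ids is None:
            return self.bv_.to_numpy()
        return self.bv_.loc[[str(i) for i in ids]].to_numpy()
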