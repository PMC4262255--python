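"""Single-step mixed model equations in three equivalent formulations.

The single-step marker effects model (MEM) regresses phenotypes of both
genotyped and non-genotyped animals on marker covariates,

    y = X beta + J mu_g + W alpha + Z1 eps + e,

where W stacks observed dosages M2 (genotyped) and pedigree-imputed dosages
M1_hat (non-genotyped), J is the covariate of the fixed effect mu_g = k'alpha
that stands in for centering, and eps is the imputation residual with
precision A^{11} / sigma^2_eps. Three formulations of the normal equations
are assembled here:

* MEM       -- unknowns (beta, mu_g, alpha, eps); marker diagonal shrunk by
               lambda_alpha = sigma^2_e / sigma^2_alpha, eps block
               Z1'Z1 + lambda_eps A^{11}.
* BVM       -- the equivalent breeding value model with unknowns
               (beta, mu_g, a), Var(a) induced by a2 = M2 alpha,
               a1 = M1_hat alpha + eps.
* ABSORBED  -- the MEM with eps eliminated by absorption, leaving a dense
               system over (beta, mu_g, alpha) whose solutions (and the
               corresponding inverse-lhs elements) match the full MEM.

All three give identical fixed-effect solutions and breeding values; the MEM
dimension is fixed + 1 + markers + |set 1| and does not grow with the number
of genotyped animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import cg as _cg

from .imputation import ImputedCovariates, MarkerData
from .pedigree import Pedigree, RelationshipSystem

__all__ = [
    "ModelSpec",
    "MMESystem",
    "Design",
    "Formulation",
    "build_W",
    "build_mme_mem",
    "build_mme_bvm",
    "absorb_epsilon",
    "solve_blup",
    "predict_bv",
    "build_H",
]


class Formulation(str, Enum):
    MEM = "mem"
    BVM = "bvm"
    ABSORBED = "absorbed"


@dataclass
class ModelSpec:
    """Variances, priors and fixed-effect layout for a single-step model.

    Either the variances (var_alpha, var_eps) or the ratios
    (lambda_alpha = var_e/var_alpha, lambda_eps = var_e/var_eps) may be given;
    if both are given they must agree. ``prior`` carries the MCMC
    hyperparameters: pi (prior exclusion probability), nu_* degrees of
    freedom and S2_* scales of the scaled-inverse-chi-square priors.
    """

    var_e: float = 1.0
    var_alpha: float | None = None
    var_eps: float | None = None
    lambda_alpha: float | None = None
    lambda_eps: float | None = None
    fit_mu_g: bool = True
    fixed_effects: tuple[str, ...] = ()
    pi: float = 0.0
    nu_alpha: float = 4.0
    nu_e: float = 4.0
    nu_g: float = 4.0
    S2_alpha: float | None = None
    S2_e: float | None = None
    S2_g: float | None = None

    def __post_init__(self):
        if self.var_e <= 0:
            raise ValueError("var_e must be positive")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        for var_name, lam_name in (("var_alpha", "lambda_alpha"),
                                   ("var_eps", "lambda_eps")):
            var = getattr(self, var_name)
            lam = getattr(self, lam_name)
            if var is not None and var <= 0:
                raise ValueError(f"{var_name} must be positive")
            if lam is not None and lam <= 0:
                raise ValueError(f"{lam_name} must be positive")
            if var is not None and lam is not None:
                if not np.isclose(lam, self.var_e / var, rtol=1e-8):
                    raise ValueError(f"{var_name} and {lam_name} are inconsistent")
            elif var is not None:
                setattr(self, lam_name, self.var_e / var)
            elif lam is not None:
                setattr(self, var_name, self.var_e / lam)
            else:
                raise ValueError(f"one of {var_name} or {lam_name} is required")

    def scales_from_mode(self) -> "ModelSpec":
        """Fill missing prior scales so the prior mode sits at the given
        variance (S2 = var * (nu + 2) / nu)."""
        if self.S2_alpha is None:
            self.S2_alpha = self.var_alpha * (self.nu_alpha + 2) / self.nu_alpha
        if self.S2_e is None:
            self.S2_e = self.var_e * (self.nu_e + 2) / self.nu_e
        if self.S2_g is None:
            self.S2_g = self.var_eps * (self.nu_g + 2) / self.nu_g
        return self


@dataclass
class Design:
    """Record-level and population-level design matrices for one data set."""

    X: np.ndarray                  # records x fixed effects (incl. intercept)
    fixed_labels: list[str]
    J: np.ndarray                  # records-level mu_g covariate
    W: np.ndarray                  # records x markers (observed or imputed)
    Z1: sp.csr_matrix              # records x |set 1|
    y: np.ndarray
    record_ids: list[str]
    W_full: np.ndarray             # individuals (set1+set2 order) x markers
    J_full: np.ndarray
    individual_ids: list[str]      # set1 ids then set2 ids
    n_set1: int


@dataclass
class MMESystem:
    """Left-hand side, right-hand side and labels of one MME formulation.

    ``shrink`` records the variance-ratio terms added to the diagonal, so
    samplers can recover raw crossproducts; the first ``n_fixed`` equations
    (fixed effects and mu_g) carry no shrinkage.
    """

    lhs: np.ndarray
    rhs: np.ndarray
    labels: list[str]
    formulation: Formulation
    n_fixed: int
    shrink: np.ndarray
    design: Design | None = field(default=None, repr=False)
    n_markers: int = 0
    lambda_eps: float | None = None
    A11: sp.spmatrix | None = field(default=None, repr=False)

    @property
    def marker_slice(self) -> slice:
        return slice(self.n_fixed, self.n_fixed + self.n_markers)

    def __post_init__(self):
        if self.lhs.shape != (len(self.labels), len(self.labels)):
            raise ValueError("lhs dimension does not match labels")
        if not np.allclose(self.lhs, self.lhs.T, atol=1e-8):
            raise ValueError("lhs is not symmetric")


def _fixed_design(phen: pd.DataFrame, fixed_effects) -> tuple[np.ndarray, list[str]]:
    n = len(phen)
    cols = [np.ones(n)]
    labels = ["mu"]
    for name in fixed_effects:
        if name not in phen.columns:
            raise ValueError(f"fixed effect column {name!r} missing from phenotypes")
        col = phen[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            labels.append(name)
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
                labels.append(c)
    return np.column_stack(cols), labels


def build_W(
    cov: ImputedCovariates,
    md: MarkerData,
    ped: Pedigree,
    phenotypes: pd.DataFrame,
    fixed_effects=(),
) -> Design:
    """Assemble record-level design matrices from phenotypes and covariates.

    ``phenotypes`` needs columns ``id`` and ``y``; repeated records per
    individual are allowed (handled by the incidence matrix Z). Individuals
    without phenotypes simply contribute no record.
    """
    phen = phenotypes.copy()
    phen["id"] = phen["id"].astype(str).str.strip()
    unknown = set(phen["id"]) - set(ped.order)
    if unknown:
        raise ValueError(f"phenotyped ids not in pedigree: {sorted(unknown)}")

    set1_ids = ped.set1_ids
    set2_ids = ped.set2_ids
    set1_index = {i: k for k, i in enumerate(set1_ids)}
    set2_index = {i: k for k, i in enumerate(set2_ids)}

    n_rec = len(phen)
    m = md.n_markers
    W = np.empty((n_rec, m))
    J = np.empty(n_rec)
    z_rows, z_cols = [], []
    for r, ind in enumerate(phen["id"]):
        if ind in set2_index:
            k = set2_index[ind]
            W[r] = md.M2[k]
            J[r] = cov.J2[k]
        else:
            k = set1_index[ind]
            W[r] = cov.M1_hat[k]
            J[r] = cov.J1[k]
            z_rows.append(r)
            z_cols.append(k)
    Z1 = sp.csr_matrix(
        (np.ones(len(z_rows)), (z_rows, z_cols)), shape=(n_rec, len(set1_ids))
    )
    X, fixed_labels = _fixed_design(phen, fixed_effects)
    W_full = np.vstack([cov.M1_hat, md.M2]) if m else np.zeros((ped.n, 0))
    J_full = np.concatenate([cov.J1, cov.J2])
    return Design(
        X=X,
        fixed_labels=fixed_labels,
        J=J,
        W=W,
        Z1=Z1,
        y=phen["y"].to_numpy(dtype=float),
        record_ids=list(phen["id"]),
        W_full=W_full,
        J_full=J_full,
        individual_ids=set1_ids + set2_ids,
        n_set1=len(set1_ids),
    )


def _effects_matrix(design: Design, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """[X, J?, W] over records, with labels."""
    blocks = [design.X]
    labels = list(design.fixed_labels)
    if spec.fit_mu_g:
        blocks.append(design.J[:, None])
        labels.append("mu_g")
    blocks.append(design.W)
    labels += [f"m{j + 1}" for j in range(design.W.shape[1])]
    return np.hstack(blocks), labels


def build_mme_mem(
    design: Design,
    rel: RelationshipSystem,
    spec: ModelSpec,
    marker_ids: list[str] | None = None,
) -> MMESystem:
    """MME for the marker effects model with imputed covariates.

    Fixed-effect and mu_g equations are unshrunk; every marker diagonal gets
    + lambda_alpha; the eps block is Z1'Z1 + lambda_eps A^{11}.
    """
    U, labels = _effects_matrix(design, spec)
    if marker_ids is not None:
        labels = labels[: len(labels) - design.W.shape[1]] + list(marker_ids)
    n_fixed = len(design.fixed_labels) + int(spec.fit_mu_g)
    m = design.W.shape[1]
    n1 = design.Z1.shape[1]

    UtU = U.T @ U
    UtZ = U.T @ design.Z1.toarray() if n1 else np.zeros((U.shape[1], 0))
    eps_block = (design.Z1.T @ design.Z1).toarray() + spec.lambda_eps * rel.A11.toarray()

    dim = U.shape[1] + n1
    lhs = np.zeros((dim, dim))
    lhs[: U.shape[1], : U.shape[1]] = UtU
    lhs[: U.shape[1], U.shape[1]:] = UtZ
    lhs[U.shape[1]:, : U.shape[1]] = UtZ.T
    lhs[U.shape[1]:, U.shape[1]:] = eps_block

    shrink = np.zeros(dim)
    shrink[n_fixed: n_fixed + m] = spec.lambda_alpha
    lhs[np.arange(n_fixed, n_fixed + m), np.arange(n_fixed, n_fixed + m)] += spec.lambda_alpha

    rhs = np.concatenate([U.T @ design.y, design.Z1.T @ design.y])
    labels = labels + [f"eps_{i}" for i in design.individual_ids[:n1]]
    return MMESystem(
        lhs, rhs, labels, Formulation.MEM, n_fixed, shrink, design,
        n_markers=m, lambda_eps=spec.lambda_eps, A11=rel.A11,
    )


def single_step_covariance(
    cov: ImputedCovariates, md: MarkerData, spec: ModelSpec
) -> np.ndarray:
    """Var(a) over individuals (set-1 then set-2 order) under the MEM:
    a2 = M2 alpha, a1 = M1_hat alpha + eps."""
    Wf = np.vstack([cov.M1_hat, md.M2])
    Sigma = spec.var_alpha * (Wf @ Wf.T)
    n1 = cov.M1_hat.shape[0]
    if n1:
        A11d = cov.rel.A11.toarray()
        Sigma[:n1, :n1] += spec.var_eps * np.linalg.inv(A11d)
    return Sigma


def build_mme_bvm(
    md: MarkerData,
    cov: ImputedCovariates,
    rel: RelationshipSystem,
    spec: ModelSpec,
    design: Design,
) -> MMESystem:
    """MME for the equivalent single-step breeding value model.

    Unknowns are (fixed, mu_g, a) with Var(a) induced by the marker model;
    requires Var(a2) = M2 M2' sigma^2_alpha to be non-singular (markers must
    outnumber genotyped animals or M2 be full row rank).
    """
    n_ind = len(design.individual_ids)
    ind_index = {i: k for k, i in enumerate(design.individual_ids)}
    n_rec = len(design.y)
    Za = sp.csr_matrix(
        (np.ones(n_rec), (np.arange(n_rec), [ind_index[i] for i in design.record_ids])),
        shape=(n_rec, n_ind),
    ).toarray()

    Sigma = single_step_covariance(cov, md, spec)
    try:
        Sigma_inv = np.linalg.inv(Sigma)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "single-step BV covariance is singular (M2 M2' rank deficient); "
            "use the MEM formulation"
        ) from exc

    F_blocks = [design.X]
    labels = list(design.fixed_labels)
    if spec.fit_mu_g:
        F_blocks.append(design.J[:, None])
        labels.append("mu_g")
    F = np.hstack(F_blocks)
    n_fixed = F.shape[1]

    dim = n_fixed + n_ind
    lhs = np.zeros((dim, dim))
    lhs[:n_fixed, :n_fixed] = F.T @ F
    lhs[:n_fixed, n_fixed:] = F.T @ Za
    lhs[n_fixed:, :n_fixed] = Za.T @ F
    lhs[n_fixed:, n_fixed:] = Za.T @ Za + spec.var_e * Sigma_inv
    rhs = np.concatenate([F.T @ design.y, Za.T @ design.y])
    shrink = np.zeros(dim)  # shrinkage here is the whole Sigma^{-1} block
    labels = labels + [f"a_{i}" for i in design.individual_ids]
    return MMESystem(lhs, rhs, labels, Formulation.BVM, n_fixed, shrink, design)


def absorb_epsilon(mme: MMESystem, rel: RelationshipSystem) -> MMESystem:
    """Eliminate eps from the MEM by absorption.

    The retained system over (fixed, mu_g, alpha) has the same solutions and
    the same corresponding inverse-lhs elements as the full MEM. Uses sparse
    solves against (Z1'Z1 + lambda_eps A^{11}); absorption with no set-1
    individuals is the identity.
    """
    if mme.formulation is not Formulation.MEM:
        raise ValueError("absorption starts from the MEM formulation")
    n1 = rel.n1
    if n1 == 0:
        return MMESystem(
            mme.lhs.copy(), mme.rhs.copy(), list(mme.labels),
            Formulation.ABSORBED, mme.n_fixed, mme.shrink.copy(), mme.design,
            n_markers=mme.n_markers, lambda_eps=mme.lambda_eps, A11=mme.A11,
        )
    k = len(mme.labels) - n1
    C_uu = mme.lhs[:k, :k]
    C_ue = mme.lhs[:k, k:]
    C_ee = mme.lhs[k:, k:]
    lu = sp.linalg.splu(sp.csc_matrix(C_ee))
    S = lu.solve(np.asarray(C_ue.T, order="C"))        # C_ee^{-1} C_eu
    lhs = C_uu - C_ue @ S
    rhs = mme.rhs[:k] - C_ue @ lu.solve(mme.rhs[k:])
    return MMESystem(
        (lhs + lhs.T) / 2.0, rhs, list(mme.labels[:k]),
        Formulation.ABSORBED, mme.n_fixed, mme.shrink[:k].copy(), mme.design,
        n_markers=mme.n_markers, lambda_eps=mme.lambda_eps, A11=mme.A11,
    )


def _check_fixed_rank(mme: MMESystem, tol: float = 1e-8) -> None:
    nf = mme.n_fixed
    if nf == 0:
        return
    block = mme.lhs[:nf, :nf]
    # Gram matrix of the fixed design; pivoted Cholesky-style check via eigh
    w, v = np.linalg.eigh(block)
    if w[0] < tol * max(w[-1], 1.0):
        weights = np.abs(v[:, 0])
        confounded = [mme.labels[i] for i in np.flatnonzero(weights > 1e-3)]
        raise np.linalg.LinAlgError(
            f"fixed-effect equations are rank deficient; confounded columns: {confounded}"
        )


def solve_blup(mme: MMESystem, method: str = "direct", tol: float = 1e-10) -> pd.Series:
    """Solve the MME; returns solutions labeled by effect.

    ``method`` "direct" uses a dense symmetric solve; "cg" runs conjugate
    gradients with a Jacobi preconditioner until the relative residual drops
    below ``tol``.
    """
    _check_fixed_rank(mme)
    if method == "direct":
        x = np.linalg.solve(mme.lhs, mme.rhs)
    elif method == "cg":
        diag = np.abs(np.diag(mme.lhs))
        diag[diag == 0] = 1.0
        Mpre = sp.diags(1.0 / diag)
        x, info = _cg(sp.csr_matrix(mme.lhs), mme.rhs, rtol=tol, maxiter=10 * len(mme.rhs), M=Mpre)
        if info != 0:
            raise np.linalg.LinAlgError(f"conjugate gradients did not converge (info={info})")
    else:
        raise ValueError(f"unknown solver {method!r}")
    return pd.Series(x, index=mme.labels, name="solution")


def predict_bv(
    solution: pd.Series,
    cov: ImputedCovariates,
    md: MarkerData,
    mme: MMESystem | None = None,
) -> pd.Series:
    """Per-individual predicted breeding values from any formulation.

    Set 2: g = M2 alpha + J2 mu_g. Set 1: g = M1_hat alpha + J1 mu_g + eps.
    For the absorbed system, eps is recovered by back-solving its block of
    the full MEM given the retained solutions. For the BVM, g = a + J mu_g.
    """
    design = mme.design if mme is not None else None
    mu_g = float(solution.get("mu_g", 0.0))
    if mme is not None and mme.formulation is Formulation.BVM:
        a = solution.iloc[mme.n_fixed:].to_numpy()
        return pd.Series(a + design.J_full * mu_g,
                         index=design.individual_ids, name="bv")

    if mme is not None:
        alpha = solution.iloc[mme.marker_slice].to_numpy()
    else:
        alpha = solution[[lab for lab in solution.index
                          if lab.startswith("m")]].to_numpy()
    n1 = cov.M1_hat.shape[0]
    eps_labels = [lab for lab in solution.index if lab.startswith("eps_")]
    if eps_labels:
        eps = solution[eps_labels].to_numpy()
    elif n1 and mme is not None and mme.formulation is Formulation.ABSORBED:
        eps = _recover_eps(mme, solution.to_numpy())
    else:
        eps = np.zeros(n1)
    g1 = cov.M1_hat @ alpha + cov.J1 * mu_g + eps
    g2 = md.M2 @ alpha + cov.J2 * mu_g
    values = np.concatenate([g1, g2])
    ids = design.individual_ids if design is not None else None
    return pd.Series(values, index=ids, name="bv")


def _recover_eps(mme: MMESystem, theta: np.ndarray) -> np.ndarray:
    """eps-hat = (Z1'Z1 + lambda_eps A^{11})^{-1} Z1'(y - U theta)."""
    design = mme.design
    if design is None or mme.A11 is None:
        raise ValueError("absorbed system carries no design; cannot recover eps")
    blocks = [design.X]
    if "mu_g" in mme.labels:
        blocks.append(design.J[:, None])
    blocks.append(design.W)
    U = np.hstack(blocks)
    resid = design.y - U @ theta
    Z1 = design.Z1
    C_ee = (Z1.T @ Z1) + mme.lambda_eps * mme.A11
    lu = sp.linalg.splu(sp.csc_matrix(C_ee))
    return lu.solve(Z1.T @ resid)


def build_H(
    rel: RelationshipSystem,
    md: MarkerData,
    spec: ModelSpec,
    ped: Pedigree,
) -> np.ndarray:
    """Dense single-step covariance H of breeding values (toy-scale oracle).

    Ordered set-1 then set-2. With G* = M2 M2' sigma^2_alpha,
    H22 = G*, H12 = A12 A22^{-1} G*, and
    H11 = A12 A22^{-1} G* A22^{-1} A21 + (A11 - A12 A22^{-1} A21) sigma^2_eps.
    BLUP under Var(g) = H (with the J covariate for mu_g) reproduces the MEM
    breeding values. With no genotyped animals H = A sigma^2_eps.
    """
    from .pedigree import build_A

    A = build_A(ped)
    p1, p2 = ped.set1_positions, ped.set2_positions
    A11d = A[np.ix_(p1, p1)]
    A12d = A[np.ix_(p1, p2)]
    A22d = A[np.ix_(p2, p2)]
    n1, n2 = len(p1), len(p2)
    if n2 == 0:
        return A11d * spec.var_eps
    try:
        B = A12d @ np.linalg.inv(A22d)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("A22 is singular") from exc
    Gstar = spec.var_alpha * (md.M2 @ md.M2.T)
    H = np.zeros((n1 + n2, n1 + n2))
    H[:n1, :n1] = B @ Gstar @ B.T + spec.var_eps * (A11d - B @ A12d.T)
    H[:n1, n1:] = B @ Gstar
    H[n1:, :n1] = H[:n1, n1:].T
    H[n1:, n1:] = Gstar
    return H


def solve_blup_H(
    H: np.ndarray,
    design: Design,
    spec: ModelSpec,
) -> tuple[pd.Series, pd.Series]:
    """GLS/BLUP with Var(g) = H, avoiding H^{-1} (handles singular H).

    Returns (fixed-effect solutions, per-individual breeding values
    including the J mu_g contribution).
    """
    ind_index = {i: k for k, i in enumerate(design.individual_ids)}
    n_rec = len(design.y)
    Za = np.zeros((n_rec, len(design.individual_ids)))
    for r, ind in enumerate(design.record_ids):
        Za[r, ind_index[ind]] = 1.0
    blocks = [design.X]
    labels = list(design.fixed_labels)
    if spec.fit_mu_g:
        blocks.append(design.J[:, None])
        labels.append("mu_g")
    F = np.hstack(blocks)
    V = Za @ H @ Za.T + spec.var_e * np.eye(n_rec)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(F.T @ Vi @ F, F.T @ Vi @ design.y)
    ghat = H @ Za.T @ Vi @ (design.y - F @ beta)
    mu_g = beta[labels.index("mu_g")] if spec.fit_mu_g else 0.0
    bv = ghat + design.J_full * mu_g
    return (
        pd.Series(beta, index=labels, name="solution"),
        pd.Series(bv, index=design.individual_ids, name="bv"),
    )
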