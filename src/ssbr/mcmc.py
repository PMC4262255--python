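"""Gibbs samplers for single-step Bayesian regression.

One sampler family works on the full marker effects model
(y = X beta + J mu_g + W alpha + Z1 eps + e) with the corrected-phenotype
caching scheme: a running vector ycorr = y minus all current effects makes
every full-conditional right-hand side a single dot product,

    rhs_i = w_i' ycorr + (w_i' w_i) alpha_i,

and ycorr is updated only when an effect actually changes. Marker-effect
priors cover BayesA (t-distributed effects: per-locus variances, pi = 0),
BayesB (mixture with point mass at zero and per-locus variances), BayesC
(mixture with a common variance) and BayesCpi (BayesC with pi unknown,
uniform prior). The imputation residual eps is sampled either single-site
over the sparse A^{11} rows or as a block via the
solve-plus-covaried-deviate scheme; its variance, the marker-effect
variance(s) and the residual variance have scaled-inverse-chi-square full
conditionals.

A second sampler works on the eps-absorbed system: once C = lhs and r = rhs
of the absorbed MME are formed, the right-hand-side cache rhs = r - C theta
is updated incrementally only when an effect changes, so per-iteration cost
is independent of the number of records -- and nearly zero when pi is close
to 1 and most effects stay null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .mme import Design, Formulation, MMESystem, ModelSpec
from .pedigree import RelationshipSystem

__all__ = [
    "MCMCState",
    "PosteriorSummary",
    "GibbsSampler",
    "AbsorbedGibbs",
    "run_chain",
    "sample_absorbed",
    "chunked_crossproduct",
]

_METHODS = ("BayesA", "BayesB", "BayesC", "BayesCpi")


@dataclass
class MCMCState:
    """Current values of every unknown plus the cached corrected phenotypes."""

    beta_star: np.ndarray          # fixed effects, mu_g last when fitted
    alpha: np.ndarray
    delta: np.ndarray              # inclusion indicators (bool)
    eps: np.ndarray
    var_alpha: np.ndarray          # scalar array (BayesC) or per-locus
    var_e: float
    var_eps: float
    pi: float
    ycorr: np.ndarray
    rng: np.random.Generator
    iteration: int = 0


@dataclass
class PosteriorSummary:
    """Posterior means/SDs and chain metadata."""

    bv_mean: pd.Series
    bv_sd: pd.Series
    bv_mcse: pd.Series
    effect_mean: pd.Series
    effect_sd: pd.Series
    effect_mcse: pd.Series
    inclusion_prob: pd.Series
    var_e_mean: float
    var_alpha_mean: float
    var_eps_mean: float
    var_g_mean: float              # posterior mean of var_individuals(BV)
    pi_mean: float
    settings: dict
    traces: dict = field(default_factory=dict)


def _chi2(rng, df):
    return rng.chisquare(df)


class GibbsSampler:
    """Single-site Gibbs sampler for the full single-step MEM.

    Sampling order per iteration: fixed effects (mu_g last) -> markers in
    storage order -> eps -> variances -> pi.
    """

    def __init__(self, design: Design, rel: RelationshipSystem, spec: ModelSpec,
                 method: str = "BayesC", seed: int = 0,
                 estimate_variances: bool = True,
                 eps_strategy: str = "single-site"):
        if method not in _METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
        if eps_strategy not in ("single-site", "block"):
            raise ValueError(f"unknown eps strategy {eps_strategy!r}")
        self.design = design
        self.rel = rel
        self.spec = spec.scales_from_mode()
        self.method = method
        self.estimate_variances = estimate_variances
        self.eps_strategy = eps_strategy

        X_blocks = [design.X]
        self.fixed_labels = list(design.fixed_labels)
        if spec.fit_mu_g:
            X_blocks.append(design.J[:, None])
            self.fixed_labels.append("mu_g")
        self.X = np.asfortranarray(np.hstack(X_blocks))
        self.W = np.asfortranarray(design.W)
        self.x2 = np.einsum("ij,ij->j", self.X, self.X)
        self.w2 = np.einsum("ij,ij->j", self.W, self.W)
        self.n_rec, self.m = self.W.shape
        self.n1 = design.Z1.shape[1]
        self.A11 = rel.A11.tocsr() if self.n1 else None
        self.A11_diag = self.A11.diagonal() if self.n1 else np.zeros(0)
        # record indices per set-1 individual (Z1 columns)
        Z1c = design.Z1.tocsc()
        self.rec_of_eps = [Z1c.indices[Z1c.indptr[k]: Z1c.indptr[k + 1]]
                           for k in range(self.n1)]
        self.z2 = np.array([len(r) for r in self.rec_of_eps], dtype=float)
        self._chol_cache: tuple[float, object] | None = None

        per_locus = method in ("BayesA", "BayesB")
        pi0 = 0.0 if method == "BayesA" else (0.5 if method == "BayesCpi" else spec.pi)
        self.state = MCMCState(
            beta_star=np.zeros(self.X.shape[1]),
            alpha=np.zeros(self.m),
            delta=np.ones(self.m, dtype=bool),
            eps=np.zeros(self.n1),
            var_alpha=(np.full(self.m, spec.var_alpha) if per_locus
                       else np.array([spec.var_alpha])),
            var_e=spec.var_e,
            var_eps=spec.var_eps,
            pi=pi0,
            ycorr=design.y.astype(float).copy(),
            rng=np.random.default_rng(seed),
        )

    # -- single updates ---------------------------------------------------

    def sample_fixed_effects(self) -> None:
        st = self.state
        for j in range(self.X.shape[1]):
            x = self.X[:, j]
            if self.x2[j] == 0:
                continue
            rhs = x @ st.ycorr + self.x2[j] * st.beta_star[j]
            mean = rhs / self.x2[j]
            new = st.rng.normal(mean, np.sqrt(st.var_e / self.x2[j]))
            st.ycorr -= x * (new - st.beta_star[j])
            st.beta_star[j] = new

    def sample_marker_effects(self) -> None:
        """One sweep over all markers: sample delta (BayesB/C) then alpha,
        updating ycorr only when alpha changes."""
        st = self.state
        rng = st.rng
        per_locus = st.var_alpha.shape[0] == self.m
        log1mpi = np.log1p(-st.pi) if st.pi < 1.0 else -np.inf
        logpi = np.log(st.pi) if st.pi > 0.0 else -np.inf
        for j in range(self.m):
            w = self.W[:, j]
            ww = self.w2[j]
            va = st.var_alpha[j] if per_locus else st.var_alpha[0]
            old = st.alpha[j]
            rhs = w @ st.ycorr + ww * old
            if st.pi >= 1.0:
                include = False
            elif st.pi > 0.0:
                if ww > 0.0:
                    v0 = ww * st.var_e
                    v1 = ww * ww * va + v0
                    logh1 = log1mpi - 0.5 * (np.log(v1) + rhs * rhs / v1)
                    logh0 = logpi - 0.5 * (np.log(v0) + rhs * rhs / v0)
                    p1 = 1.0 / (1.0 + np.exp(logh0 - logh1))
                else:
                    p1 = 1.0 - st.pi
                include = rng.random() < p1
            else:
                include = True
            st.delta[j] = include
            if include:
                c = ww + st.var_e / va
                new = rng.normal(rhs / c, np.sqrt(st.var_e / c))
            else:
                new = 0.0
            if new != old:
                st.ycorr -= w * (new - old)
                st.alpha[j] = new
        if not np.all(np.isfinite(st.ycorr)):
            raise FloatingPointError(
                f"non-finite corrected phenotypes at iteration {st.iteration}; "
                f"state: var_e={st.var_e}, var_alpha={st.var_alpha}, "
                f"var_eps={st.var_eps}"
            )

    def sample_epsilon(self) -> None:
        if self.n1 == 0:
            return
        if self.eps_strategy == "single-site":
            self._sample_eps_single_site()
        else:
            self._sample_eps_block()

    def _sample_eps_single_site(self) -> None:
        st = self.state
        lam = st.var_e / st.var_eps
        if not hasattr(self, "_A11_rows"):
            A = self.A11
            self._A11_rows = [
                (A.indices[A.indptr[k]: A.indptr[k + 1]],
                 A.data[A.indptr[k]: A.indptr[k + 1]])
                for k in range(self.n1)
            ]
        for k in range(self.n1):
            recs = self.rec_of_eps[k]
            idx, vals = self._A11_rows[k]
            off = lam * (vals @ st.eps[idx] - self.A11_diag[k] * st.eps[k])
            d = self.z2[k] + lam * self.A11_diag[k]
            rhs = st.ycorr[recs].sum() + self.z2[k] * st.eps[k] - off
            new = st.rng.normal(rhs / d, np.sqrt(st.var_e / d))
            if recs.size:
                st.ycorr[recs] -= new - st.eps[k]
            st.eps[k] = new

    def _sample_eps_block(self) -> None:
        """Blocked draw: solve for the conditional mean, then add a deviate
        with the right covariance built from auxiliary pedigree/residual
        draws (Garcia-Cortes & Sorensen construction)."""
        st = self.state
        lam = st.var_e / st.var_eps
        C = (sp.diags(self.z2) + lam * self.A11).tocsc()
        if self._chol_cache is None or self._chol_cache[0] != lam:
            self._chol_cache = (lam, sp.linalg.splu(C))
        lu = self._chol_cache[1]
        # rhs with ycorr currently corrected for eps as well
        r = np.array([st.ycorr[recs].sum() for recs in self.rec_of_eps])
        r += self.z2 * st.eps
        # auxiliary draws: eps* ~ N(0, A11^{-1} var_eps), e* ~ N(0, I var_e)
        z = st.rng.standard_normal(self.n1)
        # sample from N(0, A11^{-1} var_eps) by solving L' x = z (A11 = L L')
        eps_star = _sample_from_precision(self.A11, z) * np.sqrt(st.var_eps)
        e_star = st.rng.standard_normal(self.n_rec) * np.sqrt(st.var_e)
        y_star = np.array([
            eps_star[k] * self.z2[k] + e_star[recs].sum()
            for k, recs in enumerate(self.rec_of_eps)
        ])
        eps_hat = lu.solve(r)
        eps_hat_star = lu.solve(y_star)
        new = eps_hat + (eps_star - eps_hat_star)
        for k, recs in enumerate(self.rec_of_eps):
            if recs.size:
                st.ycorr[recs] -= new[k] - st.eps[k]
        st.eps = new

    def sample_variances(self) -> None:
        st = self.state
        spec = self.spec
        rng = st.rng
        per_locus = st.var_alpha.shape[0] == self.m
        if per_locus:
            for j in range(self.m):
                if st.delta[j]:
                    scale = st.alpha[j] ** 2 + spec.nu_alpha * spec.S2_alpha
                    st.var_alpha[j] = scale / _chi2(rng, spec.nu_alpha + 1)
                else:
                    st.var_alpha[j] = (spec.nu_alpha * spec.S2_alpha
                                       / _chi2(rng, spec.nu_alpha))
        else:
            k = int(st.delta.sum())
            ssq = float(st.alpha[st.delta] @ st.alpha[st.delta])
            st.var_alpha[0] = ((ssq + spec.nu_alpha * spec.S2_alpha)
                               / _chi2(rng, spec.nu_alpha + k))
        st.var_e = ((st.ycorr @ st.ycorr + spec.nu_e * spec.S2_e)
                    / _chi2(rng, spec.nu_e + self.n_rec))
        if self.n1:
            quad = float(st.eps @ (self.A11 @ st.eps))
            st.var_eps = ((quad + spec.nu_g * spec.S2_g)
                          / _chi2(rng, self.n1 + spec.nu_g))

    def sample_pi(self) -> None:
        if self.method != "BayesCpi":
            return
        st = self.state
        k = int(st.delta.sum())
        st.pi = st.rng.beta(self.m - k + 1, k + 1)

    # -- bookkeeping ------------------------------------------------------

    def recompute_ycorr(self) -> np.ndarray:
        """y minus all current effects, from scratch (bookkeeping oracle)."""
        st = self.state
        out = self.design.y - self.X @ st.beta_star - self.W @ st.alpha
        if self.n1:
            out -= self.design.Z1 @ st.eps
        return out

    def current_bv(self) -> np.ndarray:
        """Breeding values under the current state, set-1 then set-2 order."""
        st = self.state
        mu_g = st.beta_star[-1] if self.spec.fit_mu_g else 0.0
        g = self.design.W_full @ st.alpha + self.design.J_full * mu_g
        g[: self.n1] += st.eps
        return g

    def iterate(self) -> None:
        self.sample_fixed_effects()
        self.sample_marker_effects()
        self.sample_epsilon()
        if self.estimate_variances:
            self.sample_variances()
        self.sample_pi()
        self.state.iteration += 1


def _sample_from_precision(Q: sp.spmatrix, z: np.ndarray) -> np.ndarray:
    """Draw x ~ N(0, Q^{-1}) given a sparse SPD precision Q and z ~ N(0, I)."""
    from scipy.linalg import cholesky, solve_triangular

    # dense Cholesky is fine at the set-1 sizes this sampler targets
    L = cholesky(Q.toarray(), lower=True)
    return solve_triangular(L.T, z, lower=False)


def run_chain(design: Design, rel: RelationshipSystem, spec: ModelSpec,
              method: str = "BayesC", n_iter: int = 10000,
              burn_in: int | None = None, thin: int = 1, seed: int = 0,
              estimate_variances: bool = True,
              eps_strategy: str = "single-site",
              trace: bool = False) -> PosteriorSummary:
    """Run a Gibbs chain and summarize the posterior.

    Deterministic given ``seed``. ``burn_in`` defaults to 20% of the chain;
    every ``thin``-th post-burn-in sample contributes to the summaries.
    Breeding values are accumulated per sample as W alpha + J mu_g + eps.
    """
    if burn_in is None:
        burn_in = n_iter // 5
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    sampler = GibbsSampler(design, rel, spec, method=method, seed=seed,
                           estimate_variances=estimate_variances,
                           eps_strategy=eps_strategy)
    st = sampler.state
    n_ind = len(design.individual_ids)
    n_eff = sampler.X.shape[1] + sampler.m + sampler.n1

    bv_sum = np.zeros(n_ind)
    bv_sq = np.zeros(n_ind)
    eff_sum = np.zeros(n_eff)
    eff_sq = np.zeros(n_eff)
    incl_sum = np.zeros(sampler.m)
    var_sums = np.zeros(5)  # var_e, var_alpha(mean over loci), var_eps, pi, var_g
    n_kept = 0
    # batch means for Monte-Carlo SEs of the BV posterior means
    n_post = (n_iter - burn_in + thin - 1) // thin
    batch_len = max(10, n_post // 50)
    batch_acc = np.zeros(n_ind)
    batch_acc_eff = np.zeros(n_eff)
    batch_cnt = 0
    batch_means: list[np.ndarray] = []
    batch_means_eff: list[np.ndarray] = []
    traces: dict[str, list] = {"var_e": [], "var_alpha": [], "var_eps": [], "pi": []}

    for it in range(n_iter):
        sampler.iterate()
        if it < burn_in or (it - burn_in) % thin:
            continue
        g = sampler.current_bv()
        bv_sum += g
        bv_sq += g * g
        theta = np.concatenate([st.beta_star, st.alpha, st.eps])
        eff_sum += theta
        eff_sq += theta * theta
        incl_sum += st.delta
        var_sums += (st.var_e, float(st.var_alpha.mean()), st.var_eps, st.pi,
                     float(np.var(g)))
        n_kept += 1
        batch_acc += g
        batch_acc_eff += theta
        batch_cnt += 1
        if batch_cnt == batch_len:
            batch_means.append(batch_acc / batch_cnt)
            batch_means_eff.append(batch_acc_eff / batch_cnt)
            batch_acc = np.zeros(n_ind)
            batch_acc_eff = np.zeros(n_eff)
            batch_cnt = 0
        if trace:
            traces["var_e"].append(st.var_e)
            traces["var_alpha"].append(float(st.var_alpha.mean()))
            traces["var_eps"].append(st.var_eps)
            traces["pi"].append(st.pi)

    bv_mean = bv_sum / n_kept
    bv_var = np.maximum(bv_sq / n_kept - bv_mean**2, 0.0)
    eff_mean = eff_sum / n_kept
    eff_var = np.maximum(eff_sq / n_kept - eff_mean**2, 0.0)
    if len(batch_means) >= 2:
        B = np.array(batch_means)
        mcse = B.std(axis=0, ddof=1) / np.sqrt(B.shape[0])
        Be = np.array(batch_means_eff)
        eff_mcse = Be.std(axis=0, ddof=1) / np.sqrt(Be.shape[0])
    else:
        mcse = np.sqrt(bv_var / n_kept)
        eff_mcse = np.sqrt(eff_var / n_kept)

    ids = design.individual_ids
    marker_labels = [f"m{j + 1}" for j in range(sampler.m)]
    labels = (sampler.fixed_labels + marker_labels
              + [f"eps_{i}" for i in ids[: sampler.n1]])
    vmeans = var_sums / n_kept
    return PosteriorSummary(
        bv_mean=pd.Series(bv_mean, index=ids, name="bv"),
        bv_sd=pd.Series(np.sqrt(bv_var), index=ids, name="bv_sd"),
        bv_mcse=pd.Series(mcse, index=ids, name="bv_mcse"),
        effect_mean=pd.Series(eff_mean, index=labels, name="mean"),
        effect_sd=pd.Series(np.sqrt(eff_var), index=labels, name="sd"),
        effect_mcse=pd.Series(eff_mcse, index=labels, name="mcse"),
        inclusion_prob=pd.Series(incl_sum / n_kept, index=marker_labels),
        var_e_mean=vmeans[0],
        var_alpha_mean=vmeans[1],
        var_eps_mean=vmeans[2],
        var_g_mean=vmeans[4],
        pi_mean=vmeans[3],
        settings={"method": method, "n_iter": n_iter, "burn_in": burn_in,
                  "thin": thin, "seed": seed,
                  "estimate_variances": estimate_variances,
                  "eps_strategy": eps_strategy},
        traces={k: np.asarray(v) for k, v in traces.items()} if trace else {},
    )


# ---------------------------------------------------------------------------
# the absorbed-system alternative sampler


class AbsorbedGibbs:
    """Single-site Gibbs on the eps-absorbed MME with an incremental rhs cache.

    Maintains v = r - C theta; before sampling effect i the full-conditional
    right-hand side is v_i + C_ii theta_i, and v is updated with column i of
    C only when theta_i actually changes -- with pi near 1 almost no updates
    happen per sweep.
    """

    def __init__(self, mme: MMESystem, spec: ModelSpec, seed: int = 0):
        if mme.formulation is not Formulation.ABSORBED:
            raise ValueError("sampler requires the absorbed formulation")
        self.C = np.ascontiguousarray(mme.lhs)
        self.r = mme.rhs.copy()
        self.shrink = mme.shrink
        self.labels = list(mme.labels)
        self.n_fixed = mme.n_fixed
        self.spec = spec
        self.theta = np.zeros(len(self.r))
        self.v = self.r.copy()               # rhs cache: r - C theta
        self.delta = np.ones(len(self.r), dtype=bool)
        self.rng = np.random.default_rng(seed)
        self.updates_last_sweep = 0

    def sweep(self) -> None:
        spec = self.spec
        rng = self.rng
        C = self.C
        diag = np.diag(C)
        self.updates_last_sweep = 0
        for i in range(len(self.theta)):
            old = self.theta[i]
            rhs = self.v[i] + diag[i] * old
            if i < self.n_fixed:
                new = rng.normal(rhs / diag[i], np.sqrt(spec.var_e / diag[i]))
                include = True
            else:
                q = diag[i] - self.shrink[i]   # crossproduct part only
                if spec.pi >= 1.0:
                    include = False
                elif spec.pi > 0.0:
                    if q > 0:
                        v0 = q * spec.var_e
                        v1 = q * q * spec.var_alpha + v0
                        logh1 = np.log1p(-spec.pi) - 0.5 * (np.log(v1) + rhs * rhs / v1)
                        logh0 = np.log(spec.pi) - 0.5 * (np.log(v0) + rhs * rhs / v0)
                        p1 = 1.0 / (1.0 + np.exp(logh0 - logh1))
                    else:
                        p1 = 1.0 - spec.pi
                    include = rng.random() < p1
                else:
                    include = True
                if include:
                    c = q + spec.var_e / spec.var_alpha
                    new = rng.normal(rhs / c, np.sqrt(spec.var_e / c))
                else:
                    new = 0.0
            self.delta[i] = include
            if new != old:
                self.v -= C[:, i] * (new - old)
                self.theta[i] = new
                self.updates_last_sweep += 1

    def rhs_from_scratch(self) -> np.ndarray:
        return self.r - self.C @ self.theta


def sample_absorbed(mme_absorbed: MMESystem, spec: ModelSpec, n_iter: int,
                    seed: int = 0, burn_in: int | None = None) -> PosteriorSummary:
    """Posterior for (fixed effects, mu_g, markers) from the absorbed system
    with fixed variance components."""
    if burn_in is None:
        burn_in = n_iter // 5
    gibbs = AbsorbedGibbs(mme_absorbed, spec, seed=seed)
    k = len(gibbs.theta)
    s1 = np.zeros(k)
    s2 = np.zeros(k)
    incl = np.zeros(k)
    n_kept = 0
    batch_len = max(10, (n_iter - burn_in) // 50)
    b_acc = np.zeros(k)
    b_cnt = 0
    b_means: list[np.ndarray] = []
    for it in range(n_iter):
        gibbs.sweep()
        if it < burn_in:
            continue
        s1 += gibbs.theta
        s2 += gibbs.theta**2
        incl += gibbs.delta
        n_kept += 1
        b_acc += gibbs.theta
        b_cnt += 1
        if b_cnt == batch_len:
            b_means.append(b_acc / b_cnt)
            b_acc = np.zeros(k)
            b_cnt = 0
    mean = s1 / n_kept
    var = np.maximum(s2 / n_kept - mean**2, 0.0)
    if len(b_means) >= 2:
        B = np.array(b_means)
        eff_mcse = B.std(axis=0, ddof=1) / np.sqrt(B.shape[0])
    else:
        eff_mcse = np.sqrt(var / n_kept)
    labels = gibbs.labels
    marker_mask = np.array([bool(gibbs.shrink[i]) for i in range(k)])
    empty = pd.Series(dtype=float)
    return PosteriorSummary(
        bv_mean=empty, bv_sd=empty, bv_mcse=empty,
        effect_mean=pd.Series(mean, index=labels, name="mean"),
        effect_sd=pd.Series(np.sqrt(var), index=labels, name="sd"),
        effect_mcse=pd.Series(eff_mcse, index=labels, name="mcse"),
        inclusion_prob=pd.Series((incl / n_kept)[marker_mask],
                                 index=[l for l, m in zip(labels, marker_mask) if m]),
        var_e_mean=spec.var_e, var_alpha_mean=spec.var_alpha,
        var_eps_mean=spec.var_eps, var_g_mean=float("nan"), pi_mean=spec.pi,
        settings={"method": "absorbed", "n_iter": n_iter, "burn_in": burn_in,
                  "seed": seed},
    )


def chunked_crossproduct(S: np.ndarray, chunk_rows: int) -> np.ndarray:
    """S'S as a sum of per-chunk crossproducts over row slices.

    The chunks are independent (parallelizable contract); this reference
    implementation runs them serially.
    """
    if chunk_rows < 1:
        raise ValueError("chunk_rows must be >= 1")
    S = np.asarray(S)
    out = np.zeros((S.shape[1], S.shape[1]))
    for start in range(0, S.shape[0], chunk_rows):
        block = S[start: start + chunk_rows]
        out += block.T @ block
    return out
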