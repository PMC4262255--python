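"""Gibbs samplers: full conditionals, bookkeeping, and posterior behaviour."""

import numpy as np
import pandas as pd
import pytest

import ssbr
from ssbr import mcmc as M

from conftest import make_random_dataset


def _all_genotyped(rng, n, m, alpha=None, var_e=1.0, mu=0.0):
    """Model-simulated data with everyone genotyped (no imputation residual)."""
    ids = [f"i{k}" for k in range(n)]
    p = rng.uniform(0.1, 0.9, m)
    Mmat = rng.binomial(2, p, size=(n, m)).astype(float)
    if alpha is None:
        alpha = np.zeros(m)
    y = mu + Mmat @ alpha + rng.normal(0, np.sqrt(var_e), n)
    md = ssbr.MarkerData([f"m{j + 1}" for j in range(m)], Mmat)
    phen = pd.DataFrame({"id": ids, "y": y})
    data = ssbr.SSBRData.from_tables([(i, "0", "0") for i in ids], ids, md, phen)
    return data, Mmat, alpha


def _design_for(data, fit_mu_g=False):
    md, cov = data.imputed()
    return md, cov, ssbr.build_W(cov, md, data.pedigree, data.phenotypes)


class TestFullConditionals:
    def test_site_updates_match_mme_brute_force(self, example):
        """Every single-site conditional mean/variance equals the brute-force
        expression from the assembled MME at a random state."""
        spec, design, rel, mem = (example["spec"], example["design"],
                                  example["rel"], example["mem"])
        g = M.GibbsSampler(design, rel, spec, seed=0, estimate_variances=False)
        rng = np.random.default_rng(42)
        g.state.beta_star = rng.normal(size=2)
        g.state.alpha = rng.normal(size=10) * 0.1
        g.state.eps = rng.normal(size=3) * 0.1
        g.state.ycorr = g.recompute_ycorr()
        theta = np.concatenate([g.state.beta_star, g.state.alpha, g.state.eps])
        C, r = mem.lhs, mem.rhs
        st = g.state
        lam_a = spec.var_e / spec.var_alpha
        lam_e = spec.var_e / spec.var_eps
        A = g.A11.tocsr()
        for i in range(len(theta)):
            bf_mean = (r[i] - C[i] @ theta + C[i, i] * theta[i]) / C[i, i]
            if i < 2:
                x = g.X[:, i]
                mine = (x @ st.ycorr + g.x2[i] * st.beta_star[i]) / g.x2[i]
            elif i < 12:
                j = i - 2
                w = g.W[:, j]
                mine = (w @ st.ycorr + g.w2[j] * st.alpha[j]) / (g.w2[j] + lam_a)
            else:
                k = i - 12
                idx = A.indices[A.indptr[k]: A.indptr[k + 1]]
                vals = A.data[A.indptr[k]: A.indptr[k + 1]]
                off = lam_e * (vals @ st.eps[idx] - A.diagonal()[k] * st.eps[k])
                recs = g.rec_of_eps[k]
                d = g.z2[k] + lam_e * A.diagonal()[k]
                mine = (st.ycorr[recs].sum() + g.z2[k] * st.eps[k] - off) / d
            assert mine == pytest.approx(bf_mean, abs=1e-10)

    def test_single_marker_conjugate_posterior(self):
        # one marker, orthogonal (single-column) design, fixed variances:
        # sampled effect must match the closed-form normal posterior
        rng = np.random.default_rng(5)
        n = 200
        w = rng.binomial(2, 0.5, n).astype(float)
        alpha_true = 0.7
        y = w * alpha_true + rng.normal(0, 1.0, n)
        ids = [str(i) for i in range(n)]
        md = ssbr.MarkerData(["m1"], w[:, None])
        phen = pd.DataFrame({"id": ids, "y": y})
        data = ssbr.SSBRData.from_tables([(i, "0", "0") for i in ids], ids, md, phen)
        md2, cov, design = _design_for(data)
        # drop the intercept to keep the design a single orthogonal column
        design.X = np.zeros((n, 0))
        design.fixed_labels = []
        spec = ssbr.ModelSpec(var_e=1.0, var_alpha=0.5, var_eps=1.0,
                              fit_mu_g=False)
        summ = M.run_chain(design, data.rel, spec, n_iter=4000, seed=1,
                           estimate_variances=False)
        c = w @ w + 1.0 / 0.5
        post_mean = (w @ y) / c
        post_sd = np.sqrt(1.0 / c)
        assert summ.effect_mean["m1"] == pytest.approx(post_mean, abs=4 * post_sd / np.sqrt(3000))
        assert summ.effect_sd["m1"] == pytest.approx(post_sd, rel=0.1)


class TestBookkeeping:
    def test_ycorr_consistent_after_random_sweeps(self, example):
        g = M.GibbsSampler(example["design"], example["rel"], example["spec"], seed=2)
        for _ in range(10):
            g.iterate()
        assert np.abs(g.state.ycorr - g.recompute_ycorr()).max() < 1e-8

    def test_pi_one_forces_all_effects_null(self, example):
        spec = ssbr.ModelSpec(var_e=1.0, lambda_alpha=10 / 9, lambda_eps=1 / 9,
                              pi=1.0)
        g = M.GibbsSampler(example["design"], example["rel"], spec, seed=3,
                           estimate_variances=False)
        for _ in range(20):
            g.iterate()
        assert np.all(g.state.alpha == 0.0)
        assert np.all(~g.state.delta)

    def test_same_seed_gives_identical_summaries(self, example):
        kw = dict(method="BayesC", n_iter=1500, seed=7)
        a = M.run_chain(example["design"], example["rel"], example["spec"], **kw)
        b = M.run_chain(example["design"], example["rel"], example["spec"], **kw)
        assert (a.bv_mean == b.bv_mean).all()
        assert a.var_e_mean == b.var_e_mean

    def test_invalid_method_rejected(self, example):
        with pytest.raises(ValueError, match="unknown method"):
            M.run_chain(example["design"], example["rel"], example["spec"],
                        method="BayesZ", n_iter=10)


class TestBlupAgreement:
    def test_bayesc_pi0_fixed_variances_converges_to_blup(self, example):
        """BayesC(pi=0) with fixed variances is a Gaussian model whose
        posterior mean is the MME solution."""
        summ = M.run_chain(example["design"], example["rel"], example["spec"],
                           method="BayesC", n_iter=20000, seed=11,
                           estimate_variances=False)
        blup = example["bv"].reindex(summ.bv_mean.index)
        diff = (summ.bv_mean - blup).abs()
        assert bool((diff <= 3 * summ.bv_mcse).all())

    @pytest.mark.parametrize("seed", [21, 22])
    def test_blup_agreement_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        data = make_random_dataset(rng, n=15, m=5)
        spec = ssbr.ModelSpec(var_e=1.0, var_alpha=0.5, var_eps=1.0)
        md, cov, design = _design_for(data)
        mem = ssbr.build_mme_mem(design, data.rel, spec, md.marker_ids)
        blup = ssbr.predict_bv(ssbr.solve_blup(mem), cov, md, mem)
        summ = M.run_chain(design, data.rel, spec, n_iter=12000, seed=seed,
                           estimate_variances=False)
        diff = (summ.bv_mean - blup.reindex(summ.bv_mean.index)).abs()
        assert bool((diff <= 3 * summ.bv_mcse).all())


class TestEpsilon:
    def test_no_set1_is_noop(self):
        rng = np.random.default_rng(1)
        data, _, _ = _all_genotyped(rng, 12, 3)
        md, cov, design = _design_for(data)
        spec = ssbr.ModelSpec(var_e=1.0, var_alpha=1.0, var_eps=1.0,
                              fit_mu_g=False)
        g = M.GibbsSampler(design, data.rel, spec, seed=0)
        g.iterate()
        assert g.state.eps.size == 0

    def test_single_founder_scalar_conjugate_formula(self):
        # one non-genotyped founder with one record plus one genotyped animal:
        # eps full conditional is the scalar normal
        # N(z'ycorr / (1 + lam), var_e / (1 + lam))
        records = [("f", "0", "0"), ("g", "0", "0")]
        md = ssbr.MarkerData(["m1"], np.array([[1.0]]))
        phen = pd.DataFrame({"id": ["f", "g"], "y": [0.8, 0.2]})
        data = ssbr.SSBRData.from_tables(records, ["g"], md, phen)
        md2, cov, design = _design_for(data)
        spec = ssbr.ModelSpec(var_e=1.0, var_alpha=1.0, var_eps=2.0,
                              fit_mu_g=False)
        g = M.GibbsSampler(design, data.rel, spec, seed=4,
                           estimate_variances=False)
        g.state.beta_star[:] = 0.0
        g.state.alpha[:] = 0.0
        g.state.eps[:] = 0.3
        g.state.ycorr = g.recompute_ycorr()
        # capture the sampled value and invert the N(mean, var) draw
        rng_clone = np.random.default_rng(999)
        g.state.rng = np.random.default_rng(999)
        g._sample_eps_single_site()
        lam = 0.5
        mean = 0.8 / (1 + lam)
        sd = np.sqrt(1.0 / (1 + lam))
        expected = rng_clone.normal(mean, sd)
        assert g.state.eps[0] == pytest.approx(expected)

    def test_block_and_single_site_agree_statistically(self, example):
        kw = dict(method="BayesC", n_iter=15000, estimate_variances=False)
        s1 = M.run_chain(example["design"], example["rel"], example["spec"],
                         seed=31, eps_strategy="single-site", **kw)
        s2 = M.run_chain(example["design"], example["rel"], example["spec"],
                         seed=32, eps_strategy="block", **kw)
        se = np.sqrt(s1.bv_mcse**2 + s2.bv_mcse**2)
        assert bool(((s1.bv_mean - s2.bv_mean).abs() <= 3 * se).all())


class TestVariances:
    def test_prior_dominated_limit_concentrates_at_scale(self, example):
        spec = ssbr.ModelSpec(var_e=1.0, var_alpha=0.9, var_eps=9.0,
                              nu_alpha=5e4, S2_alpha=0.9)
        g = M.GibbsSampler(example["design"], example["rel"], spec, seed=5)
        draws = []
        for _ in range(50):
            g.state.alpha[:] = 0.0
            g.sample_variances()
            draws.append(g.state.var_alpha[0])
        assert np.mean(draws) == pytest.approx(0.9, rel=0.05)

    def test_variance_recovery_small_simulation(self):
        rng = np.random.default_rng(17)
        alpha = rng.normal(0, 0.3, 10)
        data, _, _ = _all_genotyped(rng, 100, 10, alpha=alpha, var_e=1.0)
        md, cov, design = _design_for(data)
        spec = ssbr.ModelSpec(var_e=1.0, var_alpha=0.09, var_eps=1.0,
                              fit_mu_g=False)
        summ = M.run_chain(design, data.rel, spec, n_iter=3000, seed=6)
        assert summ.var_e_mean == pytest.approx(1.0, rel=0.3)

    def test_bayescpi_recovers_high_pi_for_null_markers(self):
        rng = np.random.default_rng(18)
        data, _, _ = _all_genotyped(rng, 500, 50, alpha=None, var_e=1.0)
        md, cov, design = _design_for(data)
        spec = ssbr.ModelSpec(var_e=1.0, var_alpha=0.05, var_eps=1.0,
                              fit_mu_g=False)
        summ = M.run_chain(design, data.rel, spec, method="BayesCpi",
                           n_iter=1500, seed=8)
        assert summ.pi_mean > 0.8

    def test_bayesb_ranks_qtl_markers_highest(self):
        rng = np.random.default_rng(19)
        m, n = 60, 400
        alpha = np.zeros(m)
        qtl = rng.choice(m, 20, replace=False)
        alpha[qtl] = rng.normal(0, 0.5, 20)
        data, _, _ = _all_genotyped(rng, n, m, alpha=alpha, var_e=1.0)
        md, cov, design = _design_for(data)
        spec = ssbr.ModelSpec(var_e=1.0, var_alpha=0.25, var_eps=1.0,
                              fit_mu_g=False, pi=0.95)
        summ = M.run_chain(design, data.rel, spec, method="BayesB",
                           n_iter=1200, seed=9)
        probs = summ.inclusion_prob.to_numpy()
        is_qtl = np.zeros(m, dtype=bool)
        is_qtl[qtl] = True
        assert probs[is_qtl].mean() > 2 * probs[~is_qtl].mean()


class TestAbsorbedSampler:
    def test_rhs_cache_equals_brute_force_recompute(self, example):
        absd = ssbr.absorb_epsilon(example["mem"], example["rel"])
        g = M.AbsorbedGibbs(absd, example["spec"], seed=1)
        for _ in range(8):
            g.sweep()
            assert np.abs(g.v - g.rhs_from_scratch()).max() < 1e-10

    def test_pi_one_gives_no_marker_updates(self, example):
        absd = ssbr.absorb_epsilon(example["mem"], example["rel"])
        spec = ssbr.ModelSpec(var_e=1.0, lambda_alpha=10 / 9, lambda_eps=1 / 9,
                              pi=1.0)
        g = M.AbsorbedGibbs(absd, spec, seed=2)
        g.sweep()
        g.sweep()
        # only the two fixed effects (mu, mu_g) ever change
        assert g.updates_last_sweep <= absd.n_fixed

    def test_agrees_with_full_system_sampler(self, example):
        absd = ssbr.absorb_epsilon(example["mem"], example["rel"])
        sa = M.sample_absorbed(absd, example["spec"], n_iter=20000, seed=41)
        sf = M.run_chain(example["design"], example["rel"], example["spec"],
                         n_iter=20000, seed=42, estimate_variances=False)
        for lab in sa.effect_mean.index:
            d = abs(sa.effect_mean[lab] - sf.effect_mean[lab])
            se = np.hypot(sa.effect_mcse[lab], sf.effect_mcse[lab])
            assert d <= 3.5 * se, lab

    def test_requires_absorbed_formulation(self, example):
        with pytest.raises(ValueError, match="absorbed"):
            M.AbsorbedGibbs(example["mem"], example["spec"], seed=0)


class TestChunkedCrossproduct:
    def test_identity(self):
        assert np.array_equal(M.chunked_crossproduct(np.eye(4), 2), np.eye(4))

    def test_matches_direct_product(self):
        S = np.random.default_rng(0).normal(size=(100, 8))
        assert np.abs(M.chunked_crossproduct(S, 7) - S.T @ S).max() < 1e-12

    def test_single_chunk_is_whole_matrix(self):
        S = np.random.default_rng(1).normal(size=(10, 3))
        assert np.allclose(M.chunked_crossproduct(S, 10), S.T @ S)

    def test_rejects_nonpositive_chunks(self):
        with pytest.raises(ValueError):
            M.chunked_crossproduct(np.eye(2), 0)
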