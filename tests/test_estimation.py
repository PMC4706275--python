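"""SAEM estimation, OFV, empirical Bayes, shrinkage, LRT."""

from dataclasses import replace

import numpy as np
import pytest

import circamix as cm
from circamix.likelihood import (
    empirical_bayes,
    importance_ofv,
    lrt,
    shrinkage_percent,
)
from circamix.model import Problem
from circamix.saem import _eta_logjac

from conftest import true_result


def _no_cov_params():
    return replace(cm.reference_params(), theta_sem=0.0, theta_age=0.0,
                   theta_boxcox=0.0)


def gh_marginal_ofv(problem, state, n_nodes=60):
    """Tensor-product Gauss-Hermite quadrature oracle for a 2-eta model."""
    from circamix.likelihood import _subject_obs_loglik, _typicals

    assert problem.R == 2
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    sd = np.sqrt(np.diag(state.omega))
    e1 = np.sqrt(2.0) * sd[0] * x
    e2 = np.sqrt(2.0) * sd[1] * x
    E1, E2 = np.meshgrid(e1, e2, indexing="ij")
    W = np.outer(w, w).ravel() / np.pi
    eta = np.column_stack([E1.ravel(), E2.ravel()])
    typ = _typicals(problem, state)
    total = 0.0
    for i in range(problem.n_sub):
        ll = _subject_obs_loglik(problem, state, typ, i, eta)
        total += np.log(np.sum(W * np.exp(ll - ll.max()))) + ll.max()
    return -2.0 * total


class TestOfv:
    def test_closed_form_without_random_effects(self):
        sim = cm.SimulationConfig(params=_no_cov_params(), omega=np.zeros((4, 4)),
                                  sigma_prop=0.1)
        ds = cm.dense_cohort(1, seed=41, sim=sim)
        cfg = cm.ModelConfig(iiv_on=(), boxcox_on_base=False, covariates_on_base=())
        res = cm.CircadianMixedModel(ds, cfg).fit(
            settings=cm.SaemSettings(n_burn=40, n_iter=20, compute_se=False), seed=42)
        pr = res.model.problem
        f = pr.predict({k: np.full(pr.n_obs, res.estimates[k]) for k in pr.pnames})
        s = res.sigma_prop
        ll = (-np.log(s * f) - 0.5 * ((pr.y - f) / (s * f)) ** 2
              - 0.5 * np.log(2 * np.pi)).sum()
        assert res.ofv == pytest.approx(-2.0 * ll, abs=1e-9)
        assert res.ofv_se == 0.0

    def test_matches_gauss_hermite_quadrature_on_toy(self):
        """3-subject, 2-eta toy: importance sampling vs quadrature oracle."""
        p = _no_cov_params()
        cv = {"amplitude": 0.2, "base": 0.2}
        sim = cm.SimulationConfig(params=p, omega=cm.omega_from_cv(cv),
                                  sigma_prop=0.12)
        ds = cm.dense_cohort(3, seed=43, sim=sim)
        cfg = cm.ModelConfig(iiv_on=("amplitude", "base"), boxcox_on_base=False,
                             covariates_on_base=(),
                             omega_blocks=(("amplitude",), ("base",)))
        res = true_result(ds, config=cfg, params=p, cv=cv, sigma=0.12)
        pr, state = res.model.problem, res.state
        oracle = gh_marginal_ofv(pr, state, 120)
        oracle_err = abs(oracle - gh_marginal_ofv(pr, state, 90))
        ofvs, ses = [], []
        for s in range(5):
            ofv, se, _ = importance_ofv(pr, state, 4000, np.random.default_rng(s))
            ofvs.append(ofv)
            ses.append(se)
        mc_sd = max(np.std(ofvs, ddof=1), np.mean(ses))
        assert np.mean(ofvs) == pytest.approx(oracle, abs=3 * mc_sd + oracle_err)

    def test_monte_carlo_error_shrinks_with_samples(self, small_dataset):
        res = true_result(small_dataset)
        pr, state = res.model.problem, res.state
        eta0, _ = _eta_logjac(pr, state)
        lo = np.mean([importance_ofv(pr, state, 150, np.random.default_rng(s),
                                     eta0=eta0)[1] for s in range(3)])
        hi = np.mean([importance_ofv(pr, state, 1200, np.random.default_rng(s),
                                     eta0=eta0)[1] for s in range(3)])
        assert hi < lo / 1.5


class TestFit:
    def test_noiseless_identifiability(self):
        sim = cm.SimulationConfig(params=_no_cov_params(), omega=np.zeros((4, 4)),
                                  sigma_prop=1e-5)
        ds = cm.dense_cohort(20, seed=44, sim=sim)
        cfg = cm.ModelConfig(iiv_on=(), boxcox_on_base=False, covariates_on_base=())
        res = cm.CircadianMixedModel(ds, cfg).fit(
            settings=cm.SaemSettings(n_burn=60, n_iter=30, compute_se=False,
                                     compute_ofv=False), seed=45)
        for name, truth in (("base", 239.0), ("amplitude", 32.1),
                            ("t_max", 9.3667), ("t_min", 14.0333)):
            assert res.estimates[name] == pytest.approx(truth, rel=1e-3)

    def test_same_seed_same_estimates(self):
        ds = cm.dense_cohort(30, seed=46)
        st = cm.SaemSettings(n_burn=60, n_iter=30, compute_se=False,
                             compute_ofv=False, compute_ebes=False)
        a = cm.CircadianMixedModel(ds).fit(settings=st, seed=47)
        b = cm.CircadianMixedModel(ds).fit(settings=st, seed=47)
        assert a.estimates == b.estimates
        assert np.array_equal(a.omega, b.omega)
        assert a.sigma_prop == b.sigma_prop

    def test_double_cosine_comparator_fits(self):
        """Two-harmonic comparator: runs and recovers the 24-h component."""
        ds = cm.dense_cohort(40, seed=59)
        res = cm.CircadianMixedModel(ds, cm.ModelConfig.double()).fit(
            settings=cm.SaemSettings(n_burn=100, n_iter=50, compute_se=False,
                                     ofv_samples=150, compute_ebes=False),
            seed=60)
        assert res.estimates["base"] == pytest.approx(239.0, rel=0.10)
        assert 0 < res.estimates["amp2"] < res.estimates["amplitude"]
        assert np.isfinite(res.ofv)

    def test_degenerate_dataset_rejected(self):
        ds = cm.dense_cohort(1, seed=48)
        with pytest.raises(ValueError):
            cm.CircadianMixedModel(ds)  # 1 subject cannot carry random effects

    def test_saem_agrees_with_direct_ml_on_one_eta_toy(self):
        """SAEM vs numerical maximum likelihood (quadrature + optimizer)."""
        from scipy.optimize import minimize

        p = _no_cov_params()
        cv = {"base": 0.25}
        sim = cm.SimulationConfig(params=p, omega=cm.omega_from_cv(cv),
                                  sigma_prop=0.138)
        ds = cm.dense_cohort(60, seed=49, sim=sim)
        cfg = cm.ModelConfig(iiv_on=("base",), boxcox_on_base=False,
                             covariates_on_base=(), omega_blocks=(("base",),))
        saem = cm.CircadianMixedModel(ds, cfg).fit(
            settings=cm.SaemSettings(n_burn=400, n_iter=400, compute_se=False,
                                     compute_ofv=False, compute_ebes=False),
            seed=50)

        pr = saem.model.problem
        x_gh, w_gh = np.polynomial.hermite.hermgauss(40)
        subj = [pr.subject_slice(i) for i in range(pr.n_sub)]

        def nll(x):
            tmax, tmin, amp, base, lw, ls = x
            om, sg = np.exp(lw), np.exp(ls)
            eta = np.sqrt(2.0) * om * x_gh
            total = 0.0
            for t, y in subj:
                f = base * np.exp(eta)[:, None] + cm.circadian_value(
                    t[None, :], amp, tmax, tmin)
                bad = (f <= 0).any(axis=1)  # those eta carry zero likelihood
                fs = np.where(f > 0, f, 1.0)
                ll = (-np.log(sg * fs) - 0.5 * ((y[None, :] - fs) / (sg * fs)) ** 2
                      - 0.5 * np.log(2 * np.pi)).sum(axis=1)
                ll[bad] = -np.inf
                m = ll.max()
                if not np.isfinite(m):
                    return 1e12
                total += np.log(np.sum(w_gh / np.sqrt(np.pi) * np.exp(ll - m))) + m
            return -total

        starts = [
            np.array([9.4, 14.0, 32.0, 240.0, np.log(0.25), np.log(0.14)]),
            np.array([saem.estimates["t_max"], saem.estimates["t_min"],
                      saem.estimates["amplitude"], saem.estimates["base"],
                      0.5 * np.log(saem.omega[0, 0]), np.log(saem.sigma_prop)]),
        ]
        direct = None
        for x0 in starts:
            cand = minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9})
            cand = minimize(nll, cand.x, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9})
            if direct is None or cand.fun < direct.fun:
                direct = cand
        tmax, tmin, amp, base, lw, ls = direct.x
        assert saem.estimates["base"] == pytest.approx(base, rel=0.01)
        assert saem.estimates["amplitude"] == pytest.approx(amp, rel=0.01)
        assert saem.estimates["t_max"] == pytest.approx(tmax, rel=0.01)
        assert saem.estimates["t_min"] == pytest.approx(tmin, rel=0.01)
        assert np.sqrt(saem.omega[0, 0]) == pytest.approx(np.exp(lw), rel=0.05)
        assert saem.sigma_prop == pytest.approx(np.exp(ls), rel=0.05)


class TestEmpiricalBayes:
    def test_subject_on_typical_curve_has_zero_ebe(self, ref_params):
        sim = cm.SimulationConfig(params=_no_cov_params(), omega=np.zeros((4, 4)),
                                  sigma_prop=1e-9)
        demo = cm.generate_demographics(2, seed=51, config=sim)
        ds = cm.simulate_dataset([replace(cm.DENSE_DESIGN, n_subjects=2)],
                                 demo, sim, seed=52)
        cfg = cm.ModelConfig(boxcox_on_base=False, covariates_on_base=())
        # the proportional-error likelihood rewards smaller predictions via
        # its -log f term, so the mode sits O(sigma^2) below zero; a small
        # sigma keeps that offset negligible
        res = true_result(ds, config=cfg, params=_no_cov_params(), sigma=0.01)
        ebes = empirical_bayes(res.model.problem, res.state)
        assert np.all(np.abs(ebes) < 1e-3)

    def test_tiny_omega_component_shrinks_to_zero(self):
        ds = cm.dense_cohort(5, seed=53)
        cfg = cm.ModelConfig(boxcox_on_base=False, covariates_on_base=())
        res = true_result(ds, config=cfg, params=_no_cov_params(),
                          cv={"t_max": 1e-5, "t_min": 0.19, "amplitude": 0.5,
                              "base": 0.25})
        ebes = empirical_bayes(res.model.problem, res.state)
        assert np.all(np.abs(ebes[:, 0]) < 1e-4)   # t_max effect pinned
        assert np.any(np.abs(ebes[:, 3]) > 1e-3)   # base effect free


class TestShrinkage:
    def test_all_zero_ebes_give_full_shrinkage(self):
        om = np.diag([0.1**2, 0.2**2])
        s = shrinkage_percent(np.zeros((10, 2)), om, ("a", "b"))
        assert s == {"a": 100.0, "b": 100.0}

    def test_sd_equal_to_omega_gives_zero(self):
        rng = np.random.default_rng(54)
        e = rng.standard_normal(4000)[:, None] * 0.2
        e = e / e.std(ddof=1) * 0.2
        s = shrinkage_percent(e, np.array([[0.04]]), ("b",))
        assert s["b"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_omega_is_nan(self):
        s = shrinkage_percent(np.zeros((5, 1)), np.zeros((1, 1)), ("a",))
        assert np.isnan(s["a"])


class TestLrt:
    def test_zero_delta_is_one(self):
        assert lrt(100.0, 100.0, 1).p_value == 1.0

    def test_chi2_reference_values(self):
        assert lrt(0.0, 10.83, 1).p_value == pytest.approx(0.001, rel=0.01)
        assert lrt(0.0, 3.84, 1).p_value == pytest.approx(0.05, rel=0.01)

    def test_negative_delta_warns_and_caps(self):
        res = lrt(105.0, 100.0, 2)
        assert res.warning is not None
        assert res.p_value == 1.0

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            lrt(1.0, 2.0, 0)
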