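"""Marginal likelihood (OFV), empirical Bayes estimates, shrinkage and LRT.

The objective function value (OFV) is -2 log of the marginal likelihood.
With random effects present the per-subject integral over eta is
approximated by two-stage adaptive importance sampling from defensive
multivariate-t mixtures (see :func:`importance_ofv`); without random
effects the OFV is exact.  Standard errors use the BHHH
(outer-product-of-scores) estimator, with per-subject scores obtained by
finite differences of the importance-sampled marginal log-likelihood
reusing common random samples.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .structural import boxcox_eta

_LOG2PI = np.log(2.0 * np.pi)


# ----------------------------------------------------------------------
# per-subject likelihood pieces (eta space)


def _typicals(problem, state):
    """Per-subject typical parameter values (covariates folded into base)."""
    typ = {}
    for k, p in enumerate(problem.pnames):
        if p == "base":
            lf = problem.log_cov_factor(state.beta)
            if lf is None:
                raise ValueError("covariate coefficients leave the admissible region")
            typ[p] = np.exp(state.mu[k] + lf)
        else:
            typ[p] = np.full(problem.n_sub, np.exp(state.mu[k]))
    return typ


def _subject_ind(problem, state, typ, i, eta):
    """Individual parameters of subject i for eta of shape (S, R).

    Rows whose parameters are non-finite or geometrically degenerate
    (coincident peak and nadir) are replaced by typical values and
    reported in the returned invalid mask.
    """
    eta = np.atleast_2d(eta)
    ind = {}
    invalid = np.zeros(eta.shape[0], bool)
    with np.errstate(over="ignore", invalid="ignore"):
        for p in problem.pnames:
            if p in problem.iiv_pos:
                e = eta[:, problem.iiv_pos[p]]
                if p == "base" and problem.boxcox:
                    e = boxcox_eta(e, state.theta1)
                v = typ[p][i] * np.exp(e)
            else:
                v = np.full(eta.shape[0], typ[p][i])
            invalid |= ~np.isfinite(v) | (v > 1e12)
            ind[p] = v
        if problem.config.structural == "stretched_cosine":
            with np.errstate(invalid="ignore"):
                L1 = np.mod(ind["t_min"] - ind["t_max"], 24.0)
            invalid |= ~np.isfinite(L1) | (L1 == 0.0)
        for p in problem.pnames:  # safe placeholders on flagged rows
            ind[p] = np.where(invalid, typ[p][i], ind[p])
    return ind, invalid


def _subject_obs_loglik(problem, state, typ, i, eta, sigma=None):
    """Observation log-likelihood of subject i for eta (S, R) -> (S,)."""
    sigma = state.sigma if sigma is None else sigma
    t, y = problem.subject_slice(i)
    ind, invalid = _subject_ind(problem, state, typ, i, eta)
    f = problem.predict({k: v[:, None] for k, v in ind.items()}, t=t[None, :])
    bad = ~(f > 0)
    fs = np.where(bad, 1.0, f)
    ll = (-np.log(sigma * fs) - 0.5 * ((y[None, :] - fs) / (sigma * fs)) ** 2
          - 0.5 * _LOG2PI).sum(axis=1)
    ll[bad.any(axis=1) | invalid] = -np.inf
    return ll


def _mvn_loglik(eta, omega_inv, logdet, R):
    quad = np.einsum("sj,jk,sk->s", eta, omega_inv, eta)
    return -0.5 * (R * _LOG2PI + logdet + quad)


def _omega_inv_logdet(omega):
    w, v = np.linalg.eigh(omega)
    w = np.clip(w, 1e-12, None)
    return (v / w) @ v.T, float(np.log(w).sum())


# ----------------------------------------------------------------------
# empirical Bayes estimates


def empirical_bayes(problem, state, subjects=None, eta0=None):
    """Posterior modes of eta (normal scale), shape (n_sub, R).

    ``eta0`` optionally provides per-subject warm starts (e.g. the final
    SAEM chain state).  Subjects whose inner optimization fails are
    flagged with NaN rows.
    """
    R = problem.R
    if R == 0:
        return np.zeros((problem.n_sub, 0))
    typ = _typicals(problem, state)
    omega_inv, logdet = _omega_inv_logdet(state.omega)
    subjects = range(problem.n_sub) if subjects is None else subjects
    out = np.full((problem.n_sub, R), np.nan)
    for i in subjects:
        def nll(e):
            e = e[None, :]
            val = (_subject_obs_loglik(problem, state, typ, i, e)[0]
                   + _mvn_loglik(e, omega_inv, logdet, R)[0])
            return -val if np.isfinite(val) else 1e12

        if eta0 is not None and np.all(np.isfinite(eta0[i])):
            x0 = np.asarray(eta0[i], float)
        else:
            x0 = np.zeros(R)
        res = minimize(nll, x0, method="L-BFGS-B")
        if np.isfinite(res.fun):
            out[i] = res.x
    return out


def shrinkage_percent(ebes, omega, names):
    """eta-shrinkage: 100 * (1 - SD(EBE_k) / omega_k) per random effect."""
    out = {}
    sd_om = np.sqrt(np.diag(omega))
    for r, name in enumerate(names):
        col = ebes[:, r]
        col = col[np.isfinite(col)]
        if sd_om[r] <= 0 or len(col) < 2:
            out[name] = float("nan")
        else:
            out[name] = float(100.0 * (1.0 - np.std(col, ddof=1) / sd_om[r]))
    return out


# ----------------------------------------------------------------------
# importance-sampled OFV


def _batched_posterior_cov(problem, state, typ, centers, omega_inv, h=1e-4):
    """Approximate per-subject posterior covariances of eta in one sweep.

    Gauss-Newton curvature of the observation likelihood (finite-difference
    sensitivities of the prediction to each eta component, evaluated for
    all subjects simultaneously) plus the prior precision.
    """
    R = problem.R
    n = problem.n_sub

    def predict_all(eta):
        ind = {}
        for p in problem.pnames:
            if p in problem.iiv_pos:
                e = eta[:, problem.iiv_pos[p]]
                if p == "base" and problem.boxcox:
                    e = boxcox_eta(e, state.theta1)
                ind[p] = typ[p] * np.exp(e)
            else:
                ind[p] = typ[p]
        return problem.predict({k: v[problem.sub_idx] for k, v in ind.items()})

    f0 = predict_all(centers)
    G = np.empty((problem.n_obs, R))
    for r in range(R):
        ep = centers.copy(); ep[:, r] += h
        em = centers.copy(); em[:, r] -= h
        G[:, r] = (predict_all(ep) - predict_all(em)) / (2 * h)
    w_obs = 1.0 / np.maximum(state.sigma * np.abs(f0), 1e-8) ** 2
    covs = np.empty((n, R, R))
    H = np.empty((n, R, R))
    for r in range(R):
        for s in range(r, R):
            val = np.bincount(problem.sub_idx, weights=G[:, r] * G[:, s] * w_obs,
                              minlength=n)
            H[:, r, s] = H[:, s, r] = val
    H += omega_inv[None, :, :]
    for i in range(n):
        w, v = np.linalg.eigh(H[i])
        w = np.clip(w, 1e-8, None)
        covs[i] = (v / w) @ v.T
    return covs


def _t_proposal_logpdf(z2, logdet_cov, R, df):
    return (gammaln((df + R) / 2) - gammaln(df / 2) - 0.5 * R * np.log(df * np.pi)
            - 0.5 * logdet_cov - 0.5 * (df + R) * np.log1p(z2 / df))


def importance_ofv(problem, state, n_samples, rng, ebes=None, eta0=None,
                   return_samples=False, df=4.0):
    """OFV = -2 log marginal likelihood with its Monte-Carlo SE.

    Exact (no integral) when the model carries no random effects.  The
    per-subject proposal is adapted in two rounds: a pilot round centered
    on the empirical Bayes mode (Laplace covariance) when ``ebes`` is
    given, or on ``eta0`` (e.g. the final SAEM chain state) with a
    prior-scaled covariance otherwise; the final round samples from the
    pilot's weighted posterior moments.  Returns ``(ofv, mc_se, samples)``
    where ``samples`` (optional) holds per-subject importance draws for
    score-based standard errors.
    """
    R = problem.R
    typ = _typicals(problem, state)
    if R == 0:
        ind = {k: v[problem.sub_idx] for k, v in typ.items()}
        f = problem.predict(ind)
        ll = problem.obs_loglik_subjects(f, state.sigma).sum()
        return float(-2.0 * ll), 0.0, None

    omega_inv, logdet = _omega_inv_logdet(state.omega)
    if eta0 is None:
        # fall back to posterior modes as proposal centers
        eta0 = ebes if ebes is not None else empirical_bayes(problem, state)
    total_ll = 0.0
    var_sum = 0.0
    samples = [] if return_samples else None
    degenerate = 0
    centers = np.where(np.isfinite(eta0), eta0, 0.0)
    gn_covs = _batched_posterior_cov(problem, state, typ, centers, omega_inv)
    gn_covs += 0.05 * state.omega[None, :, :]  # guard against over-sharp curvature
    w_pr, v_pr = np.linalg.eigh(state.omega)
    prior_chol = v_pr * np.sqrt(np.clip(w_pr, 1e-12, None))
    for i in range(problem.n_sub):
        mode = centers[i]

        def nll(e):
            v = (_subject_obs_loglik(problem, state, typ, i, e[None, :])[0]
                 + _mvn_loglik(e[None, :], omega_inv, logdet, R)[0])
            return -v if np.isfinite(v) else 1e10

        def draw(center, cov, n):
            """Defensive mixture: local t, wide t, and the prior itself.

            The prior component bounds the importance weights by
            ``p(y|eta)/p_prior``, guaranteeing finite-variance estimates
            even where the local approximation misses posterior mass.
            """
            L = np.linalg.cholesky(cov)
            wide, p_wide, p_prior = 3.0, 0.2, 0.15
            comp = rng.random(n)
            z = rng.standard_normal((n, R))
            u = rng.chisquare(df, n) / df
            step = (z @ L.T) / np.sqrt(u)[:, None]
            step[comp < p_wide] *= wide
            eta = center[None, :] + step
            from_prior = comp >= 1.0 - p_prior
            eta[from_prior] = (rng.standard_normal((int(from_prior.sum()), R))
                               @ prior_chol.T)
            d = np.linalg.solve(L, (eta - center[None, :]).T)
            z2 = (d * d).sum(axis=0)
            ldc = 2.0 * np.log(np.diag(L)).sum()
            lq1 = _t_proposal_logpdf(z2, ldc, R, df)
            lq2 = _t_proposal_logpdf(z2 / wide**2, ldc + 2 * R * np.log(wide), R, df)
            lq3 = _mvn_loglik(eta, omega_inv, logdet, R)
            logq = logsumexp(np.stack([
                lq1 + np.log(1.0 - p_wide - p_prior),
                lq2 + np.log(p_wide),
                lq3 + np.log(p_prior),
            ]), axis=0)
            lpost = (_subject_obs_loglik(problem, state, typ, i, eta)
                     + _mvn_loglik(eta, omega_inv, logdet, R))
            return eta, logq, lpost - logq, lpost

        lap_cov = gn_covs[i]
        # pilot round from the Laplace approximation, then a fresh final
        # round from the pilot's weighted posterior moments (the final
        # estimate uses only the fresh draws, so it stays unbiased given
        # the adapted proposal)
        n_pilot = max(150, n_samples // 2)
        eta_p, _, lw_p, lpost_p = draw(mode, 1.3 * lap_cov, n_pilot)
        wn_p = np.exp(lw_p - logsumexp(lw_p))
        ess_p = 1.0 / np.sum(wn_p**2)
        center = wn_p @ eta_p
        dev = eta_p - center[None, :]
        cov_w = (wn_p[:, None] * dev).T @ dev
        cov_w = 0.5 * (cov_w + cov_w.T) + 0.1 * lap_cov
        if ess_p < 8 or not np.all(np.isfinite(cov_w)):
            center, cov_w = mode, 2.0 * lap_cov
        best = int(np.argmax(lpost_p))
        if lpost_p[best] > lpost_p[np.argmin(((eta_p - mode) ** 2).sum(1))] + 10:
            # pilot found a much better region than the supplied mode
            res = minimize(nll, eta_p[best], method="Nelder-Mead",
                           options={"maxiter": 200})
            center = res.x
        eta, logq, lw, _ = draw(center, 1.3 * cov_w, n_samples)
        m = logsumexp(lw)
        if not np.isfinite(m):
            degenerate += 1
            continue
        ll_i = m - np.log(n_samples)
        wn = np.exp(lw - m)
        wn /= wn.sum()
        ess = 1.0 / np.sum(wn**2)
        var_sum += max(0.0, 1.0 / ess - 1.0 / n_samples)
        total_ll += ll_i
        if return_samples:
            samples.append((eta, logq))
    if degenerate == problem.n_sub:
        raise FloatingPointError(
            "all importance weights degenerate; check parameter values against the data"
        )
    ofv = float(-2.0 * total_ll)
    mc_se = float(2.0 * np.sqrt(var_sum))
    return ofv, mc_se, samples


def paired_delta_ofv(fit_full, fit_reduced, n_samples=1000, seed=None, n_rep=3):
    """ΔOFV = OFV_reduced − OFV_full between two nested fits on one dataset.

    Both marginal likelihoods are importance-sampled per subject on one
    common set of draws from a proposal covering both posteriors, so the
    Monte-Carlo errors are strongly correlated and mostly cancel in the
    difference.  Repeated ``n_rep`` times for an empirical SE.

    Requires the two fits to share the dataset and the same random-effect
    structure (the usual situation for covariate-model comparisons).
    """
    pA, sA = fit_full.model.problem, fit_full.state
    pB, sB = fit_reduced.model.problem, fit_reduced.state
    if pA.n_sub != pB.n_sub or pA.R != pB.R or pA.n_obs != pB.n_obs:
        raise ValueError("paired OFV difference needs matching datasets and "
                         "random-effect structures")
    R = pA.R
    typA, typB = _typicals(pA, sA), _typicals(pB, sB)
    oiA, ldA = _omega_inv_logdet(sA.omega)
    oiB, ldB = _omega_inv_logdet(sB.omega)
    from .saem import _eta_logjac

    etaA, _ = _eta_logjac(pA, sA)
    etaB, _ = _eta_logjac(pB, sB)
    centers = 0.5 * (np.where(np.isfinite(etaA), etaA, 0.0)
                     + np.where(np.isfinite(etaB), etaB, 0.0))
    covA = _batched_posterior_cov(pA, sA, typA, centers, oiA)
    covB = _batched_posterior_cov(pB, sB, typB, centers, oiB)
    # widest of the two curvatures per subject, plus a prior-scale guard
    covs = np.where(np.linalg.det(covA)[:, None, None]
                    > np.linalg.det(covB)[:, None, None], covA, covB)
    covs = covs + 0.05 * (sA.omega + sB.omega)[None, :, :] / 2.0
    rng = np.random.default_rng(seed)
    df = 4.0
    omega_mix = 0.5 * (sA.omega + sB.omega)
    w_pr, v_pr = np.linalg.eigh(omega_mix)
    prior_chol = v_pr * np.sqrt(np.clip(w_pr, 1e-12, None))
    oiM, ldM = _omega_inv_logdet(omega_mix)
    deltas = np.empty(n_rep)
    for k in range(n_rep):
        total = 0.0
        for i in range(pA.n_sub):
            L = np.linalg.cholesky(1.5 * covs[i])
            wide, p_wide, p_prior = 3.0, 0.2, 0.15
            comp = rng.random(n_samples)
            z = rng.standard_normal((n_samples, R))
            u = rng.chisquare(df, n_samples) / df
            step = (z @ L.T) / np.sqrt(u)[:, None]
            step[comp < p_wide] *= wide
            eta = centers[i][None, :] + step
            from_prior = comp >= 1.0 - p_prior
            eta[from_prior] = (rng.standard_normal((int(from_prior.sum()), R))
                               @ prior_chol.T)
            d = np.linalg.solve(L, (eta - centers[i][None, :]).T)
            z2 = (d * d).sum(axis=0)
            ldc = 2.0 * np.log(np.diag(L)).sum()
            lq1 = _t_proposal_logpdf(z2, ldc, R, df)
            lq2 = _t_proposal_logpdf(z2 / wide**2, ldc + 2 * R * np.log(wide), R, df)
            lq3 = _mvn_loglik(eta, oiM, ldM, R)
            logq = logsumexp(np.stack([
                lq1 + np.log(1.0 - p_wide - p_prior),
                lq2 + np.log(p_wide),
                lq3 + np.log(p_prior),
            ]), axis=0)
            lwA = (_subject_obs_loglik(pA, sA, typA, i, eta)
                   + _mvn_loglik(eta, oiA, ldA, R) - logq)
            lwB = (_subject_obs_loglik(pB, sB, typB, i, eta)
                   + _mvn_loglik(eta, oiB, ldB, R) - logq)
            total += logsumexp(lwA) - logsumexp(lwB)
        deltas[k] = 2.0 * total
    delta = float(deltas.mean())
    se = float(deltas.std(ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else 0.0
    return delta, se, deltas


# ----------------------------------------------------------------------
# BHHH standard errors


def _pack(problem, state):
    names, x = [], []
    for k, p in enumerate(problem.pnames):
        names.append(f"mu_{p}"); x.append(state.mu[k])
    for j, nm in enumerate(problem.beta_names):
        names.append(nm); x.append(state.beta[j])
    if problem.boxcox:
        names.append("theta_boxcox"); x.append(state.theta1)
    for r, p in enumerate(problem.iiv):
        names.append(f"logvar_{p}"); x.append(np.log(max(state.omega[r, r], 1e-12)))
    for b in problem.blocks:
        for a in range(len(b)):
            for c in range(a + 1, len(b)):
                r = state.omega[b[a], b[c]] / np.sqrt(
                    state.omega[b[a], b[a]] * state.omega[b[c], b[c]])
                names.append(f"corr_{problem.iiv[b[a]]}_{problem.iiv[b[c]]}")
                x.append(np.arctanh(np.clip(r, -0.99, 0.99)))
    names.append("log_sigma"); x.append(np.log(state.sigma))
    return names, np.array(x)


def _unpack(problem, state, names, x):
    from dataclasses import replace

    mu = state.mu.copy()
    beta = state.beta.copy()
    theta1 = state.theta1
    R = problem.R
    var = np.zeros(R)
    corr = {}
    sigma = state.sigma
    pos = 0
    for k, p in enumerate(problem.pnames):
        mu[k] = x[pos]; pos += 1
    for j in range(problem.n_beta):
        beta[j] = x[pos]; pos += 1
    if problem.boxcox:
        theta1 = x[pos]; pos += 1
    for r in range(R):
        var[r] = np.exp(x[pos]); pos += 1
    for b in problem.blocks:
        for a in range(len(b)):
            for c in range(a + 1, len(b)):
                corr[(b[a], b[c])] = np.tanh(x[pos]); pos += 1
    sigma = np.exp(x[pos]); pos += 1
    omega = np.diag(var)
    for (ra, rc), r in corr.items():
        omega[ra, rc] = omega[rc, ra] = r * np.sqrt(var[ra] * var[rc])
    return replace(state, mu=mu, beta=beta, theta1=float(theta1),
                   omega=omega, sigma=float(sigma))


def _subject_logliks(problem, state, samples):
    typ = _typicals(problem, state)
    omega_inv, logdet = _omega_inv_logdet(state.omega)
    out = np.empty(problem.n_sub)
    for i, (eta, logq) in enumerate(samples):
        lw = (_subject_obs_loglik(problem, state, typ, i, eta)
              + _mvn_loglik(eta, omega_inv, logdet, problem.R) - logq)
        out[i] = logsumexp(lw) - np.log(len(lw))
    return out


def bhhh_standard_errors(problem, state, samples, h=1e-3):
    """Relative standard errors (%) keyed like the reported estimates.

    Scores are finite differences of the per-subject importance-sampled
    marginal log-likelihoods, reusing the same eta draws on both sides of
    each perturbation so the Monte-Carlo noise cancels to first order.
    """
    names, x0 = _pack(problem, state)
    scores = np.zeros((problem.n_sub, len(x0)))
    for k in range(len(x0)):
        xp = x0.copy(); xp[k] += h
        xm = x0.copy(); xm[k] -= h
        try:
            lp = _subject_logliks(problem, _unpack(problem, state, names, xp), samples)
            lm = _subject_logliks(problem, _unpack(problem, state, names, xm), samples)
        except (ValueError, FloatingPointError):
            return None
        scores[:, k] = (lp - lm) / (2 * h)
    fisher = scores.T @ scores
    cov = np.linalg.pinv(fisher)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    rse = {}
    pos = 0
    for p in problem.pnames:
        rse[p] = 100.0 * se[pos]; pos += 1  # log scale -> relative SE
    for j, nm in enumerate(problem.beta_names):
        val = abs(state.beta[j])
        rse[nm] = 100.0 * se[pos] / val if val > 1e-12 else float("inf")
        pos += 1
    if problem.boxcox:
        val = abs(state.theta1)
        rse["theta_boxcox"] = 100.0 * se[pos] / val if val > 1e-12 else float("inf")
        pos += 1
    for p in problem.iiv:
        rse[f"iiv_{p}"] = 100.0 * 0.5 * se[pos]  # CV = sqrt(var)
        pos += 1
    for b in problem.blocks:
        for a in range(len(b)):
            for c in range(a + 1, len(b)):
                nm = f"corr_{problem.iiv[b[a]]}_{problem.iiv[b[c]]}"
                rse[nm] = 100.0 * se[pos]
                pos += 1
    rse["sigma"] = 100.0 * se[pos]
    return rse


# ----------------------------------------------------------------------
# likelihood-ratio test


class LrtResult(NamedTuple):
    delta_ofv: float
    df: int
    p_value: float
    warning: str | None = None


def lrt(ofv_full, ofv_reduced, df: int) -> LrtResult:
    """LRT of nested models: p = P(chi2_df > OFV_reduced - OFV_full)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = float(ofv_reduced - ofv_full)
    warning = None
    if delta < 0:
        warning = ("negative delta-OFV for nested models; "
                   "likely Monte-Carlo noise in the OFV")
    p = float(chi2.sf(max(delta, 0.0), df))
    return LrtResult(delta_ofv=delta, df=df, p_value=min(p, 1.0), warning=warning)
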