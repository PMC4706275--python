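"""Simulation-based model evaluation: VPC, NPDE and non-parametric bootstrap."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.stats import chi2, kstest, norm

from .likelihood import _typicals
from .model import CircadianMixedModel, ModelConfig
from .structural import boxcox_eta


def simulate_replicates(result, n_sim: int, seed=None) -> np.ndarray:
    """Simulate ``n_sim`` full-dataset replicates under the fitted model.

    Each replicate keeps every subject's own design (observation times)
    and covariates, draws fresh random effects from the estimated omega
    and fresh proportional residual errors.  Returns (n_sim, n_obs).
    """
    problem = result.model.problem
    state = result.state if result.state is not None else result.rebuild_state()
    rng = np.random.default_rng(seed)
    typ = _typicals(problem, state)
    R = problem.R
    omega = np.asarray(result.omega, float)
    if R:
        w, v = np.linalg.eigh(omega)
        A = (v * np.sqrt(np.clip(w, 0.0, None)))
    out = np.empty((n_sim, problem.n_obs))
    for s in range(n_sim):
        ind = {}
        eta = rng.standard_normal((problem.n_sub, R)) @ A.T if R else None
        for p in problem.pnames:
            if p in problem.iiv_pos:
                e = eta[:, problem.iiv_pos[p]]
                if p == "base" and problem.boxcox:
                    e = boxcox_eta(e, state.theta1)
                ind[p] = typ[p] * np.exp(e)
            else:
                ind[p] = typ[p]
        f = problem.predict({k: v[problem.sub_idx] for k, v in ind.items()})
        out[s] = f * (1.0 + rng.normal(0.0, state.sigma, size=problem.n_obs))
    return out


# ----------------------------------------------------------------------
# visual predictive check


@dataclass
class VpcReport:
    """Observed vs simulated percentiles of the concentration by time bin."""

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    percentiles: tuple
    observed: np.ndarray          # (n_bins, n_pct)
    sim_median: np.ndarray        # (n_bins, n_pct)
    sim_lower: np.ndarray         # 95% PI of each percentile
    sim_upper: np.ndarray
    fraction_below: dict          # percentile -> fraction of obs below its surface
    n_sim: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in range(len(self.bin_mid)):
            for j, p in enumerate(self.percentiles):
                rows.append({
                    "bin_mid": self.bin_mid[b], "percentile": p,
                    "observed": self.observed[b, j],
                    "sim_median": self.sim_median[b, j],
                    "sim_lower": self.sim_lower[b, j],
                    "sim_upper": self.sim_upper[b, j],
                })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "percentiles": list(self.percentiles),
            "observed": self.observed.tolist(),
            "sim_median": self.sim_median.tolist(),
            "sim_lower": self.sim_lower.tolist(),
            "sim_upper": self.sim_upper.tolist(),
            "fraction_below": {str(k): v for k, v in self.fraction_below.items()},
            "n_sim": self.n_sim,
        }


def vpc(result, n_sim: int = 200, bin_edges=None, n_bins: int = 8, seed=None,
        percentiles=(5, 50, 95)) -> VpcReport:
    """Yano-style predictive check of the fitted model against its data."""
    problem = result.model.problem
    t, y = problem.t, problem.y
    if bin_edges is None:
        qs = np.linspace(0.0, 1.0, n_bins + 1)
        bin_edges = np.unique(np.quantile(t, qs))
        bin_edges[0], bin_edges[-1] = t.min(), t.max() + 1e-9
    bin_edges = np.asarray(bin_edges, float)
    idx = np.clip(np.searchsorted(bin_edges, t, side="right") - 1, 0,
                  len(bin_edges) - 2)
    n_b = len(bin_edges) - 1
    counts = np.bincount(idx, minlength=n_b)
    if (counts == 0).any():
        raise ValueError(f"empty time bin(s) at {np.where(counts == 0)[0]}")

    sims = simulate_replicates(result, n_sim, seed=seed)
    pct = np.asarray(percentiles, float)
    observed = np.vstack([np.percentile(y[idx == b], pct) for b in range(n_b)])
    sim_pct = np.empty((n_sim, n_b, len(pct)))
    for b in range(n_b):
        sim_pct[:, b, :] = np.percentile(sims[:, idx == b], pct, axis=1).T
    sim_median = np.median(sim_pct, axis=0)
    sim_lower = np.percentile(sim_pct, 2.5, axis=0)
    sim_upper = np.percentile(sim_pct, 97.5, axis=0)

    # pooled-simulation percentile surface per bin, then the share of
    # observations falling below it
    fraction_below = {}
    for j, p in enumerate(pct):
        curve = np.array([np.percentile(sims[:, idx == b].ravel(), p)
                          for b in range(n_b)])
        fraction_below[float(p)] = float(np.mean(y < curve[idx]))
    mids = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return VpcReport(bin_edges, mids, tuple(percentiles), observed,
                     sim_median, sim_lower, sim_upper, fraction_below, n_sim)


# ----------------------------------------------------------------------
# normalized prediction distribution errors


@dataclass
class NpdeReport:
    """NPDE values with their calibration summaries (N(0,1) under the model)."""

    npde: np.ndarray
    mean: float
    mean_ci: tuple
    sd: float
    sd_ci: tuple
    normality_p: float
    n_sim: int
    n_regularized: int = 0

    def to_dict(self) -> dict:
        return {
            "mean": self.mean, "mean_ci": list(self.mean_ci),
            "sd": self.sd, "sd_ci": list(self.sd_ci),
            "normality_p": self.normality_p, "n_sim": self.n_sim,
            "n_obs": int(len(self.npde)), "n_regularized": self.n_regularized,
        }


def npde(result, n_sim: int = 1000, seed=None) -> NpdeReport:
    """Decorrelated, rank-based prediction discrepancies per observation.

    For each subject the observed vector and ``n_sim`` simulated vectors
    are centered on the empirical simulation mean and whitened with the
    Cholesky root of the empirical simulation covariance; the rank of
    each decorrelated observation among its simulated counterparts maps
    through the standard-normal quantile.
    """
    problem = result.model.problem
    sims = simulate_replicates(result, n_sim, seed=seed)
    order = problem._order
    bounds = problem._bounds
    npde_vals = np.empty(problem.n_obs)
    n_reg = 0
    for i in range(problem.n_sub):
        rows = order[bounds[i]:bounds[i + 1]]
        Y = sims[:, rows]                       # (n_sim, n_i)
        yobs = problem.y[rows]
        E = Y.mean(axis=0)
        C = np.cov(Y, rowvar=False)
        C = np.atleast_2d(C)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            n_reg += 1
            ridge = 1e-8 * np.trace(C) / len(C)
            L = np.linalg.cholesky(C + ridge * np.eye(len(C)))
        ystar = solve_triangular(L, yobs - E, lower=True)
        sstar = solve_triangular(L, (Y - E).T, lower=True)  # (n_i, n_sim)
        pde = (sstar < ystar[:, None]).mean(axis=1)
        pde = np.clip(pde, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        npde_vals[rows] = norm.ppf(pde)
    if n_reg:
        warnings.warn(f"singular simulation covariance for {n_reg} subject(s); "
                      "ridge-regularized the decorrelation")
    n = len(npde_vals)
    m, s = float(npde_vals.mean()), float(npde_vals.std(ddof=1))
    half = 1.96 * s / np.sqrt(n)
    sd_lo = s * np.sqrt((n - 1) / chi2.ppf(0.975, n - 1))
    sd_hi = s * np.sqrt((n - 1) / chi2.ppf(0.025, n - 1))
    ks_p = float(kstest(npde_vals, "norm").pvalue)
    return NpdeReport(npde_vals, m, (m - half, m + half), s, (sd_lo, sd_hi),
                      ks_p, n_sim, n_reg)


# ----------------------------------------------------------------------
# non-parametric bootstrap


@dataclass
class BootstrapReport:
    """Subject-resampling bootstrap summaries of the parameter estimates."""

    table: pd.DataFrame          # index: parameter; mean, ci_lower, ci_upper
    n_rep: int
    n_failed: int
    replicates: pd.DataFrame = field(repr=False, default=None)

    @property
    def failure_percent(self) -> float:
        return 100.0 * self.n_failed / self.n_rep if self.n_rep else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_rep": self.n_rep, "n_failed": self.n_failed,
            "summary": self.table.to_dict(orient="index"),
        }


def _resample_ids(ids, rng, strata=None):
    if strata is None:
        return rng.choice(ids, size=len(ids), replace=True)
    out = []
    for s in pd.unique(strata):
        pool = ids[strata == s]
        out.append(rng.choice(pool, size=len(pool), replace=True))
    return np.concatenate(out)


def bootstrap(dataset, config: ModelConfig, n_rep: int, seed=None, settings=None,
              stratify_by_study: bool = False) -> BootstrapReport:
    """Resample subjects with replacement and refit each replicate.

    Replicates whose fit raises or yields non-finite estimates are
    counted as failures and excluded from the summaries.
    """
    from .saem import SaemSettings

    settings = settings or SaemSettings.fast(compute_ofv=False, compute_ebes=False)
    rng = np.random.default_rng(seed)
    df = dataset.df
    cov = dataset.covariate_table()
    ids = cov["ID"].to_numpy()
    strata = cov["STUDY"].to_numpy() if (stratify_by_study and "STUDY" in cov) else None
    groups = {s: g for s, g in df.groupby("ID", sort=False)}

    rows = []
    n_failed = 0
    for rep in range(n_rep):
        chosen = _resample_ids(ids, rng, strata)
        parts = []
        for j, s in enumerate(chosen):
            g = groups[s].copy()
            g["ID"] = f"B{j:05d}"
            parts.append(g)
        from .data import Dataset

        boot_ds = Dataset(pd.concat(parts, ignore_index=True),
                          provenance={"bootstrap_rep": rep})
        try:
            fit = CircadianMixedModel(boot_ds, config).fit(
                settings=settings, seed=int(rng.integers(2**31 - 1)))
            rec = dict(fit.estimates)
            for p, cv in fit.cv_percent.items():
                rec[f"cv_{p}"] = cv
            rec["sigma_cv"] = fit.sigma_cv_percent
            if not all(np.isfinite(list(rec.values()))):
                raise FloatingPointError("non-finite estimates")
            rows.append(rec)
        except Exception:
            n_failed += 1
    reps = pd.DataFrame(rows)
    if len(reps):
        table = pd.DataFrame({
            "mean": reps.mean(),
            "ci_lower": reps.quantile(0.025),
            "ci_upper": reps.quantile(0.975),
        })
    else:
        table = pd.DataFrame(columns=["mean", "ci_lower", "ci_upper"])
    return BootstrapReport(table=table, n_rep=n_rep, n_failed=n_failed,
                           replicates=reps)
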