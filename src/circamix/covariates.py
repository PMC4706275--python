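"""Two-stage covariate analysis.

Stage 1 (:func:`screen`) regresses empirical Bayes estimates on candidate
covariates, parameter by parameter, flagging relationships that are both
statistically significant (p < 0.05) and large enough to matter
(r^2 > 0.2).  Screening is only trusted where eta-shrinkage is below 30%;
effects on high-shrinkage parameters must be tested directly in the
mixed model.  Stage 2 (:func:`stepwise_search`) runs forward inclusion
(p < 0.005) and backward elimination (p < 0.001) on the full model using
likelihood-ratio tests on the importance-sampled OFV, requiring the OFV
drop to clear the chi-square cutoff by three combined Monte-Carlo SEs
before a change is accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist, linregress

from .model import COVARIATE_META, CircadianMixedModel, ConfigError, ModelConfig

SHRINKAGE_CUTOFF = 30.0  # percent
SCREEN_P = 0.05
SCREEN_R2 = 0.2
FORWARD_ALPHA = 0.005
BACKWARD_ALPHA = 0.001


@dataclass
class ScreeningResult:
    """Per (parameter, covariate) screening regressions."""

    table: pd.DataFrame
    shrinkage: dict
    excluded_parameters: tuple

    def eligible(self) -> pd.DataFrame:
        return self.table[self.table["eligible"]]


def _anova_r2_p(x_levels, y):
    levels = pd.unique(x_levels)
    groups = [y[x_levels == lv] for lv in levels]
    grand = y.mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_t = ((y - grand) ** 2).sum()
    if ss_t <= 0 or len(levels) < 2:
        return 0.0, 1.0
    df_b, df_w = len(levels) - 1, len(y) - len(levels)
    ss_w = ss_t - ss_b
    if ss_w <= 0 or df_w <= 0:
        return 1.0, 0.0
    F = (ss_b / df_b) / (ss_w / df_w)
    return float(ss_b / ss_t), float(f_dist.sf(F, df_b, df_w))


def screen(ebes: pd.DataFrame, covariate_table: pd.DataFrame, shrinkage: dict,
           covariates=("age", "weight", "bmi", "ethnicity", "season",
                       "semester1", "semester2"),
           shrinkage_cutoff: float = SHRINKAGE_CUTOFF,
           p_threshold: float = SCREEN_P, r2_threshold: float = SCREEN_R2,
           ) -> ScreeningResult:
    """Regress EBEs on covariates for low-shrinkage parameters.

    ``ebes`` is indexed by subject ID with ``eta_<param>`` columns (as
    returned by ``CircadianFitResult.ebes_frame()``); ``covariate_table``
    is one row per subject (``Dataset.covariate_table()``).
    """
    cov = covariate_table.set_index("ID").loc[ebes.index]
    rows = []
    excluded = tuple(p for p, s in shrinkage.items()
                     if not np.isfinite(s) or s >= shrinkage_cutoff)
    for col in ebes.columns:
        param = col.removeprefix("eta_")
        if param in excluded:
            continue
        y = ebes[col].to_numpy(float)
        ok = np.isfinite(y)
        for c in covariates:
            colname, kind, _ = COVARIATE_META[c]
            if colname not in cov.columns:
                continue
            x = cov[colname].to_numpy()
            if len(pd.unique(x[ok])) < 2:
                warnings.warn(f"covariate {c} is constant; excluded from screening")
                continue
            if kind == "categorical":
                r2, p = _anova_r2_p(x[ok], y[ok])
            else:
                res = linregress(x[ok].astype(float), y[ok])
                r2, p = float(res.rvalue**2), float(res.pvalue)
            rows.append({
                "parameter": param, "covariate": c, "p_value": p, "r2": r2,
                "eligible": bool(p < p_threshold and r2 > r2_threshold),
            })
    return ScreeningResult(pd.DataFrame(rows), dict(shrinkage), excluded)


def _candidate_df(name: str) -> int:
    return 3 if COVARIATE_META[name][1] == "categorical" else 1


def _fit_cached(dataset, config, cache, settings, seed):
    key = tuple(sorted(config.covariates_on_base))
    if key not in cache:
        model = CircadianMixedModel(dataset, config)
        cache[key] = model.fit(settings=settings, seed=seed)
    return cache[key]


def stepwise_search(dataset, base_config: ModelConfig, candidates,
                    settings=None, seed=None,
                    forward_alpha: float = FORWARD_ALPHA,
                    backward_alpha: float = BACKWARD_ALPHA,
                    mc_guard: float = 3.0, ofv_rep: int = 3,
                    ofv_samples: int = 1500):
    """Forward-inclusion / backward-elimination covariate search on base.

    Returns ``(final_config, trace)`` where the trace records every
    tested step.  Each nested comparison is scored by a paired
    importance-sampled OFV difference (common per-subject draws for both
    models, ``ofv_rep`` replicates for an empirical SE); a change is only
    accepted when the difference clears the chi-square cutoff by
    ``mc_guard`` Monte-Carlo SEs.
    """
    from .likelihood import paired_delta_ofv
    from .saem import SaemSettings

    settings = settings or SaemSettings.fast(compute_ofv=False, compute_ebes=False)
    rng = np.random.default_rng(seed)
    cache: dict = {}
    delta_cache: dict = {}
    trace = []
    current = tuple(base_config.covariates_on_base)
    fit_seed = int(rng.integers(2**31 - 1))
    pair_seed = int(rng.integers(2**31 - 1))

    def fit_for(covs):
        try:
            cfg = base_config.with_covariates(covs)
        except ConfigError as exc:
            return None, str(exc)
        return _fit_cached(dataset, cfg, cache, settings, fit_seed), None

    def compare(full_covs, red_covs, df):
        key = (tuple(sorted(full_covs)), tuple(sorted(red_covs)))
        if key not in delta_cache:
            full, _ = fit_for(full_covs)
            red, _ = fit_for(red_covs)
            delta, se, _ = paired_delta_ofv(full, red, n_samples=ofv_samples,
                                            seed=pair_seed, n_rep=ofv_rep)
            p = float(chi2.sf(max(delta, 0.0), df))
            delta_cache[key] = (delta, se, p)
        return delta_cache[key]

    # forward inclusion
    remaining = [c for c in candidates if c not in current]
    while remaining:
        best = None
        for c in remaining:
            cand, err = fit_for(tuple(current) + (c,))
            if cand is None:
                trace.append({"step": "forward", "candidate": c, "action": f"skipped ({err})"})
                continue
            df = _candidate_df(c)
            delta, se, p = compare(tuple(current) + (c,), current, df)
            cutoff = chi2.ppf(1 - forward_alpha, df)
            significant = delta > cutoff + mc_guard * se
            trace.append({"step": "forward", "candidate": c, "delta_ofv": delta,
                          "df": df, "p_value": p, "mc_se": se,
                          "action": "candidate" if significant else "rejected"})
            if significant and (best is None or delta > best[1]):
                best = (c, delta)
        if best is None:
            break
        current = tuple(current) + (best[0],)
        remaining.remove(best[0])
        trace.append({"step": "forward", "candidate": best[0], "action": "included"})

    # backward elimination
    changed = True
    while changed and current:
        changed = False
        for c in list(current):
            reduced = tuple(x for x in current if x != c)
            df = _candidate_df(c)
            delta, se, p = compare(current, reduced, df)
            cutoff = chi2.ppf(1 - backward_alpha, df)
            keep = delta > cutoff + mc_guard * se
            trace.append({"step": "backward", "candidate": c, "delta_ofv": delta,
                          "df": df, "p_value": p, "mc_se": se,
                          "action": "kept" if keep else "removed"})
            if not keep:
                current = reduced
                changed = True
                break
    return base_config.with_covariates(current), trace
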