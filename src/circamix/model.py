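"""Model specification and the statsmodels-style model class.

:class:`CircadianMixedModel` binds a validated long-format dataset to a
:class:`ModelConfig` (structural form, which parameters carry
between-subject variability, the random-effect block structure, Box-Cox
on the baseline effect, and covariates on the baseline).  ``fit()`` runs
SAEM and returns a :class:`~circamix.results.CircadianFitResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import Dataset
from .structural import circadian_value, double_cosine, standard_circadian

STRUCTURAL_PARAMS = {
    "stretched_cosine": ("t_max", "t_min", "amplitude", "base"),
    "standard_cosine": ("phase", "amplitude", "base"),
    "double_cosine": ("phase", "amplitude", "base", "amp2", "phase2"),
}

#: covariate name -> (column, kind, scale); continuous covariates are
#: centered on the dataset median (or a pinned reference) and divided by
#: ``scale`` so e.g. the age effect reads "fraction per 10 years".
COVARIATE_META = {
    "age": ("AGE", "continuous", 10.0),
    "weight": ("WT", "continuous", 10.0),
    "bmi": ("BMI", "continuous", 1.0),
    "height": ("HT", "continuous", 10.0),
    "ethnicity": ("ETHN", "indicator", 1.0),
    "semester1": ("SEM1", "indicator", 1.0),
    "semester2": ("SEM2", "indicator", 1.0),
    "season": ("SEASON", "categorical", 1.0),
}


class ConfigError(ValueError):
    """Invalid model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Which model to fit.

    The default is the final published model: stretched cosine,
    between-subject variability on all four structural parameters in two
    correlated 2x2 blocks, Box-Cox transformed baseline random effect,
    and age + semester (winter/spring) effects on the baseline.
    """

    structural: str = "stretched_cosine"
    iiv_on: tuple = ("t_max", "t_min", "amplitude", "base")
    boxcox_on_base: bool = True
    omega_blocks: tuple = (("t_max", "t_min"), ("amplitude", "base"))
    covariates_on_base: tuple = ("age", "semester1")
    covariate_form: str = "multiplicative"
    covariate_refs: tuple = ()  # e.g. (("age", 49.9),) pins centering references

    def __post_init__(self):
        if self.structural not in STRUCTURAL_PARAMS:
            raise ConfigError(f"unknown structural model {self.structural!r}")
        pnames = STRUCTURAL_PARAMS[self.structural]
        bad = [p for p in self.iiv_on if p not in pnames]
        if bad:
            raise ConfigError(f"iiv_on parameters {bad} not in structural model {self.structural}")
        if self.structural == "stretched_cosine" and not (
            "t_max" in pnames and "t_min" in pnames
        ):  # pragma: no cover - structural table guarantees this
            raise ConfigError("stretched_cosine requires both t_max and t_min")
        for c in self.covariates_on_base:
            if c not in COVARIATE_META:
                raise ConfigError(f"unknown covariate {c!r}")
        if "height" in self.covariates_on_base and "bmi" in self.covariates_on_base:
            raise ConfigError("height may not be tested alongside BMI (it enters BMI)")
        if self.covariate_form not in ("multiplicative", "additive"):
            raise ConfigError(f"unknown covariate form {self.covariate_form!r}")
        flat = [p for b in self.omega_blocks for p in b]
        if len(flat) != len(set(flat)):
            raise ConfigError("omega blocks overlap")
        object.__setattr__(
            self, "iiv_on", tuple(p for p in pnames if p in self.iiv_on)
        )

    @property
    def param_names(self) -> tuple:
        return STRUCTURAL_PARAMS[self.structural]

    def active_blocks(self) -> list:
        """Omega blocks filtered to the active random effects."""
        blocks, seen = [], set()
        for b in self.omega_blocks:
            members = [p for p in b if p in self.iiv_on]
            if members:
                blocks.append(tuple(members))
                seen.update(members)
        for p in self.iiv_on:
            if p not in seen:
                blocks.append((p,))
        order = {p: i for i, p in enumerate(self.iiv_on)}
        return sorted(blocks, key=lambda b: min(order[p] for p in b))

    def with_covariates(self, covariates) -> "ModelConfig":
        return replace(self, covariates_on_base=tuple(covariates))

    def n_parameters(self) -> int:
        """Count of estimated quantities (for likelihood-ratio df)."""
        n = len(self.param_names)  # fixed effects
        for c in self.covariates_on_base:
            n += 3 if COVARIATE_META[c][1] == "categorical" else 1
        if self.boxcox_on_base and "base" in self.iiv_on:
            n += 1
        for b in self.active_blocks():
            k = len(b)
            n += k * (k + 1) // 2
        n += 1  # sigma
        return n

    @classmethod
    def standard(cls, covariates_on_base=(), boxcox_on_base=False) -> "ModelConfig":
        """Symmetric-cosinor comparator with variability on all parameters."""
        return cls(
            structural="standard_cosine",
            iiv_on=("phase", "amplitude", "base"),
            boxcox_on_base=boxcox_on_base,
            omega_blocks=(("phase",), ("amplitude", "base")),
            covariates_on_base=tuple(covariates_on_base),
        )

    @classmethod
    def double(cls, covariates_on_base=()) -> "ModelConfig":
        """Two-harmonic cosinor comparator (random effects on the 24-h part)."""
        return cls(
            structural="double_cosine",
            iiv_on=("phase", "amplitude", "base"),
            boxcox_on_base=False,
            omega_blocks=(("phase",), ("amplitude", "base")),
            covariates_on_base=tuple(covariates_on_base),
        )


class Problem:
    """Arrays and callables the SAEM engine and likelihood code work on."""

    def __init__(self, dataset: Dataset, config: ModelConfig):
        self.config = config
        df = dataset.df
        ids = df["ID"].to_numpy()
        uniq, first = np.unique(ids, return_index=True)
        # keep subjects in order of first appearance
        self.subject_ids = ids[np.sort(first)]
        id_to_idx = {s: i for i, s in enumerate(self.subject_ids)}
        self.sub_idx = np.array([id_to_idx[s] for s in ids])
        self.n_sub = len(self.subject_ids)
        self.t = df["CLOCKTIME"].to_numpy(float)
        self.y = df["DV"].to_numpy(float)
        self.n_obs = len(self.y)
        order = np.argsort(self.sub_idx, kind="stable")
        self._order = order
        counts = np.bincount(self.sub_idx, minlength=self.n_sub)
        self._bounds = np.concatenate([[0], np.cumsum(counts)])
        self.obs_counts = counts

        self.pnames = config.param_names
        self.iiv = config.iiv_on
        self.R = len(self.iiv)
        self.iiv_pos = {p: r for r, p in enumerate(self.iiv)}
        self.direct = tuple(p for p in self.pnames if p not in self.iiv)
        self.boxcox = bool(config.boxcox_on_base and "base" in self.iiv)

        cov_table = dataset.covariate_table().set_index("ID").loc[self.subject_ids]
        self.beta_names, self.beta_terms, Z = [], [], []
        refs = dict(config.covariate_refs)
        self.covariate_refs_used = {}
        for c in config.covariates_on_base:
            col, kind, scale = COVARIATE_META[c]
            if col not in cov_table.columns:
                raise ConfigError(f"covariate {c} needs column {col} in the dataset")
            x = cov_table[col].to_numpy()
            if kind == "continuous":
                ref = float(refs.get(c, np.median(x.astype(float))))
                self.covariate_refs_used[c] = ref
                Z.append((x.astype(float) - ref) / scale)
                self.beta_names.append(f"theta_{c}")
                self.beta_terms.append((c, [len(Z) - 1]))
            elif kind == "indicator":
                Z.append(x.astype(float))
                self.beta_names.append(f"theta_{c}")
                self.beta_terms.append((c, [len(Z) - 1]))
            else:  # categorical season, winter as reference
                idxs = []
                for level in ("spring", "summer", "fall"):
                    Z.append((x == level).astype(float))
                    self.beta_names.append(f"theta_season_{level}")
                    idxs.append(len(Z) - 1)
                self.beta_terms.append((c, idxs))
        self.Z = np.column_stack(Z) if Z else np.zeros((self.n_sub, 0))
        self.n_beta = self.Z.shape[1]
        self.blocks = [
            [self.iiv_pos[p] for p in b] for b in config.active_blocks()
        ]

    # --- per-subject slicing -------------------------------------------

    def subject_slice(self, i):
        """(times, observations) of subject ``i`` in stable order."""
        rows = self._order[self._bounds[i]:self._bounds[i + 1]]
        return self.t[rows], self.y[rows]

    # --- covariate factor on base --------------------------------------

    def log_cov_factor(self, beta):
        """log of the covariate multiplier on base per subject, or None if invalid."""
        if self.n_beta == 0:
            return np.zeros(self.n_sub)
        bz = self.Z * np.asarray(beta)
        if self.config.covariate_form == "multiplicative":
            fac = 1.0 + bz
            if np.any(fac <= 0.0):
                return None
            return np.log(fac).sum(axis=1)
        fac = 1.0 + bz.sum(axis=1)
        if np.any(fac <= 0.0):
            return None
        return np.log(fac)

    # --- structural prediction -----------------------------------------

    def predict(self, ind: dict, t=None):
        """Predicted concentrations given per-subject parameter arrays.

        ``ind`` maps structural parameter names to arrays broadcastable
        against the observation vector (typically values expanded per
        observation by the caller).
        """
        t = self.t if t is None else t
        s = self.config.structural
        if s == "stretched_cosine":
            return ind["base"] + circadian_value(t, ind["amplitude"], ind["t_max"], ind["t_min"])
        if s == "standard_cosine":
            return ind["base"] + standard_circadian(t, ind["amplitude"], ind["phase"])
        return ind["base"] + double_cosine(
            t, ind["amplitude"], ind["phase"], ind["amp2"], ind["phase2"]
        )

    def obs_loglik_subjects(self, f, sigma):
        """Per-subject Gaussian log-likelihood under proportional error."""
        bad = ~(f > 0)
        fs = np.where(bad, 1.0, f)
        ll = -np.log(sigma * fs) - 0.5 * ((self.y - fs) / (sigma * fs)) ** 2 \
            - 0.5 * np.log(2.0 * np.pi)
        out = np.bincount(self.sub_idx, weights=np.where(bad, 0.0, ll),
                          minlength=self.n_sub)
        if bad.any():
            out[np.unique(self.sub_idx[bad])] = -np.inf
        return out


class CircadianMixedModel:
    """Nonlinear mixed-effects circadian rhythm model.

    Parameters
    ----------
    dataset : Dataset
        Validated long-format observations.
    config : ModelConfig, optional
        Structural/statistical specification (defaults to the final
        published model form).
    """

    def __init__(self, dataset: Dataset, config: ModelConfig | None = None):
        self.dataset = dataset
        self.config = config or ModelConfig()
        if dataset.n_subjects < 2 and self.config.iiv_on:
            raise ValueError("random-effect models need at least 2 subjects")
        self.problem = Problem(dataset, self.config)

    @classmethod
    def from_dataframe(cls, df, config: ModelConfig | None = None, **meta):
        return cls(Dataset(df.copy(), provenance=meta), config=config)

    def fit(self, settings=None, seed=None, start=None):
        """Estimate the model by SAEM; returns a CircadianFitResult."""
        from .saem import fit_saem

        return fit_saem(self, settings=settings, seed=seed, start=start)
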