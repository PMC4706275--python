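"""Fit results container: estimates, uncertainties, diagnostics, summary table."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .model import CircadianMixedModel, ModelConfig
from .structural import CircadianParams


def _clock(hours: float) -> str:
    h = int(hours) % 24
    m = int(round((hours - int(hours)) * 60))
    if m == 60:
        h, m = (h + 1) % 24, 0
    return f"{h}:{m:02d}"


@dataclass
class CircadianFitResult:
    """Approximate maximum-likelihood estimates of the circadian mixed model.

    ``estimates`` maps structural parameter names (ng/dL and clock hours),
    covariate fractions (``theta_*``) and the Box-Cox shape to their
    typical values; ``omega`` is the random-effect covariance over
    ``iiv_names``; ``sigma_prop`` the proportional residual SD.
    """

    model: CircadianMixedModel | None
    config: ModelConfig
    settings: Any
    seed: Any
    estimates: dict
    omega: np.ndarray
    iiv_names: tuple
    sigma_prop: float
    ofv: float | None
    ofv_se: float | None
    rse: dict | None
    ebes: np.ndarray | None
    shrinkage: dict | None
    convergence: dict
    state: Any = field(default=None, repr=False)

    # --- derived quantities --------------------------------------------

    @property
    def converged(self) -> bool:
        return bool(self.convergence.get("converged", False))

    @property
    def n_parameters(self) -> int:
        return self.config.n_parameters()

    @property
    def cv_percent(self) -> dict:
        """Interindividual variability as CV% = 100*sqrt(omega^2) per effect."""
        d = np.sqrt(np.clip(np.diag(self.omega), 0.0, None))
        return {p: float(100.0 * d[r]) for r, p in enumerate(self.iiv_names)}

    @property
    def sigma_cv_percent(self) -> float:
        return float(100.0 * self.sigma_prop)

    @property
    def params(self) -> CircadianParams | None:
        """Typical values as a CircadianParams (stretched model only)."""
        if self.config.structural != "stretched_cosine":
            return None
        e = self.estimates
        refs = getattr(self.model.problem, "covariate_refs_used", {}) if self.model else {}
        return CircadianParams(
            base=e["base"], amplitude=e["amplitude"], t_max=e["t_max"], t_min=e["t_min"],
            theta_sem=e.get("theta_semester1", 0.0), theta_age=e.get("theta_age", 0.0),
            theta_boxcox=e.get("theta_boxcox", 0.0), age_ref=refs.get("age", 49.9),
        )

    def ebes_frame(self) -> pd.DataFrame | None:
        if self.ebes is None or self.model is None:
            return None
        return pd.DataFrame(
            self.ebes, columns=[f"eta_{p}" for p in self.iiv_names],
        ).assign(ID=self.model.problem.subject_ids).set_index("ID")

    # --- presentation ---------------------------------------------------

    def summary(self) -> str:
        """Human-readable parameter table (estimate, RSE%, IIV CV%)."""
        lines = []
        lines.append("Circadian mixed-effects model fit")
        lines.append(f"  structural model : {self.config.structural}")
        if self.model is not None:
            pr = self.model.problem
            lines.append(f"  subjects / observations : {pr.n_sub} / {pr.n_obs}")
        if self.ofv is not None:
            se = f" (MC SE {self.ofv_se:.2f})" if self.ofv_se else ""
            lines.append(f"  OFV : {self.ofv:.2f}{se}")
        lines.append(f"  estimated parameters : {self.n_parameters}")
        lines.append(f"  converged : {self.converged}")
        lines.append("")
        lines.append(f"  {'Parameter':<28}{'Estimate':>12}{'RSE%':>8}")
        rse = self.rse or {}

        def row(label, value, key, fmt="{:.3g}"):
            r = rse.get(key)
            rs = f"{r:.1f}" if isinstance(r, float) and np.isfinite(r) else "-"
            lines.append(f"  {label:<28}{fmt.format(value):>12}{rs:>8}")

        for p in self.config.param_names:
            v = self.estimates[p]
            if p in ("t_max", "t_min", "phase", "phase2"):
                row(f"{p} (clock time)", v, p, fmt="{:.4g}")
                lines[-1] += f"   [{_clock(v)}]"
            else:
                row(f"{p} (ng/dL)", v, p)
        for name, val in self.estimates.items():
            if name.startswith("theta_") and name != "theta_boxcox":
                row(f"{name} (% on base)", 100.0 * val, name, fmt="{:.3g}")
        if "theta_boxcox" in self.estimates:
            row("Box-Cox shape on base", self.estimates["theta_boxcox"], "theta_boxcox")
        lines.append("  Interindividual variability (CV%)")
        for p, cv in self.cv_percent.items():
            row(f"    eta_{p}", cv, f"iiv_{p}", fmt="{:.3g}")
        lines.append("  Residual variability (CV%)")
        row("    sigma_proportional", self.sigma_cv_percent, "sigma", fmt="{:.3g}")
        if self.shrinkage:
            shr = ", ".join(f"{p} {v:.0f}%" for p, v in self.shrinkage.items()
                            if np.isfinite(v))
            lines.append(f"  eta-shrinkage: {shr}")
        return "\n".join(lines)

    # --- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": {
                "structural": self.config.structural,
                "iiv_on": list(self.config.iiv_on),
                "boxcox_on_base": self.config.boxcox_on_base,
                "omega_blocks": [list(b) for b in self.config.omega_blocks],
                "covariates_on_base": list(self.config.covariates_on_base),
                "covariate_form": self.config.covariate_form,
                "covariate_refs": [list(x) for x in self.config.covariate_refs],
            },
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "omega": np.asarray(self.omega).tolist(),
            "iiv_names": list(self.iiv_names),
            "sigma_prop": float(self.sigma_prop),
            "ofv": self.ofv,
            "ofv_se": self.ofv_se,
            "rse": self.rse,
            "shrinkage": self.shrinkage,
            "convergence": {k: v for k, v in self.convergence.items() if k != "traces"},
            "n_parameters": self.n_parameters,
            "seed": self.seed,
            "covariate_refs_used": (
                getattr(self.model.problem, "covariate_refs_used", {})
                if self.model else {}
            ),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path, dataset=None) -> "CircadianFitResult":
        """Rebuild a result from JSON; attach ``dataset`` to enable
        simulation-based diagnostics (VPC/NPDE)."""
        with open(path) as fh:
            d = json.load(fh)
        cfgd = d["config"]
        refs = d.get("covariate_refs_used", {})
        config = ModelConfig(
            structural=cfgd["structural"],
            iiv_on=tuple(cfgd["iiv_on"]),
            boxcox_on_base=cfgd["boxcox_on_base"],
            omega_blocks=tuple(tuple(b) for b in cfgd["omega_blocks"]),
            covariates_on_base=tuple(cfgd["covariates_on_base"]),
            covariate_form=cfgd["covariate_form"],
            covariate_refs=tuple((k, float(v)) for k, v in refs.items()),
        )
        model = CircadianMixedModel(dataset, config) if dataset is not None else None
        result = cls(
            model=model, config=config, settings=None, seed=d.get("seed"),
            estimates=d["estimates"], omega=np.asarray(d["omega"], float),
            iiv_names=tuple(d["iiv_names"]), sigma_prop=float(d["sigma_prop"]),
            ofv=d.get("ofv"), ofv_se=d.get("ofv_se"), rse=d.get("rse"),
            ebes=None, shrinkage=d.get("shrinkage"),
            convergence=d.get("convergence", {}),
        )
        if model is not None:
            result.state = result.rebuild_state()
        return result

    def rebuild_state(self):
        """Reconstruct the internal parameter state from the estimates."""
        from .saem import _State

        pr = self.model.problem
        mu = np.array([np.log(self.estimates[p]) for p in pr.pnames])
        beta = np.array([self.estimates[n] for n in pr.beta_names])
        theta1 = float(self.estimates.get("theta_boxcox", 0.0))
        return _State(mu=mu, beta=beta, theta1=theta1,
                      omega=np.asarray(self.omega, float),
                      sigma=float(self.sigma_prop),
                      phi=np.zeros((pr.n_sub, pr.R)))
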