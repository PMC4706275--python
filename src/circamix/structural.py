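"""Structural circadian model: stretched-cosine rhythm, covariate and Box-Cox machinery.

The rhythm of a hormone concentration over the 24-h day is modelled as a
baseline level plus a cosine oscillation.  The standard cosinor uses a
symmetric cosine (peak-to-nadir = nadir-to-peak = 12 h); the stretched
cosine lets the peak-to-nadir interval ``L1 = (t_min - t_max) mod 24``
differ from 12 h by advancing the cosine phase piecewise linearly, so the
decline after the morning peak can be faster than the overnight recovery.

All clock times are decimal hours interpreted modulo 24 into ``[0, 24)``;
concentrations are ng/dL throughout.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CircadianParams",
    "SubjectCovariates",
    "classify_season",
    "wrap24",
    "stretch_tau",
    "circadian_value",
    "standard_circadian",
    "double_cosine",
    "boxcox_eta",
    "boxcox_eta_inv",
    "typical_base",
    "individual_params",
    "predict_concentration",
]

#: |theta1| below this uses the analytic theta1 -> 0 limit of the Box-Cox map.
_BOXCOX_TOL = 1e-8


def wrap24(t):
    """Wrap clock times / offsets into [0, 24), including negative inputs."""
    return np.mod(t, 24.0)


# --- season / semester encoding -------------------------------------------

# (month, day) lower bounds of each season; winter wraps the year end.
_SEASON_BOUNDS = [
    ((3, 20), "spring"),
    ((6, 20), "summer"),
    ((9, 22), "fall"),
    ((12, 21), "winter"),
]


def classify_season(date):
    """Map a calendar date to its season and the two semester indicators.

    Seasons use fixed civil boundaries: winter Dec 21 - Mar 19, spring
    Mar 20 - Jun 19, summer Jun 20 - Sep 21, fall Sep 22 - Dec 20.
    ``semester1`` is 1 for winter/spring (vs summer/fall); ``semester2``
    is 1 for fall/winter (vs spring/summer).

    Parameters
    ----------
    date : datetime.date, datetime.datetime or ISO "YYYY-MM-DD" string

    Returns
    -------
    (season, semester1, semester2) : (str, int, int)
    """
    if isinstance(date, str):
        try:
            date = _dt.date.fromisoformat(date.strip())
        except ValueError as exc:
            raise ValueError(f"unparseable date {date!r}") from exc
    if isinstance(date, _dt.datetime):
        date = date.date()
    if not isinstance(date, _dt.date):
        raise ValueError(f"not a calendar date: {date!r}")
    md = (date.month, date.day)
    season = "winter"  # Jan 1 - Mar 19 and Dec 21 - Dec 31
    for bound, name in _SEASON_BOUNDS:
        if md >= bound:
            season = name
    sem1 = int(season in ("winter", "spring"))
    sem2 = int(season in ("fall", "winter"))
    return season, sem1, sem2


def semesters_from_season(season: str) -> tuple[int, int]:
    """Semester indicators implied by a season label."""
    if season not in ("winter", "spring", "summer", "fall"):
        raise ValueError(f"unknown season {season!r}")
    return int(season in ("winter", "spring")), int(season in ("fall", "winter"))


# --- core rhythm functions -------------------------------------------------


def stretch_tau(t, t_max, t_min):
    """Piecewise-linear warped phase tau in [0, 24).

    ``tau`` runs 0 -> 12 linearly over the peak-to-nadir interval
    ``L1 = (t_min - t_max) mod 24`` and 12 -> 24 over the remaining
    ``L2 = 24 - L1``, so ``cos(2*pi*tau/24)`` peaks at ``t_max`` and
    bottoms at ``t_min`` regardless of the asymmetry.
    """
    L1 = wrap24(np.asarray(t_min, float) - np.asarray(t_max, float))
    if np.any(L1 == 0.0):
        raise ValueError("degenerate geometry: t_max == t_min modulo 24 (L1 = 0)")
    L2 = 24.0 - L1
    t24 = wrap24(np.asarray(t, float) - t_max)
    return np.where(t24 <= L1, 12.0 / L1 * t24, 12.0 + 12.0 / L2 * (t24 - L1))


def circadian_value(t, amplitude, t_max, t_min):
    """Asymmetric (stretched-cosine) circadian deviation in ng/dL."""
    tau = stretch_tau(t, t_max, t_min)
    return amplitude * np.cos(2.0 * np.pi * tau / 24.0)


def standard_circadian(t, amplitude, phase):
    """Symmetric cosinor deviation: amplitude * cos(2*pi*(t - phase)/24)."""
    return amplitude * np.cos(2.0 * np.pi * (np.asarray(t, float) - phase) / 24.0)


def double_cosine(t, amp1, phase1, amp2, phase2):
    """Two-harmonic cosinor comparator: a 24-h plus a 12-h cosine."""
    t = np.asarray(t, float)
    return amp1 * np.cos(2.0 * np.pi * (t - phase1) / 24.0) + amp2 * np.cos(
        2.0 * np.pi * (t - phase2) / 12.0
    )


# --- Box-Cox transformed random effects ------------------------------------


def boxcox_eta(eta, theta1):
    """Box-Cox transform of a normal random effect: ((e^eta)^theta1 - 1)/theta1.

    Monotone increasing, fixes 0, and tends to the identity as theta1 -> 0
    (handled analytically below ``1e-8``).  Negative ``theta1`` yields a
    negatively skewed exp(eta*) distribution bounded above by ``-1/theta1``.
    """
    eta = np.asarray(eta, float)
    if abs(theta1) < _BOXCOX_TOL:
        return eta + 0.0
    return np.expm1(theta1 * eta) / theta1


def boxcox_eta_inv(eta_star, theta1):
    """Inverse of :func:`boxcox_eta`; requires 1 + theta1*eta_star > 0."""
    eta_star = np.asarray(eta_star, float)
    if abs(theta1) < _BOXCOX_TOL:
        return eta_star + 0.0
    arg = theta1 * eta_star
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(arg > -1.0, np.log1p(np.maximum(arg, -1.0 + 1e-300)) / theta1,
                        np.nan)


# --- parameter containers ---------------------------------------------------


@dataclass
class CircadianParams:
    """Typical (population) parameters of the stretched-cosine model.

    ``theta_sem`` and ``theta_age`` are fractional covariate effects on the
    baseline: winter/spring raises the typical baseline by ``100*theta_sem``
    percent, and each decade of age beyond ``age_ref`` scales it by
    ``(1 + theta_age)``.  ``theta_boxcox`` shapes the skewness of the
    between-subject baseline distribution (0 = plain log-normal).
    """

    base: float
    amplitude: float
    t_max: float
    t_min: float
    theta_sem: float = 0.0
    theta_age: float = 0.0
    theta_boxcox: float = 0.0
    age_ref: float = 49.9

    def __post_init__(self):
        self.t_max = float(wrap24(self.t_max))
        self.t_min = float(wrap24(self.t_min))
        if not self.base > 0:
            raise ValueError("base must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.amplitude >= self.base:
            raise ValueError("amplitude must be below base (prediction must stay positive)")
        if wrap24(self.t_min - self.t_max) == 0.0:
            raise ValueError("t_max and t_min must differ modulo 24")

    @property
    def L1(self) -> float:
        """Peak-to-nadir interval in hours."""
        return float(wrap24(self.t_min - self.t_max))


@dataclass
class SubjectCovariates:
    """Per-subject covariates; semester indicators derive from season."""

    age: float
    season: str = "summer"
    semester1: int | None = None
    semester2: int | None = None
    body_weight: float = float("nan")
    bmi: float = float("nan")
    height: float = float("nan")
    ethnicity: int = 1
    age_bounds: tuple[float, float] = field(default=(18.0, 100.0), repr=False)

    def __post_init__(self):
        s1, s2 = semesters_from_season(self.season)
        if self.semester1 is None:
            self.semester1 = s1
        if self.semester2 is None:
            self.semester2 = s2
        if (self.semester1, self.semester2) != (s1, s2):
            raise ValueError("semester indicators inconsistent with season")
        lo, hi = self.age_bounds
        if not (lo <= self.age <= hi):
            raise ValueError(f"age {self.age} outside plausible range {self.age_bounds}")


def typical_base(params: CircadianParams, cov: SubjectCovariates, form: str = "multiplicative"):
    """Typical baseline for a subject's covariates, in ng/dL.

    Multiplicative (default): ``base*(1+theta_sem*sem1)*(1+theta_age*dz)``
    with ``dz = (age - age_ref)/10``; additive combines the fractional
    effects inside one factor: ``base*(1 + theta_sem*sem1 + theta_age*dz)``.
    """
    dz = (cov.age - params.age_ref) / 10.0
    if form == "multiplicative":
        value = params.base * (1.0 + params.theta_sem * cov.semester1) * (
            1.0 + params.theta_age * dz
        )
    elif form == "additive":
        value = params.base * (1.0 + params.theta_sem * cov.semester1 + params.theta_age * dz)
    else:
        raise ValueError(f"unknown covariate form {form!r}")
    if value <= 0:
        raise ValueError("covariate combination drives typical base non-positive")
    return value


def individual_params(params: CircadianParams, eta, cov: SubjectCovariates | None = None,
                      form: str = "multiplicative") -> dict:
    """Subject-level parameters from typicals and a 4-vector of random effects.

    ``eta`` orders as (t_max, t_min, amplitude, base); each acts
    multiplicatively through ``exp(eta)``, with the baseline effect passed
    through the Box-Cox map first.  Times re-wrap into [0, 24).
    """
    e1, e2, e3, e4 = np.asarray(eta, float)
    if cov is None:
        cov = SubjectCovariates(age=params.age_ref)
    t_max_j = float(wrap24(params.t_max * np.exp(e1)))
    t_min_j = float(wrap24(params.t_min * np.exp(e2)))
    if wrap24(t_min_j - t_max_j) == 0.0:
        raise ValueError("perturbed t_max and t_min coincide modulo 24")
    eta_star = float(boxcox_eta(e4, params.theta_boxcox))
    return {
        "t_max": t_max_j,
        "t_min": t_min_j,
        "amplitude": params.amplitude * np.exp(e3),
        "base": typical_base(params, cov, form=form) * np.exp(eta_star),
    }


def predict_concentration(t, params: CircadianParams, cov: SubjectCovariates | None = None,
                          eta=None, form: str = "multiplicative"):
    """Model-predicted concentration at clock time(s) ``t``.

    With ``eta`` omitted this is the typical curve for the given covariates
    (population median curve for the reference subject when ``cov`` is None).
    """
    if eta is None:
        eta = np.zeros(4)
    p = individual_params(params, eta, cov, form=form)
    return p["base"] + circadian_value(t, p["amplitude"], p["t_max"], p["t_min"])
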