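"""Generic excess relative risk (ERR) and excess absolute rate (EAR) models.

A risk model factorises the radiation-attributed excess into a sex-specific
dose-response term ``p(d)`` and a multiplicative modifier term ``r(s, a, e)``
covering sex, attained age and age at exposure::

    ERR or EAR = p(d) * r(s, a, e)

while the spontaneous (baseline) rate is a log-linear function of sex,
attained age and birth year, optionally multiplied by a cohort-averaged
city/in-city factor ``g`` and a calendar-period screening factor.  ERR is
dimensionless; EAR is expressed per 10^4 person-years per unit dose term.
Parameters carry a full covariance matrix from the original maximum
likelihood fit so that parameter uncertainty can be propagated by
multivariate normal sampling.

Sex is coded as an indicator ``s = -1`` (male) / ``+1`` (female); doses are
in Gy throughout this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "BaselineSpec",
    "DoseResponseSpec",
    "ModifierSpec",
    "ScreeningSpec",
    "RiskModel",
    "dose_term",
    "modifier_term",
    "excess",
    "baseline_f",
    "cohort_g",
    "model_baseline",
    "sample_params",
    "regularize_covariance",
]

DOSE_FORMS = (
    "none",
    "linear",
    "linear_quadratic",
    "quadratic",
    "power",
    "quadratic_exponential",
    "threshold_linear_spline",
)

#: parameter names consumed by each dose-response form, in order
DOSE_FORM_PARAMS = {
    "none": (),
    "linear": ("beta",),
    "linear_quadratic": ("beta", "alpha"),
    "quadratic": ("alpha",),
    "power": ("beta", "gamma"),
    "quadratic_exponential": ("alpha", "delta"),
    "threshold_linear_spline": ("beta1", "beta2"),
}


@dataclass(frozen=True)
class DoseResponseSpec:
    """Functional form of the dose response ``p(d)``; ``p(0) = 0`` always.

    ``knot_dose`` (Gy) only applies to the two-slope spline form, whose
    slope changes at the knot while remaining continuous.
    """

    form: str = "linear"
    knot_dose: float = 0.7

    def __post_init__(self):
        if self.form not in DOSE_FORMS:
            raise ConfigurationError(f"unknown dose-response form {self.form!r}")
        if self.form == "threshold_linear_spline" and self.knot_dose <= 0:
            raise ConfigurationError("spline knot dose must be positive")


@dataclass(frozen=True)
class ModifierSpec:
    """Which effect modifiers are active and how they are centred.

    With every modifier inactive (or its coefficient zero) the modifier
    term is exactly 1.  Conventions:

    * sex: ``exp(sigma * s)`` (log-linear, default) or ``1 + sigma * s``;
    * attained age: power law ``(a / age_centre)**phi``, centred at 70 y;
    * age at exposure: ``exp(psi * (e - exposure_centre) / 10)`` (per
      decade), centred at 30 y;
    * smoking intensity x (cigarettes/day, lung models only):
      ``exp(theta1 * x/10 + theta2 * (x/10)**2)``.
    """

    sex: bool = False
    sex_convention: str = "loglinear"  # or "linear"
    attained_age: bool = False
    age_centre: float = 70.0
    age_at_exposure: bool = False
    exposure_centre: float = 30.0
    smoking: bool = False

    def __post_init__(self):
        if self.sex_convention not in ("loglinear", "linear"):
            raise ConfigurationError(
                f"unknown sex convention {self.sex_convention!r}"
            )


@dataclass(frozen=True)
class ScreeningSpec:
    """Multiplicative baseline factor by calendar period.

    ``breaks`` are ascending year boundaries; ``factors`` has one more
    entry than ``breaks``: factor ``factors[i]`` applies to years strictly
    below ``breaks[i]`` and the final entry to all later years.
    """

    breaks: tuple = ()
    factors: tuple = (1.0,)

    def __post_init__(self):
        if len(self.factors) != len(self.breaks) + 1:
            raise ConfigurationError("screening needs len(factors) == len(breaks)+1")
        if any(f <= 0 for f in self.factors):
            raise ConfigurationError("screening factors must be positive")
        if list(self.breaks) != sorted(self.breaks):
            raise ConfigurationError("screening breaks must be ascending")

    def factor(self, year: float) -> float:
        idx = int(np.searchsorted(np.asarray(self.breaks), year, side="right"))
        return float(self.factors[idx])


@dataclass(frozen=True)
class BaselineSpec:
    """Log-linear spontaneous-rate model with a pre-averaged cohort factor.

    ln f = b0 + b_sex*s + b_age*ln(a/age_centre) + b_byr*(b - byr_centre)/10

    Coefficients absent from the parameter vector count as zero.  The
    city/in-city cohort factor, meaningless outside the study cohort, is
    pre-averaged into ``g_average`` (defaults to 1).
    """

    age_centre: float = 70.0
    byr_centre: float = 1930.0
    g_average: float = 1.0

    def __post_init__(self):
        if self.g_average <= 0:
            raise ConfigurationError("g_average must be positive")


@dataclass
class RiskModel:
    """One fitted ERR- or EAR-type risk model.

    ``params`` maps parameter names to fitted values; ``covariance`` (same
    order as ``params``) is the covariance of the fit, used for
    multivariate-normal parameter sampling.  ``kind`` fixes the unit of the
    excess term: ERR is dimensionless, EAR is per 10^4 PY.  ``twin_id``
    points to a linear-in-dose companion sharing baseline and modifiers
    (used by the max-of-twins rule for non-linear leukaemia models).
    ``lss_cohort_flags`` switches on the cohort dosimetry / neutron
    uncertainty factors.
    """

    id: str
    kind: str  # "ERR" | "EAR"
    disease_class: str  # "solid" | "hematopoietic"
    dose_response: DoseResponseSpec = field(default_factory=DoseResponseSpec)
    modifier_spec: ModifierSpec = field(default_factory=ModifierSpec)
    baseline_spec: BaselineSpec | None = None
    screening_spec: ScreeningSpec | None = None
    params: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    aic: float = 0.0
    twin_id: str | None = None
    lss_cohort_flags: bool = False

    def __post_init__(self):
        if self.kind not in ("ERR", "EAR"):
            raise ConfigurationError(f"model kind must be ERR or EAR, got {self.kind!r}")
        if self.disease_class not in ("solid", "hematopoietic"):
            raise ConfigurationError(
                f"disease class must be solid or hematopoietic, got {self.disease_class!r}"
            )
        k = len(self.params)
        if self.covariance is None:
            self.covariance = np.zeros((k, k))
        else:
            self.covariance = np.asarray(self.covariance, dtype=float)
            if self.covariance.shape != (k, k):
                raise ConfigurationError(
                    f"covariance shape {self.covariance.shape} does not match "
                    f"{k} parameters of model {self.id!r}"
                )
            self.covariance = regularize_covariance(self.covariance, self.id)

    @property
    def param_names(self) -> list:
        return list(self.params)

    def param_vector(self) -> np.ndarray:
        return np.array(list(self.params.values()), dtype=float)

    def with_params(self, values: np.ndarray) -> dict:
        return dict(zip(self.params, np.asarray(values, dtype=float)))

    def replace(self, **kw) -> "RiskModel":
        return replace(self, **kw)


def regularize_covariance(cov: np.ndarray, model_id: str = "?") -> np.ndarray:
    """Symmetrise and clip tiny negative eigenvalues; reject genuine non-PSD.

    Round-tripped matrices may carry eigenvalues slightly below zero; those
    within ``-1e-10 * trace`` are clipped to zero, anything worse is a
    configuration error.
    """
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-8 * (1.0 + np.abs(cov).max(initial=0.0))):
        raise ConfigurationError(f"covariance of model {model_id!r} is not symmetric")
    cov = 0.5 * (cov + cov.T)
    if cov.size == 0:
        return cov
    w, v = np.linalg.eigh(cov)
    tol = 1e-10 * max(np.trace(cov), 1e-300)
    if w.min() < -tol:
        raise ConfigurationError(
            f"covariance of model {model_id!r} is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})"
        )
    if w.min() < 0:
        cov = (v * np.clip(w, 0.0, None)) @ v.T
        cov = 0.5 * (cov + cov.T)
    return cov


def dose_term(spec: DoseResponseSpec, params: dict, d, s: float = 0.0):
    """Evaluate the dose response ``p(d)`` (dose in Gy); vectorised in ``d``.

    ``s`` is accepted for interface symmetry; sex dependence is carried by
    the modifier term in this parameterisation.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise InputError("dose must be non-negative")
    form = spec.form
    if form == "none":  # baseline-only models: no radiation term
        out = 0.0 * d
    elif form == "linear":
        out = params["beta"] * d
    elif form == "linear_quadratic":
        out = params["beta"] * d + params["alpha"] * d**2
    elif form == "quadratic":
        out = params["alpha"] * d**2
    elif form == "power":
        gamma = params["gamma"]
        if gamma <= 0:
            raise ConfigurationError("power-form exponent must be positive")
        out = params["beta"] * np.where(d > 0, d, 1.0) ** gamma * (d > 0)
    elif form == "quadratic_exponential":
        out = params["alpha"] * d**2 * np.exp(params["delta"] * d)
    elif form == "threshold_linear_spline":
        k = spec.knot_dose
        out = np.where(
            d <= k,
            params["beta1"] * d,
            params["beta1"] * k + params["beta2"] * (d - k),
        )
    else:  # pragma: no cover - guarded in the spec constructor
        raise ConfigurationError(f"unknown dose-response form {form!r}")
    return out if out.ndim else float(out)


def modifier_term(
    spec: ModifierSpec,
    params: dict,
    s: float = 0.0,
    a: float = 70.0,
    e: float = 30.0,
    smoking_intensity: float = 0.0,
):
    """Evaluate the effect-modifier product ``r(s, a, e)`` (> 0)."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(a < e):
        raise InputError("attained age must be >= age at exposure")
    out = np.ones(np.broadcast(a, e).shape)
    if spec.sex:
        sigma = params["sigma"]
        if spec.sex_convention == "loglinear":
            out = out * math.exp(sigma * s)
        else:
            fac = 1.0 + sigma * s
            if fac <= 0:
                raise ConfigurationError("linear sex modifier drives r non-positive")
            out = out * fac
    if spec.attained_age:
        out = out * (a / spec.age_centre) ** params["phi"]
    if spec.age_at_exposure:
        out = out * np.exp(params["psi"] * (e - spec.exposure_centre) / 10.0)
    if spec.smoking:
        x = smoking_intensity / 10.0
        out = out * math.exp(params.get("theta1", 0.0) * x + params.get("theta2", 0.0) * x**2)
    return out if out.ndim else float(out)


def excess(
    model: RiskModel,
    params: dict,
    d,
    s: float = 0.0,
    a: float = 70.0,
    e: float = 30.0,
    smoking_intensity: float = 0.0,
):
    """Excess term ``p(d) * r(s,a,e)``: ERR (dimensionless) or EAR (per 10^4 PY)."""
    return dose_term(model.dose_response, params, d, s) * modifier_term(
        model.modifier_spec, params, s, a, e, smoking_intensity
    )


def baseline_f(spec: BaselineSpec, params: dict, s: float, a, b):
    """Cohort-independent log-linear baseline rate f(s, a, b), per PY."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise InputError("attained age must be positive for the baseline rate")
    b = np.asarray(b, dtype=float)
    ln = (
        params.get("b0", 0.0)
        + params.get("b_sex", 0.0) * s
        + params.get("b_age", 0.0) * np.log(a / spec.age_centre)
        + params.get("b_byr", 0.0) * (b - spec.byr_centre) / 10.0
    )
    out = np.exp(ln)
    return out if out.ndim else float(out)


def cohort_g(params: dict, c, ic):
    """Cohort-specific city/in-city factor ``g = exp(g_city*c + g_incity*IC)``."""
    c = np.asarray(c, dtype=float)
    ic = np.asarray(ic, dtype=float)
    out = np.exp(params.get("g_city", 0.0) * c + params.get("g_incity", 0.0) * ic)
    return out if out.ndim else float(out)


def model_baseline(model: RiskModel, params: dict, s: float, a, calendar_year):
    """Model baseline rate f * g_average * screening(year), per PY.

    Birth year is derived as ``calendar_year - a``.  Models shipped without
    a baseline (generic-transfer models such as breast/lung) cannot supply
    this and must use the generic baseline-ratio transfer instead.
    """
    if model.baseline_spec is None:
        raise ConfigurationError(
            f"model {model.id!r} has no baseline: generic transfer required"
        )
    b = np.asarray(calendar_year, dtype=float) - np.asarray(a, dtype=float)
    out = baseline_f(model.baseline_spec, params, s, a, b) * model.baseline_spec.g_average
    if model.screening_spec is not None:
        out = out * model.screening_spec.factor(float(np.asarray(calendar_year)))
    return out


def sample_params(model: RiskModel, rng: np.random.Generator) -> dict:
    """One multivariate-normal draw of the parameter vector.

    Centred at the fitted values with the model covariance; a zero
    covariance returns the fitted values exactly.
    """
    mean = model.param_vector()
    if model.covariance is None or not np.any(model.covariance):
        return dict(model.params)
    draw = rng.multivariate_normal(mean, model.covariance, method="eigh")
    return model.with_params(draw)
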