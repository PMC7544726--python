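"""Poisson regression of grouped cohort person-year tables.

Cohort data are stratified into cells carrying sex s (+-1), attained age a,
age at exposure e, organ dose d (Gy), city c (+-1), in-city indicator IC
(0/1), observed cases n and person-years PY.  Model parameters minimise
the Poisson deviance

    dev = 2 sum_{n_i>0} [n_i ln(n_i/mu_i) - (n_i - mu_i)] + 2 sum_{n_i=0} mu_i

with expected counts mu_i = rate(cell) * PY_i, where the cell rate uses the
same generic ERR/EAR model forms as risk prediction, multiplied by the
cohort factor g(c, IC).  The parameter covariance is taken as the inverse
of half the deviance Hessian at the optimum (observed information);
AIC = dev + 2 * n_params.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import models as _models
from .errors import ConfigurationError, InputError
from .models import RiskModel, regularize_covariance

__all__ = [
    "CohortCells",
    "FitResult",
    "cell_rate",
    "expected_counts",
    "deviance",
    "fit",
    "aic",
    "likelihood_ratio_test",
    "prune",
    "average_cohort_factor",
]

CELL_COLUMNS = ["s", "a", "e", "d", "c", "IC", "n", "PY"]

#: the radiation dose-response coefficients: never pruned even when
#: statistically non-significant (the uncertainty flows to Z instead)
PROTECTED_PARAMS = {"beta", "alpha", "gamma", "delta", "beta1", "beta2", "b0"}


@dataclass
class CohortCells:
    """Stratified person-year table; validates the indicator coding."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        missing = [col for col in CELL_COLUMNS if col not in df.columns]
        if missing:
            raise InputError(f"cohort cells miss columns {missing}")
        if (df["PY"] <= 0).any():
            raise InputError("person-years must be positive")
        if (df["n"] < 0).any() or not np.allclose(df["n"], df["n"].round()):
            raise InputError("case counts must be non-negative integers")
        if not set(np.unique(df["s"])).issubset({-1, 1}):
            raise InputError("sex indicator must be coded -1/+1")
        if not set(np.unique(df["c"])).issubset({-1, 1}):
            raise InputError("city indicator must be coded -1/+1")
        if not set(np.unique(df["IC"])).issubset({0, 1}):
            raise InputError("in-city indicator must be coded 0/1")
        if (df["d"] < 0).any():
            raise InputError("doses must be non-negative")
        df["n"] = df["n"].round().astype(int)
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "CohortCells":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class FitResult:
    """Optimum of the deviance with uncertainty and diagnostics."""

    model: RiskModel
    params: dict
    covariance: np.ndarray
    deviance: float
    aic: float
    p_values: dict
    converged: bool
    n_evaluations: int = 0

    def fitted_model(self) -> RiskModel:
        """The input model with fitted params, covariance and AIC filled in."""
        return self.model.replace(
            params=dict(self.params),
            covariance=self.covariance,
            aic=self.aic,
        )


def cell_rate(model: RiskModel, params: dict, cells: CohortCells) -> np.ndarray:
    """Total incidence rate per cell: baseline * g * (1 + ERR), or + EAR."""
    df = cells.data
    s = df["s"].to_numpy(float)
    a = df["a"].to_numpy(float)
    e = df["e"].to_numpy(float)
    d = df["d"].to_numpy(float)
    if model.baseline_spec is None:
        raise ConfigurationError("fitting requires a model baseline specification")
    b = a * 0.0 + model.baseline_spec.byr_centre  # birth year absorbed into intercept
    base = _models.baseline_f(model.baseline_spec, params, 0.0, a, b) * np.exp(
        params.get("b_sex", 0.0) * s
    )
    g = _models.cohort_g(params, df["c"].to_numpy(float), df["IC"].to_numpy(float))
    exc = (
        _models.dose_term(model.dose_response, params, d)
        * np.exp(params.get("sigma", 0.0) * s if model.modifier_spec.sex else 0.0 * s)
        * (
            (a / model.modifier_spec.age_centre) ** params.get("phi", 0.0)
            if model.modifier_spec.attained_age
            else 1.0
        )
        * (
            np.exp(params.get("psi", 0.0) * (e - model.modifier_spec.exposure_centre) / 10.0)
            if model.modifier_spec.age_at_exposure
            else 1.0
        )
    )
    if model.kind == "ERR":
        lam = base * g * (1.0 + exc)
    else:
        lam = base * g + exc * 1e-4
    return lam


def expected_counts(model: RiskModel, params: dict, cells: CohortCells) -> np.ndarray:
    """mu_i = rate_i * PY_i."""
    mu = cell_rate(model, params, cells) * cells.data["PY"].to_numpy(float)
    return mu


def deviance(model: RiskModel, params: dict, cells: CohortCells) -> float:
    """Grouped Poisson deviance; >= 0, zero only at a saturated fit."""
    n = cells.data["n"].to_numpy(float)
    mu = expected_counts(model, params, cells)
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        return np.inf
    pos = n > 0
    dev = 2.0 * np.sum(n[pos] * np.log(n[pos] / mu[pos]) - (n[pos] - mu[pos]))
    dev += 2.0 * np.sum(mu[~pos])
    return float(dev)


def aic(result_or_dev, n_params: int | None = None) -> float:
    """AIC = deviance + 2 * number of parameters."""
    if isinstance(result_or_dev, FitResult):
        return result_or_dev.deviance + 2 * len(result_or_dev.params)
    return float(result_or_dev) + 2 * int(n_params)


def _hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with parameter-scaled steps."""
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[[i, j]] += [h[i], -h[j]]
                xmp[[i, j]] += [-h[i], h[j]]
                xmm[[i, j]] += [-h[i], -h[j]]
                H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                    4 * h[i] * h[j]
                )
    return H


def fit(
    model: RiskModel,
    cells: CohortCells,
    start: dict | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Minimise the deviance over the model's free parameters.

    Quasi-Newton (BFGS) with a Nelder-Mead polish, multi-start from
    jittered initial points to guard against local minima.  The covariance
    is 2 * inverse deviance Hessian at the optimum.
    """
    names = model.param_names
    if not names:
        raise ConfigurationError("model has no free parameters to fit")
    x0 = np.array([(start or model.params)[k] for k in names], dtype=float)
    n_eval = 0

    def obj(x):
        nonlocal n_eval
        n_eval += 1
        dev = deviance(model, dict(zip(names, x)), cells)
        # large finite penalty keeps finite-difference gradients usable
        return dev if np.isfinite(dev) else 1e12

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max(n_starts, 1)):
        xs = x0 if attempt == 0 else x0 + rng.normal(scale=0.1 * (np.abs(x0) + 0.1))
        res = optimize.minimize(obj, xs, method="BFGS", options={"gtol": 1e-6})
        res = optimize.minimize(
            obj, res.x, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-10}
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    x_opt = best.x
    dev_opt = float(best.fun)
    if not np.isfinite(dev_opt):
        raise ConfigurationError("deviance minimisation failed to find a finite optimum")

    H = _hessian(obj, x_opt)
    singular = False
    try:
        cov = 2.0 * np.linalg.inv(H)
        cov = regularize_covariance(cov, model.id)
    except (np.linalg.LinAlgError, ConfigurationError):
        cov = np.full((len(names), len(names)), np.nan)
        singular = True

    params = dict(zip(names, x_opt))
    p_values = {}
    for i, name in enumerate(names):
        if singular or cov[i, i] <= 0:
            p_values[name] = np.nan
        else:
            zstat = params[name] / np.sqrt(cov[i, i])
            p_values[name] = float(2 * stats.norm.sf(abs(zstat)))

    return FitResult(
        model=model,
        params=params,
        covariance=cov,
        deviance=dev_opt,
        aic=dev_opt + 2 * len(names),
        p_values=p_values,
        converged=bool(best.success) and not singular,
        n_evaluations=n_eval,
    )


def likelihood_ratio_test(nested: FitResult, full: FitResult) -> float:
    """Chi-squared p-value on the deviance difference of nested fits."""
    df = len(full.params) - len(nested.params)
    if df < 0:
        raise InputError("the nested fit must have fewer parameters")
    ddev = max(nested.deviance - full.deviance, 0.0)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(ddev, df))


def _drop_param(model: RiskModel, name: str) -> RiskModel:
    """Model with one parameter (and its switch, if a modifier) removed."""
    params = {k: v for k, v in model.params.items() if k != name}
    mod = model.modifier_spec
    kwargs = {}
    if name == "sigma":
        kwargs["sex"] = False
    elif name == "phi":
        kwargs["attained_age"] = False
    elif name == "psi":
        kwargs["age_at_exposure"] = False
    if kwargs:
        from dataclasses import replace as dc_replace

        mod = dc_replace(mod, **kwargs)
    return model.replace(params=params, modifier_spec=mod, covariance=None)


def prune(
    model: RiskModel,
    cells: CohortCells,
    alpha: float = 0.05,
    seed: int = 0,
) -> FitResult:
    """Backward elimination of non-significant modifiers by LRT.

    Repeatedly drops the least significant removable parameter whose LRT
    p-value exceeds ``alpha``.  The primary dose-response coefficients and
    the baseline intercept are never removed, even when their confidence
    interval includes zero.
    """
    current = fit(model, cells, seed=seed)
    while True:
        removable = [k for k in current.params if k not in PROTECTED_PARAMS]
        if not removable:
            return current
        candidates = []
        for name in removable:
            reduced = _drop_param(current.model.replace(params=dict(current.params)), name)
            red_fit = fit(reduced, cells, seed=seed)
            candidates.append((likelihood_ratio_test(red_fit, current), name, red_fit))
        p_best, _, red_fit = max(candidates, key=lambda t: t[0])
        if p_best > alpha:
            current = red_fit
        else:
            return current


def average_cohort_factor(
    fit_result: FitResult, cells: CohortCells, weight: str = "cases"
) -> float:
    """Average the fitted g(c, IC) over strata, weighted by cases or PY.

    The city/in-city factor is meaningless outside the study cohort, so it
    is collapsed into a single multiplier for the transferable baseline.
    """
    if weight not in ("cases", "PY"):
        raise InputError("weight must be 'cases' or 'PY'")
    df = cells.data
    g = _models.cohort_g(fit_result.params, df["c"].to_numpy(float), df["IC"].to_numpy(float))
    w = df["n"].to_numpy(float) if weight == "cases" else df["PY"].to_numpy(float)
    if w.sum() <= 0:
        raise InputError("averaging weights are all zero")
    return float(np.average(g, weights=w))
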