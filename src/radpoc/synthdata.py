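"""Synthetic data generators and packaged example model sets.

Everything the other modules consume can be generated here: population
incidence tables with Poisson case counts on a log-linear rate surface,
stratified cohort person-year cells simulated from a known true risk
model (for testing the Poisson fitter), a smoking prevalence table, and a
ready-to-run example model set built from published headline constants for
several grouped solid-cancer models.

The example model sets are ILLUSTRATIVE: the published tables print point
estimates and Wald p-values but neither covariance matrices nor baseline
parameterisations, so diagonal covariances are back-computed from the
p-values, AICs are reconstructed from the published per-group MMI weights
(AIC = -2 ln w up to a constant), and the baselines are synthetic
log-linear stand-ins.  They exercise the full computational pathway but do
not reproduce any cohort's fitted supplement values.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .fitting import CohortCells
from .mmi import WeightTree
from .models import (
    BaselineSpec,
    DoseResponseSpec,
    ModifierSpec,
    RiskModel,
)
from .modelset import ModelGroup, ModelSet
from .popdata import PopulationTable

__all__ = [
    "generate_population_table",
    "generate_cohort_cells",
    "generate_smoking_prevalence",
    "example_model_set",
]


def generate_population_table(
    rng: np.random.Generator,
    years=(1995, 2014),
    age_max: int = 90,
    base_rate: float = 2e-4,
    rate_age_slope: float = 4.0,
    rate_year_slope: float = 0.0,
    sex_ratio: float = 1.0,
    py_per_group: float = 2.5e6,
) -> PopulationTable:
    """Synthetic registry table: Poisson cases on a log-linear rate surface.

    The rate at age a, year y is
    ``base_rate * (a/70)^rate_age_slope * exp(rate_year_slope*(y-y0)/10)``
    (female rate additionally multiplied by ``sex_ratio``), evaluated at
    the 5-year age-group midpoint; person-years taper linearly above age
    60 to mimic a population pyramid.
    """
    if base_rate < 0 or py_per_group <= 0:
        raise InputError("rates must be >= 0 and person-years positive")
    rows = []
    y0 = years[0]
    for year in range(years[0], years[1] + 1):
        for lo in range(0, age_max, 5):
            hi = lo + 4
            mid = lo + 2.5
            py = py_per_group * max(0.2, 1.0 - max(mid - 60.0, 0.0) / 40.0)
            for sex, mult in (("m", 1.0), ("f", sex_ratio)):
                rate = (
                    base_rate
                    * mult
                    * (max(mid, 2.5) / 70.0) ** rate_age_slope
                    * math.exp(rate_year_slope * (year - y0) / 10.0)
                )
                cases = int(rng.poisson(rate * py)) if rate > 0 else 0
                rows.append(
                    {
                        "sex": sex,
                        "age_low": lo,
                        "age_high": hi,
                        "year": year,
                        "cases": cases,
                        "person_years": py,
                    }
                )
    return PopulationTable(pd.DataFrame(rows))


def generate_cohort_cells(
    true_model: RiskModel,
    rng: np.random.Generator,
    doses=(0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0),
    ages=(30.0, 45.0, 60.0, 75.0),
    ages_at_exposure=(10.0, 25.0, 40.0),
    py_per_cell: float = 5e4,
) -> CohortCells:
    """Simulate a stratified person-year table from a known true model.

    Cells cover both sexes, both cities, in/out-of-city strata and the
    requested dose/age grid; case counts are Poisson with mean
    rate * PY.  Used for parameter-recovery checks of the fitter.
    """
    from .fitting import cell_rate

    rows = []
    for s in (-1, 1):
        for c in (-1, 1):
            for ic in (0, 1):
                for a in ages:
                    for e in ages_at_exposure:
                        if e >= a:
                            continue
                        for d in doses:
                            rows.append(
                                {"s": s, "a": a, "e": e, "d": d, "c": c, "IC": ic,
                                 "n": 0, "PY": py_per_cell}
                            )
    df = pd.DataFrame(rows)
    cells = CohortCells(df)
    mu = cell_rate(true_model, true_model.params, cells) * df["PY"].to_numpy()
    if np.any(mu < 0):
        raise InputError("true model produces negative expected counts")
    df["n"] = rng.poisson(mu)
    return CohortCells(df)


def generate_smoking_prevalence(
    rng: np.random.Generator | None = None,
    never: float = 0.45,
    past: float = 0.25,
    intensity_gm: float = 12.0,
    intensity_gsd: float = 1.8,
) -> dict:
    """Synthetic national smoking prevalence table (status + intensity).

    A stand-in with plausible Western-population magnitudes; probabilities
    sum to 1 per sex.  ``rng`` perturbs the shares slightly when given, so
    generated tables differ across seeds.
    """
    current = 1.0 - never - past
    if current < 0:
        raise InputError("status probabilities exceed 1")
    out = {}
    for sex, shift in (("m", 0.05), ("f", -0.05)):
        nv, pa, cu = never - shift, past, current + shift
        if rng is not None:
            jitter = rng.uniform(-0.02, 0.02)
            nv, cu = nv + jitter, cu - jitter
        total = nv + pa + cu
        out[sex] = {
            "never": nv / total,
            "past": pa / total,
            "current": cu / total,
            "intensity_lognormal": {"gm": intensity_gm, "gsd": intensity_gsd},
        }
    return out


# ---------------------------------------------------------------------------
# example model set from published headline constants (illustrative)
# ---------------------------------------------------------------------------

def _wald_var(estimate: float, p_value: float) -> float:
    """Back out a Wald variance from a point estimate and two-sided p-value."""
    z = stats.norm.isf(p_value / 2.0)
    return (estimate / z) ** 2


def _weights_to_aics(weights) -> list:
    """AICs reproducing the given MMI weights (up to a common constant)."""
    return [-2.0 * math.log(w) for w in weights]


def _baseline(g_average: float = 1.0) -> BaselineSpec:
    return BaselineSpec(age_centre=70.0, byr_centre=1930.0, g_average=g_average)


# synthetic stand-in baseline coefficients: rate 1e-4/PY at age 70 rising
# with age, mild sex effect.  Illustrative only; no cohort baseline is
# published at this level of detail.
_BASE_PARAMS = {"b0": math.log(1e-4), "b_sex": -0.1, "b_age": 2.5}


def _model(
    mid,
    kind,
    constant,
    p_const,
    *,
    form="linear",
    phi=None,
    p_phi=0.05,
    gamma=None,
    psi=None,
    p_psi=0.001,
    aic=0.0,
    disease_class="solid",
    twin_id=None,
    with_baseline=True,
    lss=True,
):
    """Assemble one illustrative model from printed constants and p-values."""
    const_name = {"linear": "beta", "quadratic": "alpha", "power": "beta"}[form]
    params = dict(_BASE_PARAMS) if with_baseline else {}
    params[const_name] = constant
    var = {const_name: _wald_var(constant, p_const)}
    modifier = {}
    if gamma is not None:
        params["gamma"] = gamma
        var["gamma"] = _wald_var(gamma, 0.001)
    if phi is not None:
        params["phi"] = phi
        var["phi"] = _wald_var(phi, p_phi)
        modifier["attained_age"] = True
    if psi is not None:
        params["psi"] = psi
        var["psi"] = _wald_var(psi, p_psi)
        modifier["age_at_exposure"] = True
    names = list(params)
    cov = np.diag([var.get(nm, 0.0) for nm in names])
    return RiskModel(
        id=mid,
        kind=kind,
        disease_class=disease_class,
        dose_response=DoseResponseSpec(form=form),
        modifier_spec=ModifierSpec(**modifier),
        baseline_spec=_baseline() if with_baseline else None,
        params=params,
        covariance=cov,
        aic=aic,
        twin_id=twin_id,
        lss_cohort_flags=lss,
    )


def example_model_set(include_smoking_prevalence: bool = True) -> ModelSet:
    """Illustrative ready-to-run model set for grouped solid cancers.

    Covers the digestive-remainder (DIG), urinary (URI), cervical (GNF1),
    other-female-genital (GNF2), male-genital (GNM), brain/CNS (BCNS),
    non-melanoma skin (SKIN) and remaining-organs (REM) groups, each as an
    AIC-weighted ERR/EAR pair (GNM: triple), plus a synthetic
    hematopoietic quadratic model with a linear twin (HEMSYN) for the
    max-of-twins rule.  Covariances are diagonal (from printed Wald
    p-values) and baselines synthetic: illustrative, not fitted values.
    """
    ms_models = []
    groups = {}

    def add_group(name, members, weights, disease_class="solid", max_group=()):
        aics = _weights_to_aics(weights)
        for m, a in zip(members, aics):
            m.aic = a
        ms_models.extend(members)
        groups[name] = ModelGroup(
            name=name,
            disease_class=disease_class,
            tree=WeightTree(model_ids=[m.id for m in members], aics=aics),
            max_group=list(max_group),
        )

    add_group(
        "DIG",
        [
            _model("DIG-ERR", "ERR", 0.24, 0.001, phi=-3.04, p_phi=0.001),
            _model("DIG-EAR", "EAR", 6.85, 0.001, phi=2.26, p_phi=0.001),
        ],
        [0.71, 0.29],
    )
    add_group(
        "URI",
        [
            _model("URI-ERR", "ERR", 1.21, 0.001),
            _model("URI-EAR", "EAR", 4.19, 0.001, phi=3.63, p_phi=0.001),
        ],
        [0.47, 0.53],
    )
    add_group(
        "GNF1",
        [
            _model("GNF1-ERR", "ERR", 0.06, 0.68),
            _model("GNF1-EAR", "EAR", 0.57, 0.4),
        ],
        [0.43, 0.57],
    )
    add_group(
        "GNF2",
        [
            _model("GNF2-ERR", "ERR", 0.35, 0.12),
            _model("GNF2-EAR", "EAR", 0.49, 0.3),
        ],
        [0.72, 0.28],
    )
    add_group(
        "GNM",
        [
            _model("GNM-ERR1", "ERR", 0.12, 0.56),
            _model("GNM-ERR2", "ERR", 1.39, 0.38, phi=2.7, p_phi=0.3),
            _model("GNM-EAR", "EAR", 0.20, 0.37, phi=-3.7, p_phi=0.3),
        ],
        [0.76, 0.19, 0.05],
    )
    add_group(
        "BCNS",
        [
            _model("BCNS-ERR", "ERR", 0.23, 0.23, phi=-2.97, p_phi=0.009),
            _model("BCNS-EAR", "EAR", 0.46, 0.046),
        ],
        [0.58, 0.42],
    )
    add_group(
        "SKIN",
        [
            _model("SKIN-ERR", "ERR", 0.71, 0.018, form="power", gamma=1.55,
                   psi=-0.89, p_psi=0.001),
            _model("SKIN-EAR", "EAR", 1.1, 0.021, form="power", gamma=1.60,
                   psi=-0.75, p_psi=0.001, phi=3.65, p_phi=0.001),
        ],
        [0.72, 0.28],
    )
    add_group(
        "REM",
        [
            _model("REM-ERR", "ERR", 0.25, 0.20, phi=-2.77, p_phi=0.02),
            _model("REM-EAR", "EAR", 0.60, 0.03),
        ],
        [0.67, 0.33],
    )
    # synthetic hematopoietic quadratic/linear twin pair: equal excess at
    # 1 Gy so the twin dominates below 1 Gy and the quadratic above
    quad = _model(
        "HEMSYN-Q", "ERR", 1.0, 0.001, form="quadratic",
        disease_class="hematopoietic", twin_id="HEMSYN-L",
    )
    lin = _model(
        "HEMSYN-L", "ERR", 1.0, 0.001, disease_class="hematopoietic",
    )
    add_group("HEMSYN", [quad, lin], [0.8, 0.2], disease_class="hematopoietic")

    return ModelSet(
        id="example-illustrative",
        models={m.id: m for m in ms_models},
        groups=groups,
        smoking_prevalence=(
            generate_smoking_prevalence() if include_smoking_prevalence else None
        ),
    )
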