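"""Per-case Monte Carlo computation of the assigned-share distribution.

The assigned share Z = h / (lambda0 + h) is the probability that a
diagnosed cancer was caused by the person's past radiation exposure.  Each
Monte Carlo iteration draws one self-consistent realisation of every
uncertain ingredient — risk model (by MMI weight), model parameters
(multivariate normal from the fit covariance), latency parameters,
transfer weight f, DREF percentile, target baseline rate (Poisson), cohort
dosimetry/neutron factors and per-exposure doses — and evaluates

    Z = [(1-f) sum_i h_mi + f sum_i h_mi B_i]
        / [lambda0 + (1-f) sum_i h_mi + f sum_i h_mi B_i]

over the exposure history.  Iteration-level samples are shared across
exposures (fully correlated); only dose draws are exposure-specific.
Non-linear leukaemia models are paired with linear "twins" and the larger
of the two Z values is kept; lung models may form a max-ERR group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import adjust, mmi, models, transfer
from .errors import ConfigurationError, InputError
from .modelset import ModelSet
from .popdata import PopulationTable

__all__ = [
    "ExposureEvent",
    "CaseSpec",
    "RunConfig",
    "ZDistribution",
    "assigned_share",
    "capped_time_since_exposure",
    "combine_exposures",
    "twin_rule",
    "max_err_rule",
    "summarize",
    "run_case",
]

MAX_ITERATIONS = 50_000
DEFAULT_ITERATIONS = 5_000
#: EAR models are parameterised per 10^4 person-years
EAR_UNIT = 1e-4

_SEX_INDICATOR = {"m": -1.0, "f": +1.0}

_DOSE_DIST_TYPES = ("fixed", "normal", "lognormal", "uniform", "triangular")


@dataclass
class ExposureEvent:
    """One exposure: calendar year, uncertain dose, optional duration.

    Doses are given in mSv for low-LET radiation (converted to Gy
    internally), in working level months for mine radon, and as an indoor
    air activity concentration (Bq/m^3) for indoor radon, where the
    product with ``duration_hours`` forms the total exposure.  The dose
    distribution is a mapping with a ``type`` key: fixed(value),
    normal(mean, sd), lognormal(gm, gsd), uniform(low, high) or
    triangular(low, mode, high).
    """

    year: int
    dose: dict = field(default_factory=lambda: {"type": "fixed", "value": 0.0})
    duration_hours: float | None = None
    radiation_class: str = "lowLET"  # lowLET | radon_miner | radon_indoor
    organ_class: str = "internal"

    def __post_init__(self):
        dtype = self.dose.get("type")
        if dtype not in _DOSE_DIST_TYPES:
            raise InputError(f"unknown dose distribution type {dtype!r}")
        if self.radiation_class not in ("lowLET", "radon_miner", "radon_indoor"):
            raise InputError(f"unknown radiation class {self.radiation_class!r}")
        if self.radiation_class == "radon_indoor" and not self.duration_hours:
            raise InputError("indoor radon exposures require duration_hours")
        if self.duration_hours is not None and self.duration_hours <= 0:
            raise InputError("duration_hours must be positive")

    def nominal_dose(self) -> float:
        """Central value of the dose distribution (used in frozen runs)."""
        d = self.dose
        t = d["type"]
        if t == "fixed":
            return float(d["value"])
        if t == "normal":
            return max(float(d["mean"]), 0.0)
        if t == "lognormal":
            return float(d["gm"])
        if t == "uniform":
            return 0.5 * (float(d["low"]) + float(d["high"]))
        return float(d["mode"])  # triangular

    def sample_dose(self, rng: np.random.Generator) -> float:
        """One dose draw in the exposure's native unit, truncated at >= 0."""
        d = self.dose
        t = d["type"]
        if t == "fixed":
            return float(d["value"])
        if t == "normal":
            # rejection sampling keeps the shape above the physical floor
            for _ in range(10_000):
                x = rng.normal(d["mean"], d["sd"])
                if x >= 0:
                    return float(x)
            return 0.0
        if t == "lognormal":
            return float(rng.lognormal(np.log(d["gm"]), np.log(d["gsd"])))
        if t == "uniform":
            return float(rng.uniform(d["low"], d["high"]))
        return float(rng.triangular(d["low"], d["mode"], d["high"]))


@dataclass
class CaseSpec:
    """Diagnosis context and exposure history of one individual."""

    cancer_group: str
    sex: str  # "m" | "f"
    birth_year: int
    diagnosis_year: int
    exposures: list = field(default_factory=list)
    smoking: dict | None = None  # {"status": ..., "intensity": cpd, ...}

    def __post_init__(self):
        if self.sex not in _SEX_INDICATOR:
            raise InputError("sex must be 'm' or 'f'")
        if self.diagnosis_year < self.birth_year:
            raise InputError("diagnosis year precedes birth year")
        for ex in self.exposures:
            if not self.birth_year <= ex.year <= self.diagnosis_year:
                raise InputError(
                    f"exposure year {ex.year} outside [birth, diagnosis] interval"
                )

    @property
    def attained_age(self) -> int:
        return self.diagnosis_year - self.birth_year

    @property
    def sex_indicator(self) -> float:
        return _SEX_INDICATOR[self.sex]


@dataclass
class RunConfig:
    """Monte Carlo run settings; the flags also support frozen runs.

    Setting every ``sample_*`` flag False, ``dref_enabled`` False and
    ``transfer_mode="fixed"`` collapses the simulation onto the closed-form
    mixed-transfer expression (used for verification).
    """

    iterations: int = DEFAULT_ITERATIONS
    percentiles: tuple = (2.5, 16.0, 50.0, 84.0, 97.5)
    transfer_mode: str = "uniform"  # "uniform" | "fixed"
    transfer_value: float = 0.5
    selection_mode: str = "stratified"  # "stratified" | "random"
    clip_negative: str = "after_sum"  # "after_sum" | "per_exposure"
    sample_parameters: bool = True
    sample_latency: bool = True
    apply_latency: bool = True
    dref_enabled: bool = True
    sample_baseline: bool = True
    sample_doses: bool = True
    sample_cohort_factors: bool = True
    sample_generic_b: bool = True
    neutron_sensitivity: float = 0.0

    def __post_init__(self):
        if not 1 <= self.iterations <= MAX_ITERATIONS:
            raise ConfigurationError(
                f"iterations must lie in [1, {MAX_ITERATIONS}], got {self.iterations}"
            )
        if self.transfer_mode not in ("uniform", "fixed"):
            raise ConfigurationError(f"unknown transfer mode {self.transfer_mode!r}")
        if self.selection_mode not in ("stratified", "random"):
            raise ConfigurationError(f"unknown selection mode {self.selection_mode!r}")
        if self.clip_negative not in ("after_sum", "per_exposure"):
            raise ConfigurationError(f"unknown clipping mode {self.clip_negative!r}")


@dataclass
class ZDistribution:
    """Monte Carlo sample of assigned-share values with summary statistics."""

    values: np.ndarray
    summary: dict
    metadata: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return self.summary["mean"]

    @property
    def median(self) -> float:
        return self.summary["median"]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def assigned_share(h_total: float, lambda0: float) -> float:
    """Z = h / (lambda0 + h); negative sampled excess is floored at Z = 0."""
    if lambda0 <= 0:
        raise InputError("baseline rate must be positive")
    h = max(float(h_total), 0.0)
    return h / (lambda0 + h)


def capped_time_since_exposure(disease_class: str, t: float) -> float:
    """Clamp time since exposure to the span supported by the cohort data.

    Solid cancers: capped at 53 years (no floor).  Hematopoietic: clamped
    to [5, 56] years — the models are not extrapolated below 5 years since
    exposure; the latency factor handles the early suppression using the
    raw time.
    """
    if t < 0:
        raise InputError("time since exposure must be non-negative")
    if disease_class == "solid":
        return min(t, 53.0)
    if disease_class == "hematopoietic":
        return min(max(t, 5.0), 56.0)
    raise ConfigurationError(f"unknown disease class {disease_class!r}")


def combine_exposures(h_m, B, f: float, lambda0: float, clip: str = "after_sum") -> float:
    """Assigned share from per-exposure model excess rates and baseline ratios.

    Z = [(1-f) sum h_mi + f sum h_mi B_i] / [lambda0 + same].  Negative
    sampled excess is clipped either after summing (default; preserves
    parameter correlations across exposures) or per exposure.
    """
    if lambda0 <= 0:
        raise InputError("baseline rate must be positive")
    h_m = np.asarray(h_m, dtype=float)
    B = np.asarray(B, dtype=float)
    if h_m.shape != B.shape:
        raise InputError("h_m and B must have matching lengths")
    if clip == "per_exposure":
        h_m = np.clip(h_m, 0.0, None)
    num = (1.0 - f) * h_m.sum() + f * (h_m * B).sum()
    num = max(num, 0.0)
    return num / (lambda0 + num)


def twin_rule(z_selected: float, z_twin: float) -> float:
    """Max of the non-linear model's Z and its linear twin's Z."""
    return max(z_selected, z_twin)


def max_err_rule(err_values) -> np.ndarray:
    """Pointwise maximum of ERR across a conservative max-group.

    ``err_values`` is an iterable of per-exposure ERR arrays, one per
    eligible model.
    """
    arrs = [np.asarray(v, dtype=float) for v in err_values]
    if not arrs:
        raise InputError("max-ERR rule needs at least one model")
    return np.maximum.reduce(arrs)


def summarize(sample, percentiles=(2.5, 16.0, 50.0, 84.0, 97.5)) -> dict:
    """Mean, median, requested percentiles and 68%/95% intervals.

    Percentiles use linear interpolation between order statistics.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise InputError("cannot summarise an empty sample")
    pct = {float(p): float(np.percentile(sample, p)) for p in percentiles}
    return {
        "mean": float(sample.mean()),
        "median": float(np.median(sample)),
        "percentiles": pct,
        "ci68": (float(np.percentile(sample, 16)), float(np.percentile(sample, 84))),
        "ci95": (float(np.percentile(sample, 2.5)), float(np.percentile(sample, 97.5))),
    }


# ---------------------------------------------------------------------------
# per-iteration machinery
# ---------------------------------------------------------------------------

@dataclass
class _IterationContext:
    """Samples shared by all models evaluated within one iteration."""

    lp: adjust.LatencyParams
    f: float
    u_dref: float
    lambda0: float
    doses: np.ndarray  # native units per exposure
    generic_B: float
    cohort: adjust.CohortFactors
    smoking_intensity: float


def _frozen_latency(disease_class: str) -> adjust.LatencyParams:
    if disease_class == "solid":
        return adjust.LatencyParams(3.5, 6.25)
    return adjust.LatencyParams(1.5, 7.66)


def _resolve_smoking(case: CaseSpec, model_set: ModelSet, rng, group) -> float:
    """Smoking intensity (cpd) for this iteration; samples unknown status."""
    needs = any(
        model_set.models[mid].modifier_spec.smoking
        for mid in group.tree.all_model_ids()
    )
    if not needs:
        return 0.0
    smoking = case.smoking or {"status": "unknown"}
    status = smoking.get("status", "unknown")
    if status == "never":
        return 0.0
    if status in ("current", "past") and "intensity" in smoking:
        return float(smoking["intensity"])
    # unknown (or current/past without intensity): national prevalence
    prev = model_set.smoking_prevalence
    if prev is None:
        raise ConfigurationError(
            "smoking status is unknown but the model set carries no prevalence table"
        )
    p = prev[case.sex]
    statuses = ["never", "past", "current"]
    probs = np.array([p[s] for s in statuses])
    drawn = statuses[rng.choice(3, p=probs / probs.sum())]
    if drawn == "never":
        return 0.0
    lg = p["intensity_lognormal"]
    return float(rng.lognormal(np.log(lg["gm"]), np.log(lg["gsd"])))


def _exposure_terms(model, params, case, ctx, config):
    """Per-exposure model excess rates h_mi and baseline ratios B_i."""
    s = case.sex_indicator
    n = len(case.exposures)
    h_m = np.empty(n)
    B = np.empty(n)
    for i, ex in enumerate(case.exposures):
        dose = ctx.doses[i]
        t_raw = case.diagnosis_year - ex.year
        e_i = ex.year - case.birth_year
        t_eff = capped_time_since_exposure(model.disease_class, t_raw)
        a_eff = e_i + t_eff

        if ex.radiation_class == "lowLET":
            d = dose / 1000.0  # mSv -> Gy
        elif ex.radiation_class == "radon_indoor":
            d = dose * ex.duration_hours  # Bq/m^3 * h
        else:  # radon_miner, cumulative WLM
            d = dose

        exc = models.excess(
            model, params, d, s, a_eff, e_i, smoking_intensity=ctx.smoking_intensity
        )

        fl = 1.0
        if config.apply_latency:
            fl = adjust.latency_factor(t_raw, ctx.lp)

        dref = 1.0
        if (
            config.dref_enabled
            and ex.radiation_class == "lowLET"
            and ex.duration_hours is not None
        ):
            dr = dose / ex.duration_hours  # mGy/h (mSv ~ mGy for low LET)
            dref = adjust.dref_value(ctx.u_dref, adjust.dref_gsd(dr))

        cohort_div = 1.0
        cohort_mult = 1.0
        if model.lss_cohort_flags:
            cohort_div = ctx.cohort.dosimetry_factor
            cohort_mult = ctx.cohort.neutron_factor()

        scale = fl * cohort_mult / (dref * cohort_div)
        if model.kind == "ERR":
            if model.baseline_spec is not None:
                lss_year = transfer.lss_calendar_year(ex.year, case.diagnosis_year)
                lam0m = models.model_baseline(model, params, s, a_eff, lss_year)
                h_m[i] = lam0m * exc * scale
                B[i] = ctx.lambda0 / lam0m
            else:
                B[i] = ctx.generic_B
                lam0m = ctx.lambda0 / ctx.generic_B
                h_m[i] = lam0m * exc * scale
        else:  # EAR
            h_m[i] = exc * EAR_UNIT * scale
            if model.baseline_spec is not None:
                lss_year = transfer.lss_calendar_year(ex.year, case.diagnosis_year)
                lam0m = models.model_baseline(model, params, s, a_eff, lss_year)
                B[i] = ctx.lambda0 / lam0m
            else:
                B[i] = ctx.generic_B
    return h_m, B


def _model_z(model, model_set, case, ctx, rng, config, group) -> float:
    params = (
        models.sample_params(model, rng)
        if config.sample_parameters
        else dict(model.params)
    )
    if group.max_group and model.id in group.max_group:
        # conservative rule: pointwise max of ERR over the group, then the
        # selected model's baseline
        h_list, B = None, None
        err_stack = []
        for mid in group.max_group:
            other = model_set.models[mid]
            op = (
                params
                if mid == model.id
                else (
                    models.sample_params(other, rng)
                    if config.sample_parameters
                    else dict(other.params)
                )
            )
            h_other, B_other = _exposure_terms(other, op, case, ctx, config)
            err_stack.append(h_other)
            if mid == model.id:
                B = B_other
        h_m = max_err_rule(err_stack)
    else:
        h_m, B = _exposure_terms(model, params, case, ctx, config)
    return combine_exposures(h_m, B, ctx.f, ctx.lambda0, clip=config.clip_negative)


class _StratifiedSelector:
    """Deterministic largest-deficit model scheduling within tree branches.

    Flat trees reproduce exact largest-remainder counts; hierarchical trees
    draw a branch at random per iteration by its fixed weight and then
    schedule leaves within the branch deterministically.
    """

    def __init__(self, tree: mmi.WeightTree):
        self.tree = tree
        self._counters: dict = {}

    def _leaf_pick(self, node: mmi.WeightTree) -> str:
        key = id(node)
        counts = self._counters.setdefault(key, np.zeros(len(node.model_ids)))
        w = node.weights()
        deficit = w * (counts.sum() + 1.0) - counts
        idx = int(np.argmax(deficit))
        counts[idx] += 1
        return node.model_ids[idx]

    def pick(self, rng: np.random.Generator) -> str:
        node = self.tree
        while not node.is_leaf:
            probs = np.array([w for w, _ in node.branches])
            node = node.branches[rng.choice(len(node.branches), p=probs)][1]
        return self._leaf_pick(node)


def run_case(
    case: CaseSpec,
    model_set: ModelSet,
    population: PopulationTable,
    config: RunConfig | None = None,
    seed: int = 0,
) -> ZDistribution:
    """Full Monte Carlo assigned-share computation for one case.

    Deterministic for a fixed seed.  Returns the Z sample with mean,
    median, percentile table and 68%/95% intervals.
    """
    config = config or RunConfig()
    if case.cancer_group not in model_set.groups:
        raise ConfigurationError(
            f"cancer group {case.cancer_group!r} not in model set {model_set.id!r}"
        )
    group = model_set.groups[case.cancer_group]
    rng = np.random.default_rng(seed)
    n_iter = config.iterations
    a = case.attained_age

    selector = _StratifiedSelector(group.tree)
    z = np.empty(n_iter)
    counts: dict = {}
    any_generic = any(
        model_set.models[mid].baseline_spec is None
        for mid in group.tree.all_model_ids()
    )
    for it in range(n_iter):
        if config.selection_mode == "random":
            mid = mmi.select_model(group.tree, rng)
        else:
            mid = selector.pick(rng)
        model = model_set.models[mid]
        counts[mid] = counts.get(mid, 0) + 1

        lp = (
            adjust.sample_latency(group.disease_class, rng)
            if config.sample_latency
            else _frozen_latency(group.disease_class)
        )
        f = (
            transfer.sample_transfer_weight(rng)
            if config.transfer_mode == "uniform"
            else transfer.sample_transfer_weight(rng, fixed=config.transfer_value)
        )
        u_dref = float(rng.uniform()) if config.dref_enabled else 0.5
        lambda0 = (
            population.sample_baseline(case.sex, a, case.diagnosis_year, rng)
            if config.sample_baseline
            else population.baseline_rate(case.sex, a, case.diagnosis_year)
        )
        if lambda0 <= 0:
            lambda0 = population.baseline_rate(case.sex, a, case.diagnosis_year)
        doses = np.array(
            [
                ex.sample_dose(rng) if config.sample_doses else ex.nominal_dose()
                for ex in case.exposures
            ]
        )
        generic_B = (
            transfer.generic_baseline_ratio(rng)
            if (any_generic and config.sample_generic_b)
            else 1.0
        )
        cohort = (
            adjust.sample_cohort_factors(
                rng, neutron_sensitivity=config.neutron_sensitivity
            )
            if config.sample_cohort_factors
            else adjust.CohortFactors(1.0, 10.0, config.neutron_sensitivity)
        )
        smoking_intensity = _resolve_smoking(case, model_set, rng, group)
        ctx = _IterationContext(
            lp=lp,
            f=f,
            u_dref=u_dref,
            lambda0=lambda0,
            doses=doses,
            generic_B=generic_B,
            cohort=cohort,
            smoking_intensity=smoking_intensity,
        )
        z_val = _model_z(model, model_set, case, ctx, rng, config, group)
        if model.twin_id is not None:
            twin = model_set.models.get(model.twin_id)
            if twin is None:
                raise ConfigurationError(
                    f"model {model.id!r} declares missing twin {model.twin_id!r}"
                )
            z_val = twin_rule(z_val, _model_z(twin, model_set, case, ctx, rng, config, group))
        z[it] = z_val

    return ZDistribution(
        values=z,
        summary=summarize(z, config.percentiles),
        metadata={
            "seed": seed,
            "iterations": n_iter,
            "model_set": model_set.id,
            "cancer_group": case.cancer_group,
            "model_counts": counts,
        },
    )
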