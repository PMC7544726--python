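"""Risk-adjustment factors: latency, dose-rate effectiveness, cohort factors.

The latency factor is an asymmetric S-curve in time since exposure that is
exactly zero at t = 0 and 1/2 at the median latency t0.  The dose-rate
effectiveness factor (DREF) is a lognormal multiplier with geometric mean 1
whose geometric standard deviation grows log-linearly as the dose rate
falls below 6 mGy/h; dividing the excess rate by a sampled DREF leaves the
median risk unchanged while widening its uncertainty bounds.  Study-cohort
models additionally carry a lognormal dosimetry factor (GSD 1.1) and a
triangular neutron weighting factor (5, 10, 30).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InputError

__all__ = [
    "LatencyParams",
    "CohortFactors",
    "latency_factor",
    "sample_latency",
    "dref_gsd",
    "dref_value",
    "sample_cohort_factors",
    "DREF_THRESHOLD_MGY_H",
]

#: dose-rate threshold above which the DREF spread collapses to GSD = 1
DREF_THRESHOLD_MGY_H = 6.0

# latency sampling ranges (years) and fixed width parameters per class
_LATENCY = {
    "solid": ((3.0, 4.0), 6.25),
    "hematopoietic": ((1.25, 1.75), 7.66),
}


@dataclass(frozen=True)
class LatencyParams:
    """Median latency t0 (years) and transition-width parameter eta."""

    t0: float
    eta: float

    def __post_init__(self):
        if self.t0 <= 0 or self.eta <= 0:
            raise ConfigurationError("latency parameters must be positive")


@dataclass(frozen=True)
class CohortFactors:
    """Per-iteration cohort uncertainty factors for study-cohort models."""

    dosimetry_factor: float
    neutron_weight: float
    #: linear response of the excess to the neutron weight, per organ class;
    #: 0 keeps the neutron factor a no-op (the response curve is external)
    neutron_sensitivity: float = 0.0

    def neutron_factor(self) -> float:
        """Multiplier 1 + sensitivity * (w - 10), centred at the mode."""
        return 1.0 + self.neutron_sensitivity * (self.neutron_weight - 10.0)


def latency_factor(t, lp: LatencyParams):
    """S-shaped latency factor in [0, 1): [1 + exp(-eta ln(t/t0))]^-1.

    Equals 0 at t = 0 (limit), 1/2 at t = t0 and rises monotonically
    towards 1.  Vectorised in ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("time since exposure must be non-negative")
    with np.errstate(divide="ignore"):
        ratio = np.where(t > 0, t / lp.t0, 1.0)
        out = np.where(t > 0, 1.0 / (1.0 + ratio ** (-lp.eta)), 0.0)
    return out if out.ndim else float(out)


def sample_latency(disease_class: str, rng: np.random.Generator) -> LatencyParams:
    """Draw latency parameters: t0 uniform over the class range, eta fixed.

    Solid cancers: t0 ~ U(3, 4) y, eta = 6.25; hematopoietic malignancies:
    t0 ~ U(1.25, 1.75) y, eta = 7.66.
    """
    try:
        (lo, hi), eta = _LATENCY[disease_class]
    except KeyError:
        raise ConfigurationError(f"unknown disease class {disease_class!r}") from None
    return LatencyParams(t0=float(rng.uniform(lo, hi)), eta=eta)


def dref_gsd(dr: float) -> float:
    """GSD(dr) = max(1.0, 1.1803 - 0.2317 log10(dr)), dr in mGy/h.

    Returns 1.0 at or above the 6 mGy/h threshold; the two pieces join
    continuously.
    """
    if dr <= 0:
        raise InputError("dose rate must be positive")
    if dr >= DREF_THRESHOLD_MGY_H:
        return 1.0
    return max(1.0, 1.1803 - 0.2317 * math.log10(dr))


def dref_value(u: float, gsd: float) -> float:
    """DREF draw at percentile u of the lognormal(GM=1, GSD=gsd): gsd**PPF(u).

    The median (u = 0.5) is exactly 1 regardless of the spread, so the
    DREF adjustment never shifts the median risk.
    """
    if not 0.0 < u < 1.0:
        raise InputError("percentile must lie strictly inside (0, 1)")
    if gsd < 1.0:
        raise InputError("GSD must be >= 1")
    if gsd == 1.0:
        return 1.0
    return float(gsd ** stats.norm.ppf(u))


def sample_cohort_factors(
    rng: np.random.Generator,
    organ_class: str = "internal",
    neutron_sensitivity: float = 0.0,
) -> CohortFactors:
    """Sample the study-cohort dosimetry and neutron-weighting factors.

    Dosimetry factor ~ lognormal(GM = 1, GSD = 1.1); neutron weight ~
    triangular(5, 10, 30).  ``neutron_sensitivity`` is the configurable
    linear response of the excess to the weight (default 0: no effect).
    """
    if organ_class not in ("internal", "external"):
        raise ConfigurationError(f"unknown organ class {organ_class!r}")
    dosim = float(rng.lognormal(mean=0.0, sigma=math.log(1.1)))
    weight = float(rng.triangular(5.0, 10.0, 30.0))
    return CohortFactors(
        dosimetry_factor=dosim,
        neutron_weight=weight,
        neutron_sensitivity=neutron_sensitivity,
    )
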