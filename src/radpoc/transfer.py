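"""Transfer of excess risk from the study cohort to the target population.

Cohort-derived risk is adjusted to the target population as a random
mixture of additive and multiplicative transfer::

    h = h_m * (1 - f + f * B)

where f ~ U(0, 1) is the multiplicative weight and B the ratio of the
target baseline rate to the model (cohort) baseline rate at matched sex
and attained age.  Because cohort and target rates refer to different
calendar periods, the cohort rate is evaluated at an equivalent calendar
year counted from the 1945 exposure epoch of the atomic-bomb survivor
cohort.  Models with no usable cohort baseline (breast, lung) instead draw
B from a log-uniform(1/3, 3) distribution.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import InputError

__all__ = [
    "lss_calendar_year",
    "baseline_ratio",
    "generic_baseline_ratio",
    "sample_transfer_weight",
    "transferred_excess",
]

_LN3 = math.log(3.0)


def lss_calendar_year(exposure_year: float, diagnosis_year: float) -> float:
    """Cohort calendar year matching the individual's time since exposure.

    An exposure in 1980 diagnosed in 2010 (30 years later) maps to cohort
    year 1975, i.e. 30 years after the 1945 detonations.
    """
    if diagnosis_year < exposure_year:
        raise InputError("diagnosis year precedes exposure year")
    return 1945 + (diagnosis_year - exposure_year)


def baseline_ratio(target_rate: float, model_rate: float) -> float:
    """B = target baseline rate / model baseline rate."""
    if target_rate <= 0 or model_rate <= 0:
        raise InputError("baseline rates must be positive")
    return target_rate / model_rate


def generic_baseline_ratio(rng: np.random.Generator) -> float:
    """One draw of B with ln(B) ~ U(ln 1/3, ln 3) (median and GM exactly 1)."""
    return float(np.exp(rng.uniform(-_LN3, _LN3)))


def sample_transfer_weight(rng: np.random.Generator, fixed: float | None = None) -> float:
    """Multiplicative-transfer weight f ~ U(0, 1), or a fixed override.

    ``fixed=0.5`` gives the conventional best-estimate mode.
    """
    if fixed is not None:
        if not 0.0 <= fixed <= 1.0:
            raise InputError("transfer weight must lie in [0, 1]")
        return float(fixed)
    return float(rng.uniform(0.0, 1.0))


def transferred_excess(h_m, f: float, B):
    """Mixed-transfer excess rate h = h_m * (1 - f + f*B); vectorised."""
    if not 0.0 <= f <= 1.0:
        raise InputError("transfer weight must lie in [0, 1]")
    h_m = np.asarray(h_m, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(B <= 0):
        raise InputError("baseline ratio must be positive")
    out = h_m * (1.0 - f + f * B)
    return out if out.ndim else float(out)
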