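"""NHANES III adult spirometric reference equations.

Predicted values and lower limits of normal (LLN) for FVC, FEV1,
FEF25-75 and the FEV1/FVC ratio follow the adult polynomial reference
equations derived from the third National Health and Nutrition
Examination Survey (Hankinson, Odencrantz & Fedan 1999):

    value = b0 + b1*age + b2*age^2 + b3*height^2

with age in years and height in centimetres, stratified by sex and by
race/ethnicity (Caucasian, African-American, Mexican-American).  The
LLN (5th percentile of the reference population) shares the age terms
and carries its own intercept and height^2 coefficient.  The FEV1/FVC
ratio equations are linear in age only; this module returns the ratio
as a dimensionless fraction.

For FEF25-75 no explicit LLN coefficient pair is shipped; the lower
limit is approximated by the normal-theory form predicted - 1.645*RSD
with a per-stratum residual standard deviation.  Users who need
regulatory-grade limits for mid-expiratory flow should consult the
original coefficient tables.

Subjects with a race/ethnicity outside the three coefficient sets are
mapped to the Caucasian set by default (a logged fallback), matching
common clinical-software practice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QUANTITIES",
    "RACE_CATEGORIES",
    "normalize_race",
    "predicted_and_lln",
]

log = logging.getLogger(__name__)

QUANTITIES = ("FEV1", "FVC", "FEF25-75", "FEV1/FVC")
RACE_CATEGORIES = ("caucasian", "african_american", "mexican_american")

#: age range (years) over which the adult equations are considered valid
AGE_RANGE = (18.0, 80.0)
#: height range (cm) outside which extrapolation is flagged
HEIGHT_RANGE = (130.0, 210.0)

_RACE_ALIASES = {
    "caucasian": "caucasian",
    "white": "caucasian",
    "african_american": "african_american",
    "african-american": "african_american",
    "black": "african_american",
    "mexican_american": "mexican_american",
    "mexican-american": "mexican_american",
    "hispanic": "mexican_american",
}


@dataclass(frozen=True)
class _Volume:
    """Coefficients for a volume/flow quantity (litres or L/s)."""

    b0: float
    b_age: float
    b_age2: float
    b_h2: float
    lln_b0: float | None = None
    lln_b_h2: float | None = None
    lln_rsd: float | None = None  # normal-theory fallback for the LLN

    def predicted(self, age, h2):
        return self.b0 + self.b_age * age + self.b_age2 * age**2 + self.b_h2 * h2

    def lln(self, age, h2):
        if self.lln_b0 is not None:
            return (
                self.lln_b0
                + self.b_age * age
                + self.b_age2 * age**2
                + self.lln_b_h2 * h2
            )
        return self.predicted(age, h2) - 1.645 * self.lln_rsd


@dataclass(frozen=True)
class _Ratio:
    """Coefficients for FEV1/FVC, published in percent, returned as fraction."""

    b0: float
    b_age: float
    lln_b0: float

    def predicted(self, age, h2):
        return (self.b0 + self.b_age * age) / 100.0

    def lln(self, age, h2):
        return (self.lln_b0 + self.b_age * age) / 100.0


_COEFFS = {
    ("male", "caucasian"): {
        "FVC": _Volume(-0.1933, 0.00064, -0.000269, 0.00018642, -0.1571, 0.00015695),
        "FEV1": _Volume(0.5536, -0.01303, -0.000172, 0.00014098, 0.4333, 0.00011607),
        "FEV1/FVC": _Ratio(88.066, -0.2066, 78.388),
        "FEF25-75": _Volume(2.7006, -0.04995, 0.0, 0.00014473, lln_rsd=0.78),
    },
    ("male", "african_american"): {
        "FVC": _Volume(-0.1517, -0.01821, 0.0, 0.00016643, -0.0714, 0.00013499),
        "FEV1": _Volume(0.3411, -0.02309, 0.0, 0.00013194, 0.2182, 0.00010561),
        "FEV1/FVC": _Ratio(89.239, -0.1828, 78.822),
        "FEF25-75": _Volume(2.1477, -0.04238, 0.0, 0.00012837, lln_rsd=0.73),
    },
    ("male", "mexican_american"): {
        "FVC": _Volume(0.2376, -0.00891, -0.000182, 0.00017823, 0.2976, 0.00014615),
        "FEV1": _Volume(0.6306, -0.02928, 0.0, 0.00015104, 0.5757, 0.00012670),
        "FEV1/FVC": _Ratio(90.024, -0.2186, 80.810),
        "FEF25-75": _Volume(1.7503, -0.05018, 0.0, 0.00014106, lln_rsd=0.74),
    },
    ("female", "caucasian"): {
        "FVC": _Volume(-0.3560, 0.01870, -0.000382, 0.00014815, -0.2800, 0.00012198),
        "FEV1": _Volume(0.4333, -0.00361, -0.000194, 0.00011496, 0.3411, 0.00009283),
        "FEV1/FVC": _Ratio(90.809, -0.2125, 81.015),
        "FEF25-75": _Volume(2.3670, -0.01904, -0.000200, 0.00006982, lln_rsd=0.60),
    },
    ("female", "african_american"): {
        "FVC": _Volume(-0.3039, 0.00536, -0.000265, 0.00013606, -0.1981, 0.00010916),
        "FEV1": _Volume(0.3433, -0.01283, -0.000097, 0.00010846, 0.2433, 0.00009111),
        "FEV1/FVC": _Ratio(91.655, -0.2039, 80.978),
        "FEF25-75": _Volume(2.0828, -0.03793, 0.0, 0.00008572, lln_rsd=0.58),
    },
    ("female", "mexican_american"): {
        "FVC": _Volume(0.1210, 0.00307, -0.000237, 0.00014246, 0.1910, 0.00011682),
        "FEV1": _Volume(0.4529, -0.01178, -0.000113, 0.00012154, 0.3729, 0.00009966),
        "FEV1/FVC": _Ratio(92.360, -0.2248, 83.044),
        "FEF25-75": _Volume(1.7456, -0.01195, -0.000291, 0.00010125, lln_rsd=0.58),
    },
}


def normalize_race(race: str, fallback: str | None = "caucasian") -> str:
    """Map a free-form race/ethnicity label onto a coefficient set.

    Unknown labels fall back to ``fallback`` (with a logged warning), or
    raise ``ValueError`` when ``fallback`` is ``None``.
    """
    key = str(race).strip().lower().replace(" ", "_")
    if key in _RACE_ALIASES:
        return _RACE_ALIASES[key]
    if fallback is None:
        raise ValueError(
            f"race category {race!r} has no reference-equation coefficients "
            "and no fallback is configured"
        )
    log.warning(
        "race category %r not covered by the reference equations; "
        "using the %s coefficient set",
        race,
        fallback,
    )
    return _RACE_ALIASES[fallback]


def predicted_and_lln(
    age: float,
    sex: str,
    race: str,
    height_cm: float,
    quantity: str,
    race_fallback: str | None = "caucasian",
) -> tuple[float, float]:
    """Predicted value and lower limit of normal for one subject.

    Parameters
    ----------
    age : years (adult equations; extrapolation outside 18-80 is flagged)
    sex : ``"male"`` or ``"female"``
    race : race/ethnicity label (see :func:`normalize_race`)
    height_cm : standing height in centimetres
    quantity : one of ``"FEV1"``, ``"FVC"``, ``"FEF25-75"``, ``"FEV1/FVC"``

    Returns
    -------
    (predicted, lln) in litres (FVC, FEV1), litres/second (FEF25-75) or
    as a dimensionless fraction (FEV1/FVC).
    """
    if quantity not in QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; expected one of {QUANTITIES}")
    sex = str(sex).strip().lower()
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not age > 0 or not height_cm > 0:
        raise ValueError("age and height must be positive")
    if not (AGE_RANGE[0] <= age <= AGE_RANGE[1]):
        warnings.warn(
            f"age {age:g} outside the {AGE_RANGE} validity range of the adult "
            "reference equations; value is an extrapolation",
            stacklevel=2,
        )
    if not (HEIGHT_RANGE[0] <= height_cm <= HEIGHT_RANGE[1]):
        warnings.warn(
            f"height {height_cm:g} cm outside {HEIGHT_RANGE}; "
            "value is an extrapolation",
            stacklevel=2,
        )
    eq = _COEFFS[(sex, normalize_race(race, fallback=race_fallback))][quantity]
    h2 = float(height_cm) ** 2
    pred = float(eq.predicted(float(age), h2))
    lln = float(eq.lln(float(age), h2))
    return pred, lln
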