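"""Patient data model, Cockcroft-Gault renal function, and cohort screening.

The unit of risk assessment is a single critically ill patient on standard
meropenem dosing. Renal function drives meropenem elimination, so every
patient must resolve to a creatinine clearance (CLCR): either supplied
directly or estimated from sex, age, total body weight and serum creatinine
via the Cockcroft-Gault equation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import ValidationError

log = logging.getLogger(__name__)

#: mg/dL per umol/L for creatinine
_UMOL_PER_MGDL = 88.4

MALE = "male"
FEMALE = "female"


def cockcroft_gault(
    sex: str,
    age: float,
    weight: float,
    serum_creatinine: float,
    scr_unit: str = "mg/dl",
) -> float:
    """Estimate creatinine clearance (mL/min) by Cockcroft-Gault.

    CLCR = (140 - age) * weight / (72 * SCr), multiplied by 0.85 for
    female patients. SCr is in mg/dL; pass ``scr_unit="umol/l"`` to convert
    from µmol/L internally (divide by 88.4).

    Parameters
    ----------
    sex : {"male", "female"}
    age : years, in (0, 140)
    weight : total body weight, kg, > 0
    serum_creatinine : > 0

    Raises
    ------
    ValidationError
        If any input is non-positive or out of range; the message names
        the offending field.
    """
    if sex not in (MALE, FEMALE):
        raise ValidationError(f"sex must be 'male' or 'female', got {sex!r}")
    if not 0 < age < 140:
        raise ValidationError(f"age must be in (0, 140) years, got {age}")
    if weight <= 0:
        raise ValidationError(f"weight must be > 0 kg, got {weight}")
    if serum_creatinine <= 0:
        raise ValidationError(f"serum_creatinine must be > 0, got {serum_creatinine}")
    unit = scr_unit.lower().replace("µ", "u")
    if unit in ("mg/dl", "mg_dl"):
        scr = serum_creatinine
    elif unit in ("umol/l", "umol_l"):
        scr = serum_creatinine / _UMOL_PER_MGDL
    else:
        raise ValidationError(f"scr_unit must be 'mg/dl' or 'umol/l', got {scr_unit!r}")
    clcr = (140.0 - age) * weight / (72.0 * scr)
    if sex == FEMALE:
        clcr *= 0.85
    return clcr


@dataclass
class Patient:
    """A patient record with either CLCR or its four determinants.

    ``clcr``, if supplied, takes precedence over the determinants; when both
    are present and disagree by more than 1% a warning is logged. ``rrt``
    flags renal replacement therapy (an exclusion criterion — clearance
    estimates are not meaningful under extracorporeal elimination).
    """

    id: str
    sex: Optional[str] = None
    age: Optional[float] = None                 # years
    weight: Optional[float] = None              # kg
    serum_creatinine: Optional[float] = None    # mg/dL
    serum_albumin: Optional[float] = None       # g/dL, required for PK simulation
    rrt: bool = False
    clcr: Optional[float] = None                # mL/min, optional override

    def __post_init__(self) -> None:
        if self.clcr is None and not self._has_determinants():
            raise ValidationError(
                f"patient {self.id!r}: supply clcr directly or all of "
                "sex, age, weight, serum_creatinine"
            )
        for name in ("age", "weight", "serum_creatinine", "serum_albumin", "clcr"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"patient {self.id!r}: {name} must be > 0, got {v}")

    def _has_determinants(self) -> bool:
        return None not in (self.sex, self.age, self.weight, self.serum_creatinine)

    def resolve_clcr(self) -> float:
        """Return the patient's creatinine clearance in mL/min.

        A directly supplied value wins; otherwise Cockcroft-Gault is applied
        to the determinants.
        """
        if self.clcr is not None:
            if self._has_determinants():
                computed = cockcroft_gault(
                    self.sex, self.age, self.weight, self.serum_creatinine
                )
                if abs(computed - self.clcr) > 0.01 * self.clcr:
                    log.warning(
                        "patient %s: supplied clcr %.1f disagrees with "
                        "Cockcroft-Gault %.1f by >1%%; using supplied value",
                        self.id, self.clcr, computed,
                    )
            return self.clcr
        return cockcroft_gault(self.sex, self.age, self.weight, self.serum_creatinine)


@dataclass
class InclusionCriteria:
    """Cohort screen: CLCR within the calculator's applicability range,
    no renal replacement therapy, and optional per-characteristic bounds
    (used to restrict a cohort to the covariate ranges a PK model was
    developed on).
    """

    clcr_min: float = 25.0
    clcr_max: float = 255.0
    exclude_rrt: bool = True
    characteristic_ranges: Optional[Mapping[str, tuple]] = None

    def __post_init__(self) -> None:
        if not self.clcr_min < self.clcr_max:
            raise ValidationError(
                f"clcr_min ({self.clcr_min}) must be < clcr_max ({self.clcr_max})"
            )


@dataclass
class ExclusionRecord:
    patient_id: str
    reasons: list = field(default_factory=list)


def apply_inclusion_criteria(
    patients: Sequence[Patient],
    criteria: InclusionCriteria = InclusionCriteria(),
) -> tuple[list[Patient], list[ExclusionRecord]]:
    """Split a cohort into included patients and an exclusion log.

    Order is preserved; every excluded patient carries at least one
    machine-readable reason (``clcr_below_min``, ``clcr_above_max``,
    ``rrt``, ``out_of_range:<characteristic>``). The operation is
    idempotent: filtering the included set again changes nothing.
    """
    included: list[Patient] = []
    excluded: list[ExclusionRecord] = []
    for p in patients:
        reasons = []
        clcr = p.resolve_clcr()
        if clcr < criteria.clcr_min:
            reasons.append("clcr_below_min")
        elif clcr > criteria.clcr_max:
            reasons.append("clcr_above_max")
        if criteria.exclude_rrt and p.rrt:
            reasons.append("rrt")
        if criteria.characteristic_ranges:
            for name, (low, high) in criteria.characteristic_ranges.items():
                v = clcr if name == "clcr" else getattr(p, name, None)
                if v is not None and not low <= v <= high:
                    reasons.append(f"out_of_range:{name}")
        if reasons:
            excluded.append(ExclusionRecord(p.id, reasons))
        else:
            included.append(p)
    return included, excluded
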