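"""Subject records: the anthropometric + BIA + DXA bundle for one adolescent.

A :class:`Subject` carries the predictors every fat-free-mass (FFM) equation
may draw on — sex, age, height, weight, and the 50 kHz bioimpedance triplet
(resistance R, reactance Xc, impedance Z) — together with the DXA criterion
measurement when available.  Impedance obeys ``Z = sqrt(R² + Xc²)``; when a
record supplies only R and Xc the impedance is derived, and when a supplied Z
disagrees with the derived value by more than 1 % a warning is emitted and the
supplied (measured) value wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "FEMALE",
    "MALE",
    "STUDY_AGE_RANGE",
    "Subject",
    "SubjectError",
    "derive_impedance",
    "check_study_population",
]

FEMALE = "F"
MALE = "M"

#: Inclusion age range (years) of the obese-adolescent study population.
STUDY_AGE_RANGE = (11.0, 18.0)

#: Relative disagreement between supplied and derived impedance that
#: triggers a warning (supplied value still wins).
_Z_TOLERANCE = 0.01


class SubjectError(ValueError):
    """A subject record violates a physical or schema invariant."""


def derive_impedance(resistance_ohm: float, reactance_ohm: float) -> float:
    """Impedance magnitude from resistance and reactance, ``sqrt(R² + Xc²)``."""
    return math.hypot(resistance_ohm, reactance_ohm)


@dataclass
class Subject:
    """One adolescent's predictor/criterion record.

    Parameters
    ----------
    sex
        ``"F"`` or ``"M"``; ``None`` when unknown (sex-specific equations
        will refuse to evaluate such a subject).
    impedance_ohm
        Measured impedance at 50 kHz.  If omitted it is derived from
        resistance and reactance.
    tanner_stage
        Pubertal maturation stage 1–5, or ``None`` when not assessed.
    ffm_dxa_kg
        DXA-measured fat-free mass (the validation criterion), or ``None``.
    zi_latent
        The latent height²/impedance index used by the synthetic-cohort
        generator; ``None`` for real data.  Not exported to CSV.
    """

    id: str
    sex: Optional[str]
    age: float
    height_cm: float
    weight_kg: float
    resistance_ohm: float
    reactance_ohm: Optional[float] = None
    impedance_ohm: Optional[float] = None
    tanner_stage: Optional[int] = None
    ffm_dxa_kg: Optional[float] = None
    bmi_sds: Optional[float] = None
    zi_latent: Optional[float] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE, None):
            raise SubjectError(f"subject {self.id!r}: sex must be 'F', 'M' or None, got {self.sex!r}")
        if not self.height_cm > 0:
            raise SubjectError(f"subject {self.id!r}: height_cm must be > 0, got {self.height_cm}")
        if not self.weight_kg > 0:
            raise SubjectError(f"subject {self.id!r}: weight_kg must be > 0, got {self.weight_kg}")
        if not self.resistance_ohm > 0:
            raise SubjectError(
                f"subject {self.id!r}: resistance_ohm must be > 0, got {self.resistance_ohm}"
            )
        if self.reactance_ohm is not None and self.reactance_ohm < 0:
            raise SubjectError(
                f"subject {self.id!r}: reactance_ohm must be >= 0, got {self.reactance_ohm}"
            )
        if self.tanner_stage is not None and self.tanner_stage not in (1, 2, 3, 4, 5):
            raise SubjectError(
                f"subject {self.id!r}: tanner_stage must be 1-5 or None, got {self.tanner_stage}"
            )
        if self.reactance_ohm is None and self.impedance_ohm is None:
            raise SubjectError(
                f"subject {self.id!r}: need reactance_ohm (to derive impedance) "
                "or a measured impedance_ohm"
            )
        if self.impedance_ohm is None:
            self.impedance_ohm = derive_impedance(self.resistance_ohm, self.reactance_ohm)
        else:
            if self.impedance_ohm < self.resistance_ohm:
                raise SubjectError(
                    f"subject {self.id!r}: impedance ({self.impedance_ohm}) < resistance "
                    f"({self.resistance_ohm}) is unphysical"
                )
            if self.reactance_ohm is not None:
                derived = derive_impedance(self.resistance_ohm, self.reactance_ohm)
                if abs(self.impedance_ohm - derived) > _Z_TOLERANCE * derived:
                    warnings.warn(
                        f"subject {self.id!r}: supplied impedance {self.impedance_ohm:.1f} Ω "
                        f"disagrees with sqrt(R²+Xc²) = {derived:.1f} Ω by more than 1%; "
                        "keeping the supplied value",
                        stacklevel=2,
                    )

    @property
    def height_m(self) -> float:
        return self.height_cm / 100.0

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m²."""
        return self.weight_kg / self.height_m**2

    @property
    def zi(self) -> float:
        """Impedance index height(cm)²/Z, cm²/Ω — the principal BIA predictor."""
        return self.height_cm**2 / self.impedance_ohm

    @property
    def ri(self) -> float:
        """Resistance index height(cm)²/R, cm²/Ω."""
        return self.height_cm**2 / self.resistance_ohm

    def with_(self, **changes) -> "Subject":
        return replace(self, **changes)


def check_study_population(
    cohort: Iterable[Subject],
    *,
    enforce: bool = False,
) -> Sequence[Subject]:
    """Check the 11–18 y inclusion age window.

    With ``enforce=True`` (a cohort flagged as study population) out-of-range
    subjects raise :class:`SubjectError`; otherwise each triggers a warning.
    Returns the cohort unchanged for chaining.
    """
    lo, hi = STUDY_AGE_RANGE
    cohort = list(cohort)
    for s in cohort:
        if not (lo <= s.age <= hi):
            msg = f"subject {s.id!r}: age {s.age} y outside study range [{lo}, {hi}]"
            if enforce:
                raise SubjectError(msg)
            warnings.warn(msg, stacklevel=2)
    return cohort
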