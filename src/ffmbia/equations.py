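"""Registry and evaluator for BIA fat-free-mass prediction equations.

Fourteen equations are built in: thirteen published 50 kHz hand-to-foot BIA
equations developed in healthy and/or obese children, adolescents and adults
(Deurenberg 1990/1991, Houtkooper, Kyle, Suprasongsin, Gray, Lukaski,
Schaefer, Sun, Haroun, Horie, Lazzer, Wabitsch) plus the obese-adolescent
equation ``FFM = 0.527·H(cm)²/Z + 0.306·W − 1.862`` developed against DXA.

All formulas are stored with height in centimetres (the two Deurenberg
equations, published with height in metres and a 10⁴ scale factor on the
impedance index, are algebraically pre-converted so every spec consumes cm —
one conversion point, fewer unit bugs).  Sex enters as an indicator coded
male = 1, female = 0.  The Wabitsch equation converts a total-body-water-like
linear combination to FFM by dividing by the assumed lean-tissue hydration
fraction 0.732; the Horie equation predicts fat mass and returns
``weight − FM``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .subjects import FEMALE, MALE, Subject

__all__ = [
    "PREDICTOR_TAGS",
    "CoefficientSet",
    "EquationSpec",
    "Prediction",
    "PredictionRun",
    "EquationError",
    "UnknownEquationError",
    "MissingPredictorError",
    "list_equations",
    "get_equation",
    "register_equation",
    "evaluate_equation",
    "predict_cohort",
    "export_registry",
]

#: Predictor-expression tags an equation term may reference, and how each
#: resolves from a Subject (H in cm, W in kg, R/X/Z in Ω, AGE in years).
PREDICTOR_TAGS: Mapping[str, str] = {
    "H2_over_R": "height_cm² / resistance_ohm",
    "H2_over_Z": "height_cm² / impedance_ohm",
    "H2": "height_cm²",
    "H": "height_cm",
    "W": "weight_kg",
    "AGE": "age (years)",
    "SEX01": "1 if male, 0 if female",
    "R": "resistance_ohm",
    "X": "reactance_ohm",
    "Z": "impedance_ohm",
}

#: Subject fields needed to resolve each tag.
_TAG_FIELDS: Mapping[str, Tuple[str, ...]] = {
    "H2_over_R": ("height_cm", "resistance_ohm"),
    "H2_over_Z": ("height_cm", "impedance_ohm"),
    "H2": ("height_cm",),
    "H": ("height_cm",),
    "W": ("weight_kg",),
    "AGE": ("age",),
    "SEX01": ("sex",),
    "R": ("resistance_ohm",),
    "X": ("reactance_ohm",),
    "Z": ("impedance_ohm",),
}

#: FFM above this is flagged as implausible (not clipped).
_IMPLAUSIBLE_FFM_KG = 120.0

#: Lean-tissue hydration fraction assumed by total-body-water-based equations.
HYDRATION_FACTOR = 0.732


class EquationError(ValueError):
    """Problem evaluating or registering an FFM prediction equation."""


class UnknownEquationError(KeyError, EquationError):
    """Requested equation id is not in the registry."""


class MissingPredictorError(EquationError):
    """A subject lacks a field the equation requires."""

    def __init__(self, eq_id: str, subject_id: str, field_name: str):
        super().__init__(
            f"equation {eq_id!r} requires {field_name!r}, missing for subject {subject_id!r}"
        )
        self.eq_id = eq_id
        self.subject_id = subject_id
        self.field_name = field_name


@dataclass(frozen=True)
class CoefficientSet:
    """One linear combination: ordered (tag, coefficient) terms plus intercept."""

    terms: Tuple[Tuple[str, float], ...]
    intercept: float

    def linear_value(self, values: Mapping[str, float]) -> float:
        """Evaluate the combination on a tag → value mapping."""
        return self.intercept + sum(coef * values[tag] for tag, coef in self.terms)


@dataclass(frozen=True)
class EquationSpec:
    """A registered FFM prediction formula.

    ``form='linear'`` returns the linear combination directly;
    ``form='weight_minus_fm'`` treats the combination as a fat-mass estimate
    and returns ``weight − FM``.  ``postscale`` divides the combination
    before any form handling (hydration-factor conversion).  Sex-specific
    equations key their coefficient sets ``'male'``/``'female'``; age-branched
    equations key them ``'young'``/``'old'`` with the boundary at
    ``age_cut_years`` (age < cut → young, else old).
    """

    eq_id: str
    citation_label: str
    population: str
    sex_handling: str  # 'unisex' | 'sex_specific'
    coef_sets: Mapping[str, CoefficientSet]
    age_cut_years: Optional[float] = None
    height_unit: str = "cm"
    postscale: Optional[float] = None
    form: str = "linear"  # 'linear' | 'weight_minus_fm'

    def __post_init__(self):
        if self.sex_handling not in ("unisex", "sex_specific"):
            raise EquationError(f"{self.eq_id}: bad sex_handling {self.sex_handling!r}")
        if self.sex_handling == "sex_specific" and set(self.coef_sets) != {"male", "female"}:
            raise EquationError(f"{self.eq_id}: sex_specific needs 'male' and 'female' sets")
        if self.age_cut_years is not None and set(self.coef_sets) != {"young", "old"}:
            raise EquationError(f"{self.eq_id}: age branching needs 'young' and 'old' sets")
        for cs in self.coef_sets.values():
            for tag, _ in cs.terms:
                if tag not in PREDICTOR_TAGS:
                    raise EquationError(f"{self.eq_id}: unknown predictor tag {tag!r}")

    @property
    def required_fields(self) -> frozenset:
        """Subject field names needed to evaluate this equation."""
        fields = set()
        for cs in self.coef_sets.values():
            for tag, _ in cs.terms:
                fields.update(_TAG_FIELDS[tag])
        if self.form == "weight_minus_fm":
            fields.add("weight_kg")
        if self.sex_handling == "sex_specific":
            fields.add("sex")
        if self.age_cut_years is not None:
            fields.add("age")
        return frozenset(fields)

    def coefficient_set_for(self, subject: Subject) -> CoefficientSet:
        if self.sex_handling == "sex_specific":
            if subject.sex == MALE:
                return self.coef_sets["male"]
            if subject.sex == FEMALE:
                return self.coef_sets["female"]
            raise EquationError(
                f"equation {self.eq_id!r} is sex-specific but subject {subject.id!r} has unknown sex"
            )
        if self.age_cut_years is not None:
            return self.coef_sets["young" if subject.age < self.age_cut_years else "old"]
        return self.coef_sets["all"]


@dataclass(frozen=True)
class Prediction:
    subject_id: str
    eq_id: str
    ffm_pred_kg: float
    flags: Tuple[str, ...] = ()


@dataclass
class PredictionRun:
    """Predictions for a cohort plus an accounting of skipped pairs."""

    predictions: List[Prediction]
    skipped: List[Tuple[str, str, str]] = field(default_factory=list)  # (subject, eq, reason)

    def for_equation(self, eq_id: str) -> List[Prediction]:
        return [p for p in self.predictions if p.eq_id == eq_id]


def _cs(*terms: Tuple[str, float], intercept: float) -> CoefficientSet:
    return CoefficientSet(terms=tuple(terms), intercept=intercept)


def _builtin_specs() -> List[EquationSpec]:
    # Height-in-metres originals pre-converted: a·10⁴·H(m)²/Z ≡ a·H(cm)²/Z
    # and b·H(m) ≡ (b/100)·H(cm).
    return [
        EquationSpec(
            eq_id="deurenberg91",
            citation_label="Deurenberg 1991",
            population="healthy, 7-83 y",
            sex_handling="unisex",
            age_cut_years=16.0,
            coef_sets={
                "young": _cs(  # published for ages <= 15 completed years
                    ("H2_over_Z", 0.406), ("W", 0.360), ("H", 0.0558), ("SEX01", 0.56),
                    intercept=-6.48,
                ),
                "old": _cs(
                    ("H2_over_Z", 0.340), ("H", 0.1534), ("W", 0.273), ("AGE", -0.127),
                    ("SEX01", 4.56),
                    intercept=-12.44,
                ),
            },
        ),
        EquationSpec(
            eq_id="deurenberg90",
            citation_label="Deurenberg 1990",
            population="healthy, 10-25 y",
            sex_handling="unisex",
            coef_sets={
                "all": _cs(
                    ("H2_over_R", 0.438), ("W", 0.308), ("SEX01", 1.6), ("H", 0.0704),
                    intercept=-8.5,
                ),
            },
        ),
        EquationSpec(
            eq_id="houtkooper",
            citation_label="Houtkooper 1992",
            population="healthy children, 10-14 y",
            sex_handling="unisex",
            coef_sets={
                "all": _cs(("H2_over_R", 0.61), ("W", 0.25), intercept=1.31),
            },
        ),
        EquationSpec(
            eq_id="kyle",
            citation_label="Kyle 2001",
            population="healthy adults, 22-94 y",
            sex_handling="unisex",
            coef_sets={
                "all": _cs(
                    ("H2_over_R", 0.518), ("W", 0.231), ("X", 0.130), ("SEX01", 4.229),
                    intercept=-4.104,
                ),
            },
        ),
        EquationSpec(
            eq_id="suprasongsin",
            citation_label="Suprasongsin 1995",
            population="healthy, 8-26 y",
            sex_handling="unisex",
            coef_sets={
                "all": _cs(("H2_over_R", 0.524), ("W", 0.415), intercept=-0.32),
            },
        ),
        EquationSpec(
            eq_id="gray",
            citation_label="Gray 1989",
            population="normal-weight and obese adults, 19-74 y",
            sex_handling="sex_specific",
            coef_sets={
                "male": _cs(
                    ("H2", 0.00139), ("R", -0.0801), ("W", 0.187), intercept=39.830
                ),
                "female": _cs(
                    ("H2", 0.00151), ("R", -0.0344), ("W", 0.140), ("AGE", -0.158),
                    intercept=20.387,
                ),
            },
        ),
        EquationSpec(
            eq_id="lukaski",
            citation_label="Lukaski 1986",
            population="healthy adults, 18-50 y",
            sex_handling="unisex",
            coef_sets={
                "all": _cs(
                    ("H2_over_R", 0.756), ("W", 0.110), ("X", 0.107), intercept=-5.463
                ),
            },
        ),
        EquationSpec(
            eq_id="schaefer",
            citation_label="Schaefer 1994",
            population="children and adolescents, 4-19 y",
            sex_handling="unisex",
            coef_sets={
                "all": _cs(("H2_over_Z", 0.65), ("AGE", 0.68), intercept=0.15),
            },
        ),
        EquationSpec(
            eq_id="sun",
            citation_label="Sun 2003",
            population="multi-ethnic, 12-94 y",
            sex_handling="sex_specific",
            coef_sets={
                "male": _cs(
                    ("H2_over_R", 0.65), ("W", 0.26), ("R", 0.02), intercept=-10.68
                ),
                "female": _cs(
                    ("H2_over_R", 0.69), ("W", 0.17), ("R", 0.02), intercept=-9.53
                ),
            },
        ),
        EquationSpec(
            eq_id="haroun",
            citation_label="Haroun 2009",
            population="obese children and young adults, 5-22 y",
            sex_handling="unisex",
            coef_sets={
                "all": _cs(("H2_over_Z", 1.115), intercept=-2.211),
            },
        ),
        EquationSpec(
            eq_id="horie",
            citation_label="Horie 2008",
            population="severely obese adults (pre-bariatric), 18-62 y",
            sex_handling="unisex",
            form="weight_minus_fm",
            coef_sets={
                # fat-mass expression; FFM = weight - FM
                "all": _cs(
                    ("AGE", 0.13), ("W", 1.0), ("R", 0.09), ("H", -0.80), intercept=23.25
                ),
            },
        ),
        EquationSpec(
            eq_id="lazzer",
            citation_label="Lazzer 2008",
            population="severely obese adolescents, 10-17 y",
            sex_handling="unisex",
            coef_sets={
                "all": _cs(("H2_over_Z", 0.87), intercept=3.1),
            },
        ),
        EquationSpec(
            eq_id="wabitsch",
            citation_label="Wabitsch 1996",
            population="obese children and adolescents, 5-17 y",
            sex_handling="unisex",
            postscale=HYDRATION_FACTOR,
            coef_sets={
                "all": _cs(
                    ("H2_over_R", 0.35), ("AGE", 0.27), ("W", 0.14), intercept=-0.12
                ),
            },
        ),
        EquationSpec(
            eq_id="new_hofsteenge",
            citation_label="obese-adolescent DXA-derived equation",
            population="obese adolescents, 11-18 y",
            sex_handling="unisex",
            coef_sets={
                "all": _cs(("H2_over_Z", 0.527), ("W", 0.306), intercept=-1.862),
            },
        ),
    ]


_REGISTRY: Dict[str, EquationSpec] = {spec.eq_id: spec for spec in _builtin_specs()}

#: ids of the published literature equations (excludes the new equation).
LITERATURE_EQ_IDS: Tuple[str, ...] = tuple(
    eq_id for eq_id in _REGISTRY if eq_id != "new_hofsteenge"
)


def list_equations() -> List[EquationSpec]:
    """All registered equations in stable (registration) order."""
    return list(_REGISTRY.values())


def get_equation(eq_id: str) -> EquationSpec:
    try:
        return _REGISTRY[eq_id]
    except KeyError:
        raise UnknownEquationError(
            f"no equation {eq_id!r}; known: {', '.join(_REGISTRY)}"
        ) from None


def register_equation(spec: EquationSpec, *, overwrite: bool = False) -> None:
    """Add a user equation (e.g. a fitted model) to the registry."""
    if spec.eq_id in _REGISTRY and not overwrite:
        raise EquationError(f"equation {spec.eq_id!r} already registered")
    _REGISTRY[spec.eq_id] = spec


def resolve_predictor(tag: str, subject: Subject) -> float:
    """Value of a predictor-expression tag for one subject."""
    if tag == "H2_over_R":
        return subject.height_cm**2 / subject.resistance_ohm
    if tag == "H2_over_Z":
        return subject.height_cm**2 / subject.impedance_ohm
    if tag == "H2":
        return subject.height_cm**2
    if tag == "H":
        return subject.height_cm
    if tag == "W":
        return subject.weight_kg
    if tag == "AGE":
        return subject.age
    if tag == "SEX01":
        if subject.sex == MALE:
            return 1.0
        if subject.sex == FEMALE:
            return 0.0
        raise EquationError(f"subject {subject.id!r}: SEX01 needs a known sex")
    if tag == "R":
        return subject.resistance_ohm
    if tag == "X":
        return subject.reactance_ohm
    if tag == "Z":
        return subject.impedance_ohm
    raise EquationError(f"unknown predictor tag {tag!r}")


def _check_required(eq: EquationSpec, s: Subject) -> None:
    for name in sorted(eq.required_fields):
        if getattr(s, name, None) is None:
            raise MissingPredictorError(eq.eq_id, s.id, name)


def evaluate_equation(eq: EquationSpec, s: Subject) -> float:
    """FFM in kg predicted by one equation for one subject.

    Deterministic: computed exactly from the registered coefficients.
    Raises :class:`MissingPredictorError` when a required field is absent and
    :class:`EquationError` for a sex-specific equation on a subject of
    unknown sex.  Negative or implausible values are returned, not clipped
    (callers flag them; the validation must see equation failures).
    """
    _check_required(eq, s)
    cs = eq.coefficient_set_for(s)
    values = {tag: resolve_predictor(tag, s) for tag, _ in cs.terms}
    result = cs.linear_value(values)
    if eq.postscale is not None:
        result = result / eq.postscale
    if eq.form == "weight_minus_fm":
        result = s.weight_kg - result
    return result


def _flags_for(ffm_kg: float) -> Tuple[str, ...]:
    flags = []
    if ffm_kg < 0:
        flags.append("negative_prediction")
    if ffm_kg > _IMPLAUSIBLE_FFM_KG:
        flags.append("implausible_high")
    return tuple(flags)


def predict_cohort(
    cohort: Sequence[Subject],
    eq_ids: Optional[Sequence[str]] = None,
) -> PredictionRun:
    """Evaluate equations over a cohort.

    One :class:`Prediction` per (subject, equation) pair where the required
    fields are present; pairs missing a predictor are skipped and recorded
    in the run report with the reason.
    """
    if len(cohort) == 0:
        raise EquationError("empty cohort")
    specs = [get_equation(e) for e in eq_ids] if eq_ids is not None else list_equations()
    run = PredictionRun(predictions=[])
    for spec in specs:
        for s in cohort:
            try:
                ffm = evaluate_equation(spec, s)
            except (MissingPredictorError, EquationError) as exc:
                run.skipped.append((s.id, spec.eq_id, str(exc)))
                continue
            run.predictions.append(
                Prediction(subject_id=s.id, eq_id=spec.eq_id, ffm_pred_kg=ffm,
                           flags=_flags_for(ffm))
            )
    return run


def export_registry() -> str:
    """Registry as JSON: id, citation, coefficients, units, required fields."""
    out = []
    for spec in list_equations():
        out.append({
            "eq_id": spec.eq_id,
            "citation": spec.citation_label,
            "population": spec.population,
            "sex_handling": spec.sex_handling,
            "age_cut_years": spec.age_cut_years,
            "height_unit": spec.height_unit,
            "postscale": spec.postscale,
            "form": spec.form,
            "required_fields": sorted(spec.required_fields),
            "coefficient_sets": {
                key: {"terms": list(cs.terms), "intercept": cs.intercept}
                for key, cs in spec.coef_sets.items()
            },
        })
    return json.dumps(out, indent=2)
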