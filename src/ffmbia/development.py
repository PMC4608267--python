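"""Development of a new FFM prediction equation by forward-selected OLS.

Candidate predictors follow standard BIA practice: body weight, age, height,
BMI, the resistance index RI = H(cm)²/R, the impedance index ZI = H(cm)²/Z,
the raw electrical quantities R, Z, X, sex (male = 1, female = 0), and a
pubertal-stage indicator.  Selection is greedy on explained variance: at
each step the candidate giving the largest R² is added, stopping when the
improvement falls below a threshold (default ΔR² < 0.01).  Coefficient
p-values are reported but never drive selection.

The goodness-of-fit quantities follow the usual regression conventions:
R² = 1 − SSE/SST and SEE = sqrt(SSE/(n − p − 1)) with p slope terms.
Internal accuracy is the percentage of fitted values within ±5 % of the
observed DXA FFM (see :mod:`ffmbia.metrics`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from . import equations as eqmod
from .metrics import compute_metrics
from .subjects import FEMALE, MALE, Subject

__all__ = [
    "CANDIDATE_TAGS",
    "DEFAULT_CANDIDATES",
    "DevelopmentError",
    "CollinearityError",
    "RegressionFit",
    "resolve_candidate",
    "fit_ols",
    "forward_select",
    "subgroup_stability",
    "as_equation_spec",
]

logger = logging.getLogger(__name__)

#: Candidate predictor tags and their meaning.
CANDIDATE_TAGS: Mapping[str, str] = {
    "ZI": "impedance index H(cm)²/Z, cm²/Ω",
    "RI": "resistance index H(cm)²/R, cm²/Ω",
    "W": "weight, kg",
    "AGE": "age, years",
    "H": "height, cm",
    "BMI": "body mass index, kg/m²",
    "BMI_SDS": "BMI standard-deviation score (requires precomputed column)",
    "SEX": "1 if male, 0 if female",
    "R": "resistance, Ω",
    "Z": "impedance, Ω",
    "X": "reactance, Ω",
    "TANNER_PUB": "1 if Tanner stage >= 2 (pubertal), 0 if stage 1",
}

#: The candidate set used for equation development.
DEFAULT_CANDIDATES: Tuple[str, ...] = (
    "W", "AGE", "H", "BMI", "RI", "ZI", "R", "Z", "X", "SEX", "TANNER_PUB",
)

DEFAULT_R2_THRESHOLD = 0.01


class DevelopmentError(ValueError):
    pass


class CollinearityError(DevelopmentError):
    """Design matrix is rank deficient for the requested terms."""


@dataclass(frozen=True)
class RegressionFit:
    """A fitted linear FFM model and its selection history."""

    response: str
    selected_terms: Tuple[str, ...]
    coefficients: Mapping[str, float]  # term -> slope, plus 'intercept'
    pvalues: Mapping[str, float]
    r2: float
    see_kg: float
    n: int
    internal_pct_accurate: float
    selection_trace: Tuple[Tuple[str, float], ...] = ()  # (term added, cumulative R²)


def resolve_candidate(tag: str, s: Subject) -> Optional[float]:
    """Candidate value for a subject, or None when the field is missing."""
    if tag == "ZI":
        return s.zi
    if tag == "RI":
        return s.ri
    if tag == "W":
        return s.weight_kg
    if tag == "AGE":
        return s.age
    if tag == "H":
        return s.height_cm
    if tag == "BMI":
        return s.bmi
    if tag == "BMI_SDS":
        return s.bmi_sds
    if tag == "SEX":
        if s.sex == MALE:
            return 1.0
        if s.sex == FEMALE:
            return 0.0
        return None
    if tag == "R":
        return s.resistance_ohm
    if tag == "X":
        return s.reactance_ohm
    if tag == "Z":
        return s.impedance_ohm
    if tag == "TANNER_PUB":
        if s.tanner_stage is None:
            return None
        return 1.0 if s.tanner_stage >= 2 else 0.0
    raise DevelopmentError(f"unknown candidate tag {tag!r}")


def _design(
    cohort: Sequence[Subject], terms: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray, List[Subject]]:
    """Response vector and design matrix, dropping rows with missing values."""
    kept: List[Subject] = []
    rows: List[List[float]] = []
    y: List[float] = []
    n_dropped = 0
    for s in cohort:
        if s.ffm_dxa_kg is None:
            n_dropped += 1
            continue
        vals = [resolve_candidate(t, s) for t in terms]
        if any(v is None for v in vals):
            n_dropped += 1
            continue
        kept.append(s)
        rows.append([float(v) for v in vals])
        y.append(s.ffm_dxa_kg)
    if n_dropped:
        logger.info("dropped %d subjects with missing response/predictors", n_dropped)
    return np.asarray(y, float), np.asarray(rows, float).reshape(len(kept), len(terms)), kept


def fit_ols(cohort: Sequence[Subject], terms: Sequence[str]) -> RegressionFit:
    """Ordinary least squares of DXA FFM on the given candidate terms.

    Raises :class:`CollinearityError` when the design matrix is rank
    deficient (naming the terms) and :class:`DevelopmentError` when there
    are too few complete rows.
    """
    terms = tuple(terms)
    y, X, kept = _design(cohort, terms)
    n, p = X.shape
    if n <= p + 1:
        raise DevelopmentError(
            f"need n > p + 1 complete rows (got n={n} for {p} terms)"
        )
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(
            f"rank-deficient design for terms {list(terms)}: "
            "some predictors are collinear"
        )
    res = sm.OLS(y, design).fit()

    fitted = np.asarray(res.fittedvalues)
    sse = float(np.sum((y - fitted) ** 2))
    see = float(np.sqrt(sse / (n - p - 1)))
    acc = compute_metrics(fitted, y).pct_accurate

    names = ["intercept", *terms]
    return RegressionFit(
        response="ffm_dxa_kg",
        selected_terms=terms,
        coefficients={name: float(c) for name, c in zip(names, res.params)},
        pvalues={name: float(v) for name, v in zip(names, res.pvalues)},
        r2=float(res.rsquared),
        see_kg=see,
        n=n,
        internal_pct_accurate=acc,
    )


def forward_select(
    cohort: Sequence[Subject],
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> RegressionFit:
    """Greedy forward selection on explained variance.

    At each step the remaining candidate with the highest resulting R² is
    added; selection stops when the improvement is below ``r2_threshold``.
    When no candidate improves on the intercept-only model an intercept-only
    fit is returned with a warning.
    """
    remaining = [c for c in candidates if c in CANDIDATE_TAGS]
    unknown = set(candidates) - set(remaining)
    if unknown:
        raise DevelopmentError(f"unknown candidate tags: {sorted(unknown)}")

    selected: List[str] = []
    trace: List[Tuple[str, float]] = []
    current_r2 = 0.0
    best_fit: Optional[RegressionFit] = None

    while remaining:
        step: List[Tuple[float, str, RegressionFit]] = []
        for cand in remaining:
            try:
                fit = fit_ols(cohort, [*selected, cand])
            except (CollinearityError, DevelopmentError):
                continue
            step.append((fit.r2, cand, fit))
        if not step:
            break
        step.sort(key=lambda t: -t[0])
        r2, cand, fit = step[0]
        if r2 - current_r2 < r2_threshold:
            logger.info(
                "stopping: best remaining candidate %r improves R² by only %.4f",
                cand, r2 - current_r2,
            )
            break
        selected.append(cand)
        remaining.remove(cand)
        trace.append((cand, r2))
        current_r2 = r2
        best_fit = fit

    if best_fit is None:
        warnings.warn("no candidate improved on the intercept-only model", stacklevel=2)
        y = np.asarray([s.ffm_dxa_kg for s in cohort if s.ffm_dxa_kg is not None], float)
        if y.size < 2:
            raise DevelopmentError("cannot fit intercept-only model on < 2 subjects")
        mean = float(y.mean())
        sse = float(np.sum((y - mean) ** 2))
        return RegressionFit(
            response="ffm_dxa_kg",
            selected_terms=(),
            coefficients={"intercept": mean},
            pvalues={"intercept": float("nan")},
            r2=0.0,
            see_kg=float(np.sqrt(sse / (y.size - 1))),
            n=int(y.size),
            internal_pct_accurate=compute_metrics(np.full_like(y, mean), y).pct_accurate,
            selection_trace=(),
        )

    return RegressionFit(
        response=best_fit.response,
        selected_terms=best_fit.selected_terms,
        coefficients=best_fit.coefficients,
        pvalues=best_fit.pvalues,
        r2=best_fit.r2,
        see_kg=best_fit.see_kg,
        n=best_fit.n,
        internal_pct_accurate=best_fit.internal_pct_accurate,
        selection_trace=tuple(trace),
    )


def subgroup_stability(
    fit: RegressionFit,
    cohort: Sequence[Subject],
    grouping: str,
) -> Dict[str, float]:
    """Refit the selected term set within subgroups; report per-group R².

    ``grouping`` is ``'sex'`` (girls vs boys) or ``'tanner_early_late'``
    (Tanner stage 1 vs ≥2, the pre-pubertal/pubertal split).  Groups with
    too few subjects for the model (n ≤ p + 2) are skipped with a warning.
    """
    if grouping == "sex":
        groups = {
            "girls": [s for s in cohort if s.sex == FEMALE],
            "boys": [s for s in cohort if s.sex == MALE],
        }
    elif grouping == "tanner_early_late":
        groups = {
            "early": [s for s in cohort if s.tanner_stage == 1],
            "late": [s for s in cohort if s.tanner_stage is not None and s.tanner_stage >= 2],
        }
    else:
        raise DevelopmentError(f"unknown grouping {grouping!r}")

    p = len(fit.selected_terms)
    out: Dict[str, float] = {}
    for name, members in groups.items():
        if len(members) <= p + 2:
            warnings.warn(
                f"subgroup {name!r} has n={len(members)} <= p+2={p + 2}; skipped",
                stacklevel=2,
            )
            continue
        try:
            out[name] = fit_ols(members, fit.selected_terms).r2
        except DevelopmentError as exc:
            warnings.warn(f"subgroup {name!r} skipped: {exc}", stacklevel=2)
    return out


# Candidate tags expressible as registry predictor tags (for round-tripping
# a fit into the equation registry).
_TAG_TO_EQ = {
    "ZI": "H2_over_Z", "RI": "H2_over_R", "W": "W", "AGE": "AGE", "H": "H",
    "SEX": "SEX01", "R": "R", "Z": "Z", "X": "X",
}


def as_equation_spec(fit: RegressionFit, eq_id: str, citation_label: str = "user fit") -> eqmod.EquationSpec:
    """Convert a fitted model into a registrable equation spec."""
    terms = []
    for t in fit.selected_terms:
        if t not in _TAG_TO_EQ:
            raise DevelopmentError(
                f"term {t!r} has no equation-registry equivalent; cannot register"
            )
        terms.append((_TAG_TO_EQ[t], fit.coefficients[t]))
    cs = eqmod.CoefficientSet(terms=tuple(terms), intercept=fit.coefficients["intercept"])
    return eqmod.EquationSpec(
        eq_id=eq_id,
        citation_label=citation_label,
        population="user-fitted",
        sex_handling="unisex",
        coef_sets={"all": cs},
    )
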