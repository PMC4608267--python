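"""Accuracy statistics for FFM prediction equations validated against DXA.

For each subject the relative error is ``e_i = 100·(pred_i − dxa_i)/dxa_i``
(percent).  A prediction is *accurate* when |e_i| ≤ cutoff (default 5 %,
inclusive; 2.5 % is the stricter clinical alternative), an *under*estimate
when e_i < −cutoff and an *over*estimate when e_i > +cutoff — every subject
falls in exactly one class.  *Bias* is the mean of the per-subject percentage
errors (group-level accuracy); RMSE is ``sqrt(mean((pred−dxa)²))`` in kg with
population denominator n.

The best-equation rule is a lexicographic comparison: highest percentage of
accurate predictions, then smallest girls-vs-boys accuracy gap (an equation
should fit both sexes), then smallest absolute bias, then smallest RMSE —
with configurable tie windows at each stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import equations as eqmod
from .subjects import FEMALE, MALE, Subject

__all__ = [
    "MetricsError",
    "ValidationMetrics",
    "RankedReport",
    "ChangeAgreement",
    "compute_metrics",
    "validate_cohort",
    "rank_equations",
    "evaluate_change",
]

DEFAULT_CUTOFF_PCT = 5.0


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ValidationMetrics:
    """One Table-row accuracy summary for one equation on one (sub)cohort."""

    eq_id: str
    n_evaluated: int
    mean_pred_kg: float
    sd_pred_kg: float
    pct_accurate: float
    pct_under: float
    pct_over: float
    bias_pct: float
    max_neg_err_pct: float
    max_pos_err_pct: float
    rmse_kg: float

    def as_dict(self) -> dict:
        return {
            "eq_id": self.eq_id,
            "n_evaluated": self.n_evaluated,
            "mean_pred_kg": self.mean_pred_kg,
            "sd_pred_kg": self.sd_pred_kg,
            "pct_accurate": self.pct_accurate,
            "pct_under": self.pct_under,
            "pct_over": self.pct_over,
            "bias_pct": self.bias_pct,
            "max_neg_err_pct": self.max_neg_err_pct,
            "max_pos_err_pct": self.max_pos_err_pct,
            "rmse_kg": self.rmse_kg,
        }


@dataclass
class RankedReport:
    """Overall and by-sex metric tables plus the best-equation decision."""

    overall: List[ValidationMetrics]
    by_sex: Dict[str, List[ValidationMetrics]]
    best_eq_id: Optional[str] = None
    ranking_trace: List[str] = field(default_factory=list)
    excluded: List[Tuple[str, str]] = field(default_factory=list)  # (eq_id, reason)
    cutoff_pct: float = DEFAULT_CUTOFF_PCT
    n_subjects: int = 0

    def metrics_for(self, eq_id: str, sex: Optional[str] = None) -> Optional[ValidationMetrics]:
        table = self.overall if sex is None else self.by_sex.get(sex, [])
        for m in table:
            if m.eq_id == eq_id:
                return m
        return None


@dataclass(frozen=True)
class ChangeAgreement:
    """Agreement between equation-tracked and DXA-measured FFM change."""

    eq_id: str
    n_pairs: int
    mean_change_dxa_kg: float
    sd_change_dxa_kg: float
    mean_change_pred_kg: float
    mean_diff_kg: float  # predicted change − DXA change
    sd_diff_kg: float
    p_value: float
    flags: Tuple[str, ...] = ()


def compute_metrics(
    preds: Sequence[float],
    dxa: Sequence[float],
    cutoff_pct: float = DEFAULT_CUTOFF_PCT,
    eq_id: str = "",
) -> ValidationMetrics:
    """Accuracy summary of predicted vs DXA-measured FFM.

    Boundary errors of exactly ±cutoff count as accurate.  Raises on length
    mismatch or a non-positive DXA value (the subject index is named).
    """
    preds = np.asarray(preds, dtype=float)
    dxa = np.asarray(dxa, dtype=float)
    if preds.shape != dxa.shape or preds.ndim != 1:
        raise MetricsError(
            f"prediction/DXA length mismatch: {preds.shape} vs {dxa.shape}"
        )
    if preds.size == 0:
        raise MetricsError("no subjects to evaluate")
    bad = np.nonzero(dxa <= 0)[0]
    if bad.size:
        raise MetricsError(f"non-positive DXA FFM at position(s) {bad.tolist()}")
    if cutoff_pct <= 0:
        raise MetricsError(f"cutoff_pct must be > 0, got {cutoff_pct}")

    err_pct = 100.0 * (preds - dxa) / dxa
    n = preds.size
    accurate = np.abs(err_pct) <= cutoff_pct
    under = err_pct < -cutoff_pct
    over = err_pct > cutoff_pct
    return ValidationMetrics(
        eq_id=eq_id,
        n_evaluated=int(n),
        mean_pred_kg=float(preds.mean()),
        sd_pred_kg=float(preds.std(ddof=1)) if n > 1 else 0.0,
        pct_accurate=float(100.0 * accurate.sum() / n),
        pct_under=float(100.0 * under.sum() / n),
        pct_over=float(100.0 * over.sum() / n),
        bias_pct=float(err_pct.mean()),
        max_neg_err_pct=float(err_pct.min()),
        max_pos_err_pct=float(err_pct.max()),
        rmse_kg=float(np.sqrt(np.mean((preds - dxa) ** 2))),
    )


def _metrics_table(
    cohort: Sequence[Subject],
    eq_ids: Sequence[str],
    cutoff_pct: float,
    excluded: List[Tuple[str, str]],
) -> List[ValidationMetrics]:
    run = eqmod.predict_cohort(cohort, eq_ids)
    dxa_by_id = {s.id: s.ffm_dxa_kg for s in cohort}
    table = []
    for eq_id in eq_ids:
        pairs = [
            (p.ffm_pred_kg, dxa_by_id[p.subject_id])
            for p in run.for_equation(eq_id)
            if dxa_by_id.get(p.subject_id) is not None
        ]
        if not pairs:
            excluded.append((eq_id, "no evaluable subject (missing predictor or DXA)"))
            continue
        preds, dxa = zip(*pairs)
        table.append(compute_metrics(preds, dxa, cutoff_pct, eq_id=eq_id))
    return table


def validate_cohort(
    cohort: Sequence[Subject],
    eq_ids: Optional[Sequence[str]] = None,
    cutoff_pct: float = DEFAULT_CUTOFF_PCT,
) -> RankedReport:
    """Validate equations against DXA over a cohort, overall and by sex.

    The overall table is sorted by percentage of accurate predictions
    (descending), ties broken by lower RMSE; the sort is stable.  Equations
    evaluable on no subject are excluded from the tables and listed in the
    report.  The best equation is chosen by :func:`rank_equations`.
    """
    cohort = list(cohort)
    if not any(s.ffm_dxa_kg is not None for s in cohort):
        raise MetricsError("no subject has a DXA FFM value")
    if eq_ids is None:
        eq_ids = [spec.eq_id for spec in eqmod.list_equations()]

    excluded: List[Tuple[str, str]] = []
    overall = _metrics_table(cohort, eq_ids, cutoff_pct, excluded)
    overall.sort(key=lambda m: (-m.pct_accurate, m.rmse_kg))

    by_sex: Dict[str, List[ValidationMetrics]] = {}
    for sex in (FEMALE, MALE):
        sub = [s for s in cohort if s.sex == sex]
        if sub and any(s.ffm_dxa_kg is not None for s in sub):
            kept = [m.eq_id for m in overall]
            by_sex[sex] = _metrics_table(sub, kept, cutoff_pct, [])

    report = RankedReport(
        overall=overall,
        by_sex=by_sex,
        excluded=excluded,
        cutoff_pct=cutoff_pct,
        n_subjects=len(cohort),
    )
    report.best_eq_id, report.ranking_trace = rank_equations(report)
    return report


def rank_equations(
    report: RankedReport,
    tie_accuracy_pts: float = 2.0,
    tie_bias_pct: float = 0.5,
) -> Tuple[str, List[str]]:
    """Best-equation decision: accuracy → sex gap → |bias| → RMSE.

    At each criterion, candidates within the tie window of the best value
    survive to the next; the final survivor (first in stable table order on
    a residual tie) wins.  Returns (best_eq_id, human-readable trace).
    """
    if not report.overall:
        raise MetricsError("empty report: nothing to rank")
    candidates = list(report.overall)
    trace: List[str] = []

    if len(candidates) == 1:
        trace.append(f"single equation {candidates[0].eq_id!r}: selected by default")
        return candidates[0].eq_id, trace

    # 1. highest % accurate
    best_acc = max(m.pct_accurate for m in candidates)
    survivors = [m for m in candidates if best_acc - m.pct_accurate <= tie_accuracy_pts]
    trace.append(
        f"criterion 1 (pct_accurate, best {best_acc:.1f}, tie window "
        f"{tie_accuracy_pts} pts): {[m.eq_id for m in survivors]}"
    )

    # 2. smallest girls-vs-boys accuracy gap
    if len(survivors) > 1 and FEMALE in report.by_sex and MALE in report.by_sex:
        def sex_gap(m: ValidationMetrics) -> float:
            g = report.metrics_for(m.eq_id, FEMALE)
            b = report.metrics_for(m.eq_id, MALE)
            if g is None or b is None:
                return math.inf
            return abs(g.pct_accurate - b.pct_accurate)

        gaps = {m.eq_id: sex_gap(m) for m in survivors}
        best_gap = min(gaps.values())
        survivors = [m for m in survivors if gaps[m.eq_id] - best_gap <= tie_accuracy_pts]
        trace.append(
            f"criterion 2 (girls-boys accuracy gap, best {best_gap:.1f}, tie window "
            f"{tie_accuracy_pts} pts): {[m.eq_id for m in survivors]}"
        )
    elif len(survivors) > 1:
        trace.append("criterion 2 (sex gap): skipped, cohort has a single sex")

    # 3. smallest |bias|
    if len(survivors) > 1:
        best_bias = min(abs(m.bias_pct) for m in survivors)
        survivors = [m for m in survivors if abs(m.bias_pct) - best_bias <= tie_bias_pct]
        trace.append(
            f"criterion 3 (|bias|, best {best_bias:.2f}%, tie window {tie_bias_pct}): "
            f"{[m.eq_id for m in survivors]}"
        )

    # 4. smallest RMSE (strict; stable order breaks exact ties)
    if len(survivors) > 1:
        best_rmse = min(m.rmse_kg for m in survivors)
        survivors = [m for m in survivors if m.rmse_kg == best_rmse]
        trace.append(f"criterion 4 (RMSE, best {best_rmse:.2f} kg): {[m.eq_id for m in survivors]}")

    best = survivors[0]
    trace.append(f"selected {best.eq_id!r}")
    return best.eq_id, trace


def evaluate_change(
    baseline: Sequence[Subject],
    followup: Sequence[Subject],
    eq_id: str,
) -> ChangeAgreement:
    """Does an equation track longitudinal FFM change as measured by DXA?

    Subjects are matched by id; per subject the DXA change and the
    equation-predicted change between visits are differenced, and a
    two-sided paired t-test is run on (predicted change − DXA change).
    """
    spec = eqmod.get_equation(eq_id)
    base_by_id = {s.id: s for s in baseline}
    pairs = [(base_by_id[s.id], s) for s in followup if s.id in base_by_id]
    pairs = [
        (b, f) for b, f in pairs
        if b.ffm_dxa_kg is not None and f.ffm_dxa_kg is not None
    ]
    if not pairs:
        raise MetricsError("no matched subject ids with DXA at both visits")
    if len(pairs) < 2:
        raise MetricsError("need at least 2 matched pairs for a paired t-test")

    dxa_change = np.array([f.ffm_dxa_kg - b.ffm_dxa_kg for b, f in pairs])
    pred_change = np.array([
        eqmod.evaluate_equation(spec, f) - eqmod.evaluate_equation(spec, b)
        for b, f in pairs
    ])
    diffs = pred_change - dxa_change

    flags: List[str] = []
    if np.allclose(diffs.std(ddof=1), 0.0):
        # degenerate: constant difference, t undefined
        flags.append("zero_variance_differences")
        p = 1.0 if np.allclose(diffs, 0.0) else 0.0
    else:
        p = float(stats.ttest_rel(pred_change, dxa_change).pvalue)

    return ChangeAgreement(
        eq_id=eq_id,
        n_pairs=len(pairs),
        mean_change_dxa_kg=float(dxa_change.mean()),
        sd_change_dxa_kg=float(dxa_change.std(ddof=1)),
        mean_change_pred_kg=float(pred_change.mean()),
        mean_diff_kg=float(diffs.mean()),
        sd_diff_kg=float(diffs.std(ddof=1)),
        p_value=p,
        flags=tuple(flags),
    )
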