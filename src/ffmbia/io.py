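"""Cohort CSV reading/writing, report serialization, and pipeline orchestration.

Cohort CSV schema (UTF-8, comma separator, dot decimal; header order
insensitive; missing values empty)::

    id,sex,age,height_cm,weight_kg,resistance_ohm,reactance_ohm,impedance_ohm,tanner,ffm_dxa_kg,bmi_sds

Rows violating physical invariants are rejected with row-numbered,
machine-readable diagnostics; impedance is back-filled from R and Xc when
blank.  Rendered tables round percentages and kg to one decimal; JSON keeps
full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .metrics import RankedReport, ValidationMetrics
from .subjects import FEMALE, MALE, STUDY_AGE_RANGE, Subject, SubjectError

__all__ = [
    "COHORT_COLUMNS",
    "CohortIOError",
    "RowIssue",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "report_to_dict",
    "write_report_json",
    "write_report_tsv",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = (
    "id", "sex", "age", "height_cm", "weight_kg",
    "resistance_ohm", "reactance_ohm", "impedance_ohm",
    "tanner", "ffm_dxa_kg", "bmi_sds",
)

_MANDATORY_COLUMNS = (
    "id", "sex", "age", "height_cm", "weight_kg",
    "resistance_ohm", "reactance_ohm",
)


class CohortIOError(ValueError):
    pass


@dataclass(frozen=True)
class RowIssue:
    """A machine-readable diagnostic for one rejected or suspect row."""

    row: int  # 1-based data-row number
    code: str
    message: str


@dataclass
class RunConfig:
    """Settings for an end-to-end validation run."""

    cutoff_pct: float = 5.0
    eq_ids: Optional[Sequence[str]] = None
    by_sex: bool = True
    out_json: Optional[Union[str, Path]] = None
    out_tsv: Optional[Union[str, Path]] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.cutoff_pct <= 0:
            raise CohortIOError(f"cutoff_pct must be > 0, got {self.cutoff_pct}")


def _parse_float(raw, row: int, col: str, issues: List[RowIssue]) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return None
    try:
        return float(raw)
    except ValueError:
        issues.append(RowIssue(row, "bad_number", f"row {row}: {col}={raw!r} is not a number"))
        raise


def read_cohort(
    path: Union[str, Path],
    *,
    study_population: bool = False,
) -> Tuple[List[Subject], List[RowIssue]]:
    """Read and validate a cohort CSV.

    Returns the typed subjects plus an issue list; rows violating invariants
    are rejected (n_in = n_used + n_rejected, all rejections coded).  With
    ``study_population=True`` the 11–18 y inclusion window is enforced;
    otherwise out-of-range ages are kept with an ``age_out_of_range`` note.
    """
    path = Path(path)
    if not path.exists():
        raise CohortIOError(f"no such cohort file: {path}")
    df = pd.read_csv(path, dtype=str)
    if df.empty and df.columns.size == 0:
        raise CohortIOError(f"empty cohort file: {path}")
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortIOError(f"{path}: missing mandatory column(s): {missing}")

    subjects: List[Subject] = []
    issues: List[RowIssue] = []
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 1
        try:
            sex_raw = (rec.get("sex") or "").strip().upper()
            sex = sex_raw if sex_raw in (FEMALE, MALE) else None
            if sex_raw and sex is None:
                issues.append(RowIssue(row, "bad_sex", f"row {row}: sex={rec['sex']!r} not F/M"))

            age = _parse_float(rec.get("age"), row, "age", issues)
            height = _parse_float(rec.get("height_cm"), row, "height_cm", issues)
            weight = _parse_float(rec.get("weight_kg"), row, "weight_kg", issues)
            r = _parse_float(rec.get("resistance_ohm"), row, "resistance_ohm", issues)
            x = _parse_float(rec.get("reactance_ohm"), row, "reactance_ohm", issues)
            z = _parse_float(rec.get("impedance_ohm"), row, "impedance_ohm", issues)
            dxa = _parse_float(rec.get("ffm_dxa_kg"), row, "ffm_dxa_kg", issues)
            sds = _parse_float(rec.get("bmi_sds"), row, "bmi_sds", issues)
            tanner_raw = _parse_float(rec.get("tanner"), row, "tanner", issues)
            tanner = int(tanner_raw) if tanner_raw is not None else None

            for name, v in (("age", age), ("height_cm", height), ("weight_kg", weight),
                            ("resistance_ohm", r)):
                if v is None:
                    raise SubjectError(f"row {row}: missing required value {name}")
            if x is None and z is None:
                raise SubjectError(
                    f"row {row}: need reactance_ohm or impedance_ohm"
                )

            s = Subject(
                id=str(rec.get("id") or f"row{row}"),
                sex=sex, age=age, height_cm=height, weight_kg=weight,
                resistance_ohm=r, reactance_ohm=x, impedance_ohm=z,
                tanner_stage=tanner, ffm_dxa_kg=dxa, bmi_sds=sds,
            )
        except (SubjectError, ValueError) as exc:
            issues.append(RowIssue(row, "invariant_violation", f"row {row}: {exc}"))
            continue

        lo, hi = STUDY_AGE_RANGE
        if not (lo <= s.age <= hi):
            issue = RowIssue(
                row, "age_out_of_range",
                f"row {row}: age {s.age} y outside study range [{lo}, {hi}]",
            )
            issues.append(issue)
            if study_population:
                continue
        subjects.append(s)

    logger.info("read %d subjects from %s (%d issue(s))", len(subjects), path, len(issues))
    return subjects, issues


def cohort_to_frame(cohort: Sequence[Subject]) -> pd.DataFrame:
    rows = []
    for s in cohort:
        rows.append({
            "id": s.id,
            "sex": s.sex if s.sex is not None else "",
            "age": s.age,
            "height_cm": s.height_cm,
            "weight_kg": s.weight_kg,
            "resistance_ohm": s.resistance_ohm,
            "reactance_ohm": s.reactance_ohm,
            "impedance_ohm": s.impedance_ohm,
            "tanner": s.tanner_stage,
            "ffm_dxa_kg": s.ffm_dxa_kg,
            "bmi_sds": s.bmi_sds,
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(cohort: Sequence[Subject], path: Union[str, Path]) -> None:
    """Write a cohort CSV (round-trips through :func:`read_cohort`)."""
    cohort_to_frame(cohort).to_csv(path, index=False, float_format="%.10g")


def _metrics_rows(table: Sequence[ValidationMetrics]) -> List[dict]:
    return [m.as_dict() for m in table]


def report_to_dict(report: RankedReport) -> dict:
    return {
        "cutoff_pct": report.cutoff_pct,
        "n_subjects": report.n_subjects,
        "best_eq_id": report.best_eq_id,
        "overall": _metrics_rows(report.overall),
        "by_sex": {sex: _metrics_rows(tab) for sex, tab in report.by_sex.items()},
        "excluded": [{"eq_id": e, "reason": r} for e, r in report.excluded],
        "ranking_trace": list(report.ranking_trace),
    }


def write_report_json(report: RankedReport, path: Union[str, Path]) -> None:
    """Full-precision JSON report; byte-identical on deterministic reruns."""
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n")


_TSV_COLUMNS = (
    ("eq_id", "{}"), ("n_evaluated", "{}"), ("mean_pred_kg", "{:.1f}"),
    ("sd_pred_kg", "{:.1f}"), ("pct_accurate", "{:.1f}"), ("pct_under", "{:.1f}"),
    ("pct_over", "{:.1f}"), ("bias_pct", "{:.1f}"), ("max_neg_err_pct", "{:.1f}"),
    ("max_pos_err_pct", "{:.1f}"), ("rmse_kg", "{:.1f}"),
)


def write_report_tsv(report: RankedReport, path: Union[str, Path]) -> None:
    """Rendered table (1-decimal) mirroring the published column order."""
    lines = ["\t".join(name for name, _ in _TSV_COLUMNS)]
    for m in report.overall:
        d = m.as_dict()
        lines.append("\t".join(fmt.format(d[name]) for name, fmt in _TSV_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(
    config: RunConfig,
    cohort: Sequence[Subject],
) -> RankedReport:
    """predict → metrics → rank over a cohort, writing any configured reports."""
    from .metrics import validate_cohort  # local import avoids cycle at module load

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report = validate_cohort(cohort, eq_ids=config.eq_ids, cutoff_pct=config.cutoff_pct)
    for eq_id, reason in report.excluded:
        logger.info("equation %s excluded: %s", eq_id, reason)
    if config.out_json:
        write_report_json(report, config.out_json)
    if config.out_tsv:
        write_report_tsv(report, config.out_tsv)
    return report
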