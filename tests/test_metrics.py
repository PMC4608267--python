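"""Accuracy metrics, ranking rule and change agreement: oracles and properties."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ffmbia.metrics import (
    ChangeAgreement,
    MetricsError,
    RankedReport,
    ValidationMetrics,
    compute_metrics,
    evaluate_change,
    rank_equations,
    validate_cohort,
)
from ffmbia.subjects import Subject


def make_metrics(eq_id, acc, gap_girls, gap_boys, bias, rmse):
    """Fixture metrics row (plus by-sex rows) with the fields ranking reads."""
    def row(a):
        return ValidationMetrics(
            eq_id=eq_id, n_evaluated=100, mean_pred_kg=56.0, sd_pred_kg=9.0,
            pct_accurate=a, pct_under=(100 - a) / 2, pct_over=(100 - a) / 2,
            bias_pct=bias, max_neg_err_pct=-10.0, max_pos_err_pct=10.0, rmse_kg=rmse,
        )
    return row(acc), row(gap_girls), row(gap_boys)


def report_from(rows):
    overall, girls, boys = [], [], []
    for spec in rows:
        o, g, b = make_metrics(*spec)
        overall.append(o)
        girls.append(g)
        boys.append(b)
    return RankedReport(overall=overall, by_sex={"F": girls, "M": boys})


class TestComputeMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics([50.0, 60.0], [50.0, 60.0])
        assert m.pct_accurate == 100.0
        assert m.bias_pct == 0.0
        assert m.rmse_kg == 0.0

    def test_hand_worked_four_subjects(self):
        """errors 0, +4, −6, +12 % → 50/25/25, bias 2.5 %, rmse 3.5 kg."""
        m = compute_metrics([50.0, 52.0, 47.0, 56.0], [50.0, 50.0, 50.0, 50.0])
        assert m.pct_accurate == pytest.approx(50.0)
        assert m.pct_under == pytest.approx(25.0)
        assert m.pct_over == pytest.approx(25.0)
        assert m.bias_pct == pytest.approx(2.5)
        assert m.max_neg_err_pct == pytest.approx(-6.0)
        assert m.max_pos_err_pct == pytest.approx(12.0)
        assert m.rmse_kg == pytest.approx(3.5)

    def test_constant_offset_rmse(self):
        m = compute_metrics([42.0, 82.0], [40.0, 80.0])
        assert m.rmse_kg == pytest.approx(2.0)

    def test_boundary_error_counts_as_accurate(self):
        m = compute_metrics([52.5], [50.0], cutoff_pct=5.0)  # exactly +5%
        assert m.pct_accurate == 100.0

    def test_errors(self):
        with pytest.raises(MetricsError, match="mismatch"):
            compute_metrics([1.0], [1.0, 2.0])
        with pytest.raises(MetricsError, match="non-positive"):
            compute_metrics([50.0], [0.0])

    @given(
        data=st.lists(
            st.tuples(
                st.floats(min_value=20, max_value=100),   # dxa
                st.floats(min_value=-0.3, max_value=0.3),  # relative error
            ),
            min_size=1, max_size=6,
        ),
        cutoff=st.floats(min_value=1.0, max_value=10.0),
    )
    def test_brute_force_oracle_small_cohorts(self, data, cutoff):
        """Vectorised metrics equal an independent per-element recomputation."""
        dxa = [d for d, _ in data]
        preds = [d * (1 + e) for d, e in data]
        m = compute_metrics(preds, dxa, cutoff)

        errs = [100.0 * (p - d) / d for p, d in zip(preds, dxa)]
        n = len(errs)
        n_acc = sum(1 for e in errs if -cutoff <= e <= cutoff)
        n_under = sum(1 for e in errs if e < -cutoff)
        n_over = sum(1 for e in errs if e > cutoff)
        assert n_acc + n_under + n_over == n  # partition
        assert m.pct_accurate == pytest.approx(100.0 * n_acc / n)
        assert m.pct_under == pytest.approx(100.0 * n_under / n)
        assert m.pct_over == pytest.approx(100.0 * n_over / n)
        assert m.bias_pct == pytest.approx(sum(errs) / n)
        assert m.max_neg_err_pct == pytest.approx(min(errs))
        assert m.max_pos_err_pct == pytest.approx(max(errs))
        assert m.rmse_kg == pytest.approx(
            math.sqrt(sum((p - d) ** 2 for p, d in zip(preds, dxa)) / n)
        )
        # RMSE dominates |mean kg error|
        assert m.rmse_kg >= abs(sum(p - d for p, d in zip(preds, dxa)) / n) - 1e-12

    @given(
        seed=st.integers(min_value=0, max_value=50),
        c1=st.floats(min_value=1.0, max_value=4.9),
        c2=st.floats(min_value=5.0, max_value=12.0),
    )
    def test_cutoff_monotonicity(self, seed, c1, c2):
        rng = np.random.default_rng(seed)
        dxa = rng.uniform(40, 80, size=20)
        preds = dxa * (1 + rng.normal(0, 0.06, size=20))
        assert (
            compute_metrics(preds, dxa, c1).pct_accurate
            <= compute_metrics(preds, dxa, c2).pct_accurate
        )


class TestValidateCohort:
    @staticmethod
    def _cohort(n=12):
        rng = np.random.default_rng(7)
        out = []
        for i in range(n):
            h = rng.uniform(155, 180)
            r = rng.uniform(420, 600)
            x = rng.uniform(50, 75)
            s = Subject(id=f"c{i}", sex="F" if i % 2 else "M", age=rng.uniform(11, 18),
                        height_cm=h, weight_kg=rng.uniform(70, 120),
                        resistance_ohm=r, reactance_ohm=x)
            z = s.impedance_ohm
            # DXA set so that the Lazzer equation is exact for every subject
            s.ffm_dxa_kg = 0.87 * h**2 / z + 3.1
            out.append(s)
        return out

    def test_exact_equation_ranks_first(self):
        report = validate_cohort(self._cohort())
        assert report.overall[0].eq_id == "lazzer"
        assert report.overall[0].pct_accurate == 100.0
        assert report.best_eq_id == "lazzer"

    def test_sorted_by_accuracy_then_rmse(self):
        report = validate_cohort(self._cohort())
        keys = [(-m.pct_accurate, m.rmse_kg) for m in report.overall]
        assert keys == sorted(keys)

    def test_sex_stratified_counts_reweight_to_overall(self):
        report = validate_cohort(self._cohort())
        for m in report.overall:
            g = report.metrics_for(m.eq_id, "F")
            b = report.metrics_for(m.eq_id, "M")
            recombined = (
                g.n_evaluated * g.pct_accurate + b.n_evaluated * b.pct_accurate
            ) / (g.n_evaluated + b.n_evaluated)
            assert recombined == pytest.approx(m.pct_accurate, abs=1e-9)

    def test_unevaluable_equation_listed_not_tabulated(self):
        cohort = [
            s.with_(reactance_ohm=None, impedance_ohm=s.impedance_ohm)
            for s in self._cohort(6)
        ]
        report = validate_cohort(cohort, eq_ids=["lazzer", "kyle"])
        assert [m.eq_id for m in report.overall] == ["lazzer"]
        assert report.excluded and report.excluded[0][0] == "kyle"

    def test_no_dxa_anywhere_raises(self):
        cohort = [s.with_(ffm_dxa_kg=None) for s in self._cohort(4)]
        with pytest.raises(MetricsError, match="DXA"):
            validate_cohort(cohort)

    def test_synthetic_default_cohort_best_is_generative_equation(self, default_cohort):
        """The generator shares the new equation's structure, so it must win."""
        report = validate_cohort(default_cohort)
        top = report.overall[0]
        assert top.eq_id == "new_hofsteenge"
        assert top.pct_accurate == max(m.pct_accurate for m in report.overall)


class TestRankEquations:
    def test_sex_gap_breaks_accuracy_tie(self):
        report = report_from([
            ("wide_gap", 60.0, 70.0, 50.0, 1.0, 3.0),   # gap 20
            ("narrow_gap", 60.0, 60.0, 59.0, 1.0, 3.0),  # gap 1
        ])
        best, trace = rank_equations(report)
        assert best == "narrow_gap"
        assert any("criterion 2" in line for line in trace)

    def test_singleton(self):
        report = report_from([("only", 50.0, 50.0, 50.0, 0.0, 3.0)])
        best, trace = rank_equations(report)
        assert best == "only"
        assert len(trace) == 1

    def test_clear_accuracy_winner(self):
        """Accuracies 68/63/61, all separated beyond the tie window."""
        report = report_from([
            ("a68", 68.0, 68.0, 68.0, 2.2, 2.8),
            ("b63", 63.1, 63.0, 63.0, -0.1, 3.2),
            ("c61", 61.2, 61.0, 61.0, 1.2, 3.1),
        ])
        best, trace = rank_equations(report)
        assert best == "a68"
        assert any("criterion 1" in line for line in trace)

    def test_bias_then_rmse(self):
        report = report_from([
            ("big_bias", 60.0, 60.0, 60.0, 3.0, 3.0),
            ("small_bias", 60.0, 60.0, 60.0, 0.1, 4.0),
            ("tied_bias_small_rmse", 60.0, 60.0, 60.0, 0.3, 2.5),
        ])
        best, _ = rank_equations(report)
        # bias window 0.5 keeps the two small-bias rows; RMSE decides
        assert best == "tied_bias_small_rmse"

    def test_empty_report_raises(self):
        with pytest.raises(MetricsError, match="empty"):
            rank_equations(RankedReport(overall=[], by_sex={}))


class TestEvaluateChange:
    @staticmethod
    def _pair(dxa_changes, pred_offsets):
        """Baseline/follow-up cohorts where haroun's predicted change is
        dxa_change + offset per subject (height drives haroun; DXA set freely)."""
        base, follow = [], []
        for i, (dc, off) in enumerate(zip(dxa_changes, pred_offsets)):
            b = Subject(id=f"p{i}", sex="F", age=14, height_cm=160, weight_kg=90,
                        resistance_ohm=500, reactance_ohm=60, ffm_dxa_kg=55.0)
            pred_change = dc + off
            # haroun: 1.115*H²/Z - 2.211; adjust follow-up Z to move prediction
            z_b = b.impedance_ohm
            target = 1.115 * 160**2 / z_b - 2.211 + pred_change
            z_f = 1.115 * 160**2 / (target + 2.211)
            f = Subject(id=f"p{i}", sex="F", age=14.5, height_cm=160, weight_kg=90,
                        resistance_ohm=math.sqrt(max(z_f**2 - 60**2, 1.0)),
                        reactance_ohm=60, impedance_ohm=z_f,
                        ffm_dxa_kg=55.0 + dc)
            base.append(b)
            follow.append(f)
        return base, follow

    def test_identical_changes_flagged_p_one(self):
        base, follow = self._pair([1.0, 2.0, -0.5], [0.0, 0.0, 0.0])
        res = evaluate_change(base, follow, "haroun")
        assert res.mean_diff_kg == pytest.approx(0.0, abs=1e-9)
        assert "zero_variance_differences" in res.flags
        assert res.p_value == 1.0

    def test_symmetric_differences(self):
        base, follow = self._pair([1.0, 1.0], [+1.0, -1.0])
        res = evaluate_change(base, follow, "haroun")
        assert res.mean_diff_kg == pytest.approx(0.0, abs=1e-9)
        assert res.sd_diff_kg == pytest.approx(math.sqrt(2), abs=1e-6)

    def test_constant_nonzero_difference_with_jitter(self):
        """diffs ≈ [2,2,2,2] with tiny jitter: t → ∞, p below 1e-6.

        Closed form at n=4: t = mean/(sd/2); with sd ~1e-12 the statistic
        explodes, so any correct implementation reports an extreme p.
        """
        jitter = [0.0, 1e-12, -1e-12, 5e-13]
        base, follow = self._pair([1.0] * 4, [2.0 + j for j in jitter])
        res = evaluate_change(base, follow, "haroun")
        assert res.mean_diff_kg == pytest.approx(2.0, abs=1e-6)
        assert res.p_value < 1e-6

    def test_mean_diff_identity(self):
        base, follow = self._pair([1.0, 2.0, 3.0], [0.5, -0.2, 0.1])
        res = evaluate_change(base, follow, "haroun")
        assert res.mean_diff_kg == pytest.approx(
            res.mean_change_pred_kg - res.mean_change_dxa_kg, abs=1e-9
        )

    def test_no_matched_ids_raises(self):
        base, _ = self._pair([1.0, 1.0], [0.0, 0.0])
        _, follow = self._pair([1.0, 1.0], [0.0, 0.0])
        follow = [f.with_(id=f.id + "_other") for f in follow]
        with pytest.raises(MetricsError, match="matched"):
            evaluate_change(base, follow, "haroun")
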