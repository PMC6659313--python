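"""Diagnostic accuracy: 2x2 tables, metrics, CIs, binary AUROC,
reconstruction from published marginals."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import beta

from prestart import (
    ConfusionTable,
    RiskClassification,
    binary_auroc,
    binary_auroc_rounded,
    ci_binomial,
    confusion_table,
    evaluate,
    metrics,
    reconstruct_from_marginals,
)
from prestart.errors import PairingError, ValidationError

HIGH, LOW = RiskClassification.HIGH, RiskClassification.LOW


class TestConfusionTable:
    def test_enumeration(self):
        preds = {"a": HIGH, "b": HIGH, "c": LOW, "d": LOW}
        refs = {"a": HIGH, "b": LOW, "c": HIGH, "d": LOW}
        ct = confusion_table(preds, refs)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (1, 1, 1, 1)

    def test_perfect_agreement(self):
        preds = {f"p{i}": HIGH for i in range(5)}
        ct = confusion_table(preds, dict(preds))
        assert ct.fp == ct.fn == 0 and ct.tp == 5

    def test_disjoint_ids_raise_pairing_error(self):
        with pytest.raises(PairingError):
            confusion_table({"a": HIGH}, {"b": HIGH})

    def test_indeterminate_rejected(self):
        with pytest.raises(ValidationError):
            confusion_table(
                {"a": RiskClassification.INDETERMINATE}, {"a": HIGH})


class TestMetrics:
    def test_reconstructed_study_table(self):
        """The 2x2 recovered from the published marginals reproduces the
        published metric percentages at 1-decimal rounding."""
        ct = reconstruct_from_marginals(636, 241, 214, 0.639)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (154, 60, 87, 335)
        ms = metrics(ct)
        assert ms["sensitivity"].point_pct == 63.9
        assert ms["specificity"].point_pct == 84.8
        assert ms["ppv"].point_pct == 72.0
        assert ms["npv"].point_pct == 79.4

    def test_perfect_table(self):
        ms = metrics(ConfusionTable(10, 0, 0, 10))
        assert all(m.point_pct == 100.0 for m in ms.values())

    def test_inverted_table(self):
        ms = metrics(ConfusionTable(0, 5, 5, 0))
        assert ms["sensitivity"].point_pct == 0.0
        assert ms["ppv"].point_pct == 0.0

    def test_zero_denominator_flagged_undefined(self):
        ms = metrics(ConfusionTable(0, 0, 0, 10))
        assert not ms["sensitivity"].defined
        assert not ms["ppv"].defined
        assert "undefined" in str(ms["sensitivity"])

    @given(st.tuples(st.integers(0, 40), st.integers(0, 40),
                     st.integers(0, 40), st.integers(0, 40))
           .filter(lambda t: sum(t) > 0))
    def test_metrics_in_unit_interval(self, cells):
        ct = ConfusionTable(*cells)
        for m in metrics(ct).values():
            if m.defined:
                assert 0.0 <= m.ci_low <= m.point <= m.ci_high <= 1.0


class TestBinomialCI:
    def test_boundary_intervals(self):
        assert ci_binomial(0, 20)[0] == 0.0
        assert ci_binomial(20, 20)[1] == 1.0

    def test_exact_interval_matches_beta_quantiles(self):
        """Clopper-Pearson oracle: the interval endpoints are beta
        distribution quantiles."""
        k, n, level = 154, 241, 0.95
        low, high = ci_binomial(k, n, level)
        alpha = 1 - level
        assert low == pytest.approx(beta.ppf(alpha / 2, k, n - k + 1))
        assert high == pytest.approx(beta.ppf(1 - alpha / 2, k + 1, n - k))
        # and the published interval (57.5, 70.0) within half a point
        assert low == pytest.approx(0.575, abs=0.005)
        assert high == pytest.approx(0.700, abs=0.005)

    def test_wilson_method_selectable(self):
        cp = ci_binomial(8, 10, method="clopper-pearson")
        wilson = ci_binomial(8, 10, method="wilson")
        assert cp != wilson
        assert wilson[0] < 0.8 < wilson[1]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            ci_binomial(5, 0)
        with pytest.raises(ValidationError):
            ci_binomial(-1, 10)

    def test_coverage_at_least_nominal(self):
        """Seeded Monte-Carlo: Clopper-Pearson coverage >= 95% nominal."""
        rng = np.random.default_rng(12345)
        for p in (0.1, 0.5, 0.9):
            for n in (50, 250):
                ks = rng.binomial(n, p, size=1000)
                covered = 0
                for k in ks:
                    low, high = ci_binomial(int(k), n)
                    covered += low <= p <= high
                assert covered / 1000 >= 0.95 - 0.02  # 3 sigma MC slack


class TestBinaryAuroc:
    def test_published_operating_points(self):
        assert binary_auroc_rounded(0.639, 0.848) == 0.74
        assert binary_auroc_rounded(0.925, 0.668) == 0.80

    def test_perfect_and_uninformative(self):
        assert binary_auroc(1.0, 1.0) == 1.0
        assert binary_auroc(0.3, 0.7) == 0.5

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_symmetry_and_bounds(self, sens, spec):
        assert binary_auroc(sens, spec) == binary_auroc(spec, sens)
        assert 0.0 <= binary_auroc(sens, spec) <= 1.0
        if binary_auroc(sens, spec) == 1.0:
            assert sens == spec == 1.0


class TestReconstruction:
    def test_perfect_sensitivity(self):
        ct = reconstruct_from_marginals(10, 5, 5, 1.0)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (5, 0, 0, 5)

    def test_zero_sensitivity(self):
        ct = reconstruct_from_marginals(10, 6, 2, 0.0)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (0, 2, 6, 2)

    def test_infeasible_marginals(self):
        with pytest.raises(ValidationError):
            reconstruct_from_marginals(10, 12, 5, 0.5)

    @given(st.integers(20, 400), st.data())
    def test_round_trip_from_random_tables(self, n, data):
        """Oracle: build a random 2x2, publish its marginals and its
        sensitivity rounded to 4 decimals, and recover the table
        exactly (rounding at the published precision keeps the true tp
        the unique nearest candidate for these sizes)."""
        ref_pos = data.draw(st.integers(1, n))
        tp = data.draw(st.integers(0, ref_pos))
        fp = data.draw(st.integers(0, n - ref_pos))
        sens_published = round(tp / ref_pos, 4)
        ct = reconstruct_from_marginals(n, ref_pos, tp + fp, sens_published)
        assert (ct.tp, ct.fp) == (tp, fp)
        assert ct.fn == ref_pos - tp
        assert ct.n == n


class TestEvaluate:
    def test_known_table_recovered_exactly(self):
        """End-to-end: labels generated with known tp/fp/fn/tn yield
        exactly those ratios."""
        tp, fp, fn, tn = 12, 3, 5, 30
        preds, refs = {}, {}
        idx = 0
        for count, (p, r) in [(tp, (HIGH, HIGH)), (fp, (HIGH, LOW)),
                              (fn, (LOW, HIGH)), (tn, (LOW, LOW))]:
            for _ in range(count):
                preds[f"p{idx}"], refs[f"p{idx}"] = p, r
                idx += 1
        report = evaluate(preds, refs)
        assert (report.table.tp, report.table.fp,
                report.table.fn, report.table.tn) == (tp, fp, fn, tn)
        assert report.metrics["sensitivity"].point == tp / (tp + fn)
        assert report.auroc == binary_auroc(tp / (tp + fn), tn / (tn + fp))

    def test_indeterminate_excluded_with_count(self):
        preds = {"a": HIGH, "b": RiskClassification.INDETERMINATE,
                 "c": LOW}
        refs = {"a": HIGH, "b": HIGH, "c": LOW}
        report = evaluate(preds, refs)
        assert report.n == 2
        assert report.n_indeterminate_excluded == 1

    def test_report_serialises(self):
        report = evaluate({"a": HIGH, "b": LOW}, {"a": HIGH, "b": LOW})
        payload = report.to_dict()
        assert payload["confusion"] == {"tp": 1, "fp": 0, "fn": 0, "tn": 1}
        assert "Sensitivity" in report.to_text()
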