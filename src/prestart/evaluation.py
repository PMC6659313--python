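"""Diagnostic-accuracy evaluation against an adjudicated reference.

The screening tool is a single-threshold binary test, so its ROC "curve"
has one operating point and the trapezoidal area under it collapses to
(sensitivity + specificity) / 2 — :func:`binary_auroc`.

Because the study published marginal counts and rounded metrics rather
than the underlying 2x2 table, :func:`reconstruct_from_marginals`
recovers the unique integer table consistent with the totals and the
printed sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

from statsmodels.stats.proportion import proportion_confint

from .errors import InfeasibleError, PairingError, ValidationError
from .rounding import percent, round_half_away
from .rules import RiskClassification

#: supported binomial CI methods -> statsmodels method name
_CI_METHODS = {"clopper-pearson": "beta", "wilson": "wilson"}


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-classification of tool vs reference (both high/low)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n == 0:
            raise ValidationError("confusion table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def ref_pos(self) -> int:
        return self.tp + self.fn

    @property
    def pred_pos(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion-type metric with two-sided confidence bounds."""

    name: str
    numerator: int
    denominator: int
    level: float = 0.95
    point: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def point_pct(self) -> float:
        return percent(self.point)

    @property
    def ci_pct(self) -> Tuple[float, float]:
        return percent(self.ci_low), percent(self.ci_high)

    def __str__(self) -> str:
        if not self.defined:
            return f"{self.name}: undefined (denominator 0)"
        lo, hi = self.ci_pct
        return f"{self.name}: {self.point_pct}% ({lo}, {hi})"


def ci_binomial(
    k: int, n: int, level: float = 0.95, method: str = "clopper-pearson"
) -> Tuple[float, float]:
    """Two-sided binomial CI for a proportion k/n.

    Default is the Clopper-Pearson exact (beta-quantile) interval;
    ``method="wilson"`` selects the Wilson score interval.
    """
    if n <= 0 or not 0 <= k <= n:
        raise ValidationError(f"invalid binomial counts k={k}, n={n}")
    if method not in _CI_METHODS:
        raise ValidationError(
            f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}"
        )
    low, high = proportion_confint(k, n, alpha=1 - level,
                                   method=_CI_METHODS[method])
    return float(low), float(high)


def _estimate(name: str, k: int, n: int, level: float,
              method: str) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(name, 0, 0, level)
    low, high = ci_binomial(k, n, level, method)
    return MetricEstimate(name, k, n, level, k / n, low, high)


def metrics(
    ct: ConfusionTable, level: float = 0.95, method: str = "clopper-pearson"
) -> Dict[str, MetricEstimate]:
    """Sensitivity, specificity, PPV and NPV with binomial CIs.

    A zero denominator yields an estimate flagged undefined, never 0.
    """
    return {
        "sensitivity": _estimate("sensitivity", ct.tp, ct.tp + ct.fn, level, method),
        "specificity": _estimate("specificity", ct.tn, ct.tn + ct.fp, level, method),
        "ppv": _estimate("ppv", ct.tp, ct.tp + ct.fp, level, method),
        "npv": _estimate("npv", ct.tn, ct.tn + ct.fn, level, method),
    }


def binary_auroc(sensitivity: float, specificity: float) -> float:
    """Trapezoidal ROC area for a single-operating-point binary test.

    The ROC polygon through (0,0), (1-specificity, sensitivity), (1,1)
    has area (sensitivity + specificity) / 2.  Symmetric in its
    arguments; 0.5 for an uninformative test (sens + spec = 1).
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValidationError("sensitivity and specificity must lie in [0, 1]")
    return (sensitivity + specificity) / 2.0


def binary_auroc_rounded(sensitivity: float, specificity: float) -> float:
    """binary_auroc at the 2-decimal precision used in published tables."""
    return round_half_away(binary_auroc(sensitivity, specificity), 2)


def confusion_table(
    predictions: Mapping[str, RiskClassification],
    references: Mapping[str, RiskClassification],
) -> ConfusionTable:
    """Cross-classify per-id tool predictions against reference labels.

    Both mappings must cover identical id sets and contain no
    INDETERMINATE values (filter or resolve them first).
    """
    if set(predictions) != set(references):
        only_pred = sorted(set(predictions) - set(references))[:5]
        only_ref = sorted(set(references) - set(predictions))[:5]
        raise PairingError(
            f"id sets differ (examples only in predictions: {only_pred}, "
            f"only in references: {only_ref})"
        )
    tp = fp = fn = tn = 0
    for pid, pred in predictions.items():
        ref = references[pid]
        if (pred is RiskClassification.INDETERMINATE
                or ref is RiskClassification.INDETERMINATE):
            raise ValidationError(
                f"indeterminate classification for id {pid!r}; "
                f"exclude or resolve before tabulating"
            )
        if pred is RiskClassification.HIGH:
            if ref is RiskClassification.HIGH:
                tp += 1
            else:
                fp += 1
        else:
            if ref is RiskClassification.HIGH:
                fn += 1
            else:
                tn += 1
    return ConfusionTable(tp, fp, fn, tn)


def reconstruct_from_marginals(
    n: int, ref_pos: int, pred_pos: int, sensitivity: float
) -> ConfusionTable:
    """Recover the integer 2x2 table from published marginals.

    Given the total n, the reference-positive and tool-positive counts
    and a (possibly rounded) sensitivity, search the feasible range of
    true-positive counts, ``max(0, ref_pos + pred_pos - n) <= tp <=
    min(ref_pos, pred_pos)``, for the tp whose implied sensitivity is
    closest to the published one (ties break to the smaller tp).
    Exact whenever the published sensitivity came from an integer table
    with these marginals.
    """
    if not (0 <= ref_pos <= n and 0 <= pred_pos <= n):
        raise ValidationError("marginals must lie within [0, n]")
    lo = max(0, ref_pos + pred_pos - n)
    hi = min(ref_pos, pred_pos)
    if lo > hi:
        raise InfeasibleError(
            f"no feasible tp for n={n}, ref_pos={ref_pos}, pred_pos={pred_pos}"
        )
    if ref_pos == 0:
        best_tp = 0
    else:
        best_tp = min(
            range(lo, hi + 1),
            key=lambda tp: (abs(tp / ref_pos - sensitivity), tp),
        )
    return ConfusionTable(
        tp=best_tp,
        fp=pred_pos - best_tp,
        fn=ref_pos - best_tp,
        tn=n - ref_pos - pred_pos + best_tp,
    )


@dataclass
class EvaluationReport:
    """Confusion table, the four accuracy metrics, and the binary AUROC."""

    table: ConfusionTable
    metrics: Dict[str, MetricEstimate]
    level: float = 0.95
    n_indeterminate_excluded: int = 0

    @property
    def n(self) -> int:
        return self.table.n

    @property
    def auroc(self) -> float:
        return binary_auroc(
            self.metrics["sensitivity"].point, self.metrics["specificity"].point
        )

    @property
    def auroc_ci(self) -> Tuple[float, float]:
        """AUROC CI obtained by pushing the per-metric binomial CIs
        through the (sens + spec)/2 identity (a documented approximation;
        the two binomials are independent conditionally on the margins,
        so this interval is conservative)."""
        s = self.metrics["sensitivity"]
        p = self.metrics["specificity"]
        return ((s.ci_low + p.ci_low) / 2.0, (s.ci_high + p.ci_high) / 2.0)

    def to_dict(self) -> Dict[str, object]:
        out: Dict[str, object] = {
            "n": self.n,
            "confusion": {"tp": self.table.tp, "fp": self.table.fp,
                          "fn": self.table.fn, "tn": self.table.tn},
            "level": self.level,
            "n_indeterminate_excluded": self.n_indeterminate_excluded,
            "auroc": round_half_away(self.auroc, 2),
            "auroc_ci": [round_half_away(v, 2) for v in self.auroc_ci],
        }
        for name, est in self.metrics.items():
            if est.defined:
                lo, hi = est.ci_pct
                out[name] = {"pct": est.point_pct, "ci_pct": [lo, hi],
                             "numerator": est.numerator,
                             "denominator": est.denominator}
            else:
                out[name] = {"pct": None, "undefined": True}
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        """Plain-text table in the style of a published performance table."""
        lines = [
            f"n = {self.n} (indeterminate excluded: "
            f"{self.n_indeterminate_excluded})",
            f"2x2: tp={self.table.tp} fp={self.table.fp} "
            f"fn={self.table.fn} tn={self.table.tn}",
            f"{'Metric':<28}{'%':>8}  95% CI",
        ]
        label = {
            "sensitivity": "Sensitivity",
            "specificity": "Specificity",
            "ppv": "Positive predictive value",
            "npv": "Negative predictive value",
        }
        for key in ("sensitivity", "specificity", "ppv", "npv"):
            est = self.metrics[key]
            if est.defined:
                lo, hi = est.ci_pct
                lines.append(f"{label[key]:<28}{est.point_pct:>8.1f}  {lo}, {hi}")
            else:
                lines.append(f"{label[key]:<28}{'--':>8}  undefined")
        lo, hi = self.auroc_ci
        lines.append(
            f"AUROC {round_half_away(self.auroc, 2):.2f} "
            f"({round_half_away(lo, 2):.2f}, {round_half_away(hi, 2):.2f})"
        )
        return "\n".join(lines)


def evaluate(
    predictions: Mapping[str, RiskClassification],
    references: Mapping[str, RiskClassification],
    level: float = 0.95,
    method: str = "clopper-pearson",
) -> EvaluationReport:
    """Full evaluation of tool predictions against reference labels.

    Ids classified INDETERMINATE on either side are excluded, with the
    excluded count reported explicitly in the result.
    """
    keep = {
        pid for pid in predictions
        if pid in references
        and predictions[pid] is not RiskClassification.INDETERMINATE
        and references[pid] is not RiskClassification.INDETERMINATE
    }
    if set(predictions) != set(references):
        raise PairingError("prediction and reference id sets differ")
    excluded = len(predictions) - len(keep)
    ct = confusion_table(
        {pid: predictions[pid] for pid in keep},
        {pid: references[pid] for pid in keep},
    )
    return EvaluationReport(ct, metrics(ct, level, method), level, excluded)
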