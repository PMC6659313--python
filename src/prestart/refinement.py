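"""Refinement ladder: sequential factor removals and amendments.

The tool was refined in two stages: plus-one factors were removed one at
a time (in an order the investigators acknowledged was arbitrary), then
a series of stakeholder-requested amendments were applied — dropping
screen time from the core, restoring family-facing factors, extending
family history to second degree, and adding back modifiable factors for
their educational value.  Each variant is evaluated identically against
the adjudicated reference, producing an AUROC per rung.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .cohort import ParticipantRecord
from .errors import ConfigurationError, ValidationError
from .evaluation import EvaluationReport, evaluate
from .factors import DEFAULT_CONFIG, ThresholdConfig
from .rounding import round_half_away
from .rules import (
    RiskClassification,
    RuleSet,
    builtin_ruleset,
    classify_cohort,
)

#: the shipped ladder: base tool, the 21 assessed variants in order, and
#: the adopted final tool restated last (tool21 was assessed after the
#: final tool but not adopted)
BUILTIN_LADDER: Tuple[str, ...] = (
    ("initial",) + tuple(f"tool{i}" for i in range(1, 22)) + ("final",)
)


# --- rule-set edits (pure: the input rule set is never modified) -----------

def remove_factor(ruleset: RuleSet, factor: str) -> RuleSet:
    """Remove a factor from wherever it sits (core or plus-one)."""
    if factor in ruleset.core:
        return replace(ruleset, core=ruleset.core - {factor})
    if factor in ruleset.plus_one:
        return replace(ruleset, plus_one=ruleset.plus_one - {factor})
    raise ConfigurationError(
        f"cannot remove {factor!r}: not in rule set {ruleset.name!r}"
    )


def add_factor(ruleset: RuleSet, factor: str) -> RuleSet:
    """Add a factor to the plus-one set."""
    if factor in ruleset.factors:
        raise ConfigurationError(
            f"cannot add {factor!r}: already in rule set {ruleset.name!r}"
        )
    return replace(ruleset, plus_one=ruleset.plus_one | {factor})


def swap_core_to_plus(ruleset: RuleSet, factor: str) -> RuleSet:
    """Demote a core factor to the plus-one set."""
    if factor not in ruleset.core:
        raise ConfigurationError(
            f"cannot demote {factor!r}: not in core of {ruleset.name!r}"
        )
    return replace(
        ruleset,
        core=ruleset.core - {factor},
        plus_one=ruleset.plus_one | {factor},
    )


def replace_factor(ruleset: RuleSet, old: str, new: str) -> RuleSet:
    """Replace one factor with another, preserving core/plus-one position."""
    if new in ruleset.factors:
        raise ConfigurationError(
            f"cannot introduce {new!r}: already in rule set {ruleset.name!r}"
        )
    if old in ruleset.core:
        return replace(ruleset, core=(ruleset.core - {old}) | {new})
    if old in ruleset.plus_one:
        return replace(ruleset, plus_one=(ruleset.plus_one - {old}) | {new})
    raise ConfigurationError(
        f"cannot replace {old!r}: not in rule set {ruleset.name!r}"
    )


_EDIT_OPS = {
    "remove": remove_factor,
    "add": add_factor,
    "demote": swap_core_to_plus,
}


def apply_edit(ruleset: RuleSet, edit: Mapping[str, str]) -> RuleSet:
    """Apply one declarative edit, e.g. {"op": "add", "factor": "SI"}."""
    op = edit.get("op")
    if op == "replace":
        out = replace_factor(ruleset, edit["old"], edit["new"])
    elif op in _EDIT_OPS:
        out = _EDIT_OPS[op](ruleset, edit["factor"])
    else:
        raise ConfigurationError(f"unknown edit op {op!r}")
    return replace(out, name=edit.get("name", f"{ruleset.name}+{op}"))


def describe_delta(previous: RuleSet, current: RuleSet) -> str:
    """Human-readable one-step difference, e.g. '+ SI' or '- AN'."""
    parts: List[str] = []
    for factor in sorted(previous.core - current.factors):
        parts.append(f"- {factor} (core)")
    for factor in sorted(previous.core & current.plus_one):
        parts.append(f"{factor}: core -> plus-one")
    for factor in sorted(previous.plus_one - current.factors):
        parts.append(f"- {factor}")
    for factor in sorted(current.factors - previous.factors):
        parts.append(f"+ {factor}")
    return ", ".join(parts) if parts else "(unchanged)"


# --- ladder construction and evaluation ------------------------------------

@dataclass
class RefinementLadder:
    """Ordered tool variants with their evaluation reports."""

    entries: List[Tuple[RuleSet, EvaluationReport]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("a refinement ladder cannot be empty")

    @property
    def rulesets(self) -> List[RuleSet]:
        return [rs for rs, _ in self.entries]

    @property
    def reports(self) -> List[EvaluationReport]:
        return [rep for _, rep in self.entries]


def builtin_ladder_rulesets() -> List[RuleSet]:
    return [builtin_ruleset(name) for name in BUILTIN_LADDER]


def load_ladder_spec(path) -> List[RuleSet]:
    """Load a ladder config: a base rule-set name plus ordered edits."""
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if "variants" in raw:
        return [builtin_ruleset(name) for name in raw["variants"]]
    current = builtin_ruleset(raw["base"])
    out = [current]
    for edit in raw.get("edits", []):
        current = apply_edit(current, edit)
        out.append(current)
    return out


def run_ladder(
    records: Sequence[ParticipantRecord],
    references: Mapping[str, RiskClassification],
    rulesets: Optional[Sequence[RuleSet]] = None,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
    level: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> RefinementLadder:
    """Classify the cohort under every variant and evaluate each one.

    Defaults to the shipped 23-variant ladder.  Deterministic given its
    inputs; record order does not affect any report.
    """
    if rulesets is None:
        rulesets = builtin_ladder_rulesets()
    entries: List[Tuple[RuleSet, EvaluationReport]] = []
    for ruleset in rulesets:
        cohort_cls = classify_cohort(records, ruleset, cfg)
        report = evaluate(cohort_cls.as_mapping(), dict(references),
                          level=level, method=ci_method)
        entries.append((ruleset, report))
    return RefinementLadder(entries)


def ladder_report(ladder: RefinementLadder) -> Dict[str, object]:
    """JSON-ready rendering: name, core, plus-one delta, AUROC with CI."""
    rows: List[Dict[str, object]] = []
    previous: Optional[RuleSet] = None
    for ruleset, report in ladder.entries:
        lo, hi = report.auroc_ci
        rows.append({
            "name": ruleset.name,
            "core": sorted(ruleset.core),
            "plus_one": sorted(ruleset.plus_one),
            "delta": ("(base)" if previous is None
                      else describe_delta(previous, ruleset)),
            "n": report.n,
            "n_indeterminate_excluded": report.n_indeterminate_excluded,
            "n_tool_high": report.table.pred_pos,
            "auroc": round_half_away(report.auroc, 2),
            "auroc_ci": [round_half_away(lo, 2), round_half_away(hi, 2)],
        })
        previous = ruleset
    return {"ladder": rows}


def ladder_report_text(ladder: RefinementLadder) -> str:
    rows = ladder_report(ladder)["ladder"]
    lines = [f"{'Tool':<10}{'Core':<10}{'Delta':<34}{'AUROC':>6}  95% CI"]
    for row in rows:
        lo, hi = row["auroc_ci"]
        lines.append(
            f"{row['name']:<10}{','.join(row['core']):<10}"
            f"{row['delta']:<34}{row['auroc']:>6.2f}  ({lo:.2f}, {hi:.2f})"
        )
    return "\n".join(lines)
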