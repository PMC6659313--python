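"""Core/plus-one rule engine and the shipped tool variants.

A rule set flags a participant at high lifetime risk when every *core*
factor is present AND at least one *plus-one* factor is present.  The
tool is deliberately unweighted: it records the presence of risk factors
rather than scoring them, so it can be completed without calculations or
equipment.

Rule sets are data, not code: the 23 built-in variants (the initial
tool, the twelve sequential-removal variants, and the nine
collaboration-amended variants ending in the final tool) ship as a YAML
config and user-defined variants load from the same format.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Optional, Sequence

import yaml

from .cohort import ParticipantRecord
from .errors import ConfigurationError, ValidationError
from .factors import (
    ALL_FACTORS,
    DEFAULT_CONFIG,
    RiskFactorProfile,
    ThresholdConfig,
    derive_profile,
)
from .rounding import percent


class RiskClassification(enum.Enum):
    HIGH = "high"
    LOW = "low"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class RuleSet:
    """A named tool variant.

    ``core``: all must be present.  ``plus_one``: at least one must be
    present.  ``unknown_policy``: how unknown factors are treated —
    ``"absent"`` (the study default; blank responses could not be used
    as evidence) or ``"strict"`` (return INDETERMINATE when unknowns
    could change the outcome).
    """

    name: str
    core: frozenset = field(default_factory=frozenset)
    plus_one: frozenset = field(default_factory=frozenset)
    unknown_policy: str = "absent"

    def __post_init__(self) -> None:
        object.__setattr__(self, "core", frozenset(self.core))
        object.__setattr__(self, "plus_one", frozenset(self.plus_one))
        if not self.core:
            raise ConfigurationError(f"rule set {self.name!r}: core is empty")
        if not self.plus_one:
            raise ConfigurationError(f"rule set {self.name!r}: plus_one is empty")
        if self.core & self.plus_one:
            raise ConfigurationError(
                f"rule set {self.name!r}: core and plus_one overlap: "
                f"{sorted(self.core & self.plus_one)}"
            )
        unknown = (self.core | self.plus_one) - set(ALL_FACTORS)
        if unknown:
            raise ConfigurationError(
                f"rule set {self.name!r}: unknown factor(s) {sorted(unknown)}"
            )
        if self.unknown_policy not in ("absent", "strict"):
            raise ConfigurationError(
                f"rule set {self.name!r}: unknown_policy must be "
                f"'absent' or 'strict'"
            )

    @property
    def factors(self) -> frozenset:
        return self.core | self.plus_one


def _classify_bool(profile: RiskFactorProfile, ruleset: RuleSet,
                   unknown_as: bool) -> bool:
    core_ok = all(
        profile[f].to_bool(default=unknown_as) for f in ruleset.core
    )
    plus_ok = any(
        profile[f].to_bool(default=unknown_as) for f in ruleset.plus_one
    )
    return core_ok and plus_ok


def classify(profile: RiskFactorProfile, ruleset: RuleSet) -> RiskClassification:
    """Classify one profile under a rule set.

    Under the default ``absent`` policy unknowns count as absent.  Under
    ``strict``, the classification is computed with unknowns mapped to
    absent and to present; if the two extremes disagree the outcome is
    INDETERMINATE (the rule is monotone in factor presence, so the two
    extremes bound every completion of the unknowns).
    """
    for f in ruleset.factors:
        if f not in profile.values:
            raise ConfigurationError(
                f"rule set {ruleset.name!r} references factor {f!r} "
                f"not present in profile"
            )
    low = _classify_bool(profile, ruleset, unknown_as=False)
    if ruleset.unknown_policy == "absent":
        return RiskClassification.HIGH if low else RiskClassification.LOW
    high = _classify_bool(profile, ruleset, unknown_as=True)
    if low == high:
        return RiskClassification.HIGH if low else RiskClassification.LOW
    return RiskClassification.INDETERMINATE


@dataclass
class CohortClassification:
    """Per-record classifications plus the high-risk count and proportion."""

    ids: List[str]
    classifications: List[RiskClassification]
    ruleset_name: str

    @property
    def n(self) -> int:
        return len(self.classifications)

    @property
    def n_high(self) -> int:
        return sum(c is RiskClassification.HIGH for c in self.classifications)

    @property
    def n_indeterminate(self) -> int:
        return sum(
            c is RiskClassification.INDETERMINATE for c in self.classifications
        )

    @property
    def proportion_high_pct(self) -> float:
        """High-risk proportion as a 1-decimal percentage."""
        return percent(self.n_high / self.n)

    def as_mapping(self) -> Dict[str, RiskClassification]:
        return dict(zip(self.ids, self.classifications))


def classify_cohort(
    records: Sequence[ParticipantRecord],
    ruleset: RuleSet,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> CohortClassification:
    """Derive profiles and classify every record in order."""
    if not records:
        raise ValidationError("classify_cohort requires at least one record")
    ids = [r.id for r in records]
    classifications = [
        classify(derive_profile(r, cfg), ruleset) for r in records
    ]
    return CohortClassification(ids, classifications, ruleset.name)


# ---------------------------------------------------------------------------
# built-in rule sets

def _load_builtin_rulesets() -> Dict[str, RuleSet]:
    text = (
        resources.files("prestart").joinpath("data/rulesets.yaml")
        .read_text(encoding="utf-8")
    )
    raw = yaml.safe_load(text)
    rulesets: Dict[str, RuleSet] = {}
    for entry in raw["rulesets"]:
        rs = RuleSet(
            name=entry["name"],
            core=frozenset(entry["core"]),
            plus_one=frozenset(entry["plus_one"]),
            unknown_policy=entry.get("unknown_policy", "absent"),
        )
        rulesets[rs.name] = rs
    for alias, target in (raw.get("aliases") or {}).items():
        rulesets[alias] = replace(rulesets[target], name=alias)
    return rulesets


_BUILTIN_CACHE: Optional[Dict[str, RuleSet]] = None


def builtin_names() -> List[str]:
    global _BUILTIN_CACHE
    if _BUILTIN_CACHE is None:
        _BUILTIN_CACHE = _load_builtin_rulesets()
    return list(_BUILTIN_CACHE)


def builtin_ruleset(name: str) -> RuleSet:
    """Look up a shipped tool variant by name.

    Valid names: ``initial``, ``tool1`` … ``tool21``, and ``final`` (an
    alias for ``tool20``).
    """
    global _BUILTIN_CACHE
    if _BUILTIN_CACHE is None:
        _BUILTIN_CACHE = _load_builtin_rulesets()
    if name not in _BUILTIN_CACHE:
        raise ConfigurationError(
            f"unknown rule set {name!r}; valid names: "
            f"{', '.join(sorted(_BUILTIN_CACHE))}"
        )
    return _BUILTIN_CACHE[name]


def load_ruleset(path) -> RuleSet:
    """Load a single user-defined rule set from a YAML file."""
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    return RuleSet(
        name=raw["name"],
        core=frozenset(raw["core"]),
        plus_one=frozenset(raw["plus_one"]),
        unknown_policy=raw.get("unknown_policy", "absent"),
    )
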