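"""Clinician-consensus reference standard.

Two clinicians independently judge each participant's lifetime risk
(high/low); where they disagree a third clinician adjudicates.  The
resulting consensus is the gold standard against which the tool is
evaluated.  Rater identities are opaque labels — how raters were
assigned (the study clustered them within countries) is a simulator
concern, not adjudication logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

from .cohort import ParticipantRecord
from .errors import UnresolvedCaseError, ValidationError
from .rules import RiskClassification
from .tristate import TriState


@dataclass(frozen=True)
class AdjudicationRecord:
    id: str
    rater1: RiskClassification
    rater2: RiskClassification
    rater3: RiskClassification | None
    consensus: RiskClassification
    needed_third: bool


def _as_label(value: TriState, rid: str, who: str) -> RiskClassification:
    if value is TriState.UNKNOWN:
        raise ValidationError(f"id {rid!r}: missing {who} rating")
    return (RiskClassification.HIGH if value is TriState.PRESENT
            else RiskClassification.LOW)


def consensus(
    rid: str,
    rater1: RiskClassification,
    rater2: RiskClassification,
    rater3: RiskClassification | None = None,
) -> AdjudicationRecord:
    """Resolve one participant's ratings to a consensus label.

    Agreeing primary raters decide; otherwise the third rating decides.
    Symmetric in rater1/rater2.
    """
    if rater1 == rater2:
        return AdjudicationRecord(rid, rater1, rater2, rater3, rater1, False)
    if rater3 is None:
        raise UnresolvedCaseError(
            f"id {rid!r}: raters disagree and no third rating is available"
        )
    return AdjudicationRecord(rid, rater1, rater2, rater3, rater3, True)


@dataclass
class AdjudicationSummary:
    records: List[AdjudicationRecord]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_agreed(self) -> int:
        return sum(not r.needed_third for r in self.records)

    @property
    def agreement_rate(self) -> float:
        return self.n_agreed / self.n

    @property
    def tiebreak_rate(self) -> float:
        return 1.0 - self.agreement_rate

    def reference_labels(self) -> Dict[str, RiskClassification]:
        return {r.id: r.consensus for r in self.records}


def agreement_rate(records: Sequence[AdjudicationRecord]) -> float:
    """Proportion of cases where the two primary raters agreed."""
    if not records:
        raise ValidationError("agreement_rate requires at least one record")
    return sum(not r.needed_third for r in records) / len(records)


def adjudicate_cohort(
    records: Sequence[ParticipantRecord],
) -> AdjudicationSummary:
    """Adjudicate a cohort from its rater columns.

    Every record must carry two primary ratings; the third is consulted
    only on disagreement.  Raises on duplicate ids or a missing primary
    rating, naming the offending id.
    """
    if not records:
        raise ValidationError("adjudicate_cohort requires at least one record")
    seen = set()
    out: List[AdjudicationRecord] = []
    for record in records:
        if record.id in seen:
            raise ValidationError(f"duplicate id in ratings: {record.id!r}")
        seen.add(record.id)
        r1 = _as_label(record.rater1_high, record.id, "rater1")
        r2 = _as_label(record.rater2_high, record.id, "rater2")
        r3 = (None if record.rater3_high is TriState.UNKNOWN
              else _as_label(record.rater3_high, record.id, "rater3"))
        out.append(consensus(record.id, r1, r2, r3))
    return AdjudicationSummary(out)


def cohen_kappa(records: Sequence[AdjudicationRecord]) -> float:
    """Optional chance-corrected agreement between the primary raters."""
    if not records:
        raise ValidationError("cohen_kappa requires at least one record")
    n = len(records)
    p_obs = sum(r.rater1 == r.rater2 for r in records) / n
    p1_high = sum(r.rater1 is RiskClassification.HIGH for r in records) / n
    p2_high = sum(r.rater2 is RiskClassification.HIGH for r in records) / n
    p_exp = p1_high * p2_high + (1 - p1_high) * (1 - p2_high)
    if p_exp == 1.0:
        return 1.0
    return (p_obs - p_exp) / (1 - p_exp)
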