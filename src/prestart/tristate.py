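"""Three-valued (present / absent / unknown) logic.

Clinical screening data routinely contains blank responses that must never
be conflated with a negative finding.  ``TriState`` makes the third state
explicit and provides Kleene-style three-valued connectives so that derived
risk factors propagate missingness instead of silently coercing it.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional


class TriState(enum.Enum):
    """A present / absent / unknown value.

    ``UNKNOWN`` is distinguishable from ``ABSENT``: a blank cell in a data
    file maps to ``UNKNOWN``, never to ``ABSENT`` or zero.
    """

    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # pragma: no cover - guard
        raise TypeError(
            "TriState is three-valued; use is_present()/is_absent() or "
            "to_bool(default=...) instead of truthiness"
        )

    @property
    def is_present(self) -> bool:
        return self is TriState.PRESENT

    @property
    def is_absent(self) -> bool:
        return self is TriState.ABSENT

    @property
    def is_known(self) -> bool:
        return self is not TriState.UNKNOWN

    def to_bool(self, default: bool = False) -> bool:
        """Collapse to a boolean, mapping UNKNOWN to ``default``."""
        if self is TriState.UNKNOWN:
            return default
        return self is TriState.PRESENT

    @staticmethod
    def from_bool(value: Optional[bool]) -> "TriState":
        if value is None:
            return TriState.UNKNOWN
        return TriState.PRESENT if value else TriState.ABSENT

    def negate(self) -> "TriState":
        """Kleene NOT: unknown stays unknown."""
        if self is TriState.PRESENT:
            return TriState.ABSENT
        if self is TriState.ABSENT:
            return TriState.PRESENT
        return TriState.UNKNOWN


def tri_any(values: Iterable[TriState]) -> TriState:
    """Kleene OR: present if any present; absent if all known-absent."""
    saw_unknown = False
    for v in values:
        if v is TriState.PRESENT:
            return TriState.PRESENT
        if v is TriState.UNKNOWN:
            saw_unknown = True
    return TriState.UNKNOWN if saw_unknown else TriState.ABSENT


def tri_all(values: Iterable[TriState]) -> TriState:
    """Kleene AND: absent if any absent; present if all known-present."""
    saw_unknown = False
    for v in values:
        if v is TriState.ABSENT:
            return TriState.ABSENT
        if v is TriState.UNKNOWN:
            saw_unknown = True
    return TriState.UNKNOWN if saw_unknown else TriState.PRESENT


#: accepted on-disk spellings, lower-cased
_TRUE = {"1", "yes", "true", "y", "present", "high"}
_FALSE = {"0", "no", "false", "n", "absent", "low"}


def parse_tristate(cell: object) -> TriState:
    """Parse a spreadsheet cell into a TriState.

    Blank, NA-like and unrecognised cells become UNKNOWN — never absent.
    """
    if cell is None:
        return TriState.UNKNOWN
    text = str(cell).strip().lower()
    if text in ("", "na", "nan", "none", "unknown", "?"):
        return TriState.UNKNOWN
    if text in _TRUE:
        return TriState.PRESENT
    if text in _FALSE:
        return TriState.ABSENT
    return TriState.UNKNOWN


def format_tristate(value: TriState) -> str:
    """Canonical on-disk encoding: '1' / '0' / '' (blank)."""
    if value is TriState.PRESENT:
        return "1"
    if value is TriState.ABSENT:
        return "0"
    return ""
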