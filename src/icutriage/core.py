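"""Deterministic ICU admission triage rule.

A bedside questionnaire with four closed questions is mapped onto the four
ordinal priority classes of the Society of Critical Care Medicine (SCCM)
prioritization model:

* **Question 1** — is the ICU request for *active intervention* (vasoactive
  drugs, mechanical ventilation, urgent dialysis in an unstable patient) or
  for *monitoring*?
* **Question 2** — comorbidity burden, four ordinal strata from *no
  comorbidities* up to *advanced disease* with a life expectancy of months.
* **Question 3** — previous functionality by Katz activities of daily living
  (ADL): independent, partially dependent, or severely dependent (capable of
  at most two ADLs).
* **Question 4** — the requesting physician's intuitive prognosis: probable
  survivor without severe disabilities, survivor with severe disabilities, or
  probable nonsurvivor.

The rule set assigns priority 4 (generally not appropriate for ICU) to
decompensated comorbidity with severe dependency, advanced disease with
partial or severe dependency, and advanced disease with preserved
functionality but a prognosis of death.  Priority 3 goes to compensated
comorbidity with severe dependency, decompensated comorbidity with partial
dependency, and advanced disease with preserved functionality and a prognosis
of survival (with or without disabilities).  Every other patient is priority
1 or 2 according to whether the request is for intervention or monitoring.

The classification is a pure, total function of the four answers: the 72
possible answer combinations partition into 18/18/16/20 patients of
priority 1/2/3/4.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = [
    "RequestType",
    "Comorbidity",
    "Functionality",
    "Prognosis",
    "PriorityClass",
    "TriageAssessment",
    "ClassificationError",
    "classify_priority",
    "enumerate_decision_table",
    "decision_table_counts",
]


class ClassificationError(ValueError):
    """Raised when an assessment answer is missing or not a known category."""


class _Answer(enum.IntEnum):
    """Base for questionnaire answers: integer-coded ordinal categories.

    Values follow the questionnaire coding (Q1: 1-2, Q2: 1-4, Q3: 1-3,
    Q4: 1-3).  ``coerce`` accepts an enum member, the integer code, or the
    mnemonic name (case-insensitive) and raises :class:`ClassificationError`
    naming the offending field otherwise.
    """

    @classmethod
    def coerce(cls, value: object, field: str | None = None) -> "_Answer":
        field = field or cls.__name__
        if value is None:
            raise ClassificationError(f"{field}: answer is missing")
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            token = value.strip().upper()
            if token in cls.__members__:
                return cls[token]
            if token.lstrip("-").isdigit():
                value = int(token)
        if not isinstance(value, bool):
            # accept any integer-like code (plain, numpy, integral float)
            try:
                code = int(value)
                if code == value:
                    return cls(code)
            except (TypeError, ValueError):
                pass
        raise ClassificationError(
            f"{field}: {value!r} is not a recognized category "
            f"(expected one of {[m.name for m in cls]} or codes "
            f"{[m.value for m in cls]})"
        )


class RequestType(_Answer):
    """Question 1 — reason for the ICU admission request."""

    INTERVENTION = 1
    MONITORING = 2


class Comorbidity(_Answer):
    """Question 2 — comorbidity stratum, ordinal from none to advanced disease."""

    NONE = 1
    COMPENSATED = 2
    DECOMPENSATED = 3
    ADVANCED = 4


class Functionality(_Answer):
    """Question 3 — previous functionality by Katz ADL; SEVERE = at most 2 ADLs."""

    INDEPENDENT = 1
    PARTIAL = 2
    SEVERE = 3


class Prognosis(_Answer):
    """Question 4 — physician's intuitive prognosis."""

    SURVIVOR_NO_DISABILITY = 1
    SURVIVOR_WITH_DISABILITY = 2
    NONSURVIVOR = 3


class PriorityClass(enum.IntEnum):
    """SCCM priority stratum; 1 = highest priority, 4 = generally not appropriate."""

    P1 = 1
    P2 = 2
    P3 = 3
    P4 = 4

    @property
    def description(self) -> str:
        return _PRIORITY_LABELS[self]


_PRIORITY_LABELS = {
    PriorityClass.P1: "critically ill, needs intensive treatment and monitoring",
    PriorityClass.P2: "requires intensive monitoring, may need immediate intervention",
    PriorityClass.P3: "critically ill with reduced likelihood of recovery",
    PriorityClass.P4: "generally not appropriate for ICU admission",
}

_QUESTION_FIELDS = ("request_type", "comorbidity", "functionality", "prognosis")
_QUESTION_TYPES = (RequestType, Comorbidity, Functionality, Prognosis)


@dataclass(frozen=True)
class TriageAssessment:
    """One admission request's answers to the four closed questions.

    Fields accept enum members, integer codes, or mnemonic strings
    (case-insensitive); they are normalized to enum members on construction.
    All four answers must be present.
    """

    request_type: RequestType
    comorbidity: Comorbidity
    functionality: Functionality
    prognosis: Prognosis

    def __post_init__(self) -> None:
        for field, typ in zip(_QUESTION_FIELDS, _QUESTION_TYPES):
            object.__setattr__(self, field, typ.coerce(getattr(self, field), field))

    @property
    def is_clinically_implausible(self) -> bool:
        """True for combinations the rule set accepts but flags as implausible.

        Severe ADL dependency without any comorbidity routes to priority 1/2
        under a literal reading of the rules; it is flagged rather than
        rejected because the questionnaire does not forbid it.
        """
        return (
            self.comorbidity is Comorbidity.NONE
            and self.functionality is Functionality.SEVERE
        )

    def codes(self) -> tuple[int, int, int, int]:
        """The four answers as the questionnaire's integer codes."""
        return (
            int(self.request_type),
            int(self.comorbidity),
            int(self.functionality),
            int(self.prognosis),
        )


def classify_priority(
    assessment: TriageAssessment, *, discussion_variant: bool = False
) -> PriorityClass:
    """Assign the SCCM priority class for a completed assessment.

    Rule precedence is priority-4 conditions, then priority-3 conditions,
    then 1 vs 2 by the request type; with the stated conditions the rules are
    mutually exclusive, so precedence is a safety net only.

    Parameters
    ----------
    assessment:
        The four answers; any object with the four answer attributes is
        coerced through :class:`TriageAssessment`.
    discussion_variant:
        Off by default.  When on, a prognosis of death additionally upgrades
        severe-dependency priority-3 patients to priority 4.  The primary rule
        set restricts the prognosis question's effect to advanced disease with
        preserved functionality; the variant reflects an alternative, broader
        reading of the question's reach and exists only to make that textual
        ambiguity explorable.
    """
    if not isinstance(assessment, TriageAssessment):
        assessment = TriageAssessment(
            getattr(assessment, "request_type", None),
            getattr(assessment, "comorbidity", None),
            getattr(assessment, "functionality", None),
            getattr(assessment, "prognosis", None),
        )
    q2, q3, q4 = assessment.comorbidity, assessment.functionality, assessment.prognosis

    priority4 = (
        (q2 is Comorbidity.DECOMPENSATED and q3 is Functionality.SEVERE)
        or (
            q2 is Comorbidity.ADVANCED
            and q3 in (Functionality.PARTIAL, Functionality.SEVERE)
        )
        or (
            q2 is Comorbidity.ADVANCED
            and q3 is Functionality.INDEPENDENT
            and q4 is Prognosis.NONSURVIVOR
        )
    )
    if priority4:
        return PriorityClass.P4

    priority3 = (
        (q2 is Comorbidity.COMPENSATED and q3 is Functionality.SEVERE)
        or (q2 is Comorbidity.DECOMPENSATED and q3 is Functionality.PARTIAL)
        or (
            q2 is Comorbidity.ADVANCED
            and q3 is Functionality.INDEPENDENT
            and q4 is not Prognosis.NONSURVIVOR
        )
    )
    if priority3:
        if discussion_variant and q3 is Functionality.SEVERE and q4 is Prognosis.NONSURVIVOR:
            return PriorityClass.P4
        return PriorityClass.P3

    if assessment.request_type is RequestType.INTERVENTION:
        return PriorityClass.P1
    return PriorityClass.P2


def iter_assessments() -> Iterator[TriageAssessment]:
    """All 72 answer combinations in question-major, code order (Q1,Q2,Q3,Q4)."""
    for q1, q2, q3, q4 in itertools.product(
        RequestType, Comorbidity, Functionality, Prognosis
    ):
        yield TriageAssessment(q1, q2, q3, q4)


def enumerate_decision_table(
    *, discussion_variant: bool = False
) -> list[tuple[TriageAssessment, PriorityClass]]:
    """Exhaustive audit of the rule set: all 72 combinations with their priority.

    The order is stable: Q1 outermost, Q4 innermost, each in ascending code
    order.
    """
    return [
        (a, classify_priority(a, discussion_variant=discussion_variant))
        for a in iter_assessments()
    ]


def decision_table_counts(*, discussion_variant: bool = False) -> dict[int, int]:
    """Number of answer combinations assigned to each priority (keys 1-4)."""
    counts = {p.value: 0 for p in PriorityClass}
    for _, priority in enumerate_decision_table(discussion_variant=discussion_variant):
        counts[priority.value] += 1
    return counts


def classify_many(
    assessments: Iterable[TriageAssessment], *, discussion_variant: bool = False
) -> list[PriorityClass]:
    """Classify a sequence of assessments in order."""
    return [classify_priority(a, discussion_variant=discussion_variant) for a in assessments]
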