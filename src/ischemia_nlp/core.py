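"""Shared document and span data model used by every pipeline stage.

Offsets are 0-based, half-open character intervals into a single source
text, the convention of most text-annotation tooling. Mentions carry the
attribute flags that the context engine sets and the classifier reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class TargetCategory(str, Enum):
    """Clinical concept classes a target rule can match.

    ISCHEMIA_TERM and REVERSIBILITY_TERM are intrinsically positive
    evidence of ischemia; a PERFUSION_FINDING (defect, reduced counts)
    is positive only when a reversibility cue attaches to it.
    """

    ISCHEMIA_TERM = "ISCHEMIA_TERM"
    REVERSIBILITY_TERM = "REVERSIBILITY_TERM"
    PERFUSION_FINDING = "PERFUSION_FINDING"


class ModifierCategory(str, Enum):
    """Context-cue classes.

    NEGATED_EXISTENCE, FIXED and ARTIFACT refute a finding (fixed defects
    are scar, artifacts are attenuation); REVERSIBLE promotes a perfusion
    finding to ischemia evidence; UNCERTAIN hedges without refuting;
    TERMINATE cuts modifier scopes at clause boundaries.
    """

    NEGATED_EXISTENCE = "NEGATED_EXISTENCE"
    FIXED = "FIXED"
    ARTIFACT = "ARTIFACT"
    REVERSIBLE = "REVERSIBLE"
    UNCERTAIN = "UNCERTAIN"
    TERMINATE = "TERMINATE"


class Direction(str, Enum):
    FORWARD = "FORWARD"
    BACKWARD = "BACKWARD"
    BIDIRECTIONAL = "BIDIRECTIONAL"


@dataclass(frozen=True)
class Span:
    """A half-open character interval [start, end) with its covered text."""

    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span offsets [{self.start}, {self.end})")
        if len(self.text) != self.end - self.start:
            raise ValueError(
                f"span text length {len(self.text)} != end - start "
                f"({self.end - self.start})"
            )

    @classmethod
    def from_text(cls, source: str, start: int, end: int) -> "Span":
        if end > len(source):
            raise ValueError(f"span end {end} beyond text length {len(source)}")
        return cls(start, end, source[start:end])


def span_overlaps(a: Span, b: Span) -> bool:
    """True iff the half-open intervals of ``a`` and ``b`` intersect."""
    return a.start < b.end and b.start < a.end


def span_contains(outer: Span, inner: Span) -> bool:
    """True iff ``inner`` lies entirely within ``outer`` (identity counts)."""
    return outer.start <= inner.start and inner.end <= outer.end


@dataclass(frozen=True)
class ReportDocument:
    """One cardiac stress test report.

    At least one of ``impression_text`` / ``full_report_text`` must be
    non-empty for the document to be classifiable. ``gold_label`` is
    optional so the same type serves annotation, classification and
    synthetic-generation roles (1 = ischemia).
    """

    report_id: str
    impression_text: str = ""
    full_report_text: str = ""
    site_id: str = ""
    gold_label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if self.gold_label not in (None, 0, 1):
            raise ValueError(f"gold_label must be 0/1/None, got {self.gold_label!r}")


@dataclass(frozen=True)
class Sentence:
    span: Span
    index: int


@dataclass(frozen=True)
class MentionAttributes:
    """Flags set on a target mention by the context engine.

    Flags accumulate independently; precedence (refutation dominating
    positivity) is applied at polarity time by the classifier.
    """

    is_negated: bool = False
    is_fixed: bool = False
    is_artifact: bool = False
    is_uncertain: bool = False
    has_reversible_modifier: bool = False


@dataclass(frozen=True)
class TargetMention:
    span: Span
    category: TargetCategory
    rule_id: str
    sentence_index: int
    attributes: MentionAttributes = field(default_factory=MentionAttributes)

    def with_attributes(self, **flags: bool) -> "TargetMention":
        return replace(self, attributes=replace(self.attributes, **flags))


@dataclass(frozen=True)
class ModifierMention:
    span: Span
    category: ModifierCategory
    direction: Direction
    rule_id: str
    scope: Optional[Span] = None  # set by resolve_scope; None until then

    def with_scope(self, scope: Optional[Span]) -> "ModifierMention":
        return replace(self, scope=scope)


@dataclass(frozen=True)
class DocumentClassification:
    """The system's output record: binary ischemia indicator plus the
    text excerpt of the targets and modifiers used in the determination."""

    report_id: str
    ischemia: int
    evidence: str
    mentions: tuple[TargetMention, ...] = ()
    source_text_provenance: str = ""


class UnclassifiableDocumentError(ValueError):
    """Raised when a document has no usable text under the chosen policy."""

    def __init__(self, report_id: str, message: str):
        self.report_id = report_id
        super().__init__(f"report {report_id!r}: {message}")
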