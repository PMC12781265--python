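"""Document-level ischemia classification.

A mention is positive evidence when it names ischemia or reversibility
outright, or is a perfusion finding promoted by a reversibility cue, and
no refuting modifier (negation, fixed, artifact) governs it; hedges never
change the outcome. The document indicator is the strict any-positive
disjunction over mentions: ischemia in any myocardial territory makes the
report positive regardless of how many territories are negative, so
positive evidence outweighs negative. A document with no target mentions
at all is a negative screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .context import contributing_modifiers, process_sentence
from .core import (
    DocumentClassification,
    ModifierMention,
    ReportDocument,
    TargetCategory,
    TargetMention,
    UnclassifiableDocumentError,
)
from .rules import Rulebook, default_ischemia_rulebook
from .textproc import TextPolicy, segment_sentences, select_analysis_text, tokenize_sentence

logger = logging.getLogger(__name__)


class Polarity(str, Enum):
    POSITIVE = "POSITIVE"
    NOT_POSITIVE = "NOT_POSITIVE"


def mention_polarity(m: TargetMention) -> Polarity:
    """Final polarity of one attributed target mention."""
    a = m.attributes
    refuted = a.is_negated or a.is_fixed or a.is_artifact
    intrinsic = m.category in (
        TargetCategory.ISCHEMIA_TERM,
        TargetCategory.REVERSIBILITY_TERM,
    )
    if (intrinsic or a.has_reversible_modifier) and not refuted:
        return Polarity.POSITIVE
    return Polarity.NOT_POSITIVE


def _evidence_fragment(m: TargetMention, mods: Sequence[ModifierMention]) -> str:
    if mods:
        names = ", ".join(mod.span.text for mod in mods)
        return f"{m.span.text} [{m.category.value}; modifiers: {names}]"
    return f"{m.span.text} [{m.category.value}]"


def classify_document(
    doc: ReportDocument,
    rb: Optional[Rulebook] = None,
    policy: TextPolicy = TextPolicy.IMPRESSION_THEN_FULL_IMPRESSION_SECTION,
) -> DocumentClassification:
    """Run the full pipeline on one report and return its classification.

    Deterministic for a fixed (document, rulebook, policy). Raises
    :class:`UnclassifiableDocumentError` when the policy yields no text.
    """
    if rb is None:
        rb = default_ischemia_rulebook()
    text, provenance = select_analysis_text(doc, policy, rb.sections)

    mentions: list[TargetMention] = []
    mention_mods: list[list[ModifierMention]] = []
    for sentence in segment_sentences(text):
        tokens = tokenize_sentence(text, sentence)
        targets, modifiers = process_sentence(
            tokens, sentence.index, rb.targets, rb.contexts
        )
        for t in targets:
            mentions.append(t)
            mention_mods.append(contributing_modifiers(t, modifiers))

    for m in mentions:
        if m.attributes.has_reversible_modifier and (
            m.attributes.is_fixed or m.attributes.is_artifact or m.attributes.is_negated
        ):
            logger.info(
                "report %s: mention %r carries both reversible and refuting "
                "modifiers; resolved as refuted",
                doc.report_id,
                m.span.text,
            )

    polarities = [mention_polarity(m) for m in mentions]
    ischemia = int(any(p is Polarity.POSITIVE for p in polarities))
    if ischemia:
        decisive = [
            (m, mods)
            for m, mods, p in zip(mentions, mention_mods, polarities)
            if p is Polarity.POSITIVE
        ]
    else:
        decisive = list(zip(mentions, mention_mods))
    evidence = " | ".join(_evidence_fragment(m, mods) for m, mods in decisive)

    return DocumentClassification(
        report_id=doc.report_id,
        ischemia=ischemia,
        evidence=evidence,
        mentions=tuple(mentions),
        source_text_provenance=provenance,
    )


@dataclass(frozen=True)
class CorpusSummary:
    n_total: int
    n_classified: int
    n_errored: int
    n_positive: int
    errors: tuple[tuple[str, str], ...] = ()

    @property
    def prevalence(self) -> Optional[float]:
        if self.n_classified == 0:
            return None
        return self.n_positive / self.n_classified


def classify_corpus(
    docs: Sequence[ReportDocument],
    rb: Optional[Rulebook] = None,
    policy: TextPolicy = TextPolicy.IMPRESSION_THEN_FULL_IMPRESSION_SECTION,
) -> tuple[list[DocumentClassification], CorpusSummary]:
    """Classify every document, aggregating per-document errors into the
    summary rather than aborting the batch; order-preserving."""
    if rb is None:
        rb = default_ischemia_rulebook()
    results: list[DocumentClassification] = []
    errors: list[tuple[str, str]] = []
    for doc in docs:
        try:
            results.append(classify_document(doc, rb, policy))
        except UnclassifiableDocumentError as exc:
            errors.append((doc.report_id, str(exc)))
    summary = CorpusSummary(
        n_total=len(docs),
        n_classified=len(results),
        n_errored=len(errors),
        n_positive=sum(r.ischemia for r in results),
        errors=tuple(errors),
    )
    return results, summary
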