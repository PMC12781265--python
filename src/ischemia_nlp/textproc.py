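"""Deterministic text processing: sentences, tokens, sections, text policy.

Impressions are short, telegraphic and list-structured, so segmentation is
rule-based rather than statistical: boundaries fall at newline runs and at
sentence-final punctuation followed by whitespace and an uppercase letter
or digit, with enumerated-list markers ("1.", "2.") exempted. Tokens carry
character offsets so every downstream mention maps back into the source.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .core import ReportDocument, Sentence, Span, UnclassifiableDocumentError
from .rules import SectionRule

# Punctuation detached as separate tokens.
_TOKEN_RE = re.compile(r"[^\s,.;:()/]+|[,.;:()/]")
# Sentence-final punctuation followed by whitespace and an uppercase/digit.
_BOUNDARY_RE = re.compile(r"[.?!]+(?=\s+[A-Z0-9])")
_NEWLINE_RUN_RE = re.compile(r"\n+")
_LIST_MARKER_RE = re.compile(r"^\W*\d+$")


@dataclass(frozen=True)
class Token:
    span: Span

    @property
    def norm(self) -> str:
        return self.span.text.lower()


@dataclass(frozen=True)
class SectionSpan:
    """A detected report section; ``span`` runs from the header to the next
    header (or end of text) so that sections partition the post-preamble
    text. ``body_span`` excludes the header line's label and separator."""

    span: Span
    section_category: str
    header_span: Optional[Span]
    body_span: Optional[Span]


class TextPolicy(str, Enum):
    """Which text field feeds the classifier.

    The system is designed to run on impression text, which is less prone
    to false positives than full reports; the fallback policy rescues
    documents whose impression field is empty but whose full report carries
    an IMPRESSION section.
    """

    IMPRESSION_ONLY = "IMPRESSION_ONLY"
    IMPRESSION_THEN_FULL_IMPRESSION_SECTION = "IMPRESSION_THEN_FULL_IMPRESSION_SECTION"
    FULL = "FULL"


def segment_sentences(text: str) -> list[Sentence]:
    """Split ``text`` into ordered, non-overlapping sentences."""
    boundaries: list[tuple[int, int]] = []  # (chunk_start, chunk_end)
    pos = 0
    for m in _NEWLINE_RUN_RE.finditer(text):
        boundaries.append((pos, m.start()))
        pos = m.end()
    boundaries.append((pos, len(text)))

    sentences: list[Sentence] = []
    for chunk_start, chunk_end in boundaries:
        start = chunk_start
        for m in _BOUNDARY_RE.finditer(text, chunk_start, chunk_end):
            head = text[start : m.start()].strip()
            if _LIST_MARKER_RE.match(head):
                continue  # "1." style list marker, not a sentence end
            _append_sentence(sentences, text, start, m.end())
            start = m.end()
        _append_sentence(sentences, text, start, chunk_end)
    return sentences


def _append_sentence(out: list[Sentence], text: str, start: int, end: int) -> None:
    seg = text[start:end]
    lead = len(seg) - len(seg.lstrip())
    trail = len(seg) - len(seg.rstrip())
    s, e = start + lead, end - trail
    if s < e:
        out.append(Sentence(span=Span.from_text(text, s, e), index=len(out)))


def tokenize(sentence_text: str, offset: int = 0) -> list[Token]:
    """Tokenize on whitespace with punctuation ``,.;:()/`` detached.

    ``offset`` shifts spans so tokens of a sentence address the full
    document text rather than the sentence substring.
    """
    return [
        Token(Span(m.start() + offset, m.end() + offset, m.group()))
        for m in _TOKEN_RE.finditer(sentence_text)
    ]


def tokenize_sentence(text: str, sentence: Sentence) -> list[Token]:
    return tokenize(sentence.span.text, offset=sentence.span.start)


def _match_header(line: str, rules: Sequence[SectionRule]) -> Optional[tuple[SectionRule, int, int]]:
    """Return (rule, header_len, body_offset_in_line) for the first rule whose
    header matches at line start, else None. A header must be followed by an
    optional ``:`` or ``-`` separator, or end the line — bare prose that merely
    starts with a header word does not count."""
    stripped = line.rstrip()
    low = stripped.lower()
    for rule in rules:
        pat = rule.header_pattern.lower().rstrip(":")
        if not low.startswith(pat):
            continue
        rest = stripped[len(pat) :]
        m = re.match(r"\s*[:\-–—]\s*", rest)
        if m:
            return rule, len(pat), len(pat) + m.end()
        if rest.strip() == "":
            return rule, len(pat), len(stripped)
    return None


def detect_sections(text: str, rules: Sequence[SectionRule]) -> list[SectionSpan]:
    """Find line-initial section headers and partition the text.

    Text before the first header forms an implicit PREAMBLE section; with
    no headers at all the whole text is PREAMBLE.
    """
    headers: list[tuple[int, int, int, str]] = []  # (line_start, hdr_end, body_start, category)
    pos = 0
    for line in text.splitlines(keepends=True):
        bare = line.rstrip("\n")
        hit = _match_header(bare, rules)
        if hit:
            rule, hdr_len, body_off = hit
            headers.append((pos, pos + hdr_len, pos + body_off, rule.section_category))
        pos += len(line)

    sections: list[SectionSpan] = []
    if not headers or headers[0][0] > 0:
        pre_end = headers[0][0] if headers else len(text)
        if text[:pre_end].strip():
            sections.append(
                SectionSpan(
                    span=Span.from_text(text, 0, pre_end),
                    section_category="PREAMBLE",
                    header_span=None,
                    body_span=Span.from_text(text, 0, pre_end),
                )
            )
    for i, (h_start, h_end, b_start, category) in enumerate(headers):
        sec_end = headers[i + 1][0] if i + 1 < len(headers) else len(text)
        body = text[b_start:sec_end]
        lead = len(body) - len(body.lstrip())
        trail = len(body) - len(body.rstrip())
        bs, be = b_start + lead, sec_end - trail
        sections.append(
            SectionSpan(
                span=Span.from_text(text, h_start, sec_end),
                section_category=category,
                header_span=Span.from_text(text, h_start, h_end),
                body_span=Span.from_text(text, bs, be) if bs < be else None,
            )
        )
    return sections


def select_analysis_text(
    doc: ReportDocument,
    policy: TextPolicy = TextPolicy.IMPRESSION_THEN_FULL_IMPRESSION_SECTION,
    section_rules: Sequence[SectionRule] = (),
) -> tuple[str, str]:
    """Return ``(analysis_text, provenance)`` under the selection policy.

    Provenance is ``"impression"``, ``"full_report_impression_section"`` or
    ``"full_report"``. Raises :class:`UnclassifiableDocumentError` when the
    policy yields no text.
    """
    if policy is TextPolicy.FULL:
        if doc.full_report_text.strip():
            return doc.full_report_text, "full_report"
        raise UnclassifiableDocumentError(doc.report_id, "full report text is empty")

    if doc.impression_text.strip():
        return doc.impression_text, "impression"

    if policy is TextPolicy.IMPRESSION_THEN_FULL_IMPRESSION_SECTION:
        if doc.full_report_text.strip():
            for sec in detect_sections(doc.full_report_text, section_rules):
                if sec.section_category == "IMPRESSION" and sec.body_span is not None:
                    return sec.body_span.text, "full_report_impression_section"
        raise UnclassifiableDocumentError(
            doc.report_id,
            "impression text is empty and no IMPRESSION section found in full report",
        )
    raise UnclassifiableDocumentError(doc.report_id, "impression text is empty")
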