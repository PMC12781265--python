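"""Token-sequence pattern matching for target and context rules.

Patterns are case-insensitive literal token sequences with optional
single-token wildcards (``*``). Matching operates on token norms, never on
raw characters, so ``ischemia`` cannot fire inside ``ischemiaX``. When
candidate matches overlap, the longest wins; among equal lengths the
leftmost, then the earlier-listed rule. The survivors never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import ModifierMention, Span, TargetMention
from .rules import ContextRule, TargetRule
from .textproc import Token, tokenize

WILDCARD = "*"


@dataclass(frozen=True)
class TokenMatch:
    """A rule firing on a contiguous token run [start, end)."""

    start: int  # token index, inclusive
    end: int  # token index, exclusive
    rule_index: int

    @property
    def length(self) -> int:
        return self.end - self.start


def pattern_tokens(pattern: str) -> list[str]:
    """Normalize a rule pattern with the same tokenizer used on text."""
    return [t.norm for t in tokenize(pattern)]


def enumerate_matches(norms: Sequence[str], patterns: Sequence[list[str]]) -> list[TokenMatch]:
    """Every (rule, position) firing, unfiltered. The brute-force half of
    the matcher; overlap resolution happens in :func:`resolve_overlaps`."""
    out: list[TokenMatch] = []
    for rule_index, pat in enumerate(patterns):
        if not pat:
            continue
        for start in range(len(norms) - len(pat) + 1):
            if all(p == WILDCARD or p == norms[start + k] for k, p in enumerate(pat)):
                out.append(TokenMatch(start, start + len(pat), rule_index))
    return out


def resolve_overlaps(candidates: Sequence[TokenMatch]) -> list[TokenMatch]:
    """Longest match wins; ties broken leftmost, then earlier-listed rule.

    Returns the surviving, mutually non-overlapping matches ordered by
    start position.
    """
    chosen: list[TokenMatch] = []
    for cand in sorted(candidates, key=lambda m: (-m.length, m.start, m.rule_index)):
        if all(cand.end <= c.start or c.end <= cand.start for c in chosen):
            chosen.append(cand)
    return sorted(chosen, key=lambda m: m.start)


def match_token_runs(tokens: Sequence[Token], patterns: Sequence[list[str]]) -> list[TokenMatch]:
    norms = [t.norm for t in tokens]
    return resolve_overlaps(enumerate_matches(norms, patterns))


def _run_span(tokens: Sequence[Token], m: TokenMatch) -> Span:
    first, last = tokens[m.start], tokens[m.end - 1]
    # Reconstruct the covering source slice, separators included.
    length = last.span.end - first.span.start
    text_parts: list[str] = []
    pos = first.span.start
    for tok in tokens[m.start : m.end]:
        text_parts.append(" " * (tok.span.start - pos))
        text_parts.append(tok.span.text)
        pos = tok.span.end
    text = "".join(text_parts)
    assert len(text) == length
    return Span(first.span.start, last.span.end, text)


def match_targets(
    tokens: Sequence[Token], sentence_index: int, rules: Sequence[TargetRule]
) -> list[TargetMention]:
    """Find all target-concept mentions in one tokenized sentence."""
    patterns = [pattern_tokens(r.pattern) for r in rules]
    return [
        TargetMention(
            span=_run_span(tokens, m),
            category=rules[m.rule_index].category,
            rule_id=rules[m.rule_index].rule_id,
            sentence_index=sentence_index,
        )
        for m in match_token_runs(tokens, patterns)
    ]


def match_modifiers(
    tokens: Sequence[Token], rules: Sequence[ContextRule]
) -> list[ModifierMention]:
    """Find all context-cue mentions (including TERMINATE markers) in one
    tokenized sentence; scopes are not yet assigned."""
    from .core import Direction, ModifierCategory

    patterns = [pattern_tokens(r.pattern) for r in rules]
    out: list[ModifierMention] = []
    for m in match_token_runs(tokens, patterns):
        rule = rules[m.rule_index]
        direction = rule.direction
        if rule.category is ModifierCategory.TERMINATE and direction is None:
            direction = Direction.BIDIRECTIONAL
        out.append(
            ModifierMention(
                span=_run_span(tokens, m),
                category=rule.category,
                direction=direction,
                rule_id=rule.rule_id,
            )
        )
    return out
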