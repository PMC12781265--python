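"""ConText-style modifier scoping and attribute assignment.

Each context cue governs a directional region of its own sentence: FORWARD
scopes run from the cue toward the sentence end, BACKWARD toward the
sentence start, BIDIRECTIONAL both ways. A scope is cut by the nearest
TERMINATE cue (clause conjunctions such as "and"/"but") and capped by the
rule's ``max_scope_tokens``; it never crosses a sentence boundary. A target
mention acquires the cue's attribute flag when its span intersects the
resolved scope. Flags accumulate independently — refutation precedence is
the classifier's job.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .core import (
    Direction,
    ModifierCategory,
    ModifierMention,
    Span,
    TargetCategory,
    TargetMention,
    span_overlaps,
)
from .matcher import match_modifiers, match_targets
from .rules import DEFAULT_MAX_SCOPE_TOKENS, ContextRule, TargetRule
from .textproc import Token

#: How a modifier category lands on a target mention's attributes.
CATEGORY_TO_FLAG = {
    ModifierCategory.NEGATED_EXISTENCE: "is_negated",
    ModifierCategory.FIXED: "is_fixed",
    ModifierCategory.ARTIFACT: "is_artifact",
    ModifierCategory.UNCERTAIN: "is_uncertain",
    ModifierCategory.REVERSIBLE: "has_reversible_modifier",
}

#: Maximum whitespace gap (in characters) for the reversible-adjacency rule.
_ADJACENCY_GAP = 1


def _token_range(tokens: Sequence[Token], span: Span) -> tuple[int, int]:
    """Token indices [first, last) of the tokens covered by a char span."""
    idx = [i for i, t in enumerate(tokens) if span_overlaps(t.span, span)]
    if not idx:
        raise ValueError(f"span {span.start}:{span.end} covers no token")
    return idx[0], idx[-1] + 1


def _range_span(tokens: Sequence[Token], first: int, last: int) -> Optional[Span]:
    if first >= last:
        return None
    a, b = tokens[first].span, tokens[last - 1].span
    joined: list[str] = []
    pos = a.start
    for tok in tokens[first:last]:
        joined.append(" " * (tok.span.start - pos))
        joined.append(tok.span.text)
        pos = tok.span.end
    return Span(a.start, b.end, "".join(joined))


def resolve_scope(
    modifier: ModifierMention,
    tokens: Sequence[Token],
    terminators: Sequence[ModifierMention] = (),
    max_scope_tokens: Optional[int] = DEFAULT_MAX_SCOPE_TOKENS,
) -> ModifierMention:
    """Attach the governed region to ``modifier`` within its sentence.

    ``tokens`` are the modifier's sentence; ``terminators`` the TERMINATE
    mentions of the same sentence. ``max_scope_tokens`` of None means the
    scope is bounded only by the sentence and terminators. A scope that
    would be empty (e.g. a FORWARD cue in sentence-final position) is None.
    """
    if modifier.category is ModifierCategory.TERMINATE:
        return modifier.with_scope(None)
    m_first, m_last = _token_range(tokens, modifier.span)
    cut_points = sorted(_token_range(tokens, t.span)[0] for t in terminators)
    cut_ends = sorted(_token_range(tokens, t.span)[1] for t in terminators)

    lo, hi = m_first, m_last  # degenerate (empty) scope by default
    if modifier.direction in (Direction.FORWARD, Direction.BIDIRECTIONAL):
        hi = len(tokens)
        for cp in cut_points:
            if cp >= m_last:
                hi = min(hi, cp)
                break
        if max_scope_tokens is not None:
            hi = min(hi, m_last + max_scope_tokens)
        hi = max(hi, m_last)
    if modifier.direction in (Direction.BACKWARD, Direction.BIDIRECTIONAL):
        lo = 0
        for ce in reversed(cut_ends):
            if ce <= m_first:
                lo = max(lo, ce)
                break
        if max_scope_tokens is not None:
            lo = max(lo, m_first - max_scope_tokens)
        lo = min(lo, m_first)

    if modifier.direction is Direction.FORWARD:
        scope = _range_span(tokens, m_last, hi)
    elif modifier.direction is Direction.BACKWARD:
        scope = _range_span(tokens, lo, m_first)
    else:  # BIDIRECTIONAL: union of both reaches, modifier tokens included
        scope = _range_span(tokens, lo, hi)
    return modifier.with_scope(scope)


def _adjacent(a: Span, b: Span) -> bool:
    gap = b.start - a.end if b.start >= a.end else a.start - b.end
    return 0 <= gap <= _ADJACENCY_GAP


def modifier_governs(target: TargetMention, mod: ModifierMention) -> bool:
    """Does ``mod``'s resolved scope reach ``target``?

    The REVERSIBLE category additionally binds to a perfusion finding it
    is immediately adjacent to ("reversible defect"), guaranteeing the cue
    reaches its head noun even under aggressive termination settings.
    """
    if mod.category not in CATEGORY_TO_FLAG:
        return False
    if mod.scope is not None and span_overlaps(target.span, mod.scope):
        return True
    if (
        mod.category is ModifierCategory.REVERSIBLE
        and target.category is TargetCategory.PERFUSION_FINDING
    ):
        return _adjacent(mod.span, target.span) or span_overlaps(mod.span, target.span)
    return False


def contributing_modifiers(
    target: TargetMention, modifiers: Sequence[ModifierMention]
) -> list[ModifierMention]:
    return [m for m in modifiers if modifier_governs(target, m)]


def apply_context(
    targets: Sequence[TargetMention], modifiers: Sequence[ModifierMention]
) -> list[TargetMention]:
    """Set attribute flags on each target governed by a modifier scope."""
    out: list[TargetMention] = []
    for target in targets:
        flags: dict[str, bool] = {}
        for mod in contributing_modifiers(target, modifiers):
            flags[CATEGORY_TO_FLAG[mod.category]] = True
        out.append(target.with_attributes(**flags) if flags else target)
    return out


def process_sentence(
    tokens: Sequence[Token],
    sentence_index: int,
    target_rules: Sequence[TargetRule],
    context_rules: Sequence[ContextRule],
) -> tuple[list[TargetMention], list[ModifierMention]]:
    """Match targets and modifiers in one sentence, resolve scopes and
    apply them; returns (attributed targets, scoped modifiers)."""
    targets = match_targets(tokens, sentence_index, target_rules)
    modifiers = match_modifiers(tokens, context_rules)
    terminators = [m for m in modifiers if m.category is ModifierCategory.TERMINATE]
    max_scope = {r.rule_id: r.max_scope_tokens for r in context_rules}
    scoped = [
        resolve_scope(
            m, tokens, terminators, max_scope.get(m.rule_id, DEFAULT_MAX_SCOPE_TOKENS)
        )
        for m in modifiers
    ]
    return apply_context(targets, scoped), scoped
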