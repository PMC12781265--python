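import random

import pytest

from ischemia_nlp import process_sentence, resolve_scope, tokenize
from ischemia_nlp.context import CATEGORY_TO_FLAG
from ischemia_nlp.core import Direction, ModifierCategory, TargetCategory
from ischemia_nlp.matcher import match_modifiers
from ischemia_nlp.rules import ContextRule, TargetRule

from .conftest import random_context_setup
from .oracles import governed_token_indices, oracle_select_matches


def _scoped_modifiers(text, context_rules):
    tokens = tokenize(text)
    mods = match_modifiers(tokens, context_rules)
    terms = [m for m in mods if m.category is ModifierCategory.TERMINATE]
    by_id = {r.rule_id: r for r in context_rules}
    return tokens, [
        resolve_scope(m, tokens, terms, by_id[m.rule_id].max_scope_tokens)
        for m in mods
    ]


def test_detects_expected_modifiers(rulebook):
    tokens = tokenize("Small, primarily fixed defect and a mild, reversible defect")
    mods = match_modifiers(tokens, rulebook.contexts)
    got = {(m.span.text, m.category.value) for m in mods}
    assert ("primarily fixed", "FIXED") in got
    assert ("and", "TERMINATE") in got
    assert ("reversible", "REVERSIBLE") in got


def test_no_modifiers_in_clean_sentence(rulebook):
    assert match_modifiers(tokenize("Normal perfusion"), rulebook.contexts) == []


def test_terminator_cuts_forward_scope(rulebook):
    text = "Small, primarily fixed defect and a mild, reversible defect"
    _, mods = _scoped_modifiers(text, rulebook.contexts)
    fixed = next(m for m in mods if m.category is ModifierCategory.FIXED)
    assert fixed.scope is not None
    assert fixed.scope.end <= text.index(" and")  # only the first defect
    assert "defect" in fixed.scope.text


def test_forward_scope_reaches_following_target(rulebook):
    text = "Large perfusion defect without evidence of reversibility"
    _, mods = _scoped_modifiers(text, rulebook.contexts)
    neg = next(m for m in mods if m.category is ModifierCategory.NEGATED_EXISTENCE)
    assert "reversibility" in neg.scope.text


def test_sentence_final_forward_modifier_has_empty_scope():
    rules = [ContextRule(rule_id="c1", pattern="likely",
                         category=ModifierCategory.UNCERTAIN,
                         direction=Direction.FORWARD)]
    _, mods = _scoped_modifiers("Recurrence considered likely", rules)
    assert mods[0].scope is None


def test_scopes_stay_within_sentence_and_respect_direction(rulebook):
    for text in (
        "Defect resolves on prone imaging, consistent with attenuation artifact",
        "Negative for reversible ischemia",
        "Moderate size, mildly reduced counts in anterior wall which is reversible",
    ):
        _, mods = _scoped_modifiers(text, rulebook.contexts)
        for m in mods:
            if m.scope is None:
                continue
            assert 0 <= m.scope.start and m.scope.end <= len(text)
            if m.direction is Direction.FORWARD:
                assert m.scope.start >= m.span.end
            if m.direction is Direction.BACKWARD:
                assert m.scope.end <= m.span.start


@pytest.mark.parametrize(
    "text,target_text,flag",
    [
        ("There is a small area of fixed ischemia", "ischemia", "is_fixed"),
        ("Moderate size, mildly reduced counts in anterior wall which is reversible",
         "reduced counts", "has_reversible_modifier"),
        ("Negative for reversible ischemia", "reversible ischemia", "is_negated"),
        ("Small perfusion abnormality is favored to be artifactual",
         "perfusion abnormality", "is_artifact"),
    ],
)
def test_attribute_assignment(rulebook, text, target_text, flag):
    tokens = tokenize(text)
    targets, _ = process_sentence(tokens, 0, rulebook.targets, rulebook.contexts)
    mention = next(t for t in targets if t.span.text == target_text)
    assert getattr(mention.attributes, flag) is True


def test_targets_without_modifiers_keep_default_attributes(rulebook):
    tokens = tokenize("Moderate area of reversibility")
    targets, _ = process_sentence(tokens, 0, rulebook.targets, rulebook.contexts)
    (mention,) = targets
    assert mention.attributes == type(mention.attributes)()


def test_inserting_terminator_always_removes_effect():
    """Termination property: a TERMINATE token between a FORWARD cue and its
    target strips the cue's attribute."""
    target = [TargetRule(rule_id="t", pattern="defect",
                         category=TargetCategory.PERFUSION_FINDING)]
    ctx = [
        ContextRule(rule_id="c", pattern="fixed", category=ModifierCategory.FIXED,
                    direction=Direction.FORWARD),
        ContextRule(rule_id="x", pattern="but", category=ModifierCategory.TERMINATE),
    ]
    with_scope, _ = process_sentence(tokenize("fixed small defect"), 0, target, ctx)
    assert with_scope[0].attributes.is_fixed
    cut, _ = process_sentence(tokenize("fixed small but defect"), 0, target, ctx)
    assert not cut[0].attributes.is_fixed


def _oracle_attributes(words, target_rules, context_rules):
    """Brute-force attribute assignment by direct token-set membership."""
    tpats = [r.pattern.split() for r in target_rules]
    cpats = [r.pattern.split() for r in context_rules]
    tsel = oracle_select_matches(words, tpats)
    csel = oracle_select_matches(words, cpats)
    term_ranges = [
        (s, e) for s, e, ri in csel
        if context_rules[ri].category is ModifierCategory.TERMINATE
    ]
    expected = []
    for ts, te, tri in tsel:
        flags = {v: False for v in CATEGORY_TO_FLAG.values()}
        for ms, me, mri in csel:
            rule = context_rules[mri]
            if rule.category is ModifierCategory.TERMINATE:
                continue
            governed = governed_token_indices(
                len(words), (ms, me), rule.direction.value,
                rule.max_scope_tokens, term_ranges,
            )
            hit = any(i in governed for i in range(ts, te))
            if not hit and rule.category is ModifierCategory.REVERSIBLE and \
                    target_rules[tri].category is TargetCategory.PERFUSION_FINDING:
                # single-space adjacency, or the cue inside its own head noun
                hit = me == ts or te == ms or (ms < te and ts < me)
            if hit:
                flags[CATEGORY_TO_FLAG[rule.category]] = True
        expected.append(flags)
    return tsel, expected


def test_context_engine_agrees_with_brute_force_oracle():
    """Randomized equivalence on sentences of <= 12 tokens: attribute
    assignment equals direct enumeration of (modifier, target) pairs with
    token-membership scope tests."""
    rng = random.Random(90210)
    n_cases = 10_000
    for _ in range(n_cases):
        text, target_rules, context_rules = random_context_setup(rng)
        words = text.split()
        tokens = tokenize(text)
        targets, _ = process_sentence(tokens, 0, target_rules, context_rules)
        tsel, expected = _oracle_attributes(words, target_rules, context_rules)
        assert len(targets) == len(tsel), (text,)
        for mention, flags in zip(targets, expected):
            got = {k: getattr(mention.attributes, k) for k in flags}
            assert got == flags, (text, mention.span.text,
                                  [r.pattern for r in context_rules])
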